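"""Synthetic populations with known ground truth, plus an exact maxent oracle.

Three generator families cover the regimes the framework is meant to probe:

* noisy two-input logic gates (AND/OR/XOR with flip probability ``epsilon``),
  available as exact weighted distributions or iid samples, with closed-form
  total and true entropies (S_true = H2(epsilon));
* planted logistic networks, where one neuron's activity is generated by a
  logistic function of a sparse subset of iid Bernoulli neurons — the
  parameter-recovery fixture for the fitter and the greedy selector;
* Ising / stochastic-Hopfield populations over {0,1} spins sampled by Gibbs
  sweeps.  With 0/1 spins the single-unit conditional is exactly the logistic
  model with weights equal to the corresponding coupling row, so conditional
  fits should recover the couplings.

``brute_force_maxent`` solves the same constrained maximum-entropy problem by
direct convex minimization of the enumerated dual (scipy L-BFGS-B) and serves
as an independent oracle for the sample-based fitter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .maxent import DEFAULT_CAP, LN2, DirectModel, binary_entropy_bits
from .raster import BinaryRaster, Raster, WeightedRaster, as_arrays

__all__ = [
    "LogicGateSpec",
    "GateTruth",
    "GroundTruthNetwork",
    "gen_logic_gate",
    "gen_logistic_network",
    "gen_ising",
    "brute_force_maxent",
    "planted_conditional_entropy",
]

_GATES: dict[str, Callable[[int, int], int]] = {
    "AND": lambda a, b: a & b,
    "OR": lambda a, b: a | b,
    "XOR": lambda a, b: a ^ b,
}


@dataclass(frozen=True)
class LogicGateSpec:
    """Two-input logic gate whose output is flipped with probability ``epsilon``."""

    gate: str
    epsilon: float
    input_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.gate not in _GATES:
            raise ValueError(f"gate must be one of {sorted(_GATES)}, got {self.gate!r}")
        if not 0.0 <= self.epsilon <= 0.5:
            raise ValueError(f"epsilon must lie in [0, 0.5], got {self.epsilon}")
        if not 0.0 < self.input_prob < 1.0:
            raise ValueError("input_prob must lie in (0, 1)")

    def fire_prob(self, x1: int, x2: int) -> float:
        """P(y=1 | x1, x2): the gate output with flip noise epsilon."""
        g = _GATES[self.gate](x1, x2)
        return (1.0 - self.epsilon) if g else self.epsilon

    @property
    def p_y(self) -> float:
        """Marginal firing probability of the noisy gate output."""
        q = self.input_prob
        probs = [(1 - q) * (1 - q), (1 - q) * q, q * (1 - q), q * q]
        return float(
            sum(
                w * self.fire_prob(x1, x2)
                for w, (x1, x2) in zip(probs, [(0, 0), (0, 1), (1, 0), (1, 1)])
            )
        )

    @property
    def s_tot_bits(self) -> float:
        return float(binary_entropy_bits(self.p_y))

    @property
    def s_true_bits(self) -> float:
        """Latent entropy: the flip noise alone, H2(epsilon)."""
        return float(binary_entropy_bits(self.epsilon))


@dataclass(frozen=True)
class GateTruth:
    """Closed-form entropies attached to a generated gate raster (bits)."""

    s_tot: float
    s_true: float
    p_y: float


def gen_logic_gate(
    spec: LogicGateSpec,
    mode: str = "exact",
    L: int | None = None,
    seed: int | None = None,
    dt: float = 1.0,
) -> tuple[Raster, GateTruth]:
    """Noisy logic gate population (neuron 0 = output y, neurons 1-2 = inputs).

    ``mode="exact"`` returns the full weighted joint distribution over
    (y, x1, x2) — up to 8 configurations, zero-weight ones dropped — so fits
    are free of sampling noise.  ``mode="sampled"`` draws L iid triples.
    """
    truth = GateTruth(spec.s_tot_bits, spec.s_true_bits, spec.p_y)
    ids = ("y", "x1", "x2")
    q = spec.input_prob
    if mode == "exact":
        cols, weights = [], []
        for x1 in (0, 1):
            for x2 in (0, 1):
                wx = (q if x1 else 1 - q) * (q if x2 else 1 - q)
                fp = spec.fire_prob(x1, x2)
                for y, wy in ((1, fp), (0, 1.0 - fp)):
                    if wx * wy > 0:
                        cols.append((y, x1, x2))
                        weights.append(wx * wy)
        values = np.array(cols, dtype=np.uint8).T
        return WeightedRaster(values, np.array(weights), dt, ids), truth
    if mode == "sampled":
        if L is None or seed is None:
            raise ValueError("sampled mode requires L and seed")
        rng = np.random.default_rng(seed)
        x = (rng.random((2, L)) < q).astype(np.uint8)
        g = np.array([_GATES[spec.gate](a, b) for a, b in zip(x[0], x[1])], dtype=np.uint8)
        flips = (rng.random(L) < spec.epsilon).astype(np.uint8)
        y = g ^ flips
        return BinaryRaster(np.vstack([y, x]), dt, ids), truth
    raise ValueError(f"mode must be 'exact' or 'sampled', got {mode!r}")


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Generating parameters behind a synthetic raster.

    ``kind="logistic"``: ``weights`` is the output neuron's planted weight
    vector aligned with ``planted_inputs``.  ``kind="ising"``: ``couplings``
    is the full symmetric J matrix and ``biases`` the fields h.
    """

    kind: str
    output: int | None = None
    planted_inputs: tuple[int, ...] = ()
    weights: np.ndarray | None = None
    bias: float | None = None
    input_rate: float | None = None
    couplings: np.ndarray | None = None
    biases: np.ndarray | None = None


def gen_logistic_network(
    n_neurons: int,
    planted_inputs: Sequence[int],
    weights: Sequence[float],
    bias: float,
    input_rate: float,
    L: int,
    seed: int,
    dt: float = 1.0,
    output: int = 0,
) -> tuple[BinaryRaster, GroundTruthNetwork]:
    """Population where neuron ``output`` is a logistic function of a planted subset.

    All non-output neurons are iid Bernoulli(``input_rate``); the output fires
    with probability sigma(bias + sum_i w_i x_i) over the planted inputs.
    """
    planted = tuple(int(i) for i in planted_inputs)
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(planted),):
        raise ValueError("one weight per planted input required")
    if output in planted or any(not 0 <= i < n_neurons for i in planted):
        raise ValueError("planted inputs must be valid non-output neuron indices")
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    values = (rng.random((n_neurons, L)) < input_rate).astype(np.uint8)
    field = bias + w @ values[list(planted)].astype(float)
    values[output] = (rng.random(L) < expit(field)).astype(np.uint8)
    truth = GroundTruthNetwork(
        "logistic",
        output=output,
        planted_inputs=planted,
        weights=w,
        bias=float(bias),
        input_rate=float(input_rate),
    )
    return BinaryRaster(values, dt), truth


def planted_conditional_entropy(truth: GroundTruthNetwork, raster: Raster) -> float:
    """Ground-truth S_true estimate (bits): <H2(p_true(x))> under the raster.

    Plugs the planted parameters into the logistic form and averages the
    conditional entropy over the empirical input distribution.
    """
    if truth.kind != "logistic":
        raise ValueError("conditional entropy is defined for planted logistic networks")
    values, wts, _ = as_arrays(raster)
    field = truth.bias + truth.weights @ values[list(truth.planted_inputs)].astype(float)
    return float(wts @ binary_entropy_bits(expit(field)))


# ---------------------------------------------------------------------------
# Ising / stochastic Hopfield sampler

try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _gibbs_kernel(J, h, L, burn_in, thin, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    N = J.shape[0]
    x = (np.random.random(N) < 0.5).astype(np.int8)
    out = np.empty((N, L), dtype=np.int8)
    total = burn_in + L * thin
    kept = 0
    for sweep in range(total):
        for i in range(N):
            f = h[i]
            for j in range(N):
                f += J[i, j] * x[j]
            p = 1.0 / (1.0 + np.exp(-f))
            x[i] = 1 if np.random.random() < p else 0
        if sweep >= burn_in and (sweep - burn_in + 1) % thin == 0:
            out[:, kept] = x
            kept += 1
    return out


def gen_ising(
    J: np.ndarray,
    h: np.ndarray,
    L: int,
    burn_in: int = 1000,
    thin: int = 5,
    seed: int = 0,
    dt: float = 1.0,
) -> tuple[BinaryRaster, GroundTruthNetwork]:
    """Gibbs samples from P(x) ~ exp(sum_i h_i x_i + sum_{i<j} J_ij x_i x_j), x in {0,1}^N.

    With 0/1 spins the conditional of unit i given the rest is exactly
    sigma(h_i + sum_j J_ij x_j), so conditional fits recover coupling rows
    without reparameterization.  One sweep updates every unit once; samples
    are taken every ``thin`` sweeps after ``burn_in`` sweeps.  Deterministic
    given ``seed``.
    """
    J = np.asarray(J, dtype=float)
    h = np.asarray(h, dtype=float)
    N = J.shape[0]
    if J.shape != (N, N) or h.shape != (N,):
        raise ValueError("J must be NxN and h length N")
    if not np.allclose(J, J.T):
        raise ValueError("Ising couplings must be symmetric")
    if np.abs(np.diag(J)).max() > 0:
        raise ValueError("Ising couplings must have zero diagonal")
    if burn_in < 1 or thin < 1 or L < 1:
        raise ValueError("burn_in, thin and L must be >= 1")
    values = _gibbs_kernel(J, h, L, burn_in, thin, seed).astype(np.uint8)
    truth = GroundTruthNetwork("ising", couplings=J, biases=h)
    return BinaryRaster(values, dt), truth


# ---------------------------------------------------------------------------
# exact oracle


def brute_force_maxent(
    input_configs: np.ndarray,
    config_weights: np.ndarray,
    output_conditional: np.ndarray,
    cap: float = DEFAULT_CAP,
) -> tuple[DirectModel, float]:
    """Exact maximum-entropy fit by convex minimization of the enumerated dual.

    ``input_configs`` is K x n distinct input configurations with probability
    ``config_weights``; ``output_conditional[k]`` is the generating
    P(y=1 | config k).  The dual F(b, w) = <ln Z> - b<y> - sum w_i <y x_i> is
    minimized with L-BFGS-B under box constraints |b|, |w_i| <= cap; its
    optimum value is S_dir in nats.  Returns the exact model (inputs indexed
    1..n after an output at index 0) and S_dir in bits.
    """
    X = np.asarray(input_configs, dtype=float)
    wts = np.asarray(config_weights, dtype=float)
    q = np.asarray(output_conditional, dtype=float)
    K, n = X.shape
    if K > 1024:
        raise ValueError(f"too many configurations to enumerate ({K} > 1024)")
    if wts.shape != (K,) or q.shape != (K,):
        raise ValueError("config_weights and output_conditional must have one entry per config")
    if not np.isclose(wts.sum(), 1.0):
        raise ValueError("config_weights must sum to 1")
    y_mean = float(wts @ q)
    corrs = X.T @ (wts * q)

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        b, w = theta[0], theta[1:]
        u = b + X @ w
        p = expit(u)
        f = float(wts @ np.logaddexp(0.0, u) - b * y_mean - w @ corrs)
        gb = float(wts @ p) - y_mean
        gw = X.T @ (wts * p) - corrs
        return f, np.concatenate(([gb], gw))

    theta0 = np.zeros(n + 1)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(-cap, cap)] * (n + 1),
        options={"maxiter": 10_000, "ftol": 1e-16, "gtol": 1e-12},
    )
    # polish to machine precision: L-BFGS-B stops ~1e-9 short of the entropy
    # identity; a few projected Newton steps on the enumerated dual finish it
    theta = res.x.copy()
    Xa = np.hstack([np.ones((K, 1)), X])
    _, g = objective(theta)
    for _ in range(50):
        viol = float(np.max(np.abs(g)))
        if viol < 1e-14:
            break
        pvec = expit(theta[0] + X @ theta[1:])
        v = wts * pvec * (1.0 - pvec)
        Hm = (Xa.T * v) @ Xa
        try:
            step = np.linalg.solve(Hm + 1e-14 * np.eye(n + 1), g)
        except np.linalg.LinAlgError:
            break
        new = np.clip(theta - step, -cap, cap)
        _, gn = objective(new)
        if float(np.max(np.abs(gn))) >= viol:
            break
        theta, g = new, gn
    b, w = float(theta[0]), theta[1:]
    model = DirectModel(
        output=0,
        inputs=tuple(range(1, n + 1)),
        bias=b,
        weights=w,
        converged=bool(res.success),
        max_violation=float(np.max(np.abs(g))),
    )
    s_dir_nats, _ = objective(theta)
    return model, s_dir_nats / LN2
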