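"""Maximum-entropy (logistic) models of a neuron's direct dependencies.

Given a binary output y and binary inputs x_1..x_n, the distribution with
maximum entropy consistent with the measured mean <y> and pairwise
correlations <y x_i> is the logistic neuron

    P(y=1 | x) = sigma(b + sum_i w_i x_i),

where sigma is the logistic function and the bias b and weights w_i are
Lagrange multipliers enforcing the constraints.  Parameters are found by
gradient descent on the KL divergence between data and model, whose
gradient components are exactly the constraint violations
<y>_P - <y> and <y x_i>_P - <y x_i>.

The model entropy (conditional entropy of the output given the inputs)
follows from the multipliers:

    S_dir = <ln Z(x)>_x - b <y> - sum_i w_i <y x_i>      (nats),

reported here in bits.  It sits in the hierarchy
S_tot >= S_dir >= S_true >= 0, and I_dir = S_tot - S_dir is the variability
explained by direct dependencies, a lower bound on the true input-output
mutual information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import entr, expit, logit

from .raster import Raster, as_arrays, eligible_inputs, empirical_stats

__all__ = [
    "DirectModel",
    "EntropyLedger",
    "fit",
    "model_entropy",
    "total_entropy",
    "ledger",
    "predict_pairwise",
    "binary_entropy_bits",
    "DEFAULT_CAP",
]

LN2 = float(np.log(2.0))

#: Box constraint |b|, |w_i| <= DEFAULT_CAP (natural-log-odds units).  Needed
#: for linearly separable data where the multipliers diverge (e.g. an exact
#: AND gate); the bias of a deterministic gate sits near -(sum of active
#: weights), so the cap is set high enough that capped solutions still satisfy
#: the constraints to ~1e-9.
DEFAULT_CAP = 60.0


def binary_entropy_bits(p: np.ndarray | float) -> np.ndarray | float:
    """H2(p) in bits, with 0*log(0) = 0."""
    p = np.asarray(p, dtype=float)
    h = (entr(p) + entr(1.0 - p)) / LN2
    return h if h.ndim else float(h)


@dataclass(frozen=True)
class DirectModel:
    """Fitted logistic maximum-entropy model for one output neuron.

    ``bias`` and ``weights`` are in natural-log-odds units.  ``max_violation``
    is the worst absolute constraint mismatch |<y x_i>_P - <y x_i>| (or the
    mean constraint) at termination; ``converged`` means it fell below the
    fitting tolerance.
    """

    output: int
    inputs: tuple[int, ...]
    bias: float
    weights: np.ndarray
    converged: bool
    max_violation: float
    n_iter: int = 0
    dt: float | None = None
    L: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.weights.shape != (len(self.inputs),):
            raise ValueError("one weight per input required")

    def fields(self, raster: Raster) -> np.ndarray:
        """Per-sample linear field b + sum_i w_i x_i."""
        values, _, _ = as_arrays(raster)
        u = np.full(values.shape[1], self.bias)
        if self.inputs:
            u = u + self.weights @ values[list(self.inputs)].astype(float)
        return u

    def predict_proba(self, raster: Raster) -> np.ndarray:
        """Per-sample firing probability P(y=1 | x(l))."""
        return expit(self.fields(raster))

    def to_dict(self) -> dict:
        return {
            "output": self.output,
            "inputs": list(self.inputs),
            "bias": self.bias,
            "weights": self.weights.tolist(),
            "converged": bool(self.converged),
            "max_violation": self.max_violation,
            "dt": self.dt,
            "L": self.L,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "DirectModel":
        return cls(
            output=int(d["output"]),
            inputs=tuple(int(i) for i in d["inputs"]),
            bias=float(d["bias"]),
            weights=np.asarray(d["weights"], dtype=float),
            converged=bool(d["converged"]),
            max_violation=float(d["max_violation"]),
            dt=d.get("dt"),
            L=d.get("L"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "DirectModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class EntropyLedger:
    """Entropy decomposition (bits) for one fitted output neuron.

    ``s_true``/``i_true`` are available only for synthetic data with known
    ground truth; the hierarchy s_tot >= s_dir >= s_true always holds up to
    fitting tolerance.
    """

    s_tot: float
    s_dir: float
    i_dir: float
    s_true: float | None = None
    i_true: float | None = None


def default_tolerance(pair_sigmas: np.ndarray) -> float:
    """Convergence tolerance: min(1e-6, 0.1 * smallest Poisson sigma).

    Keeping the fit an order of magnitude below the error bars guarantees a
    fitted correlation can never fail the 2-sigma prediction test.
    """
    if pair_sigmas.size == 0:
        return 1e-6
    return float(min(1e-6, 0.1 * pair_sigmas.min()))


def fit(
    raster: Raster,
    output: int,
    inputs: Sequence[int] = (),
    *,
    tolerance: float | None = None,
    max_iters: int = 100_000,
    cap: float = DEFAULT_CAP,
    init: tuple[float, np.ndarray] | None = None,
    check_eligibility: bool = True,
) -> DirectModel:
    """Fit the logistic maximum-entropy model by descent on the KL divergence.

    The dual objective <ln Z>_x - b<y> - sum_i w_i <y x_i> is convex with
    gradient components exactly equal to the constraint violations
    (<y>_P - <y> and <y x_i>_P - <y x_i>).  Full-batch damped Newton steps
    (the Hessian of ln Z is the (n+1)x(n+1) model covariance of the
    constraints) with a backtracking line search guarantee monotone descent;
    when the Hessian is numerically singular the step falls back to the
    gradient scaled by the inverse diagonal curvature.  Parameters are
    clipped to ``[-cap, cap]``.  Returns the model with ``converged=False``
    rather than raising when ``max_iters`` is exhausted.

    ``init`` warm-starts from ``(bias, weights)`` (used by greedy selection);
    by default b = logit(<y>) clipped and w = 0, which satisfies the mean
    constraint immediately.
    """
    inputs = tuple(int(i) for i in inputs)
    stats = empirical_stats(raster, output, inputs)
    if check_eligibility and inputs:
        elig = eligible_inputs(raster, output)
        bad = [i for i in inputs if i not in elig]
        if bad:
            raise ValueError(
                f"inputs {bad} never co-activate with output {output} "
                "(correlation 0); the multiplier would diverge"
            )
    if tolerance is None:
        tolerance = default_tolerance(stats.pair_sigmas)

    values, wts, L = as_arrays(raster)
    y_mean = stats.output_mean
    corrs = stats.pair_corrs
    n = len(inputs)
    X = values[list(inputs)].astype(float) if n else np.zeros((0, values.shape[1]))

    if init is not None:
        b = float(np.clip(init[0], -cap, cap))
        w = np.clip(np.asarray(init[1], dtype=float).copy(), -cap, cap)
        if w.shape != (n,):
            raise ValueError("init weights must match the number of inputs")
    else:
        with np.errstate(divide="ignore"):
            b = float(np.clip(logit(y_mean), -cap, cap))
        w = np.zeros(n)

    K = values.shape[1]

    def field(b: float, w: np.ndarray) -> np.ndarray:
        return b + w @ X if n else np.full(K, float(b))

    def dual(b: float, w: np.ndarray) -> float:
        return float(wts @ np.logaddexp(0.0, field(b, w)) - b * y_mean - w @ corrs)

    Xa = np.vstack([np.ones(K), X])  # constraint features incl. bias
    targets = np.concatenate(([y_mean], corrs))
    u = field(b, w)
    F = dual(b, w)
    viol = np.inf
    it = 0
    for it in range(1, max_iters + 1):
        p = expit(u)
        grad = Xa @ (wts * p) - targets
        viol = float(np.max(np.abs(grad)))
        if viol <= tolerance:
            return DirectModel(output, inputs, b, w, True, viol, it - 1, raster.dt, L)
        v = wts * p * (1.0 - p)
        H = (Xa * v) @ Xa.T
        diag = np.diag(H)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(n + 1), grad)
            if not np.all(np.isfinite(step)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            # singular curvature (saturated probabilities): inverse-diagonal
            # scaling, unit step where the diagonal has collapsed too
            step = np.where(diag >= 1e-12, grad / np.maximum(diag, 1e-12), grad)
        lam = 1.0
        accepted = False
        for _ in range(60):
            theta = np.clip(np.concatenate(([b], w)) - lam * step, -cap, cap)
            nb, nw = float(theta[0]), theta[1:]
            nF = dual(nb, nw)
            if nF < F:
                accepted = True
                break
            if lam == 1.0:
                # near the optimum the dual decrease falls below float
                # resolution; accept a full step that still shrinks the
                # worst constraint violation (Newton contracts it)
                nu = field(nb, nw)
                nviol = float(np.max(np.abs(Xa @ (wts * expit(nu)) - targets)))
                if nviol < viol:
                    accepted = True
                    break
            lam *= 0.5
        if not accepted:
            # neither the dual nor the violation can be improved: numerically
            # at the (possibly box-constrained) optimum
            break
        b, w, F = nb, nw, nF
        u = field(b, w)
    return DirectModel(output, inputs, b, w, viol <= tolerance, viol, it, raster.dt, L)


def total_entropy(raster: Raster, output: int) -> float:
    """Total output variability S_tot = H2(<y>) in bits (no input knowledge)."""
    stats = empirical_stats(raster, output, ())
    return float(binary_entropy_bits(stats.output_mean))


def model_entropy(model: DirectModel, raster: Raster) -> float:
    """Model entropy S_dir in bits via the multiplier identity.

    Evaluates (<ln Z(x)>_x - b<y> - sum_i w_i <y x_i>)/ln 2 with empirical
    averages from ``raster``; equal to the average conditional entropy
    <H2(p(x))>_x when the constraints hold exactly.
    """
    stats = empirical_stats(raster, model.output, model.inputs)
    _, wts, _ = as_arrays(raster)
    u = model.fields(raster)
    s_nats = float(
        wts @ np.logaddexp(0.0, u)
        - model.bias * stats.output_mean
        - model.weights @ stats.pair_corrs
    )
    return s_nats / LN2


def ledger(model: DirectModel, raster: Raster, s_true: float | None = None) -> EntropyLedger:
    """Entropy decomposition for a fitted model; ground-truth entries optional."""
    s_tot = total_entropy(raster, model.output)
    s_dir = model_entropy(model, raster)
    i_true = s_tot - s_true if s_true is not None else None
    return EntropyLedger(s_tot, s_dir, s_tot - s_dir, s_true, i_true)


def predict_pairwise(model: DirectModel, raster: Raster, neuron: int) -> float:
    """Model-predicted co-activity rate <y x_j>_P for any neuron j != output.

    j need not be a model input; for inputs of a converged model this equals
    the measured correlation within the fitting tolerance.
    """
    if neuron == model.output:
        raise ValueError("cannot predict the output's correlation with itself")
    values, wts, _ = as_arrays(raster)
    if not 0 <= neuron < values.shape[0]:
        raise IndexError(f"neuron index {neuron} out of range")
    p = model.predict_proba(raster)
    return float((wts * p) @ values[neuron].astype(float))
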