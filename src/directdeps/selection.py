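"""Greedy minimax-entropy selection of a neuron's optimal inputs.

The optimal inputs of an output neuron are the ones whose maximum-entropy
model has *minimum* entropy S_dir — i.e. is most predictive.  An exhaustive
search over input subsets is intractable, so inputs are grown greedily:
starting from the independent (no-input) model, each step adds the candidate
that lowers S_dir the most, either by refitting a model per candidate
(``mode="exact"``) or by a second-order perturbative estimate of the drop
(``mode="approx"``), and then refits the full model.

Selection stops at ``n*``: the first step at which the model predicts the
correlation <y x_i> of every remaining eligible neuron within two Poisson
standard deviations.  Beyond n* another input would only fit statistical
noise, so n* acts as the model's regularizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np

from .maxent import LN2, DirectModel, default_tolerance, fit, model_entropy
from .raster import Raster, as_arrays, eligible_inputs, empirical_stats, pair_sigma

__all__ = [
    "SelectionTrace",
    "StoppingCheck",
    "delta_entropy_estimate",
    "greedy_select",
    "stopping_rule",
    "random_baseline",
]


@dataclass(frozen=True)
class StoppingCheck:
    """Result of the n* test: are all unfitted correlations predicted?"""

    passes: bool
    worst_neuron: int | None
    worst_z: float


@dataclass
class SelectionTrace:
    """Record of a greedy selection run.

    ``s_dir_per_step[k]`` is S_dir (bits) after k inputs (step 0 = independent
    model); ``delta_estimates[k]`` is the score that selected input k+1.
    ``n_star`` is set when the stopping rule first passes; ``model`` is the
    final fitted model.
    """

    output: int
    chosen: list[int]
    s_dir_per_step: list[float]
    delta_estimates: list[float]
    n_star: int | None
    stop_reason: str
    model: DirectModel
    mode: str = "approx"

    def to_frame(self):
        import pandas as pd

        steps = range(len(self.s_dir_per_step))
        return pd.DataFrame(
            {
                "step": list(steps),
                "chosen_neuron": [None] + self.chosen,
                "s_dir_bits": self.s_dir_per_step,
                "delta_estimate_bits": [None] + self.delta_estimates,
            }
        )

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.tsv`` (per-step trace) and ``<prefix>.json`` summary."""
        prefix = Path(prefix)
        self.to_frame().to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
        summary = {"output": self.output, "n_star": self.n_star, "stop_reason": self.stop_reason}
        prefix.with_suffix(".json").write_text(json.dumps(summary, indent=1))


def delta_entropy_estimate(
    model: DirectModel, raster: Raster, candidate: int, **fit_options
) -> float:
    """Perturbative estimate of the S_dir drop from adding ``candidate`` (bits, <= 0).

    Expanding the entropy to second order in the candidate's prediction error
    Delta = <y x_c> - <y x_c>_P gives Delta_S ~ -Delta^2 / (2 chi_eff ln 2).
    chi_eff is the candidate constraint's *effective* susceptibility: its
    model variance <x_c p (1-p)>_x minus the Schur correction c' H^-1 c for
    its covariance c with the constraints already enforced (H is their
    curvature).  Without that correction the drop is systematically
    underestimated, because re-balancing the existing multipliers absorbs
    part of the prediction error.  When chi_eff has collapsed (the candidate
    fires only where p is saturated) the exact refit drop is returned
    instead.
    """
    if candidate in model.inputs:
        raise ValueError(f"candidate {candidate} is already a model input")
    if candidate == model.output:
        raise ValueError("candidate cannot be the output neuron")
    if candidate not in eligible_inputs(raster, model.output):
        raise ValueError(f"candidate {candidate} never co-activates with the output")
    values, wts, _ = as_arrays(raster)
    p = model.predict_proba(raster)
    xc = values[candidate].astype(float)
    measured = float((wts * values[model.output].astype(float)) @ xc)
    predicted = float((wts * p) @ xc)
    delta = measured - predicted
    v = wts * p * (1.0 - p)
    chi = float(xc @ v)
    Xa = np.vstack([np.ones(values.shape[1]), values[list(model.inputs)].astype(float)])
    H = (Xa * v) @ Xa.T
    c = Xa @ (v * xc)
    try:
        chi_eff = chi - float(c @ np.linalg.solve(H + 1e-14 * np.eye(H.shape[0]), c))
    except np.linalg.LinAlgError:
        chi_eff = 0.0
    if chi_eff < 1e-12:
        refit = fit(
            raster,
            model.output,
            model.inputs + (candidate,),
            init=(model.bias, np.append(model.weights, 0.0)),
            **fit_options,
        )
        return model_entropy(refit, raster) - model_entropy(model, raster)
    return -(delta * delta) / (2.0 * chi_eff * LN2)


def stopping_rule(model: DirectModel, raster: Raster) -> StoppingCheck:
    """Does the model predict every remaining eligible correlation within 2 sigma?

    Tested over neurons with <y x_i> > 0 that are not already inputs (fitted
    correlations match to well below sigma by the convergence tolerance).
    Passes vacuously when no eligible neuron remains.
    """
    values, wts, L = as_arrays(raster)
    remaining = sorted(eligible_inputs(raster, model.output) - set(model.inputs))
    if not remaining:
        return StoppingCheck(True, None, 0.0)
    X = values[remaining].astype(float)
    y = values[model.output].astype(float)
    measured = X @ (wts * y)
    p = model.predict_proba(raster)
    predicted = X @ (wts * p)
    sig = pair_sigma(measured, L)
    z = np.abs(measured - predicted) / sig
    worst = int(np.argmax(z))
    return StoppingCheck(bool(np.all(z <= 2.0)), remaining[worst], float(z[worst]))


def _refit_with(model: DirectModel, raster: Raster, candidate: int, **fit_options) -> DirectModel:
    """Warm-started full refit after accepting ``candidate``."""
    return fit(
        raster,
        model.output,
        model.inputs + (candidate,),
        init=(model.bias, np.append(model.weights, 0.0)),
        check_eligibility=False,
        **fit_options,
    )


def greedy_select(
    raster: Raster,
    output: int,
    budget: int | None = None,
    mode: str = "approx",
    *,
    use_stopping: bool = True,
    **fit_options,
) -> SelectionTrace:
    """Greedily grow the minimax-entropy input set for ``output``.

    At each step the candidate minimizing the (estimated or exact-refit)
    model entropy is accepted, the full model is refit from a warm start, and
    the stopping rule is evaluated.  Stops when the stopping rule passes
    (``stop_reason="predicted_all"``), the candidate pool empties
    (``"exhausted"``), or ``budget`` inputs have been chosen (``"budget"``).
    Ties are broken toward the lowest neuron index for reproducibility.
    """
    if mode not in ("approx", "exact"):
        raise ValueError(f"mode must be 'approx' or 'exact', got {mode!r}")
    if budget is not None and budget < 0:
        raise ValueError("budget must be nonnegative")
    elig = sorted(eligible_inputs(raster, output))
    model = fit(raster, output, (), **fit_options)
    s = model_entropy(model, raster)
    chosen: list[int] = []
    s_steps = [s]
    deltas: list[float] = []
    n_star: int | None = None
    stop_reason = "exhausted"

    if use_stopping and stopping_rule(model, raster).passes:
        return SelectionTrace(output, chosen, s_steps, deltas, 0, "predicted_all", model, mode)

    while True:
        remaining = [i for i in elig if i not in chosen]
        if not remaining:
            stop_reason = "exhausted"
            break
        if budget is not None and len(chosen) >= budget:
            stop_reason = "budget"
            break
        if mode == "approx":
            scores = [delta_entropy_estimate(model, raster, c, **fit_options) for c in remaining]
            best = int(np.argmin(scores))  # argmin takes first on ties -> lowest index
            cand, score = remaining[best], scores[best]
            model = _refit_with(model, raster, cand, **fit_options)
        else:
            refits = [_refit_with(model, raster, c, **fit_options) for c in remaining]
            entropies = [model_entropy(m, raster) for m in refits]
            best = int(np.argmin(entropies))
            cand, score = remaining[best], entropies[best] - s
            model = refits[best]
        chosen.append(cand)
        deltas.append(float(score))
        s = model_entropy(model, raster)
        s_steps.append(s)
        if use_stopping and stopping_rule(model, raster).passes:
            n_star = len(chosen)
            stop_reason = "predicted_all"
            break
    return SelectionTrace(output, chosen, s_steps, deltas, n_star, stop_reason, model, mode)


def random_baseline(
    raster: Raster, output: int, n: int, seed: int, **fit_options
) -> DirectModel:
    """Control model on ``n`` inputs drawn uniformly (without replacement) from the eligible pool."""
    elig = sorted(eligible_inputs(raster, output))
    if n > len(elig):
        raise ValueError(f"requested {n} random inputs but only {len(elig)} are eligible")
    rng = np.random.default_rng(seed)
    picks = tuple(sorted(rng.choice(elig, size=n, replace=False).tolist())) if n else ()
    return fit(raster, output, picks, check_eligibility=False, **fit_options)
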