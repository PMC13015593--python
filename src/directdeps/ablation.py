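"""Input ablation by marginalization, without refitting.

Removing inputs from a fitted model marginalizes the firing probability over
the removed inputs' activity under the empirical input distribution Q(x):

    P~(y=1 | x_kept) = sum_{x_removed} P(y=1 | x) Q(x) / sum_{x_removed} Q(x).

With empirical Q this is exactly the weighted mean of the per-sample firing
probability p(l) over the samples sharing a kept-input configuration; the
model parameters are untouched.  The surviving mutual information is
S_tot - sum_c Q(c) H2(P~(y=1|c)), and the prediction error is the average
probability the ablated model assigns to the *wrong* output state.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np
import pandas as pd

from .maxent import DirectModel, binary_entropy_bits, total_entropy
from .raster import Raster, as_arrays

__all__ = [
    "AblatedModel",
    "ablate",
    "ablated_information",
    "prediction_error",
    "ablation_curves",
]


@dataclass(frozen=True)
class AblatedModel:
    """Marginalized predictor over kept-input configurations.

    ``table`` maps each kept-input configuration observed in the raster to
    ``(P~(y=1|c), empirical weight)``; weights sum to 1.  ``marginal`` is the
    model's overall firing probability, used as a documented fallback for
    configurations unseen at table-building time (possible only on held-out
    rasters).
    """

    base: DirectModel
    removed: frozenset[int]
    kept: tuple[int, ...]
    table: dict[tuple[int, ...], tuple[float, float]]
    marginal: float

    def predict_proba(self, raster: Raster) -> np.ndarray:
        """Per-sample P~(y=1 | kept configuration)."""
        values, _, _ = as_arrays(raster)
        configs = values[list(self.kept)].T if self.kept else np.zeros((values.shape[1], 0), int)
        out = np.empty(values.shape[1])
        for l, row in enumerate(configs):
            out[l] = self.table.get(tuple(int(v) for v in row), (self.marginal, 0.0))[0]
        return out


def ablate(model: DirectModel, raster: Raster, removed: Sequence[int]) -> AblatedModel:
    """Marginalize ``model`` over the ``removed`` inputs' empirical activity."""
    removed_set = frozenset(int(i) for i in removed)
    if not removed_set <= set(model.inputs):
        extra = sorted(removed_set - set(model.inputs))
        raise ValueError(f"cannot ablate {extra}: not inputs of the model")
    kept = tuple(i for i in model.inputs if i not in removed_set)
    values, wts, _ = as_arrays(raster)
    p = model.predict_proba(raster)
    marginal = float(wts @ p)
    if kept:
        configs = values[list(kept)].T
        uniq, inverse = np.unique(configs, axis=0, return_inverse=True)
        table: dict[tuple[int, ...], tuple[float, float]] = {}
        for c in range(uniq.shape[0]):
            mask = inverse == c
            weight = float(wts[mask].sum())
            ptilde = float(wts[mask] @ p[mask]) / weight
            table[tuple(int(v) for v in uniq[c])] = (ptilde, weight)
    else:
        table = {(): (marginal, 1.0)}
    return AblatedModel(model, removed_set, kept, table, marginal)


def ablated_information(ablated: AblatedModel, raster: Raster) -> float:
    """Mutual information (bits) surviving ablation: S_tot - <H2(P~)>_c."""
    s_tot = total_entropy(raster, ablated.base.output)
    cond = sum(w * binary_entropy_bits(pt) for pt, w in ablated.table.values())
    return s_tot - cond


def prediction_error(ablated: AblatedModel, raster: Raster) -> float:
    """Average probability the ablated model assigns to the wrong output state."""
    values, wts, _ = as_arrays(raster)
    y = values[ablated.base.output].astype(float)
    pt = ablated.predict_proba(raster)
    correct = np.where(y == 1.0, pt, 1.0 - pt)
    return float(wts @ (1.0 - correct))


def ablation_curves(
    models: Sequence[DirectModel],
    raster: Raster,
    fractions: Sequence[float],
    repeats: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Information and prediction-error curves under random input removal.

    For each fraction f, each model loses a uniformly random ceil(f * n)
    subset of its own n inputs; information and error are averaged over all
    models and ``repeats`` random realizations.  Deterministic given ``seed``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fractions must lie in [0, 1], got {f}")
        infos, errors = [], []
        for _ in range(repeats):
            for model in models:
                n = len(model.inputs)
                k = ceil(f * n)
                removed = (
                    tuple(rng.choice(model.inputs, size=k, replace=False).tolist()) if k else ()
                )
                abl = ablate(model, raster, removed)
                infos.append(ablated_information(abl, raster))
                errors.append(prediction_error(abl, raster))
        rows.append(
            {
                "fraction_removed": f,
                "fraction_remaining": 1.0 - f,
                "mean_information_bits": float(np.mean(infos)),
                "mean_prediction_error": float(np.mean(errors)),
                "n_outputs": len(models),
                "repeats": repeats,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
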