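"""Predicting higher-order and time-delayed co-activity from a fitted model.

A model constrained only by pairwise, same-time correlations still predicts
the co-activity of the output with *groups* of neurons,

    <y x_j1 ... x_jk>_P = <p(x) x_j1 ... x_jk>_x ,

and with past activity, <y(t) x_i(t - tau)>_P = <p(t) x_i(t - tau)>.  If
these predictions match the data within error bars, the corresponding k-th
order and time-delayed dependencies carry no information beyond the direct
dependencies.  Agreement is scored per entry at two Poisson standard
deviations; a report's ``fraction_unexplained`` is the share of entries
outside that band.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Sequence

import json

import numpy as np
import pandas as pd

from .maxent import DirectModel
from .raster import BinaryRaster, Raster, as_arrays, pair_sigma

__all__ = [
    "CorrelationReport",
    "predict_higher_order",
    "measured_higher_order",
    "predict_time_delayed",
    "measured_time_delayed",
    "score_report",
    "sample_subsets",
    "higher_order_report",
    "time_delayed_report",
]


@dataclass
class CorrelationReport:
    """Measured vs model-predicted co-activity rates with 2-sigma verdicts."""

    kind: str  # e.g. "order-3" or "delay-5"
    entries: pd.DataFrame  # columns: label, measured, predicted, sigma, within_2sigma
    fraction_unexplained: float

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.entries.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
        summary = {
            "kind": self.kind,
            "fraction_unexplained": self.fraction_unexplained,
            "n_entries": self.n_entries,
        }
        prefix.with_suffix(".json").write_text(json.dumps(summary, indent=1))


def _subset_product(raster: Raster, subset: Sequence[int]) -> np.ndarray:
    values, _, _ = as_arrays(raster)
    return values[list(subset)].astype(float).prod(axis=0)


def predict_higher_order(model: DirectModel, raster: Raster, subset: Sequence[int]) -> float:
    """Predicted k-neuron co-activity rate <y * prod_j x_j>_P.

    Subset members need not be model inputs; with a single-element subset this
    reduces exactly to the pairwise prediction.
    """
    subset = tuple(int(j) for j in subset)
    if model.output in subset:
        raise ValueError("subset must not contain the output neuron")
    _, wts, _ = as_arrays(raster)
    p = model.predict_proba(raster)
    return float((wts * p) @ _subset_product(raster, subset))


def measured_higher_order(raster: Raster, output: int, subset: Sequence[int]) -> float:
    """Measured co-activity rate <y * prod_j x_j> over the raster."""
    subset = tuple(int(j) for j in subset)
    if output in subset:
        raise ValueError("subset must not contain the output neuron")
    values, wts, _ = as_arrays(raster)
    y = values[output].astype(float)
    return float((wts * y) @ _subset_product(raster, subset))


def _require_sampled(raster: Raster) -> None:
    if not isinstance(raster, BinaryRaster):
        raise TypeError("time-delayed correlations require an ordered (sampled) raster")


def predict_time_delayed(model: DirectModel, raster: BinaryRaster, neuron: int, tau: int) -> float:
    """Predicted delayed co-activity <y(t) x_i(t - tau)>_P, averaged over t = tau..L-1.

    The firing probability p(t) uses the same-time inputs only; assuming
    stationarity, both the prediction and its measured counterpart are
    averaged over the overlapping window of length L - tau.
    """
    _require_sampled(raster)
    L = raster.n_bins
    if not 0 <= tau < L:
        raise ValueError(f"tau must be in [0, L); got tau={tau}, L={L}")
    p = model.predict_proba(raster)
    x = raster.values[neuron].astype(float)
    if tau == 0:
        return float(np.mean(p * x))
    return float(np.mean(p[tau:] * x[:-tau]))


def measured_time_delayed(raster: BinaryRaster, output: int, neuron: int, tau: int) -> float:
    """Measured delayed co-activity <y(t) x_i(t - tau)> over the same window."""
    _require_sampled(raster)
    L = raster.n_bins
    if not 0 <= tau < L:
        raise ValueError(f"tau must be in [0, L); got tau={tau}, L={L}")
    y = raster.values[output].astype(float)
    x = raster.values[neuron].astype(float)
    if tau == 0:
        return float(np.mean(y * x))
    return float(np.mean(y[tau:] * x[:-tau]))


def score_report(
    measured: Sequence[float],
    predicted: Sequence[float],
    sigmas: Sequence[float],
    labels: Sequence | None = None,
    kind: str = "generic",
) -> CorrelationReport:
    """Score measured vs predicted rates: an entry is explained iff |m - p| <= 2 sigma."""
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if not (measured.shape == predicted.shape == sigmas.shape):
        raise ValueError("measured, predicted and sigmas must have equal lengths")
    if measured.size == 0:
        raise ValueError("cannot score an empty report (fraction undefined)")
    if (sigmas <= 0).any():
        raise ValueError("sigmas must be strictly positive")
    within = np.abs(measured - predicted) <= 2.0 * sigmas
    if labels is None:
        labels = list(range(measured.size))
    entries = pd.DataFrame(
        {
            "label": [str(l) for l in labels],
            "measured": measured,
            "predicted": predicted,
            "sigma": sigmas,
            "within_2sigma": within,
        }
    )
    return CorrelationReport(kind, entries, float(1.0 - within.mean()))


def sample_subsets(
    raster: Raster, output: int, k: int, count: int, seed: int
) -> list[tuple[int, ...]]:
    """``count`` distinct uniformly random k-subsets of the non-output neurons."""
    N = raster.n_neurons
    candidates = [i for i in range(N) if i != output]
    if k < 1 or k > len(candidates):
        raise ValueError(f"subset size {k} not in [1, {len(candidates)}]")
    total = comb(len(candidates), k)
    if count > total:
        raise ValueError(f"requested {count} subsets but only {total} distinct ones exist")
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    while len(out) < count:
        pick = tuple(sorted(rng.choice(candidates, size=k, replace=False).tolist()))
        if pick not in seen:
            seen.add(pick)
            out.append(pick)
    return out


def higher_order_report(
    model: DirectModel, raster: Raster, k: int, count: int, seed: int
) -> CorrelationReport:
    """Score ``count`` random order-(k+1) correlations <y x_j1 .. x_jk> against the model."""
    _, _, L = as_arrays(raster)
    subsets = sample_subsets(raster, model.output, k, count, seed)
    measured = [measured_higher_order(raster, model.output, s) for s in subsets]
    predicted = [predict_higher_order(model, raster, s) for s in subsets]
    sigmas = pair_sigma(np.asarray(measured), L)
    labels = ["+".join(map(str, s)) for s in subsets]
    return score_report(measured, predicted, sigmas, labels, kind=f"order-{k}")


def time_delayed_report(
    model: DirectModel, raster: BinaryRaster, tau: int, neurons: Sequence[int] | None = None
) -> CorrelationReport:
    """Score delayed correlations at lag ``tau`` for each given neuron (default: all others)."""
    _require_sampled(raster)
    if neurons is None:
        neurons = [i for i in range(raster.n_neurons) if i != model.output]
    window = raster.n_bins - tau
    measured = [measured_time_delayed(raster, model.output, i, tau) for i in neurons]
    predicted = [predict_time_delayed(model, raster, i, tau) for i in neurons]
    sigmas = pair_sigma(np.asarray(measured), window)
    return score_report(measured, predicted, sigmas, list(neurons), kind=f"delay-{tau}")
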