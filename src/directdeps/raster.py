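"""Binarized population rasters and their empirical statistics.

A raster is an N-neuron x L-time-bin matrix of {0,1} activity with a bin
width ``dt`` in seconds.  Time bins are half-open intervals
``[t*dt, (t+1)*dt)`` and all indices are 0-based.  Two on-disk dialects are
supported (no community standard exists for binarized rasters):

* dense  -- whitespace- or comma-delimited text, one neuron per row;
* sparse -- two-column TSV of ``neuron_index<TAB>bin_index`` events.

A :class:`WeightedRaster` holds distinct activity configurations with
probability weights instead of raw samples, so exact analytic distributions
(e.g. noisy logic gates) can stand in for sampled data; every empirical
average then becomes a weighted average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BinaryRaster",
    "WeightedRaster",
    "EmpiricalStats",
    "load_raster",
    "save_raster",
    "empirical_stats",
    "eligible_inputs",
    "significant_correlations",
    "pair_sigma",
]


def _validate_binary(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError(f"raster values must be 2-D (neurons x bins), got shape {values.shape}")
    if values.size == 0:
        raise ValueError("raster must contain at least one neuron and one time bin")
    if not np.isin(values, (0, 1)).all():
        bad = values[~np.isin(values, (0, 1))].flat[0]
        raise ValueError(f"raster entries must be 0 or 1, found {bad!r}")
    return values.astype(np.uint8)


def _default_ids(n: int) -> tuple[str, ...]:
    return tuple(f"n{i}" for i in range(n))


@dataclass(frozen=True)
class BinaryRaster:
    """N x L matrix of binarized activity samples with bin width ``dt`` (s)."""

    values: np.ndarray
    dt: float
    neuron_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _validate_binary(self.values))
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        ids = tuple(self.neuron_ids) or _default_ids(self.n_neurons)
        if len(ids) != self.n_neurons:
            raise ValueError("neuron_ids length does not match number of neurons")
        if len(set(ids)) != len(ids):
            raise ValueError("neuron_ids must be unique")
        object.__setattr__(self, "neuron_ids", ids)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        """Sample count used for Poisson error bars (= number of bins)."""
        return self.values.shape[1]

    def column_weights(self) -> np.ndarray:
        """Per-bin probability weight: uniform 1/L for sampled rasters."""
        L = self.n_bins
        return np.full(L, 1.0 / L)

    def duplicated(self, times: int = 2) -> "BinaryRaster":
        """Raster with every time bin repeated ``times`` times (L -> times*L)."""
        return BinaryRaster(np.repeat(self.values, times, axis=1), self.dt, self.neuron_ids)


@dataclass(frozen=True)
class WeightedRaster:
    """Distinct activity configurations with probability weights.

    ``values`` is N neurons x K configurations; ``weights`` sums to 1.
    ``n_samples`` (optional) is the sample count behind the weights, used for
    Poisson error bars; when absent, K is used, which yields wide
    (conservative) error bars appropriate for exact analytic distributions.
    """

    values: np.ndarray
    weights: np.ndarray
    dt: float = 1.0
    neuron_ids: tuple[str, ...] = ()
    n_samples_: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _validate_binary(self.values))
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.shape[0] != self.values.shape[1]:
            raise ValueError("weights must be 1-D with one entry per configuration")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError(f"weights must sum to 1, got {w.sum()}")
        object.__setattr__(self, "weights", w)
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        ids = tuple(self.neuron_ids) or _default_ids(self.n_neurons)
        if len(ids) != self.n_neurons or len(set(ids)) != len(ids):
            raise ValueError("neuron_ids must be unique and match the number of neurons")
        object.__setattr__(self, "neuron_ids", ids)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_configs(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.n_samples_ if self.n_samples_ is not None else self.n_configs

    def column_weights(self) -> np.ndarray:
        return self.weights


Raster = BinaryRaster | WeightedRaster


def as_arrays(raster: Raster) -> tuple[np.ndarray, np.ndarray, int]:
    """Uniform view (values, column weights, sample count) of either raster kind."""
    return raster.values, raster.column_weights(), raster.n_samples


# ---------------------------------------------------------------------------
# file formats


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def save_raster(raster: BinaryRaster, path: str | Path, format: str = "dense") -> None:
    """Write a raster plus a JSON metadata sidecar ``<path>.json``."""
    path = Path(path)
    if format == "dense":
        np.savetxt(path, raster.values, fmt="%d")
    elif format == "sparse":
        neuron, bins = np.nonzero(raster.values)
        with open(path, "w") as fh:
            for i, t in zip(neuron, bins):
                fh.write(f"{i}\t{t}\n")
    else:
        raise ValueError(f"unknown raster format {format!r}")
    meta = {
        "dt": raster.dt,
        "n_neurons": raster.n_neurons,
        "n_bins": raster.n_bins,
        "neuron_ids": list(raster.neuron_ids),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh)


def load_raster(
    path: str | Path,
    format: str = "dense",
    dt: float | None = None,
    n_neurons: int | None = None,
    n_bins: int | None = None,
) -> BinaryRaster:
    """Load a raster; a ``<path>.json`` sidecar supplies missing metadata.

    Dense files are delimited text (whitespace or comma), one neuron per row.
    Sparse files are two-column ``neuron<TAB>bin`` event lists and require
    ``n_neurons`` and ``n_bins`` (explicitly or via sidecar); duplicate events
    are tolerated (idempotent), out-of-range indices are an error.
    """
    path = Path(path)
    meta: dict = {}
    if _sidecar_path(path).exists():
        meta = json.loads(_sidecar_path(path).read_text())
    dt = dt if dt is not None else meta.get("dt")
    if dt is None:
        raise ValueError("dt must be given explicitly or via a metadata sidecar")
    neuron_ids = tuple(meta.get("neuron_ids", ()))

    if format == "dense":
        text = path.read_text()
        delim = "," if "," in text.splitlines()[0] else None
        try:
            values = np.loadtxt(path, delimiter=delim, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"could not parse dense raster {path}: {exc}") from exc
        return BinaryRaster(values, dt, neuron_ids)
    if format == "sparse":
        n_neurons = n_neurons if n_neurons is not None else meta.get("n_neurons")
        n_bins = n_bins if n_bins is not None else meta.get("n_bins")
        if n_neurons is None or n_bins is None:
            raise ValueError("sparse format requires n_neurons and n_bins")
        if path.read_text().strip():
            events = np.loadtxt(path, dtype=np.int64, ndmin=2)
        else:  # no events: an all-silent raster
            events = np.zeros((0, 2), dtype=np.int64)
        values = np.zeros((n_neurons, n_bins), dtype=np.uint8)
        if events.size:
            rows, cols = events[:, 0], events[:, 1]
            if (rows < 0).any() or (rows >= n_neurons).any():
                raise IndexError("sparse neuron index out of range")
            if (cols < 0).any() or (cols >= n_bins).any():
                raise IndexError("sparse bin index out of range")
            values[rows, cols] = 1
        return BinaryRaster(values, dt, neuron_ids)
    raise ValueError(f"unknown raster format {format!r}")


# ---------------------------------------------------------------------------
# empirical statistics


def pair_sigma(rate: np.ndarray | float, n_samples: int) -> np.ndarray | float:
    """Poisson standard deviation of a per-bin co-activity rate.

    With C = L*rate co-activity events in L bins, sigma = sqrt(max(C, 1))/L.
    The max(C,1) floor keeps the 2-sigma band strictly positive for rates
    that happen to be exactly zero.
    """
    counts = np.asarray(rate, dtype=float) * n_samples
    return np.sqrt(np.maximum(counts, 1.0)) / n_samples


@dataclass(frozen=True)
class EmpiricalStats:
    """Sample averages that define the direct dependencies of one output.

    ``pair_corrs[i]`` is the co-activity rate <y x_i> with input ``inputs[i]``;
    ``pair_sigmas`` are Poisson error bars sqrt(max(L <y x_i>, 1))/L.
    """

    output: int
    inputs: tuple[int, ...]
    output_mean: float
    input_means: np.ndarray
    pair_corrs: np.ndarray
    L: int
    pair_sigmas: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pair_sigmas is None:
            object.__setattr__(self, "pair_sigmas", pair_sigma(self.pair_corrs, self.L))


def empirical_stats(raster: Raster, output: int, inputs: Sequence[int]) -> EmpiricalStats:
    """Means <y>, <x_i> and correlations <y x_i> for one output neuron."""
    inputs = tuple(int(i) for i in inputs)
    N = raster.n_neurons
    if not 0 <= output < N:
        raise IndexError(f"output index {output} out of range for {N} neurons")
    for i in inputs:
        if not 0 <= i < N:
            raise IndexError(f"input index {i} out of range for {N} neurons")
    if output in inputs:
        raise ValueError(f"output neuron {output} cannot be one of its own inputs")
    values, w, L = as_arrays(raster)
    y = values[output].astype(float)
    out_mean = float(w @ y)
    if inputs:
        X = values[list(inputs)].astype(float)
        in_means = X @ w
        corrs = X @ (w * y)
    else:
        in_means = np.zeros(0)
        corrs = np.zeros(0)
    return EmpiricalStats(output, inputs, out_mean, in_means, corrs, L)


def eligible_inputs(raster: Raster, output: int) -> set[int]:
    """Neurons that co-activate with the output at least once (<y x_i> > 0).

    Only these have well-defined direct dependencies; fitting any other input
    would drive its weight to minus infinity.
    """
    values, w, _ = as_arrays(raster)
    if not 0 <= output < raster.n_neurons:
        raise IndexError(f"output index {output} out of range")
    y = values[output].astype(float)
    corrs = values.astype(float) @ (w * y)
    elig = set(np.nonzero(corrs > 0)[0].tolist())
    elig.discard(output)
    return elig


def significant_correlations(raster: Raster, output: int) -> np.ndarray:
    """Flag neurons whose correlation with the output deviates from independence.

    Neuron i is significant iff |<y x_i> - <y><x_i>| > 2 sigma with the Poisson
    error bar on <y x_i>; such correlations are *not* predicted by the
    independent (no-input) model.  The output's own flag is always False.
    """
    values, w, L = as_arrays(raster)
    if not 0 <= output < raster.n_neurons:
        raise IndexError(f"output index {output} out of range")
    y = values[output].astype(float)
    means = values.astype(float) @ w
    corrs = values.astype(float) @ (w * y)
    sig = pair_sigma(corrs, L)
    flags = np.abs(corrs - means[output] * means) > 2.0 * sig
    flags[output] = False
    return flags
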