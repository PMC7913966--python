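"""Data model and the sliding-window minimum-distance transform.

A *shapelet* is a short real-valued subsequence. Its distance to a time
series is the minimum, over all aligned windows, of the length-normalized
squared Euclidean distance. Transforming every series in a collection
against every shapelet in a set yields the N x K distance matrix that
downstream classifiers consume.

Distances are normalized by shapelet length so that sets holding shapelets
of different lengths are comparable within one fitness value; unnormalized
sums would systematically favour short shapelets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

MIN_SHAPELET_LEN = 4

#: Running count of pointwise comparisons performed by sliding-distance
#: kernels. Purely diagnostic; used to assert the O(K*N*M^2) cost bound.
OP_COUNTER = {"pointwise": 0}


class LengthError(ValueError):
    """A shapelet/series length precondition was violated."""


@dataclass(frozen=True)
class Shapelet:
    """One candidate subsequence; values are an immutable float array."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < MIN_SHAPELET_LEN:
            raise LengthError(
                f"shapelet must be 1-D with length >= {MIN_SHAPELET_LEN}, "
                f"got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("shapelet values must be finite")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Shapelet):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    def __hash__(self) -> int:
        return hash(self.values.tobytes())


@dataclass
class ShapeletSet:
    """An ordered, non-empty collection of shapelets (one GA individual).

    ``fitness`` caches the most recent evaluation; any structural change
    must go through a copy, leaving the cache coherent.
    """

    shapelets: list[Shapelet]
    fitness: Optional["object"] = None  # engine.FitnessValue once evaluated

    def __post_init__(self) -> None:
        self.shapelets = list(self.shapelets)
        if not self.shapelets:
            raise ValueError("a shapelet set must hold at least one shapelet")

    def __len__(self) -> int:
        return len(self.shapelets)

    def __iter__(self):
        return iter(self.shapelets)

    @property
    def complexity(self) -> int:
        """Sum of member lengths — the fitness tie-breaker."""
        return sum(len(s) for s in self.shapelets)

    def content_key(self) -> tuple[bytes, ...]:
        """Hashable identity of the member values (order-sensitive)."""
        return tuple(s.values.tobytes() for s in self.shapelets)

    def copy(self) -> "ShapeletSet":
        return ShapeletSet(list(self.shapelets), fitness=self.fitness)


@dataclass
class TimeSeriesDataset:
    """A labeled collection of univariate series of possibly unequal length.

    Labels are arbitrary hashables mapped internally to contiguous integers
    0..C-1 in first-appearance order; ``label_names`` restores the originals.
    """

    series: list[np.ndarray]
    labels: np.ndarray
    label_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.series = [np.asarray(t, dtype=float).ravel() for t in self.series]
        if len(self.series) == 0:
            raise ValueError("dataset must contain at least one series")
        for i, t in enumerate(self.series):
            if t.size < MIN_SHAPELET_LEN:
                raise LengthError(
                    f"series {i} has length {t.size} < {MIN_SHAPELET_LEN}"
                )
        raw = list(np.asarray(self.labels).tolist()) if not isinstance(
            self.labels, list
        ) else list(self.labels)
        if len(raw) != len(self.series):
            raise ValueError(
                f"{len(raw)} labels for {len(self.series)} series"
            )
        if not self.label_names:
            seen: dict = {}
            for lab in raw:
                if lab not in seen:
                    seen[lab] = len(seen)
            self.label_names = list(seen)
            self.labels = np.array([seen[lab] for lab in raw], dtype=int)
        else:
            self.labels = np.asarray(raw, dtype=int)

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def min_length(self) -> int:
        return min(t.size for t in self.series)

    @property
    def n_classes(self) -> int:
        return len(self.label_names) if self.label_names else len(
            np.unique(self.labels)
        )

    @classmethod
    def from_arrays(
        cls, X: Iterable[Sequence[float]], y: Sequence
    ) -> "TimeSeriesDataset":
        return cls(series=[np.asarray(t, float) for t in X], labels=list(y))

    def standardized(self) -> "TimeSeriesDataset":
        """Per-series standardization (optional; off by default everywhere)."""
        out = []
        for t in self.series:
            sd = t.std()
            out.append((t - t.mean()) / sd if sd > 0 else t - t.mean())
        return TimeSeriesDataset(out, self.labels.copy(), list(self.label_names))


def sliding_distance(shapelet, series) -> float:
    """Minimum length-normalized squared Euclidean distance over all windows.

    Every contiguous window of the series with the shapelet's length is
    compared; the distance is ``min_w sum_i (s_i - w_i)^2 / |s|``. It is zero
    iff the shapelet occurs pointwise-exactly somewhere in the series.
    """
    s = shapelet.values if isinstance(shapelet, Shapelet) else np.asarray(
        shapelet, float
    )
    t = np.asarray(series, dtype=float).ravel()
    L = s.size
    if L > t.size:
        raise LengthError(
            f"shapelet of length {L} longer than series of length {t.size}"
        )
    windows = sliding_window_view(t, L)
    d = windows - s
    OP_COUNTER["pointwise"] += windows.shape[0] * L
    return float(np.einsum("ij,ij->i", d, d).min() / L)


def distance_matrix(shapelet_set: ShapeletSet, dataset: TimeSeriesDataset) -> np.ndarray:
    """N x K matrix of sliding distances: entry (i, k) = dist(s_k, t_i)."""
    M = dataset.min_length
    for k, s in enumerate(shapelet_set):
        if len(s) > M:
            raise LengthError(
                f"shapelet {k} has length {len(s)} exceeding the shortest "
                f"series length {M}"
            )
    D = np.empty((dataset.n_series, len(shapelet_set)))
    for i, t in enumerate(dataset.series):
        for k, s in enumerate(shapelet_set):
            D[i, k] = sliding_distance(s, t)
    return D
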