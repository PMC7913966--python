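"""Per-candidate shapelet evaluation: the classical comparators.

Exhaustive enumeration scores every contiguous subsequence of the training
collection by the information gain of the best threshold split of its
distance vector. ``top_k_independent`` ranks candidates individually and
keeps the k best — deliberately without any interaction between picks or
similarity pruning, which is exactly the failure mode the set-based
evolutionary search avoids: near-duplicate candidates earn near-identical
gains, so the top of the ranking is dominated by redundant shapelets from
whichever class is easiest to isolate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional
import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import MIN_SHAPELET_LEN, Shapelet, ShapeletSet, TimeSeriesDataset


@dataclass(frozen=True)
class SplitQuality:
    """Best threshold split of a distance vector: gain is in bits and is
    bounded by the entropy of the full label distribution."""

    gain: float
    threshold: float
    left_counts: tuple[int, ...]
    right_counts: tuple[int, ...]


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(distances, labels) -> SplitQuality:
    """Best entropy reduction over all midpoint thresholds of ``distances``.

    Thresholds are the midpoints between consecutive distinct sorted
    distances. Ties on gain are broken toward the threshold with the larger
    margin (gap) between its neighbouring distances.
    """
    d = np.asarray(distances, dtype=float)
    labs = np.asarray(labels)
    if d.size < 2:
        raise ValueError("need at least two points to split")
    classes, y = np.unique(labs, return_inverse=True)
    C = classes.size
    order = np.argsort(d, kind="stable")
    d_sorted, y_sorted = d[order], y[order]
    total = np.bincount(y_sorted, minlength=C)
    base = _entropy(total)
    n = d.size

    best = SplitQuality(0.0, float(d_sorted[0] - 1.0), tuple([0] * C), tuple(total))
    best_margin = -np.inf
    left = np.zeros(C, dtype=int)
    for j in range(n - 1):
        left[y_sorted[j]] += 1
        if d_sorted[j + 1] == d_sorted[j]:
            continue
        right = total - left
        w_l = (j + 1) / n
        gain = base - w_l * _entropy(left) - (1 - w_l) * _entropy(right)
        margin = d_sorted[j + 1] - d_sorted[j]
        if gain > best.gain + 1e-12 or (
            abs(gain - best.gain) <= 1e-12 and margin > best_margin
        ):
            best = SplitQuality(
                gain=float(gain),
                threshold=float((d_sorted[j] + d_sorted[j + 1]) / 2.0),
                left_counts=tuple(int(c) for c in left),
                right_counts=tuple(int(c) for c in right),
            )
            best_margin = margin
    return best


def best_split_accuracy(distances, labels) -> float:
    """Highest training accuracy any single threshold on ``distances`` can
    reach, assigning each side of the split its majority label."""
    d = np.asarray(distances, dtype=float)
    labs = np.asarray(labels)
    classes, y = np.unique(labs, return_inverse=True)
    order = np.argsort(d, kind="stable")
    d_sorted, y_sorted = d[order], y[order]
    total = np.bincount(y_sorted, minlength=classes.size)
    n = d.size
    best = total.max() / n  # the no-split (single-side) baseline
    left = np.zeros(classes.size, dtype=int)
    for j in range(n - 1):
        left[y_sorted[j]] += 1
        if d_sorted[j + 1] == d_sorted[j]:
            continue
        right = total - left
        best = max(best, (left.max() + right.max()) / n)
    return float(best)


# ------------------------------------------------------------- enumeration

def _candidate_matrix(dataset: TimeSeriesDataset, length: int) -> np.ndarray:
    """All windows of the given length over all series, stacked in series
    order then offset order, deduplicated by exact value equality keeping
    the first occurrence."""
    blocks = [
        sliding_window_view(t, length)
        for t in dataset.series
        if t.size >= length
    ]
    windows = np.concatenate(blocks, axis=0)
    _, first_idx = np.unique(windows, axis=0, return_index=True)
    return windows[np.sort(first_idx)]


def enumerate_candidates(
    dataset: TimeSeriesDataset,
    length_range: Optional[tuple[int, int]] = None,
) -> Iterator[Shapelet]:
    """Yield every distinct contiguous subsequence, shortest lengths first."""
    lo, hi = _resolve_range(dataset, length_range)
    for length in range(lo, hi + 1):
        for row in _candidate_matrix(dataset, length):
            yield Shapelet(row)


def _resolve_range(
    dataset: TimeSeriesDataset, length_range: Optional[tuple[int, int]]
) -> tuple[int, int]:
    M = dataset.min_length
    if length_range is None:
        return MIN_SHAPELET_LEN, M
    lo, hi = length_range
    if lo < MIN_SHAPELET_LEN or hi > M or lo > hi:
        raise ValueError(
            f"length range [{lo}, {hi}] must lie within "
            f"[{MIN_SHAPELET_LEN}, {M}]"
        )
    return lo, hi


def _batch_distances(
    candidates: np.ndarray, dataset: TimeSeriesDataset
) -> np.ndarray:
    """Length-normalized sliding distances of every candidate (rows) to every
    series (columns), via one Gram-style matmul per call."""
    L = candidates.shape[1]
    blocks, bounds = [], [0]
    for t in dataset.series:
        w = sliding_window_view(t, L)
        blocks.append(w)
        bounds.append(bounds[-1] + w.shape[0])
    V = np.concatenate(blocks, axis=0)
    c_sq = np.einsum("ij,ij->i", candidates, candidates)
    v_sq = np.einsum("ij,ij->i", V, V)
    sq = c_sq[:, None] - 2.0 * (candidates @ V.T) + v_sq[None, :]
    np.maximum(sq, 0.0, out=sq)
    D = np.empty((candidates.shape[0], dataset.n_series))
    for i in range(dataset.n_series):
        D[:, i] = sq[:, bounds[i] : bounds[i + 1]].min(axis=1)
    return D / L


def _batch_gains(D: np.ndarray, y: np.ndarray, n_classes: int) -> np.ndarray:
    """Best information gain per row of a distance matrix (vectorized)."""
    n_cand, n = D.shape
    order = np.argsort(D, axis=1, kind="stable")
    d_sorted = np.take_along_axis(D, order, axis=1)
    y_sorted = y[order]
    onehot = np.eye(n_classes)[y_sorted]          # (n_cand, n, C)
    left = np.cumsum(onehot, axis=1)[:, :-1, :]   # counts left of split j+1
    total = left[:, -1:, :] + onehot[:, -1:, :]
    right = total - left

    def ent(counts: np.ndarray) -> np.ndarray:
        tot = counts.sum(axis=-1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(tot > 0, counts / np.maximum(tot, 1), 0.0)
            term = np.where(p > 0, p * np.log2(p), 0.0)
        return -term.sum(axis=-1)

    base = ent(total.squeeze(1))[:, None]
    w_l = np.arange(1, n)[None, :] / n
    gains = base - w_l * ent(left) - (1 - w_l) * ent(right)
    valid = d_sorted[:, 1:] > d_sorted[:, :-1]    # only distinct-value splits
    gains = np.where(valid, gains, -np.inf)
    best = gains.max(axis=1)
    return np.maximum(best, 0.0)


# ----------------------------------------------------------------- search

def best_single_shapelet(
    dataset: TimeSeriesDataset,
    length_range: Optional[tuple[int, int]] = None,
) -> tuple[Shapelet, SplitQuality]:
    """Exhaustive search for the single most informative subsequence.

    Ties on gain prefer the shorter candidate, then the earlier one in
    enumeration order (series order, then offset order).
    """
    if dataset.n_classes < 2:
        raise ValueError("need at least two classes")
    lo, hi = _resolve_range(dataset, length_range)
    y = dataset.labels
    C = dataset.n_classes
    best_gain, best_values = -np.inf, None
    for length in range(lo, hi + 1):
        cands = _candidate_matrix(dataset, length)
        D = _batch_distances(cands, dataset)
        gains = _batch_gains(D, y, C)
        j = int(np.argmax(gains))              # first index wins ties
        if gains[j] > best_gain + 1e-12:
            best_gain = float(gains[j])
            best_values = cands[j].copy()
    shapelet = Shapelet(best_values)
    quality = information_gain(
        _batch_distances(best_values[None, :], dataset)[0], y
    )
    return shapelet, quality


def top_k_independent(
    dataset: TimeSeriesDataset,
    k: int,
    length_range: Optional[tuple[int, int]] = None,
) -> ShapeletSet:
    """Rank every candidate by its individual information gain and keep the
    top k. No interaction between picks and no similarity pruning — the
    naive comparator."""
    if k < 1:
        raise ValueError("k must be >= 1")
    lo, hi = _resolve_range(dataset, length_range)
    y = dataset.labels
    C = dataset.n_classes
    all_gains, all_cands = [], []
    for length in range(lo, hi + 1):
        cands = _candidate_matrix(dataset, length)
        D = _batch_distances(cands, dataset)
        all_gains.append(_batch_gains(D, y, C))
        all_cands.append(cands)
    gains = np.concatenate(all_gains)
    if gains.size < k:
        warnings.warn(
            f"only {gains.size} candidates available for k={k}; returning all"
        )
        k = gains.size
    # stable sort: ties keep enumeration order (shorter length first)
    order = np.argsort(-gains, kind="stable")[:k]
    offsets = np.cumsum([0] + [c.shape[0] for c in all_cands])
    shapelets = []
    for idx in order:
        block = int(np.searchsorted(offsets, idx, side="right")) - 1
        shapelets.append(Shapelet(all_cands[block][idx - offsets[block]]))
    return ShapeletSet(shapelets)
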