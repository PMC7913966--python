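"""Run-to-run stability of discovered shapelet sets via dynamic time warping.

Two evolutionary runs with different seeds rarely return identical
shapelets, but stable discovery should return semantically matching ones
(the same arch, saw, or level pattern, possibly shifted or stretched). DTW
is the natural elastic measure for that comparison; the pairwise DTW matrix
between two runs' sets is rendered as a heat map, and low off-diagonal
minima indicate matching pairs.
"""

from __future__ import annotations

import numpy as np

from .core import Shapelet, ShapeletSet


def dtw_distance(a, b, normalize: bool = False) -> float:
    """Classic dynamic-programming DTW with absolute-difference local cost.

    Full alignment, no warping window. ``normalize`` divides the optimal
    path cost by the path length (off by default).
    """
    x = a.values if isinstance(a, Shapelet) else np.asarray(a, dtype=float)
    y = b.values if isinstance(b, Shapelet) else np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("DTW requires non-empty sequences")
    n, m = x.size, y.size
    cost = np.abs(x[:, None] - y[None, :])
    acc = np.full((n + 1, m + 1), np.inf)
    steps = np.zeros((n + 1, m + 1), dtype=int)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            choices = (acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1])
            k = int(np.argmin(choices))
            acc[i, j] = cost[i - 1, j - 1] + choices[k]
            prev = ((i - 1, j), (i, j - 1), (i - 1, j - 1))[k]
            steps[i, j] = steps[prev] + 1
    if normalize:
        return float(acc[n, m] / steps[n, m])
    return float(acc[n, m])


def stability_matrix(
    set1: ShapeletSet, set2: ShapeletSet, normalize: bool = False
) -> np.ndarray:
    """Pairwise DTW distances between two discovered sets: entry (i, j) is
    dtw(set1[i], set2[j])."""
    out = np.empty((len(set1), len(set2)))
    for i, s in enumerate(set1):
        for j, r in enumerate(set2):
            out[i, j] = dtw_distance(s, r, normalize=normalize)
    return out
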