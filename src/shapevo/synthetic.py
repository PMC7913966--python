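"""Synthetic labeled time-series generators.

Three families, each engineered to make one failure or success mode of
shapelet discovery provable at desk scale:

* an imbalanced three-class collection (25/5/5) whose majority class is a
  tight cluster of low-noise copies of one waveform while the two minority
  classes share a second waveform and differ only inside a short
  class-specific motif — the setting in which per-candidate ranking piles
  all its picks on majority-isolating shapelets;
* a two-class, four-series construction with one flat-top bump per series
  at nested amplitudes (class A: 0 and 4; class B: 1 and 3) in which no
  subsequence of any input series induces a threshold split of all four
  series, yet the out-of-data amplitude-2 bump — the barycenter of the two
  class-B bumps — separates the classes with a wide margin;
* a generic two-class motif dataset, linearly separable by one shapelet
  per class, used as the standard end-to-end fixture.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import numpy as np

from .core import TimeSeriesDataset


def half_sine_bump(width: int, amplitude: float = 1.0) -> np.ndarray:
    """A half-period sine arch of the given width and peak amplitude."""
    x = np.arange(1, width + 1) / (width + 1)
    return amplitude * np.sin(np.pi * x)


def _class0_waveform(length: int) -> np.ndarray:
    x = np.linspace(0.0, 1.0, length)
    return np.sin(2.0 * np.pi * 3.0 * x)


def _minority_base_waveform(length: int) -> np.ndarray:
    x = np.linspace(0.0, 1.0, length)
    return 0.8 * np.sin(2.0 * np.pi * 1.5 * x + 0.5)


def make_imbalanced_three_class(
    n0: int = 25,
    n1: int = 5,
    n2: int = 5,
    length: int = 100,
    noise_majority: float = 0.05,
    noise_minority: float = 0.3,
    motif_amplitude: float = 4.0,
    seed: int | None = None,
) -> tuple[TimeSeriesDataset, TimeSeriesDataset]:
    """Imbalanced three-class train/test pair (default 25/5/5 each).

    Class 0 is one smooth waveform plus small noise (many near-identical
    series). Classes 1 and 2 share a different base waveform and differ
    only in a short motif — an upward vs downward half-sine arch over a
    fifth of the series — under larger noise, making them internally more
    dissimilar than class 0. The motif amplitude is large relative to both
    waveforms so that majority-class subsequences never align inside the
    motif region: their distances to the two minority classes are then
    identically distributed, which is what defeats the independent top-k
    comparator. Train and test are drawn i.i.d. with identical per-class
    counts.
    """
    if min(n0, n1, n2) < 2:
        raise ValueError("each class needs at least 2 members")
    rng = np.random.default_rng(seed)
    base0 = _class0_waveform(length)
    base12 = _minority_base_waveform(length)
    m_start, m_width = int(0.6 * length), max(4, length // 5)
    m_end = min(length, m_start + m_width)
    bump = half_sine_bump(m_end - m_start, motif_amplitude)

    def draw(n: int, base: np.ndarray, sigma: float) -> list[np.ndarray]:
        return [base + rng.normal(0.0, sigma, size=length) for _ in range(n)]

    def one_split() -> TimeSeriesDataset:
        wave1 = base12.copy()
        wave1[m_start:m_end] += bump
        wave2 = base12.copy()
        wave2[m_start:m_end] -= bump
        series = (
            draw(n0, base0, noise_majority)
            + draw(n1, wave1, noise_minority)
            + draw(n2, wave2, noise_minority)
        )
        labels = [0] * n0 + [1] * n1 + [2] * n2
        return TimeSeriesDataset(series, labels)

    return one_split(), one_split()


NESTED_AMPLITUDES = {0: (0.0, 4.0), 1: (1.0, 3.0)}  # class -> amplitudes


def boxcar_bump(width: int, amplitude: float = 1.0) -> np.ndarray:
    """A flat-top (boxcar) pulse of the given width and height."""
    return np.full(width, float(amplitude))


def make_nested_amplitude_two_class(
    length: int = 50,
    bump_width: int = 20,
    noise: float = 0.0,
    seed: int | None = None,
) -> TimeSeriesDataset:
    """Four series, one bump each, amplitudes nested across the classes.

    Every series is a zero baseline with a flat-top bump of the given width
    at a fixed position, scaled by amplitude a: class A uses a in {0, 4},
    class B a in {1, 3}. Distances from any in-data subsequence interleave
    the classes (windows from amplitude a sit at normalized squared distance
    proportional to min((a-b)^2, b^2) from amplitude b, and b^2-vs-flat ties
    never separate), so no threshold splits 4/4. The amplitude-2 bump —
    outside the data, but the pointwise mean of the two class-B bumps —
    yields class distances of 4E vs E with E the normalized bump energy: a
    clean separation. The flat top matters: a smooth arch would let short
    windows ride another amplitude's rising edge and leak a separator.
    """
    if bump_width >= length:
        raise ValueError("bump_width must be smaller than length")
    rng = np.random.default_rng(seed)
    start = (length - bump_width) // 2
    profile = boxcar_bump(bump_width)
    series, labels = [], []
    for label, amplitudes in NESTED_AMPLITUDES.items():
        for a in amplitudes:
            t = np.zeros(length)
            t[start : start + bump_width] = a * profile
            if noise > 0:
                t = t + rng.normal(0.0, noise, size=length)
            series.append(t)
            labels.append(label)
    return TimeSeriesDataset(series, labels)


def separating_bump_shapelet(bump_width: int = 20) -> np.ndarray:
    """The out-of-data amplitude-2 bump that separates the nested-amplitude
    classes (reference values for tests and demos)."""
    return boxcar_bump(bump_width, 2.0)


def _class_motif(label: int, motif_length: int, amplitude: float = 1.5) -> np.ndarray:
    """Distinct per-class motif: label c gets c+1 sine half-periods, with the
    sign alternating so no motif is a scaled copy of another."""
    x = np.arange(1, motif_length + 1) / (motif_length + 1)
    sign = 1.0 if label % 2 == 0 else -1.0
    return sign * amplitude * np.sin(np.pi * (label + 1) * x)


def make_motif_multiclass(
    n_classes: int,
    n_per_class: int = 10,
    length: int = 40,
    motif_length: int = 10,
    noise: float = 0.1,
    seed: int | None = None,
) -> TimeSeriesDataset:
    """Balanced noise series with one distinct implanted motif per class.

    Each series is baseline noise plus its class motif at a uniformly random
    position; at zero noise one motif subsequence per class separates the
    data perfectly, and with C classes a useful shapelet set needs on the
    order of C members.
    """
    if motif_length > length:
        raise ValueError("motif_length must be <= length")
    if n_classes < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(seed)
    series, labels = [], []
    for label in range(n_classes):
        motif = _class_motif(label, motif_length)
        for _ in range(n_per_class):
            t = rng.normal(0.0, noise, size=length) if noise > 0 else np.zeros(length)
            pos = int(rng.integers(0, length - motif_length + 1))
            t[pos : pos + motif_length] += motif
            series.append(t)
            labels.append(label)
    return TimeSeriesDataset(series, labels)


def make_motif_two_class(
    n_per_class: int = 10,
    length: int = 40,
    motif_length: int = 10,
    noise: float = 0.1,
    seed: int | None = None,
) -> TimeSeriesDataset:
    """Two-class special case of :func:`make_motif_multiclass` (class 0: an
    upward half-sine arch; class 1: a downward full period)."""
    return make_motif_multiclass(
        2,
        n_per_class=n_per_class,
        length=length,
        motif_length=motif_length,
        noise=noise,
        seed=seed,
    )
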