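"""Greedy regression-tree binning of a power spectrum into contiguous
frequency bands, plus an exact dynamic-programming segmentation oracle.

A band partition is a piecewise-constant fit of the regression target
(ln PSD by default) against frequency. Growing the partition greedily,
best-first — always splitting whichever current band admits the largest
drop in residual sum of squares — is exactly how a regression tree with a
leaf-count cap partitions a single ordered predictor, and it yields nested
boundary sets: the k-band boundaries are a subset of the (k+1)-band ones.

The DP routine computes the globally SSE-optimal contiguous k-segmentation
in O(N^2 k); it exists to bound and test the greedy heuristic, which is not
globally optimal for k >= 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .spectral import PowerSpectrum, log_power

__all__ = [
    "BandPartition",
    "best_split",
    "grow_partition",
    "grow_nested",
    "dp_optimal_partition",
    "dp_sse_curve",
    "r_squared",
]

Target = Literal["log", "linear"]


def target_values(spectrum: PowerSpectrum, target: Target = "log") -> np.ndarray:
    """The regression target: ln PSD ("log", default) or raw PSD ("linear")."""
    if target == "log":
        return log_power(spectrum)
    if target == "linear":
        return np.asarray(spectrum.psd, dtype=float)
    raise ValueError(f"unknown target {target!r}; expected 'log' or 'linear'")


@dataclass(frozen=True)
class BandPartition:
    """k contiguous frequency bands with per-band mean target values.

    ``boundaries`` holds the k-1 interior boundary frequencies (midpoints of
    the two grid samples flanking each cut), strictly increasing and strictly
    inside the spectrum's frequency range. Bands are half-open
    ``[left, right)``, the last band closed. ``band_means`` are the per-band
    arithmetic means of the target (the SSE-minimizing constants), ``sse``
    the residual sum of squares about those means, and ``r2`` the coefficient
    of determination against the global-mean model.
    """

    k: int
    boundaries: np.ndarray
    band_means: np.ndarray
    sse: float
    r2: float
    target: str = "log"

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        m = np.asarray(self.band_means, dtype=float)
        if len(b) != self.k - 1:
            raise ValueError(f"expected {self.k - 1} boundaries, got {len(b)}")
        if len(m) != self.k:
            raise ValueError(f"expected {self.k} band means, got {len(m)}")
        if len(b) and np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if self.sse < -1e-12:
            raise ValueError("sse must be non-negative")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "band_means", m)

    def assign(self, frequencies) -> np.ndarray:
        """Band index (0-based) of each frequency."""
        return np.searchsorted(self.boundaries, np.asarray(frequencies), side="right")

    def predict(self, frequencies) -> np.ndarray:
        """Piecewise-constant prediction: each frequency's band mean."""
        return self.band_means[self.assign(frequencies)]

    def to_dict(self) -> dict:
        return {
            "k": int(self.k),
            "boundaries_hz": [float(b) for b in self.boundaries],
            "band_means": [float(m) for m in self.band_means],
            "sse": float(self.sse),
            "r2": float(self.r2),
            "target": self.target,
        }


def _prefix_sums(y: np.ndarray):
    c1 = np.concatenate(([0.0], np.cumsum(y)))
    c2 = np.concatenate(([0.0], np.cumsum(y * y)))
    return c1, c2


def _segment_sse(c1: np.ndarray, c2: np.ndarray, a: int, b: int) -> float:
    """SSE of y[a:b] about its mean, from prefix sums; clamped at 0."""
    n = b - a
    s = c1[b] - c1[a]
    q = c2[b] - c2[a]
    return max(q - s * s / n, 0.0)


def best_split(y) -> tuple[int, float]:
    """Best single cut of an ordered segment.

    Returns ``(split_index, sse_decrease)`` where the cut places
    ``y[:split_index]`` left and ``y[split_index:]`` right, chosen to minimize
    SSE(left) + SSE(right) over all len(y)-1 cut points — equivalently, to
    minimize the count-weighted average MSE of the two groups. Ties go to the
    smallest split index.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("cannot split a segment with fewer than 2 values")
    n = len(y)
    c1, c2 = _prefix_sums(y)
    i = np.arange(1, n)
    sse_left = np.maximum(c2[i] - c1[i] ** 2 / i, 0.0)
    sR = c1[n] - c1[i]
    qR = c2[n] - c2[i]
    sse_right = np.maximum(qR - sR**2 / (n - i), 0.0)
    total = sse_left + sse_right
    best = int(np.argmin(total))  # argmin returns the first minimum: smallest index
    whole = _segment_sse(c1, c2, 0, n)
    return best + 1, max(whole - total[best], 0.0)


class _Segment:
    """A current leaf: half-open index range [a, b) with its cached best cut."""

    __slots__ = ("a", "b", "cut", "gain")

    def __init__(self, a: int, b: int, y: np.ndarray):
        self.a = a
        self.b = b
        if b - a >= 2:
            idx, gain = best_split(y[a:b])
            self.cut = a + idx
            self.gain = gain
        else:
            self.cut = None
            self.gain = -1.0


def _grow_cut_sequence(y: np.ndarray, kmax: int) -> list[list[int]]:
    """Best-first growth; returns the sorted cut-index list after each split.

    Element j (0-based) is the cut list of the (j+1)-band partition.
    """
    segs = [_Segment(0, len(y), y)]
    cuts: list[int] = []
    out = [sorted(cuts)]
    for _ in range(kmax - 1):
        # largest gain wins; ties go to the segment with the lowest left edge
        best = None
        for s in segs:
            if s.cut is None:
                continue
            if best is None or s.gain > best.gain or (s.gain == best.gain and s.a < best.a):
                best = s
        if best is None:  # cannot happen while k <= N
            raise ValueError("no splittable band remains")
        segs.remove(best)
        segs.append(_Segment(best.a, best.cut, y))
        segs.append(_Segment(best.cut, best.b, y))
        cuts.append(best.cut)
        out.append(sorted(cuts))
    return out


def _partition_from_cuts(
    spectrum: PowerSpectrum, y: np.ndarray, cuts: list[int], target: Target
) -> BandPartition:
    f = spectrum.frequencies
    edges = [0] + list(cuts) + [len(y)]
    means = np.array([y[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    sse = float(sum(((y[a:b] - y[a:b].mean()) ** 2).sum() for a, b in zip(edges[:-1], edges[1:])))
    boundaries = np.array([(f[c - 1] + f[c]) / 2.0 for c in cuts])
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if sst == 0.0 else 1.0 - sse / sst
    return BandPartition(
        k=len(cuts) + 1,
        boundaries=boundaries,
        band_means=means,
        sse=sse,
        r2=r2,
        target=target,
    )


def _check_k(k: int, n: int) -> None:
    if not 1 <= k <= n:
        raise ValueError(f"band count k={k} must satisfy 1 <= k <= N={n}")


def grow_partition(
    spectrum: PowerSpectrum, k: int, target: Target = "log"
) -> BandPartition:
    """Greedy best-first partition of the spectrum into k contiguous bands.

    Starting from one band covering the whole grid, the band whose best cut
    yields the largest SSE decrease is split, k-1 times. Reported boundary
    frequencies are midpoints of the grid samples flanking each cut.
    """
    _check_k(k, spectrum.n)
    y = target_values(spectrum, target)
    cuts = _grow_cut_sequence(y, k)[k - 1]
    return _partition_from_cuts(spectrum, y, cuts, target)


def grow_nested(
    spectrum: PowerSpectrum, kmax: int, target: Target = "log"
) -> list[BandPartition]:
    """One growth pass, emitting the partition after each split (k = 1..kmax).

    Because growth only ever adds cuts, partition k's boundary set is a subset
    of partition k+1's — the nesting the greedy tree guarantees.
    """
    _check_k(kmax, spectrum.n)
    y = target_values(spectrum, target)
    return [
        _partition_from_cuts(spectrum, y, cuts, target)
        for cuts in _grow_cut_sequence(y, kmax)
    ]


def _dp_table(y: np.ndarray, kmax: int):
    """DP tables for optimal k-segmentation, all k <= kmax at once.

    cost[j, b] = minimal SSE of y[:b] split into j contiguous segments;
    back[j, b] = start index of the last segment in that optimum.
    """
    n = len(y)
    c1, c2 = _prefix_sums(y)
    INF = float("inf")
    cost = np.full((kmax + 1, n + 1), INF)
    back = np.zeros((kmax + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for j in range(1, kmax + 1):
        for b in range(j, n + 1):
            best_val, best_a = INF, j - 1
            for a in range(j - 1, b):
                v = cost[j - 1, a] + _segment_sse(c1, c2, a, b)
                if v < best_val:
                    best_val, best_a = v, a
            cost[j, b] = best_val
            back[j, b] = best_a
    return cost, back


def dp_optimal_partition(
    spectrum: PowerSpectrum, k: int, target: Target = "log"
) -> BandPartition:
    """Globally SSE-minimal contiguous partition into k bands (exact oracle).

    Dynamic programming over prefix sums, O(N^2 k). Used to bound the greedy
    result in tests; the greedy partition can only match or exceed this SSE.
    """
    _check_k(k, spectrum.n)
    y = target_values(spectrum, target)
    n = len(y)
    _, back = _dp_table(y, k)
    cuts = []
    b = n
    for j in range(k, 1, -1):
        b = int(back[j, b])
        cuts.append(b)
    cuts.reverse()
    return _partition_from_cuts(spectrum, y, cuts, target)


def dp_sse_curve(
    spectrum: PowerSpectrum, kmax: int | None = None, target: Target = "log"
) -> np.ndarray:
    """Optimal SSE for every k = 1..kmax from a single DP pass.

    Element k-1 is the global minimum SSE over all contiguous k-band
    partitions; a lower envelope for the greedy grower's SSE sequence.
    """
    if kmax is None:
        kmax = spectrum.n
    _check_k(kmax, spectrum.n)
    y = target_values(spectrum, target)
    cost, _ = _dp_table(y, kmax)
    return cost[1:, len(y)].copy()


def r_squared(partition: BandPartition, spectrum: PowerSpectrum) -> float:
    """Coefficient of determination of the partition's piecewise-constant fit.

    1 - SSE/SST on the partition's target, with per-band means recomputed on
    this spectrum, against the global-mean model. A flat spectrum (SST = 0)
    returns 0 by convention.
    """
    y = target_values(spectrum, partition.target)  # type: ignore[arg-type]
    idx = partition.assign(spectrum.frequencies)
    if idx.max() >= partition.k:  # pragma: no cover - defensive
        raise ValueError("partition does not cover the spectrum's frequencies")
    sse = 0.0
    for band in range(partition.k):
        seg = y[idx == band]
        if len(seg):
            sse += float(((seg - seg.mean()) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        return 0.0
    return 1.0 - sse / sst
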