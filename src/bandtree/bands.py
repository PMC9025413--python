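"""Fixed, named band sets (delta/theta/alpha/beta) and their evaluation
against a spectrum with the same r2/SSE machinery as discovered partitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .spectral import PowerSpectrum
from .treebin import BandPartition, Target, target_values

__all__ = [
    "NamedBandSet",
    "default_standard_bands",
    "evaluate_fixed_bands",
    "partition_as_bandset",
]


@dataclass(frozen=True)
class NamedBandSet:
    """Named contiguous bands: len(names)+1 strictly increasing edges in Hz."""

    names: tuple
    edges: np.ndarray

    def __post_init__(self) -> None:
        names = tuple(self.names)
        edges = np.asarray(self.edges, dtype=float)
        if len(edges) != len(names) + 1:
            raise ValueError(
                f"expected {len(names) + 1} edges for {len(names)} bands, got {len(edges)}"
            )
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "edges", edges)

    @property
    def k(self) -> int:
        return len(self.names)

    def to_dict(self) -> dict:
        return {"names": list(self.names), "edges_hz": [float(e) for e in self.edges]}

    @classmethod
    def from_dict(cls, d: dict) -> "NamedBandSet":
        return cls(names=tuple(d["names"]), edges=np.asarray(d["edges_hz"], dtype=float))


def default_standard_bands() -> NamedBandSet:
    """The conventional 4-band EEG taxonomy: delta [1,4), theta [4,8),
    alpha [8,12), beta [12,30) Hz. A configuration default, not a standard —
    published boundaries vary by a few Hz across reviews."""
    return NamedBandSet(
        names=("delta", "theta", "alpha", "beta"),
        edges=np.array([1.0, 4.0, 8.0, 12.0, 30.0]),
    )


def evaluate_fixed_bands(
    spectrum: PowerSpectrum,
    bandset: NamedBandSet,
    target: Target = "log",
    coverage: Literal["extend", "drop"] = "extend",
) -> BandPartition:
    """Score a fixed band set on a spectrum with the partition machinery.

    ``coverage="extend"`` (default) stretches the outermost edges to the
    spectrum's frequency range so every frequency is assigned — the whole-
    spectrum comparison a discovered partition gets. ``coverage="drop"``
    instead ignores frequencies outside [edges[0], edges[-1]]; SST is then
    computed on the surviving frequencies only.

    Returns a :class:`BandPartition` whose boundaries are the interior edges;
    its QS is ``quality_score(r2, bandset.k, spectrum.n)``.
    """
    f = spectrum.frequencies
    y = target_values(spectrum, target)
    interior = np.asarray(bandset.edges[1:-1], dtype=float)
    if coverage == "drop":
        mask = (f >= bandset.edges[0]) & (f <= bandset.edges[-1])
        if mask.sum() < bandset.k:
            raise ValueError("fewer surviving frequencies than bands after dropping")
        f = f[mask]
        y = y[mask]
    elif coverage != "extend":
        raise ValueError(f"unknown coverage mode {coverage!r}")
    idx = np.searchsorted(interior, f, side="right")
    means = np.empty(bandset.k)
    sse = 0.0
    empty = []
    for band in range(bandset.k):
        seg = y[idx == band]
        if len(seg) == 0:
            empty.append(bandset.names[band])
            means[band] = np.nan
            continue
        means[band] = seg.mean()
        sse += float(((seg - seg.mean()) ** 2).sum())
    if empty:
        raise ValueError(f"empty band(s) with no spectrum frequencies: {', '.join(empty)}")
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if sst == 0.0 else 1.0 - sse / sst
    return BandPartition(
        k=bandset.k,
        boundaries=interior,
        band_means=means,
        sse=sse,
        r2=r2,
        target=target,
    )


def partition_as_bandset(partition: BandPartition, spectrum: PowerSpectrum) -> NamedBandSet:
    """Re-express a discovered partition as a fixed band set spanning the
    spectrum's frequency range (band_1 .. band_k, low to high)."""
    edges = np.concatenate(([spectrum.fmin], partition.boundaries, [spectrum.fmax]))
    names = tuple(f"band_{i + 1}" for i in range(partition.k))
    return NamedBandSet(names=names, edges=edges)
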