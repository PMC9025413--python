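"""Quality score and automatic band-count selection.

The quality score

    QS = -ln(r2) + 2k/N

is an AIC-inspired trade-off between goodness of fit and band count: the
first (fitness) term is -ln of the coefficient of determination of the
k-band piecewise-constant fit, the second penalizes the band count k,
normalized by N, the number of observed frequency values (equivalently the
maximum possible band count). Both terms live on roughly [0, 2] in practice
(the fitness term is <= 2 whenever r2 >= e^-2 ~ 0.135), and smaller is
better. The saturated model k = N has r2 = 1 and hence QS = 2 exactly.

Unlike AIC proper, no likelihood is involved; the score is empirical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spectral import PowerSpectrum
from .treebin import BandPartition, Target, grow_nested

__all__ = ["QualityCurve", "quality_score", "select_band_count"]


def quality_score(r2: float, k: int, n: int) -> float:
    """QS = -ln(r2) + 2k/n; +inf when r2 <= 0 (fit no better than the mean)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"n={n} must be >= k={k}")
    if r2 > 1:
        raise ValueError("r2 cannot exceed 1")
    penalty = 2.0 * k / n
    if r2 <= 0:
        return math.inf
    return -math.log(r2) + penalty


@dataclass(frozen=True)
class QualityCurve:
    """Per-k record of fit quality over a band-count range.

    ``best_k`` is the QS arg-min; on ties the smallest k wins (parsimony).
    """

    ks: np.ndarray
    r2s: np.ndarray
    qss: np.ndarray
    best_k: int

    def __post_init__(self) -> None:
        ks = np.asarray(self.ks, dtype=int)
        r2s = np.asarray(self.r2s, dtype=float)
        qss = np.asarray(self.qss, dtype=float)
        if not (len(ks) == len(r2s) == len(qss)):
            raise ValueError("ks, r2s, qss must have equal length")
        object.__setattr__(self, "ks", ks)
        object.__setattr__(self, "r2s", r2s)
        object.__setattr__(self, "qss", qss)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"k": self.ks, "r2": self.r2s, "qs": self.qss})


def select_band_count(
    spectrum: PowerSpectrum,
    kmin: int = 2,
    kmax: int | None = None,
    target: Target = "log",
) -> tuple[BandPartition, QualityCurve]:
    """Grow nested partitions once, score every k in [kmin, kmax], and return
    the partition with the smallest QS together with the full quality curve.

    Defaults follow the pipeline: candidate band counts run from 2 up to the
    number of unique frequency values N (k = 1 never beats k = 2 on QS unless
    requested explicitly via ``kmin=1``).
    """
    n = spectrum.n
    if kmax is None:
        kmax = n
    if not 1 <= kmin <= kmax <= n:
        raise ValueError(f"need 1 <= kmin <= kmax <= N; got kmin={kmin}, kmax={kmax}, N={n}")
    partitions = grow_nested(spectrum, kmax, target=target)
    ks = np.arange(kmin, kmax + 1)
    r2s = np.array([partitions[k - 1].r2 for k in ks])
    qss = np.array([quality_score(r2, int(k), n) for r2, k in zip(r2s, ks)])
    best_k = int(ks[int(np.argmin(qss))])  # first minimum: smallest k on ties
    curve = QualityCurve(ks=ks, r2s=r2s, qss=qss, best_k=best_k)
    return partitions[best_k - 1], curve
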