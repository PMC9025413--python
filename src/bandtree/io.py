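"""File round-tripping: CSV spectra, JSON band reports and band sets, CSV
quality curves.

Reports use a stable key order and 12-significant-digit float formatting so
identical configs and seeds produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import NamedBandSet
from .qselect import QualityCurve, quality_score
from .spectral import PowerSpectrum
from .treebin import BandPartition

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "partition_report",
    "write_report",
    "read_report",
    "write_quality_curve_csv",
    "read_bandset_json",
    "write_bandset_json",
]

SPECTRUM_COLUMNS = ("frequency_hz", "psd")


def _fmt(x: float) -> float:
    """Round-trip a float through 12 significant digits for stable output."""
    return float(f"{float(x):.12g}")


def read_spectrum_csv(path) -> PowerSpectrum:
    """Read a two-column spectrum CSV (header ``frequency_hz,psd``)."""
    df = pd.read_csv(path)
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; expected {list(SPECTRUM_COLUMNS)}")
    return PowerSpectrum(df["frequency_hz"].to_numpy(float), df["psd"].to_numpy(float))


def write_spectrum_csv(spectrum: PowerSpectrum, path) -> None:
    df = pd.DataFrame(
        {"frequency_hz": spectrum.frequencies, "psd": spectrum.psd}
    )
    df.to_csv(path, index=False, float_format="%.12g")


def partition_report(partition: BandPartition, n_frequencies: int) -> dict:
    """Self-contained JSON-ready report: recomputing QS from its (r2, k, n)
    fields reproduces the stored qs exactly."""
    r2 = _fmt(partition.r2)
    qs = quality_score(r2, partition.k, n_frequencies)
    return {
        "k": int(partition.k),
        "boundaries_hz": [_fmt(b) for b in partition.boundaries],
        "band_means": [_fmt(m) for m in partition.band_means],
        "sse": _fmt(partition.sse),
        "r2": r2,
        # full precision: the stored qs must recompute exactly from (r2, k, n)
        "qs": qs if np.isfinite(qs) else None,
        "n_frequencies": int(n_frequencies),
        "target": partition.target,
    }


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=False) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def write_quality_curve_csv(curve: QualityCurve, path) -> None:
    """Columns k,r2,qs, one row per evaluated band count."""
    df = pd.DataFrame(
        {
            "k": curve.ks,
            "r2": [_fmt(v) for v in curve.r2s],
            "qs": [_fmt(v) if np.isfinite(v) else np.inf for v in curve.qss],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_bandset_json(path) -> NamedBandSet:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid band-set JSON: {exc}") from exc
    if not isinstance(d, dict) or "names" not in d or "edges_hz" not in d:
        raise ValueError(f'{path}: band-set JSON needs "names" and "edges_hz" keys')
    return NamedBandSet.from_dict(d)


def write_bandset_json(bandset: NamedBandSet, path) -> None:
    Path(path).write_text(json.dumps(bandset.to_dict(), indent=2) + "\n")
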