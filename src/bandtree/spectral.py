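"""Power spectra: Welch estimation, the log-power regression target, and
frequency-range utilities.

The central container is :class:`PowerSpectrum`, a validated pair of a
strictly increasing frequency grid and strictly positive power spectral
density values. All band-discovery math downstream operates on
``(frequency, target)`` pairs where the target is either the natural log of
the PSD (the default for measured spectra, whose power spans orders of
magnitude) or the raw PSD itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

__all__ = [
    "PowerSpectrum",
    "welch_psd",
    "log_power",
    "restrict",
    "aggregate_channels",
]


@dataclass(frozen=True)
class PowerSpectrum:
    """A one-sided power spectrum on a strictly increasing frequency grid.

    Parameters
    ----------
    frequencies :
        Frequencies in Hz, strictly increasing, length >= 2.
    psd :
        Power spectral density per frequency; finite and strictly positive
        (the log target must be defined everywhere). Units are whatever the
        producer used (input units squared per Hz for Welch estimates,
        arbitrary for synthetic spectra); all downstream math is unit-free.
    """

    frequencies: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.psd, dtype=float)
        if f.ndim != 1 or p.ndim != 1:
            raise ValueError("frequencies and psd must be 1-D")
        if len(f) != len(p):
            raise ValueError(
                f"length mismatch: {len(f)} frequencies vs {len(p)} psd values"
            )
        if len(f) < 2:
            raise ValueError("a spectrum needs at least 2 frequencies")
        if not np.all(np.isfinite(f)):
            raise ValueError("frequencies must be finite")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing (no duplicates)")
        if not np.all(np.isfinite(p)):
            raise ValueError("psd must be finite")
        if np.any(p <= 0):
            bad = f[np.argmax(p <= 0)]
            raise ValueError(f"psd must be strictly positive; offending frequency {bad:g} Hz")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "psd", p)

    @property
    def n(self) -> int:
        """Number of unique frequency values (the N of the quality score)."""
        return len(self.frequencies)

    @property
    def fmin(self) -> float:
        return float(self.frequencies[0])

    @property
    def fmax(self) -> float:
        return float(self.frequencies[-1])


def welch_psd(
    samples,
    fs: float,
    segment_length: int = 1028,
    window: str = "hann",
    overlap: float = 0.5,
) -> PowerSpectrum:
    """Estimate a one-sided PSD by Welch's method (averaged windowed
    periodograms).

    The zero-frequency bin is dropped: after constant detrending its estimate
    may be zero or negative and the log target would be undefined there.

    Parameters
    ----------
    samples :
        Time series, at least one segment long.
    fs :
        Sampling rate in Hz.
    segment_length :
        Samples per Welch segment; sets the grid spacing fs / segment_length.
    window :
        Window name understood by scipy (default Hann).
    overlap :
        Fractional overlap between segments in [0, 1); default 0.5.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("samples must be a 1-D sequence")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples contain non-finite values")
    if fs <= 0:
        raise ValueError("fs must be positive")
    segment_length = int(segment_length)
    if segment_length < 2:
        raise ValueError("segment_length must be >= 2")
    if len(x) < segment_length:
        raise ValueError(
            f"signal of {len(x)} samples is shorter than one segment ({segment_length})"
        )
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    freqs, psd = _signal.welch(
        x,
        fs=fs,
        window=window,
        nperseg=segment_length,
        noverlap=int(round(overlap * segment_length)),
        detrend="constant",
        scaling="density",
        return_onesided=True,
    )
    keep = freqs > 0
    return PowerSpectrum(freqs[keep], psd[keep])


def log_power(spectrum: PowerSpectrum) -> np.ndarray:
    """Natural log of the PSD: the regression target for measured spectra."""
    if np.any(spectrum.psd <= 0):  # unreachable for a valid PowerSpectrum
        bad = spectrum.frequencies[np.argmax(spectrum.psd <= 0)]
        raise ValueError(f"log undefined: psd <= 0 at {bad:g} Hz")
    return np.log(spectrum.psd)


def restrict(spectrum: PowerSpectrum, fmin: float, fmax: float) -> PowerSpectrum:
    """Keep only frequencies with fmin <= f <= fmax."""
    if fmin >= fmax:
        raise ValueError("fmin must be < fmax")
    mask = (spectrum.frequencies >= fmin) & (spectrum.frequencies <= fmax)
    if int(mask.sum()) < 2:
        raise ValueError(
            f"restriction to [{fmin:g}, {fmax:g}] Hz leaves fewer than 2 frequencies"
        )
    return PowerSpectrum(spectrum.frequencies[mask], spectrum.psd[mask])


def aggregate_channels(signals) -> np.ndarray:
    """Point-wise arithmetic mean of equal-length channels (e.g., O1 and O2)."""
    if len(signals) < 1:
        raise ValueError("need at least one channel")
    arrs = [np.asarray(s, dtype=float) for s in signals]
    n0 = len(arrs[0])
    for i, a in enumerate(arrs):
        if a.ndim != 1:
            raise ValueError("channels must be 1-D")
        if len(a) != n0:
            raise ValueError(f"channel {i} has length {len(a)}, expected {n0}")
    return np.mean(np.stack(arrs, axis=0), axis=0)


def read_edf_channels(path, channel_labels):
    """Read selected channels from an EDF file (case-insensitive label match).

    Requires the optional ``mne`` dependency. Returns ``(signals, fs)`` where
    ``signals`` is a list of 1-D arrays ordered as requested.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF input requires the optional 'mne' dependency (pip install bandtree[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    lookup = {name.strip().lower(): name for name in raw.ch_names}
    picked = []
    for label in channel_labels:
        key = label.strip().lower()
        # EDF labels are often prefixed, e.g. "EEG O1"; accept suffix matches too
        name = lookup.get(key)
        if name is None:
            suffix = [v for k, v in lookup.items() if k.endswith(key)]
            if len(suffix) == 1:
                name = suffix[0]
        if name is None:
            raise KeyError(f"channel {label!r} not found; available: {raw.ch_names}")
        picked.append(name)
    data = raw.get_data(picks=picked)
    return [data[i] for i in range(len(picked))], float(raw.info["sfreq"])
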