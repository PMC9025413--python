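"""Synthetic inputs: the artificial 1/f power spectrum and an EEG-like test
signal with a known alpha peak.

The artificial spectrum is P(f) = 1/f + r with r ~ Uniform[0, noise_high)
drawn independently per frequency, on an evenly spaced grid of ``n_freqs``
frequencies — a broadband 1/f decline with additive white noise, the
characteristic shape of an EEG power spectrum. Note the noise is additive in
power, so the spectrum is naturally analyzed on the linear-power scale
(``target="linear"``); its low-frequency power spike carries most of the
variance.

The EEG-like signal is a pure sinusoid at the alpha frequency plus white
Gaussian noise: after Welch estimation its PSD is flat with a single narrow
peak, exercising the full signal -> spectrum -> band-discovery path. Neither
generator attempts realistic EEG (no 1/f^beta background in the time-domain
signal, no non-stationarity, no artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import PowerSpectrum

__all__ = [
    "ArtificialSpecConfig",
    "generate_artificial_spectrum",
    "generate_eeg_like_signal",
]


@dataclass(frozen=True)
class ArtificialSpecConfig:
    """Parameters of the artificial 1/f spectrum.

    Defaults: 150 unique frequencies evenly spaced on [0.2, 30] Hz (i.e.,
    0.2 Hz spacing, the first 150 bins of a 0.2 Hz-resolution grid) and
    additive uniform noise on [0, 0.4).
    """

    n_freqs: int = 150
    fmin: float = 0.2
    fmax: float = 30.0
    noise_high: float = 0.4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_freqs < 2:
            raise ValueError("n_freqs must be >= 2")
        if not 0 < self.fmin < self.fmax:
            raise ValueError("need 0 < fmin < fmax")
        if self.noise_high < 0:
            raise ValueError("noise_high must be >= 0")


def generate_artificial_spectrum(config: ArtificialSpecConfig | None = None) -> PowerSpectrum:
    """P(f) = 1/f + Uniform[0, noise_high), i.i.d. per frequency, seeded."""
    if config is None:
        config = ArtificialSpecConfig()
    rng = np.random.default_rng(config.seed)
    f = np.linspace(config.fmin, config.fmax, config.n_freqs)
    psd = 1.0 / f + rng.uniform(0.0, config.noise_high, config.n_freqs)
    return PowerSpectrum(f, psd)


def generate_eeg_like_signal(
    fs: float = 500.0,
    duration: float = 60.0,
    alpha_freq: float = 10.0,
    alpha_amp: float = 1.0,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Sinusoid at ``alpha_freq`` plus white Gaussian noise, seeded.

    The sampling rate must resolve the oscillation (fs > 2 * alpha_freq).
    """
    if fs <= 2 * alpha_freq:
        raise ValueError(
            f"fs={fs} Hz violates the Nyquist requirement fs > 2*alpha_freq={2 * alpha_freq}"
        )
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(fs * duration))) / fs
    return alpha_amp * np.sin(2 * np.pi * alpha_freq * t) + rng.normal(0.0, noise_sd, len(t))
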