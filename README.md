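# bandtree

Self-supervised discovery of frequency bands from a power spectrum.

EEG analysis conventionally groups spectral power into fixed bands — delta
(1–4 Hz), theta (4–8), alpha (8–12), beta (12–30) — yet published boundaries
vary by several Hz across studies, and the best grouping plausibly depends on
the subject and task. `bandtree` instead *learns* band boundaries from the
spectrum itself, with no target variable: it works for any power spectrum
(single- or multi-channel EEG, or any other signal), needing only the
spectrum's shape.

## Method

Given a spectrum on N unique frequencies, the regression target is
Y_i = ln P̂(f_i) (the raw PSD can be used instead via `target="linear"`).

1. **Band boundaries for each k** — a regression tree on (frequency → Y) with
   a leaf-count cap: grow greedily, best-first, always splitting whichever
   current band admits the largest decrease in residual sum of squares. The
   k leaves are contiguous ("member-adjacent") frequency bands, and the
   boundary sets are *nested*: the k-band boundaries are a subset of the
   (k+1)-band ones.
2. **Band count selection** — each k ∈ {2, …, N} is scored with an
   AIC-inspired quality score

       QS(k) = −ln r²(k) + 2k/N,

   where r² is the coefficient of determination of the k-band
   piecewise-constant fit. The partition minimizing QS wins. Both terms live
   on ≈ [0, 2]: the fitness term is ≤ 2 whenever r² ≥ e⁻² ≈ 0.135, and the
   saturated model k = N has QS = 2 exactly, so the selected k is always
   interior.

An exact dynamic-programming k-segmentation oracle
(`dp_optimal_partition`) is included for validating the greedy grower, and
fixed named band sets (e.g., the standard delta/theta/alpha/beta taxonomy)
can be scored with the same r²/QS machinery for comparison
(`evaluate_fixed_bands`).

## Worked example

Simulate the artificial EEG-like spectrum P(f) = 1/f + U[0, 0.4) on 150
frequencies (0.2–30 Hz), discover its bands, and score the standard bands on
the same spectrum. This synthetic power curve is analyzed on the linear power
scale (`--target linear`); measured spectra default to ln PSD.

```bash
bandtree simulate --seed 1 --out spectrum.csv
bandtree discover --input spectrum.csv --target linear --out run
bandtree evaluate --input spectrum.csv --target linear --out run
```

which logs

```
wrote 150-frequency spectrum to spectrum.csv
best_k=6  r2=0.95  qs=0.13  boundaries_hz=[0.3, 0.5, 0.9, 1.9, 7.3]
k=4  r2=0.32  qs=1.20
```

Six bands minimize QS for this spectrum. The six-band piecewise-constant fit
explains 95% of the power variance at a QS of 0.13, against 0.32 / 1.20 for
the fixed four-band standard set — the discovered bands chop the steep 1/f
rise below 2 Hz finely (boundaries at 0.3, 0.5, 0.9, 1.9 Hz) and keep the
flat tail coarse, which no fixed taxonomy does. `run/bands.json` holds the
full-precision report (boundaries, per-band means, SSE, r², QS) and
`run/quality_curve.csv` the per-k r²/QS curve.

The same from Python:

```python
from bandtree import ArtificialSpecConfig, generate_artificial_spectrum, select_band_count

spec = generate_artificial_spectrum(ArtificialSpecConfig(seed=1))
best, curve = select_band_count(spec, target="linear")
print(curve.best_k, round(best.r2, 2))   # 6 0.95
```

For a measured recording, `bandtree discover --input rec.edf --format edf
--channels O1,O2 --fmin 1 --fmax 30 --out run` averages the occipital
channels, estimates the PSD by Welch's method (Hann window, 1028-sample
segments, 50% overlap), restricts to 1–30 Hz, and discovers bands on ln PSD.

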