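# Methods

## Model

A band partition is a piecewise-constant model of a spectrum's regression
target against frequency: k contiguous bands, each predicting the arithmetic
mean of the target inside it (the SSE-minimizing constant). Two targets are
supported:

- `target="log"` (default): Y_i = ln P̂(f_i). Measured power spectra span
  orders of magnitude; the log keeps the fit from being dominated entirely by
  the lowest frequencies and makes band means interpretable as mean log
  power. This requires strictly positive PSD values, which is why
  `PowerSpectrum` enforces psd > 0 and `welch_psd` drops the zero-frequency
  bin (after constant detrending the DC estimate can be zero or negative).
- `target="linear"`: the raw PSD. Appropriate when the spectrum is already a
  bounded, order-one curve. The bundled artificial spectrum
  P(f) = 1/f + U[0, 0.4) is of this kind: its noise is additive in power
  (taking logs would turn the uniform power noise into heavy-tailed log noise
  at high frequency and change the problem), so the case-study pipeline and
  the acceptance script analyze it on the linear scale.

## Greedy best-first growth

`grow_partition(spectrum, k)` starts from a single band and performs k−1
splits; at each step every current band's best internal cut (the one
minimizing SSE(left) + SSE(right), computed in O(band length) with prefix
sums) is known, and the band offering the largest SSE decrease is split.
This is exactly how a leaf-count-capped regression tree with one ordered
predictor grows best-first, and the test suite confirms bit-level parity of
the fitted values with `sklearn.tree.DecisionTreeRegressor(max_leaf_nodes=k)`
on random spectra. Minimum band occupancy is one sample; there is no depth
cap and no pruning.

Consequences relied on elsewhere:

- **Nesting.** Growth only ever adds cuts, so the k-band boundary set is a
  subset of the (k+1)-band set, and `grow_nested` obtains all partitions for
  k = 1..kmax in one pass.
- **Monotonicity.** SSE is non-increasing and r² non-decreasing in k.
- **Suboptimality.** Greedy growth is globally optimal at k ∈ {1, 2, N} but
  not in general; `dp_optimal_partition` / `dp_sse_curve` implement the exact
  O(N²k) dynamic program over prefix sums as a lower envelope, used
  in tests to bound the greedy SSE.

Tie-breaking is deterministic: within a band the smallest cut index wins;
across bands the band with the lowest left-edge frequency wins. Reported
boundary frequencies are midpoints of the two grid samples flanking a cut —
boundaries generally fall off-grid (e.g., 7.3 Hz on a 0.2 Hz grid).

## Quality score and band-count selection

QS(k) = −ln r²(k) + 2k/N, with N the number of unique frequencies
(equivalently the maximum band count). The natural-log base is pinned by two
arithmetic anchors: QS(0.94, 6, 150) = 0.1419 → "0.14", and the fitness term
equals 2 at r² = e⁻² ≈ 0.135. r² ≤ 0 (fit no better than the global mean)
maps to QS = +∞ rather than a complex value; such k can never be selected.
Ties on the minimum go to the smallest k (parsimony). The default candidate
range is k = 2..N; k = 1 has r² = 0 (hence QS = ∞) and is only meaningful if
explicitly requested. QS(N) = 2 always, so the saturated model never wins.

`r_squared` returns 0 for a flat spectrum (SST = 0): with no variance to
explain, any partition is declared no better than the null model.

## Fixed band sets

`evaluate_fixed_bands` scores named boundary sets with the same machinery.
By default the outermost edges are stretched to the spectrum's range so
every frequency is assigned (`coverage="extend"`) — the whole-spectrum
comparison a discovered partition gets; `coverage="drop"` instead excludes
uncovered frequencies and computes SST on the survivors. The default
standard set (delta 1–4, theta 4–8, alpha 8–12, beta 12–30 Hz) is a
configuration default; published taxonomies differ by ±1–2 Hz at most edges,
so comparisons against "the" standard bands inherit that imprecision.

## Synthetic data

`generate_artificial_spectrum` draws P(f) = 1/f + r, r ~ U[0, noise_high)
i.i.d. per frequency, on an evenly spaced grid; defaults are 150 frequencies
on [0.2, 30] Hz (0.2 Hz spacing) and noise_high = 0.4. The grid endpoints
are a design choice: the range matches the 0–30 Hz extent over which EEG
band taxonomies are defined while keeping 1/f finite, and 150 points at
0.2 Hz spacing mimics the first 150 bins of a fine Welch grid. Under these
conditions the QS-selected band count is modally 6 (about 60% of seeds, with
5 most of the remainder) and the six-band fit has median r² ≈ 0.94; both are
recomputed, not stored, by `scripts/acceptance.py` over 100 seeds.

`generate_eeg_like_signal` is a single sinusoid (default 10 Hz, unit
amplitude) in white Gaussian noise (default SD 1) at 500 Hz — after Welch
estimation, a flat PSD with one narrow alpha-like peak. It exercises the full
signal → spectrum → discovery path: the discovered partition isolates the
peak in a dedicated band in ≥ 90% of seeds. Neither generator models real
EEG (no 1/f^β time-domain background, no non-stationarity, no line noise or
artifacts), so green tests demonstrate the algorithm's contract, not
field performance on recordings.

## Numerical choices

- Welch defaults: Hann window, 1028-sample segments, 50% overlap, constant
  detrend, one-sided density scaling; grid spacing is exactly
  fs / segment_length.
- SSE from prefix sums is clamped at 0 to absorb negative rounding residue;
  reconstruction of SSE from band means agrees to 1e-9 relative in tests.
- Reports round floats to 12 significant digits for byte-stable output,
  except the QS field, which is stored at full precision so it recomputes
  exactly from the report's own (r², k, N).
- Exact ties in split gain are resolved by position (first minimum), making
  all outputs deterministic functions of the input spectrum.

## Known limitations

- Greedy growth can misplace boundaries relative to the DP optimum for
  3 ≤ k < N; the DP oracle is exposed for audit but is O(N²k) and not meant
  for large spectra.
- Band counts selected on noisy spectra are seed-dependent in a ±1–2 band
  range; only modal/median behavior is stable.
- The quality score is empirical, not a likelihood criterion; its absolute
  values are comparable only at fixed N.
- The EDF path reads whole recordings into memory and does no artifact
  handling; inputs are assumed preprocessed.
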