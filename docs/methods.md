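# Methods

## Scope and data model

The pipeline analyzes studies of repeated multichannel LFP sessions,
each tagged with a disease state (`naive`, `mild`, `moderate`) and a
session id. The canonical montage is five bipolar channels in fixed
order: L-PMC, L-M1, R-PMC, R-M1, L-STN. All connectivity matrices are
indexed `[target, source]` with NaN diagonals; a 5-node network has
5·(5−1) = 20 defined directed entries. Sample indices are 0-based,
segment windows half-open, frequencies in Hz.

## Signal conditioning (`lfpgc.preprocess`)

Order of operations: band-pass → notch → resample → segment →
normalize.

- **Band-pass** 1–150 Hz Butterworth, second order, applied
  forward-backward (zero phase; the magnitude response is squared).
- **Notch** at 60 Hz and harmonics (120, 240 Hz) as zero-phase IIR
  band-stops with quality factor Q = 35 (bandwidth f/Q ≈ 1.7 Hz at
  60 Hz). Measured two-pass attenuation at the notch center exceeds
  120 dB; a tone 25 Hz away changes by < 0.01 dB. Notches at or above
  the Nyquist rate of the current sampling rate are skipped with a
  warning, since a 240 Hz notch is meaningless at 400 Hz.
- **Resampling** to 400 Hz by polyphase rational conversion. The
  anti-aliasing FIR (Kaiser, 80 dB design) cuts off at 45% of the
  target rate — the same convention as the acquisition hardware's
  anti-aliasing filter — with a transition band of 10% of the target
  Nyquist. A 190 Hz probe (above the 180 Hz cutoff) is attenuated by
  ~83 dB; a 170 Hz probe passes within 1 dB.
- **Segmentation** into consecutive, non-overlapping windows starting
  at sample 0: 300 s segments for GC, 30 s for power/coherence; the
  trailing remainder is discarded. Concatenating the segments
  reproduces the first k·L samples exactly (partition contract).
- **Normalization**: per segment and channel, subtract the mean and
  divide by the standard deviation. GC is invariant to channel scale,
  so this only conditions the regression and the order selection;
  channels with (numerically) zero variance raise an error naming the
  channel. Normalization is per segment rather than per session — the
  narrower of the two readings of "each LFP signal" — because it makes
  trials exchangeable units; the scale invariance of GC makes the
  choice immaterial for the causality metrics themselves.

## Spectra (`lfpgc.spectra`)

Welch averaged periodograms with Hann windows, 1 s windows, 50%
overlap: 1 Hz resolution, matching the granularity of the band edges.
Coherence is the magnitude-squared cross-spectrum normalized by the
auto-spectra; it requires at least 2 averaging windows (identically 1
with one window) and warns below 8 (upward bias ≈ 1/#windows). Band
averages are arithmetic means over grid frequencies with
lo ≤ f ≤ hi, both edges inclusive. Bands: Peak A (5–20 Hz), Peak B
(25–45 Hz), overall = 5–50 Hz for power/coherence and 0–50 Hz for GC.

## Granger causality (`lfpgc.granger`)

Per 300 s segment:

1. **Order selection.** BIC(p) = ln det Σ̂(p) + p·n²·ln(T_eff)/T_eff
   over p = 1..p_max (default 30), every candidate scored on the same
   effective span (the last T − p_max samples) from one shared Gram
   matrix; Σ̂ is the ML residual covariance.
2. **OLS fit** of the VAR(p); residual covariance with denominator
   T_eff − n·p − 1. Segments whose fitted model is not stable
   (companion spectral radius ≥ 1 − 1e-6) are rejected.
3. **Autocovariance** Γ_0..Γ_q of the fitted model: lags 0..p−1 from
   the companion-form discrete Lyapunov equation, further lags by the
   Yule-Walker recursion, extended until ‖Γ_q‖/‖Γ_0‖ < 1e-8 or the
   cap q_max (default 500; at fitted radii ≈ 0.97 the cap leaves a
   relative truncation ≤ 1e-5, negligible against estimation noise).
4. **Reduced models** via Whittle's multivariate Levinson-Durbin
   recursion on sub-blocks of the autocovariance, at order q — never
   refitted to data, so full and reduced quantities describe one
   estimated process. Time-domain GC is *conditional* by default (the
   reduced model keeps all channels but the source); the *bivariate*
   mode (pair refit on the data) is selectable.
5. **Spectral GC** is bivariate (Geweke): each pair's order-q model
   comes from the pair sub-block of the full autocovariance; the
   transfer function H = A(λ)⁻¹ and CPSD S = HΣH* give
   f_{y→x} = ln[S_xx/(S_xx − Σ̃_yy|H̃_xy|²)] with the standard
   normalization transform Σ̃_yy = Σ_yy − Σ²_xy/Σ_xx (which leaves
   H_xy unchanged). Grid: 0 to Nyquist at 0.5 Hz (configurable).
6. **Band GC**: arithmetic band means of the spectrum, computed per
   trial before any averaging across trials.

Numerical contracts: GC estimates are nonnegative; relative
excursions of (reduced − full) variance above −1e-6 are clamped to
zero, anything worse raises; the spectral log-argument is floored at
1e-12·S_xx after the same check. Scale invariance holds to < 1e-6.

**Geweke integral identity.** For bivariate models the average of
f_{y→x} over [0, Nyquist] equals F_{y→x}. This is a theorem only when
the normalization-transformed target transfer function is minimum
phase; strongly fed-back processes can genuinely violate it (we
verified one such random VAR(2) against Szegő's formula — the
spectral average falls below the time-domain value). The consistency
tests therefore sample within the theorem's hypotheses, checked by a
root test on A_ss(z) − (Σ_ts/Σ_tt)·A_ts(z).

The Whittle recursion and the VAR simulation loop are jit-compiled
with numba when available, with identical pure-numpy fallbacks (the
two paths agree to machine precision in tests).

## Synthetic studies (`lfpgc.synthgen`)

Each state is a stable 5-channel VAR built from:

- **Channel dynamics**: one AR(2) resonance per oscillator frequency
  (defaults 15 and 35 Hz), pole radius 0.94, convolved into an AR(4)
  diagonal — every channel shows the two-peak spectrum this network
  exhibits, with peaks interior to the 5–20 and 25–45 Hz bands above
  the 1/f background.
- **Directed couplings**: FIR kernels on off-diagonal coefficients — a
  damped cosine at the coupling's center frequency convolved with a
  unit-circle zero pair at each *other* oscillator frequency, so the
  coupling transfers the source's oscillation in its own band only
  (without the zeros, a 35 Hz coupling leaks through the source's
  15 Hz resonance and the planted GC peak migrates out of band).
  Kernels are normalized to unit peak gain, so `strength` ×
  state-multiplier is the peak cross-transfer gain. If the assembled
  model's spectral radius reaches 0.98 the couplings are shrunk
  uniformly (0.9 per iteration) and the factor recorded in the ground
  truth (defaults shrink by ≈ 0.43).
- **Planted pattern** (defaults): L-PMC→L-STN at 15 Hz with
  multipliers 1 → 0.35 → 0.35 (descending low-band drive weakens at
  onset); L-STN→L-PMC at 35 Hz, 0.35 → 1 → 1 (ascending high-band
  drive strengthens); R-M1→R-PMC at 35 Hz, 0.35 → 1 → 1.6
  (right-cortical drive strengthens across both transitions). The
  sign of each multiplier difference is the ground-truth direction
  per (pair, band, transition). Effect sizes are free parameters of
  the generator, not estimates of any physiology.
- **Nuisances**: 1/f^α background (α = 1, amplitude 0.4 of the clean
  channel SD), a 60 Hz line component with 2nd/3rd harmonics
  (relative amplitudes 1 : 0.3 : 0.15, random phases), and — with
  probability 0.05 per recording — whole-recording amplitude
  inflation ×8 emulating movement-artifact trials.

Defaults mirror the experimental design: 15/16/5 sessions in the
naive/mild/moderate states, 300 s sessions at 400 Hz. One seed drives
everything through spawned generators; (spec, seed) reproduces a
study bit for bit.

What the generator does *not* emulate: biophysical neural-mass
dynamics, volume conduction, electrode drift, nonstationarity within
a session, and non-gain artifact morphologies. Passing tests
demonstrate that the pipeline recovers planted linear-VAR effects
under realistic noise — not that it would recover effects whose
generative physics violate the VAR assumptions.

## Compilation and statistics (`lfpgc.stats_compile`)

- **Outlier filter**: per state, a trial is excluded (all metrics at
  once) when its summary statistic — the mean over all 20 pairs of
  overall-band GC — lies outside median ± 3·MAD; MAD below 1e-12
  (degenerate spread) disables exclusion. Retention on default
  synthetic studies is ≈ 90–95%. Filtering additionally on
  pre-normalization 5–50 Hz power is available (`filter_on_power`)
  but off by default: pure-gain artifacts are invisible to GC after
  per-segment normalization (GC is scale-invariant), so retaining
  them does not bias the GC statistics, while a second summary
  roughly doubles chance exclusions.
- **State summaries**: mean, SEM = sd/√n and ci95 = 1.96·SEM per
  metric and state; a single trial yields a missing SEM with a
  warning.
- **LMM contrasts** (GC metrics): value ~ state with a session random
  intercept — the compound-symmetry (exchangeable) covariance — fitted
  by profiled REML: given λ = σ²_b/σ²_e the GLS solution is closed
  form per session block, and λ is optimized on a log grid
  (bounded scalar minimization, boundary λ = 0 checked explicitly).
  The state effect is the session-adjusted mean difference, tested by
  Wald z. With one trial per session the fit degenerates exactly to
  OLS; with λ = 0 it reproduces pooled OLS. statsmodels MixedLM is
  the independent cross-check in the test suite (agreement ≈ 1e-4);
  the in-package solver exists because the calibration studies fit
  this model tens of thousands of times.
- **Mann-Whitney U** (power/coherence metrics): two-sided; exact when
  both groups have ≤ 8 untied values, otherwise the normal
  approximation with tie correction. An optional cap subsamples
  larger groups with a seeded generator (a fidelity option mirroring
  a historical tooling limit; off by default).
- **BH adjustment** across all metric × transition cells of one
  analysis table (the family mirrors a per-table presentation);
  non-converged cells are excluded from the family with a warning.
- **Delta report**: per transition and band, a 5×5 integer matrix
  with +1/−1 at significant (adjusted p < 0.05) increases/decreases,
  non-significant cells suppressed.

## Problem sizes used by the test suite and acceptance script

Replicated studies run at reduced sizes chosen for throughput; the
statistical contracts they check are size-invariant:

- Null calibration: 100 replicates (20 in the script) of a
  zero-coupling study, 2 sessions/state × 30 s, 10 s GC segments,
  p_max 8, 1 Hz spectral grid, q_max 300. Checks: ≤ 5% (+3 binomial
  SE) of BH-adjusted report cells significant; per-pair time-GC
  medians within the small-sample bias scale 2p/T_eff; ≥ 85% trial
  retention.
- Sign recovery: 50 replicates (10 in the script) with default
  couplings, 2 sessions/state × 300 s, 60 s GC segments
  (10 trials/state), p_max 12. Every planted cell must be flagged
  with the correct direction in ≥ 90% of replicates; observed
  recovery is 100%.
- Spectral shape: one 2-sessions/state study, 300 s sessions; 30 s
  spectral and 150 s GC segments. Group-mean PSD, coherence and GC
  spectra must peak strictly inside both bands.

## Known limitations

- Spectral GC is bivariate only; conditional *spectral* GC (and
  state-space/spectral-factorization GC) is out of scope, as are
  time-varying and nonparametric variants.
- The Wald z test is anti-conservative at very small session counts
  (no Satterthwaite correction); the null-calibration study bounds
  the practical consequence after BH.
- The generator's artifacts are pure amplitude inflation; artifact
  morphologies that distort spectra would interact with the filter
  differently.
- EDF input depends on the optional `mne` extra; the HDF5 container
  is the native interchange format.
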