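# Methods

## The index

The Fetal Stress Index (FSI) quantifies parasympathetic (vagal) tone as
the magnitude of high-frequency oscillations of the fetal RR-interval
series. HF heart-rate oscillations (> 0.15 Hz) are centered on the
respiratory frequency and driven essentially by vagal modulation, so
their amplitude tracks parasympathetic activity; during umbilical-cord
occlusion the chemoreflex raises vagal outflow, and the index is
designed to read that out continuously.

The chain, per 64 s moving window of the tachogram (windows advance by
1 s and are stamped at their end):

1. **Normalization.** `w = (x - mean(x)) / mean(x)`. The window becomes a
   dimensionless fractional fluctuation with mean exactly zero, making
   the index invariant to the heart-rate scale (a 20 ms swing around
   375 ms counts the same as a 32 ms swing around 600 ms).
2. **Wavelet high-pass.** Discrete db4 wavelet decomposition at level 5
   (at 8 Hz resampling the approximation band is 0–0.125 Hz, entirely
   below the 0.15 Hz cutoff); the approximation is reconstructed and
   subtracted, along with any residual DC. The filter is specified by a
   gain contract rather than a coefficient set: amplitude gain ≥ 0.7 at
   0.40 Hz, ≤ 0.1 at 0.05 Hz, |DC| ≤ 1e-6. The shipped realization
   measures ≈ 1.0, ≈ 0.002 and 0 respectively (symmetric extension).
3. **Envelopes.** Piecewise-linear interpolants through strict local
   maxima (upper) and minima (lower), extended flat beyond the first and
   last extremum. Where sparse extrema would let the interpolants cross,
   the lower envelope is capped at the upper one.
4. **Subareas.** The inter-envelope area is split into four equal 16 s
   segments, integrated trapezoidally: A1..A4. `AUCmin = min(A1..A4)` —
   the minimum makes the index conservative, scoring the quietest
   quarter of the window.
5. **Scaling.** `FSI_inst = 100 (a·AUCmin + b) / 12.8`, clamped to
   [0, 100]. `a` and `b` keep coherence between the visual aspect of the
   trace and the numeric scale; they are configuration (defaults
   a = 5.1, b = 1.2, the published constants of the adult index in the
   same algorithm family), not re-derived here.
6. **Averaging.** The reported FSI at time t is the mean of valid
   FSI_inst over the trailing 3 minutes, emitted only when ≥ 80 % of the
   expected samples in that span are valid. The first
   64 + 180 s of a record are warm-up.

Closed-form anchors used as oracles: a constant heart rate filters to
zero, giving the floor `100·b/12.8 = 9.375`; a stationary sine of
fractional amplitude A has inter-envelope gap 2A, so every subarea is
`2A·16` n.u.·s.

### Numerical choices and degenerate inputs

- Resampling: the RR series (intervals in ms stamped at the closing
  beat) is linearly interpolated to an 8 Hz tachogram before filtering;
  Nyquist 4 Hz comfortably covers fetal HF content. No extrapolation
  beyond the first/last beat.
- A filtered window whose peak-to-peak amplitude is below 1e-7 n.u. is
  treated as zero oscillation (AUCmin = 0): this preserves the
  constant-rate fixed point exactly. A *non*-flat window with fewer than
  two maxima or two minima is invalid rather than scored, to avoid
  spuriously minimal AUCmin.
- Artifact handling: intervals deviating > 30 % from an 11-beat running
  median are replaced by linear interpolation and flagged; any 64 s span
  with > 20 % flagged intervals is rejected, and windows overlapping
  rejected spans are invalid. The cleaner preserves incoming flags, so
  it is idempotent.
- Pre-sampling summaries (FSI_min/max/mean over the 10 minutes before a
  blood-gas draw) use the left-open right-closed interval
  `(t - 600, t]` over the *averaged* series — the quantity reported as
  "the FSI" — not the instantaneous one.

## Statistics

Group comparison at the clinical acidosis threshold pH ≤ 7.20 uses the
Wilcoxon rank-sum (Mann–Whitney) form, since the two event groups are
unequal-sized and unpaired; a signed-rank mode pairing each subject's
group means is exposed for sensitivity analysis. Exact null
distributions are used when the combined tie-free sample is ≤ 25;
otherwise the normal approximation with tie correction. Spearman rho
uses exact permutation enumeration for n ≤ 9 and the t-approximation
beyond. The Friedman statistic is computed with average-rank tie
handling; an all-tie matrix yields statistic 0, p = 1 by convention.
Events are the unit of analysis by default (subjects contribute several
samplings); the pre-occlusion sample is excluded from the group
comparison. No multiple-testing correction is applied, and the output
metadata says so.

Type-I calibration of the three tests is checked by null simulation at
study-like sizes (rank-sum 12 vs 12, Friedman 8 subjects × 4 time
points, Spearman n = 12), where the realized level sits in
[0.03, 0.07] at nominal 5 %.

## The synthetic cohort

No fetal-lamb recordings are deposited, so the generator emulates the
experiment: a 30-minute baseline, then partial (75 %) cord occlusion for
at most 120 minutes with blood gases every 15 minutes. The instantaneous
RR model is

    RR(t) = mean_rr(t) · (1 + a_HF(t) sin(2π·0.4·t) + a_LF sin(2π·0.05·t) + ε),

integrated beat by beat (ε white Gaussian, sd 0.005/beat). At occlusion
the mean heart rate steps from 160 to 106 bpm and mean arterial
pressure from 42 to 58 mmHg (lognormal ~5 % inter-subject jitter) — the
chemoreflex bradycardia-plus-hypertension signature. Arterial pH follows
piecewise targets 7.40 → 7.23 → 7.18 → 7.12 at 0/15/30/45 min (per-sample
noise sd 0.02), and the HF amplitude is coupled linearly to the pH
deficit:

    a_HF(t) = 0.02 + 0.08 · max(0, 7.40 − pH(t)).

The coupling is phenomenological, not mechanistic: it reproduces the
direction and approximate magnitude of the association the index is
meant to detect (baseline a_HF = 0.02 maps near FSI ≈ 30–35; pH 7.12
maps near FSI ≈ 55). Slope 0 gives a null cohort. Gas-panel values
(pO2, pCO2, lactate, base deficit) are piecewise-linear trends through
reference cohort medians with noise scaled to the printed interquartile
ranges — no physiological model is attempted. Occlusion ends at the
first sample with pH ≤ 7.20 once at least three post-occlusion samples
exist (the realized experimental cohorts report the full 45-minute
panel), or at the 120-minute cap.

What the generator does **not** emulate: accelerations/decelerations and
movement artifacts, non-sinusoidal and drifting respiratory modulation,
ectopic beats, baroreflex dynamics, or umbilical flow itself (the 75 %
occlusion appears only through its hemodynamic and gasometric
consequences). Passing tests therefore demonstrate that the pipeline
recovers a controlled HF-amplitude signal and its pH coupling under
realistic sampling and noise — not that the index performs identically
on real fetal ECG.

A known sampling effect worth naming: a 0.4 Hz modulation carried by
beats ~0.4–0.6 s apart is attenuated by roughly sinc²(f/f_beat) when the
beat-wise samples are linearly interpolated onto the tachogram (≈ 0.93
at 375 ms RR, ≈ 0.82 at 600 ms). This is inherent to beat-sampled HRV,
affects any such device, and is why scale-invariance of the *index* is
asserted on tachograms with identical fractional modulation rather than
through the beat generator.

## Problem sizes

Default study conditions are 8 subjects, ~75 minutes of RR per subject,
four blood-gas samplings. Monte-Carlo checks use 50 seeds for direction
recovery and its null, 20 for cohort calibration, 1000 replicates for
type-I calibration, 100 random instances per enumeration sweep; the
detector benchmark uses a 5-minute record at 20 dB SNR.

## Known limitations

- Constants a, b default to the adult-index values; absolute FSI levels
  are therefore only analogous to, not identical with, any particular
  device's output. All conformance properties are either
  constant-independent or stated at these defaults.
- The envelope stage assumes oscillations dense enough to provide ≥ 2
  maxima and minima per 64 s window; very slow residual content can
  invalidate windows rather than score them.
- The Friedman table is computed over subjects with complete panels
  only; subjects stopping early are dropped from that test (not from
  the group comparison).
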