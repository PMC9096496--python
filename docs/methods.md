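# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `hepflow`. Units follow one convention throughout: time in
seconds with half-open intervals `[t0, t1)` and 0-based sample indices, EEG
in µV, inter-beat intervals (IBIs) in ms, HRV band powers in ms² (natural
log where a log power is reported), breathing rates in cycles/min.

## Study structure

The pipeline analyzes a three-condition session: a pre-game resting state,
a gameplay block split into five equal non-overlapping intervals, and a
post-game resting state (full-length design: 300 s / 1500 s / 300 s). All
per-condition metrics are computed on these half-open segments; the
"delta" summaries used by the correlation layer are last-minus-first game
interval differences (positive = increase toward the end of play).

## Synthetic data model

The generator is intentionally simple so that every downstream stage has a
closed-form or ground-truth oracle.

**ECG.** Beat times are laid down sequentially; each IBI is
`mean_ibi + d_LF·sin(2π·0.1 t) + d_HF·sin(2π·f_resp t) + N(0, ibi_sd)`,
floored at 250 ms. A pure sinusoidal modulation of depth `d` contributes a
band power of `d²/2` ms², which is the oracle for the spectral-HRV stage.
Each beat is rendered as a parametric sum-of-Gaussians PQRST template
(biphasic QRS ≈ 80 ms wide with slight Q/S asymmetry, plus P and T bumps);
the template deliberately does not equal any wavelet shape so the detector
is not trivially matched to the generator.

**EEG.** Each channel is 1/f^a-shaped Gaussian noise (default a = 1, 10 µV
SD), plus a 10 Hz alpha sinusoid on parieto-occipital channels (default
5 µV), plus a cardiac-field artifact (attenuated beat template decaying
within 100 ms of each R-peak, default 5 µV), plus an injectable
heartbeat-locked component: a Hann bump over a configurable post-R window
(default 400–500 ms) scaled by a per-channel weight map (default the
fronto-central set Fz, FC1, FC2, Cz). Condition effects are created by
generating each condition from its own config; the default study
suppresses the bump during gameplay (2 µV at rest vs 0 µV during play).

**Respiration.** An oscillation whose instantaneous rate is drawn per
breath from N(resp_rate, resp_rate_sd²), with optional movement artifacts:
sharp Gaussian jolts (σ = 50 ms) of 5–10× the signal amplitude at Poisson
times. True breath-peak times are recorded.

**Behavior.** A Gaussian copula: requested Spearman correlations between
any table columns are mapped to latent Pearson correlations via
`r = 2·sin(πρ/6)`; marginals are transformed per variable (flow-scale
scores clipped to [1, 7], visual-analog scores to [0, 10], log-normal
session-duration estimates, and so on). Infeasible (non-PSD) correlation
requests raise. The study pipeline additionally offers
`attach_behavior`, which correlates behavioral columns with *measured*
physiological summaries via a conditional-Gaussian construction on normal
scores.

What the generator does **not** emulate: volume-conducted cardiac fields
with realistic dipole topography, ectopic rhythms or atrial fibrillation,
non-stationary EEG artifacts (blinks, muscle), electrode drift, or missing
data. Passing tests therefore demonstrate the correctness and calibration
of the *analysis machinery* under the assumed signal model, not robustness
to every failure mode of real recordings.

## R-peak detection

A shift-invariant (stationary) discrete wavelet transform with `sym4`
wavelets, 5 levels (signals edge-padded to a multiple of 2⁵). The signal
is reconstructed from the *detail* levels whose dyadic passband
`[fs/2^(j+1), fs/2^j]` overlaps the QRS energy band (default 10–40 Hz):
levels 4–5 at 1000 Hz, 2–3 at 250 Hz. A literal approximation-level
reconstruction would retain only sub-16 Hz content at 1000 Hz, which does
not cover the QRS; the level choice is therefore derived from the sampling
rate. The reconstruction is squared; candidate peaks (250 ms refractory)
are kept when they exceed 0.3× a rolling median (11 peaks) of candidate
heights, plus a small global floor (5% of the upper-quartile height)
against noise runs; each detection is refined to the raw-ECG maximum
within ±40 ms. All thresholds are relative, making the detector invariant
to positive rescaling of the input.

## IBI artifact correction

IBIs deviating more than 25% (configurable) from an 11-beat running median
are flagged. A gap of ≈2× the local median (within ±25%) is interpreted as
a missed beat and split by an interpolated beat at the midpoint; two
successive short IBIs summing to ≈1 median are interpreted as one spurious
beat, which is removed. The procedure is a single forward pass and is
idempotent; flags (`original` / `interpolated` / `removed`) are retained
per beat. When more than 20% of IBIs are flagged a warning advises manual
review. This median-filter rule implements the intent of commercial
artifact-threshold correction without reproducing any proprietary rule.

## Spectral HRV

The IBI series (each IBI timestamped at its terminating beat) is cubic-
spline interpolated to a uniform 4 Hz series, linearly detrended, and
Welch-transformed (Hamming window, 256 s or the full segment if shorter,
50% overlap). LF and HF power are trapezoid integrals of the PSD over
[0.04, 0.15) and [0.15, 0.4) Hz. Preconditions: ≥120 s of beats and ≥60
beats. HF-HRV is physiologically interpretable only for breathing rates of
9–24 cycles/min; metrics carry a `resp_gate` flag (`fail_low`/`fail_high`
outside the *inclusive* [9, 24] band) and gated segments are excluded from
frequency-domain group analyses. Log powers are natural logs of ms²
(the choice of log base is a reporting convention; ln matches common HRV
software output).

## Respiration

The belt signal is decimated to 25 Hz (anti-aliased polyphase), low-pass
filtered at 2 Hz with an 8th-order Butterworth applied forward-backward
(zero phase; effective order 16), and amplitude-clipped: samples outside
mean ± 2 SD are replaced by linear interpolation. Two numerical choices
extend the plain rule: the band is re-estimated iteratively (large spikes
inflate the first-pass SD and would otherwise hide smaller excursions),
and a 1 s guard margin around each out-of-band run is interpolated as
well, because a sharp artifact leaks zero-phase filter ringing into
otherwise in-band neighboring samples. The degenerate SD = 0 case skips
clipping. Breath peaks are local maxima with prominence ≥ 0.2× the segment
SD and spacing ≥ 1.5 s; RR-mean and RR-STD are the mean and SD of the
breath-by-breath instantaneous rates (60/inter-peak interval), making the
metrics invariant to positive rescaling.

## EEG preprocessing and heartbeat-evoked potentials

Reduced, ICA-free preprocessing: decimation to 250 Hz, zero-phase 4th-
order Butterworth band-pass 1.5–70 Hz, common-average re-reference.
ICA-based artifact removal (and source localization) is deliberately out
of scope; an optional absolute-amplitude epoch rejection (off by default,
100 µV when enabled) stands in for it. Note that common-average
re-referencing subtracts a fraction of any spatially broad evoked
component — with the default fronto-central weight map, k target channels
out of C total retain (1 − k/C) of the injected amplitude; calibration
experiments therefore use montages with flanking channels.

Epochs span −200 to +600 ms around each R-peak (half-open sample slices);
the per-channel mean over −200 to −100 ms (the pre-R interval least
contaminated by the cardiac field) is subtracted. Epochs exceeding the
recording bounds are dropped (`edge`), optionally also high-amplitude
epochs (`amplitude`); retained + rejected = in-bounds R-peaks. Epoch
overlap at IBIs < 800 ms is allowed. The per-subject/condition average and
its fronto-central 400–500 ms window mean are the quantities carried into
group statistics. Alpha power uses Welch with a 2000-sample Hamming window
and 10% overlap, reported as band-mean PSD × bandwidth over 8–12 Hz
(a pure in-band sinusoid of amplitude A yields A²/2).

## Surrogate-heartbeat null

A surrogate R-peak train is the original train circularly shifted by one
uniform random offset and wrapped modulo the segment duration: the IBI
sequence is preserved exactly (up to the single wrap-join interval) while
beats are decoupled from the EEG. Per-beat independent jitter would
destroy the IBI variability and was rejected. The surrogate suite repeats
the condition contrast (default: paired t-test on fronto-central window
means) with fresh surrogates per repetition; on data without a genuine
heartbeat-locked condition difference its significance rate matches the
nominal α.

## Cluster-based permutation test

Element-wise paired (or pooled two-sample) t statistics are thresholded at
the two-tailed critical value (α = 0.05); supra-threshold channel×time
bins of equal sign are clustered under spatial adjacency × temporal
contiguity; cluster mass is the sum of t values. The null distribution is
the maximum absolute cluster mass over permutations — per-subject sign
flips of difference maps for paired designs, group-label shuffles for
independent designs — and Monte-Carlo p = (1 + #{null ≥ |mass|}) /
(n_perm + 1), so the smallest attainable p is 1/(n_perm + 1) and p = 0 is
impossible. Using max |mass| across both signs jointly controls the
family-wise error over both tails. Channel adjacency comes from electrode
positions (bundled standard 10-10 montage): channels closer than 1.6× the
median nearest-neighbor distance are linked (a Delaunay option exists).
The implementation is cross-checked in tests against an exhaustive
sign-flip enumeration on a toy grid and against MNE's spatio-temporal
cluster test.

The bin-wise alternative (`pointwise_perm_fdr`, 1000 permutations) builds
each bin's own permutation null and applies Benjamini–Hochberg FDR across
all channel×time bins.

## ANOVA, correlations, summary tests

The mixed repeated-measures ANOVA is computed from split-plot sums of
squares (within effect, between-group effect, interaction; partial η²
reported). The Greenhouse–Geisser ε comes from the *pooled within-group*
covariance of the level scores (double-centered; clamped to
[1/(k−1), 1]; ε = 1 exactly at k = 2); within-effect degrees of freedom
are multiplied by ε. Note that some packages estimate ε from the grand
covariance ignoring group structure — for single-group designs the two
definitions coincide, and tests verify agreement with an independent
implementation there.

Correlations are Pearson by default, switching to Spearman whenever
Shapiro–Wilk rejects normality (α = 0.05) for either variable; missing
values are dropped pairwise with counts recorded, and BH-FDR is applied
per correlation family. Summary-statistic group comparisons use the
pooled-variance two-sample t (df = n₁+n₂−2), oriented as
(second − first group) so that published group-order-dependent signs are
reproduced; Mann–Whitney U uses midrank ties with an exact p for small
tie-free samples and the tie-corrected normal approximation otherwise.

## Problem sizes used in validation

Calibration experiments run at deliberately scaled sizes chosen once:
type-I calibration uses 200 runs of 10 subjects × 4 channels × 60 s
segments with 500 permutations; effect recovery uses 20 runs of 20
subjects × 8 channels × 120 s with 1000 permutations (2 µV injected
difference); the surrogate suite uses 12 subjects × 90 s × 100
repetitions; the default synthetic study uses 150 s rest blocks and a
750 s game block so every 5-min-scaled interval still satisfies the
spectral-HRV preconditions. `scripts/acceptance.py` reruns all of these
from scratch under a caller-supplied seed.

## Known limitations

* EDF/BrainVision writing is minimal (16-bit EDF with 1 s records;
  float32 multiplexed BrainVision) and declares µV units for all
  channels; files from other systems with different physical units must
  be converted before reading (the readers assume µV).
* The detector assumes upward R-peaks; inverted leads should be negated
  upstream.
* Unbalanced missing cells are not handled inside the ANOVA (callers must
  listwise-delete); condition/interaction sums of squares use the
  unweighted cell-mean formulas, exact for balanced designs.
* The surrogate suite's default per-repetition test is the window-mean
  paired t-test, not the full cluster test, for tractable repetition
  counts.
* No source localization, ICA decomposition, or time-frequency analyses.
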