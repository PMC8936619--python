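# Methods

This note documents the models, numerical choices and limitations of the
package, in the order data flows through it.

## Signals and preprocessing

**EGG.** Multichannel abdominal recordings are modelled at 10 Hz (the rate
obtained after anti-alias decimation of a raw amplifier stream). Spectra
are Welch estimates on Hann-tapered 200-s windows with 150-s overlap,
density-scaled so band-integrated power equals signal variance; a sinusoid
of amplitude A integrates to A²/2 over its peak. "Peak power" of a single
bin is the density times the taper's equivalent noise bandwidth, which
recovers A²/2 for a pure oscillation and is the quantity compared with the
15 µV² acceptance threshold. Peak *sharpness* — used to pick the channel —
is the peak power minus the mean band power in the two flanking bands of
equal width; ties go to larger absolute power, then lower channel index.
When no channel has a qualifying in-band local maximum the extraction
returns a no-peak verdict (`None`), the participant-exclusion signal.

**Narrow-band filter.** The gastric filter is a frequency-sampled FIR
band-pass over [f₀ − 0.015, f₀ + 0.015] Hz applied forward and backward
(zero phase). A literal 5-tap filter cannot isolate 0.05 Hz at any of the
sampling rates involved, so the order parameter is interpreted as a cycle
multiplier: the filter length is five cycles of the band's low edge,
`round(5·fs/(f₀ − 0.015))` taps (forced odd). The same design is used for
the EGG (fs = 10 Hz) and for BOLD (fs = 1/TR), so both phase estimates
share their filter response. Physio records carry 30 s of padding on both
sides of the scan; filtering happens on the padded record and the padding
is cut afterwards.

**Decimation** is multi-stage (factors ≤ 10), each stage a zero-phase FIR
anti-alias low-pass (cutoff 0.8/q of Nyquist) followed by integer
subsampling, keeping the first output sample aligned to the first input
sample. `scipy.signal.decimate` was deliberately not used because its FIR
path leaves edge transients on short records; the edge behaviour here is
governed by `filtfilt`'s odd-extension padding instead.

**Cycle statistics.** Cycles are delimited by linearly interpolated upward
crossings of the unwrapped phase through multiples of 2π, on the full-rate
narrow-band phase over the scan window. Normogastria is the fraction of
cycle durations inside 15–30 s; participants under 70% would be excluded.

**HRV.** Interbeat intervals are assigned to the closing beat, cubic-spline
interpolated at 1 Hz, and Welch-integrated over LF = 0.06–0.15 Hz and
HF = 0.16–0.4 Hz (120-s windows, 100-s overlap). Both bands are
configurable; the defaults follow the textbook definitions above.

**BOLD cleaning.** Per voxel: 3-mm FWHM Gaussian smoothing (volume-wise),
removal of linear and quadratic trends by least squares, order-4
Butterworth band-pass 0.01–0.1 Hz applied forward–backward, OLS projection
of nuisance regressors (mean series of a 9-mm sphere at the configured
CSF location; optionally six cardiac Fourier regressors cos(mθ), sin(mθ),
m = 1..3, with cardiac phase linear between R peaks, at volume rather than
slice granularity), then the participant-specific narrow-band filter and
trimming of 15 volumes per edge. Both filters are zero-phase by
construction because the downstream metric is a phase statistic. The
band-pass output is re-demeaned: edge transients of finite-length
filtering can reintroduce a small offset, and the detrending contract
(zero mean) is kept exact. Frame-wise displacement is the sum of absolute
backward differences of the translations plus 50 mm times that of the
rotations.

## Coupling and group inference

PLV uses wrapped phase differences, so unwrapping conventions cannot
affect it; it is symmetric, bounded in [0, 1], and invariant to a common
phase offset and to positive amplitude scaling of either raw signal.

Chance level pairs a participant's BOLD (filtered at their *own* f₀) with
each other participant's gastric phase exactly once, in cohort order, and
takes the voxelwise median (even counts: mean of the two middle order
statistics). The white-phase expectation E[PLV] = √π/(2√T) ≈ 0.043 at
T = 420 applies only to i.i.d. phases; the surrogate chance level of
narrow-band signals is several times larger because the effective number
of independent samples is the bandwidth–duration product, not T. That is
why the surrogate median — not the analytic i.i.d. value — is the null.
A known consequence of this surrogate design is a small positive bias of
empirical-minus-chance at frequency-matched noise voxels: the empirical
pair shares f₀ exactly while surrogate pairs differ by up to the f₀
spread, which slowly rotates their phase difference.

The cluster test forms candidate clusters from connected voxels (face
adjacency by default, 18/26 configurable) exceeding the one-sided t
threshold at p < 0.005, scores each by its summed t, and compares positive
(negative) cluster masses against the per-permutation maximum (minimum)
mass under per-participant sign flips of the difference maps — the exact
label-exchange null for a paired two-condition design. Monte-Carlo
p = (1 + #{null ≥ mass})/(n_perm + 1), never zero; significance at
p < 0.025 per sign. When 2ⁿ ≤ n_perm the flips are enumerated
exhaustively; the identity flip is then part of the null, so the smallest
attainable p is 2/(2ⁿ + 1) — cohorts of n ≤ 6 cannot reach the 0.025
level, which the test suite respects by using n ≥ 8. Effect size is
d = t/√n, with participant-bootstrap SDs for mask summaries. Shared
variance is magnitude-squared coherence at the bin containing f₀, with
Welch settings mirroring the EGG spectra (200 s / 150 s on the trimmed
840-s series).

## Anatomical annotation

Label overlap is reported in both directions (share of the mask per label,
share of each label covered) plus the mean effect size over the
intersection. Resampling between grids is a nearest-neighbour pull-back
through world space with half-up rounding (banker's rounding would split
ties inconsistently across a block). Gradient profiles divide the observed
cortex-masked gradient range into 100 equidistant bins (values at an inner
edge go to the higher bin, the maximum to the last) and report the
percentage of each bin's cortex voxels inside the mask. The relocation
null redraws masks of the same size uniformly over the cortex and flags
empirical bins outside the null's [2.5, 97.5] percentile envelope — a
pointwise 5% test that ignores the mask's spatial autocorrelation (as
does the procedure it implements) and becomes conservative when bins hold
few voxels, because the envelope is then discrete.

## Covariate battery

Continuous covariates are tested by Huber-weighted IRLS regression
(tuning 1.345) with the slope t on a t reference at df = n − 2 (the
reference distribution is a package choice; normal-theory df is the
conventional one). Group factors use pooled-variance unpaired t tests.
JZS Bayes factors integrate the Cauchy-prior marginal likelihood over the
variance mixing parameter with adaptive quadrature; the Cauchy scale
defaults to √2/2, which reproduces the conventional default-prior values,
and is configurable to 1. Regression Bayes factors use the BIC
approximation BF01 ≈ exp(ΔBIC/2) from Gaussian OLS likelihoods even though
the headline fit is robust — the approximation presumes likelihoods, and
OLS is the closest generative model. Corrections: Bonferroni and
Benjamini–Hochberg; ROI scans correct across ROIs within each covariate.
Voxelwise group GLMs mean-center covariates, include an intercept, and
control FWE by Freedman–Lane residual permutation with the max-|t|
statistic. Power/sample-size uses the noncentral t: the smallest n with
P(T_{n−1, d√n} > t_{1−α, n−1}) ≥ power.

## Synthetic cohort: what it emulates, and what it does not

Defaults encode the emulated protocol: 900-s scans at TR 2 s
(450 volumes), EGG at 10 Hz with 30-s padding, per-participant f₀ uniform
on [0.041, 0.057] Hz (the observed cohort range within normogastria), a
24×24×12 grid of 3-mm voxels, and a 200-voxel planted region. Gastric
phase is a Wiener-perturbed rotation dφ = 2πf₀dt + σ√dt·ε with
σ = 0.2 rad/√s, giving a cycle-length SD near 3 s at 0.05 Hz (the
inverse-Gaussian passage-time SD is σ/(2πf₀^{3/2})), matching the scale of
adult cycle-duration variability. EGG channels are A·sin(φ) with
channel-specific lognormal gains around 8–30 µV, a 20% second harmonic and
2 µV broadband noise, so selected-channel peak powers fall in the
hundreds of µV² (above threshold) while weak channels can fall below it.
Coupled voxels carry cos(φ + delay + η) with η i.i.d. von Mises(0, κ);
κ = 2 by default (planted PLV I₁(2)/I₀(2) ≈ 0.698), delays ramp linearly
over [0, π] across the region. Nuisance: per-voxel linear+quadratic drift,
a shared low-pass-filtered CSF-like source with weight 1 inside the CSF
sphere and small weights elsewhere, beat-locked cardiac pulsation
(aliased by the 2-s sampling) from the participant's simulated R peaks,
and unit-variance white noise. IBIs are base + LF (0.1 Hz) + HF (0.25 Hz)
sinusoids plus noise; R-peak times are their cumulative sums. Seeding
derives one independent stream per participant per signal class from the
master seed, so outputs are bit-reproducible and extending the cohort
never perturbs existing participants.

The generator deliberately omits: realistic anatomy, hemodynamic-response
convolution, gastric amplitude dynamics (the analysis is phase-only),
vendor physio formats, and slice-level timing. The CSF sphere is placed
away from the planted central region because an overlap would feed locked
signal into the nuisance regressor and corrupt the ground truth.
Consequently, passing tests demonstrate the correctness and calibration of
the *analysis chain* under known coupling — not that real recordings meet
the generator's assumptions.

## Recovery experiments and problem sizes

The parameter-recovery experiment (200-voxel planted region, κ = 2,
n = 20 participants, fixed seed, voxel p < 0.005, cluster p < 0.025,
1000 permutations) requires the significant-cluster mask to cover ≥ 90% of
planted voxels with ≤ 1% false positives. It runs with smoothing disabled
(`fwhm_mm = 0`): 3-mm smoothing leaks a genuinely phase-locked fraction of
the planted signal into the one-voxel shell around the region, and a
well-powered test then (correctly) detects that shell, which a
voxel-resolved ground-truth comparison would miscount as false positives.
Disabling smoothing keeps the estimand aligned with the planted mask;
smoothing remains the pipeline default for ordinary use.

Family-wise error calibration uses 200 null cohorts of n = 12 difference
maps on a 12×12×6 grid at 200 permutations each; gradient-null calibration
uses 100 uniform masks over a 32×32×12 cortex at 1000 relocations each.
These sizes keep the default suite to a few minutes while leaving
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- The surrogate chance level inherits the matched-frequency bias described
  above; the cluster test's sign-flip null does not remove a bias shared
  by all participants, so weak diffuse positive strength can reach
  significance in large cohorts. This mirrors the implemented procedure
  rather than deviating from it.
- RETROICOR operates at volume granularity; slice-time-resolved cardiac
  phase is out of scope.
- The BIC Bayes-factor approximation can collapse to extreme values for
  strongly non-Gaussian residuals, where the OLS likelihood is a poor
  stand-in for the robust fit.
- `cluster_permutation` recomputes the t map per permutation from sign
  matrices; grids much larger than ~10⁵ voxels would need a blocked
  implementation.
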