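# Methods

## Higuchi's fractal dimension

The estimator follows the classical construction: for each time step
k = 1..k_max the series is decimated into k subseries (1-based starting
offsets m = 1..k), each subseries' curve length L_m(k) is normalised by
(N−1)/(int((N−m)/k)·k) so that all k offsets are comparable, and L(k) is
their mean. The power law L(k) ~ k^(−FD) is fitted by ordinary least
squares of log L(k) on log k, and FD = −slope.

Two details are worth making explicit:

* **Sign convention.** Some presentations fit log L(k) against log(1/k)
  and read the slope as −FD; that assignment is inconsistent with
  L(k) ~ k^(−FD) itself. We regress on log k and take FD = −slope, which
  yields FD = 1 exactly on straight lines and FD → 2 on white noise —
  the magnitudes expected of the measure.
* **Fit range.** The regression uses all k = 1..k_max by default (the
  curve lengths are computed from k = 1 even though the k_max sweep grid
  starts at 2). Whether k = 1 should enter the fit is genuinely open;
  `fit_k_min` exposes the choice.

Natural logarithms are used on both axes; FD is base-invariant when both
axes share a base. The estimate is exactly invariant under affine
amplitude transforms a·y + b (a ≠ 0), because L(k) is homogeneous of
degree one in the signal: this is verified to 1e−12 in the tests.

**Windowing.** Long recordings are analysed in consecutive
non-overlapping windows of `round(fs · window_seconds)` samples (default
2 s = 256 samples at 128 Hz; a 5-minute recording yields 150 windows),
and the per-window estimates are averaged. A trailing partial window is
discarded. Constant windows — impossible in real EEG but easy to
construct synthetically — are dropped from the average with a logged
count rather than aborting the subject.

**Choice of k_max.** The single free parameter is chosen by a sweep: the
whole-sample grand average of the whole-brain windowed HFD is computed
for every k_max on a grid (default 2..128, half the 256-sample window),
and the selected k_max is the grid value whose grand average is nearest
the median of the curve. The median of an even-length list is the
midpoint of its two central values, and distance ties break toward the
smaller k_max (the cheaper, less smoothed estimate); both rules are
stated here because the selection is otherwise ambiguous. The default
k_max is 65. On correlated signals the curve rises with k_max; on white
noise it is already saturated at the plane-filling limit (≈ 2.000) and
is flat up to Monte-Carlo noise of order 1e−3, so monotonicity of the
sweep is asserted in the tests only up to the standard error of the
grand average, not step by step.

The sweep computes L(k) once per window up to the grid maximum and reads
every prefix regression off cumulative sums, so the full 127-point grid
costs barely more than a single estimate.

## Preprocessing

Recordings are band-pass filtered with a zero-phase (forward–backward)
4th-order Butterworth (default 0.1–100 Hz), resampled to 128 Hz
(polyphase, rational ratio), then re-referenced to the average reference:
the instantaneous mean across channels is subtracted, making the
channel-mean exactly zero at every sample. The zero-phase realisation is
chosen to avoid phase distortion of the fractal scaling; order and band
are configurable and filtering can be disabled.

A 100 Hz upper edge cannot survive resampling to 128 Hz (Nyquist 64 Hz);
when the requested edge reaches the target Nyquist it is capped at
0.45 × target rate (57.6 Hz) with a logged warning. The original
acquisition reference does not need modelling: average re-referencing is
invariant to the recording reference up to a common-mode term.

Artifact screening by expert inspection or ICA is inherently
irreproducible; in its place a simple configurable amplitude threshold
marks any analysis window in which any channel exceeds |threshold| μV for
exclusion. It is disabled by default so that deterministic tests bypass
it. Channel labels are normalised through the 10–20 old/new alias table
(T3↔T7, T4↔T8, T5↔P7, T6↔P8).

## Regions and the symmetry index

The default region map groups the 19-channel montage as: frontal
(Fp1, F3, F7 | Fp2, F4, F8), central (C3 | C4), temporal (T5 | T4),
parietal (P3, P7 | P4, P8), occipital (O1 | O2). Written in modern
nomenclature the temporal-left channel T5 *is* P7, which also belongs to
parietal-left, and its right counterpart is T4 = T8 — an overlapping,
anatomically asymmetric assignment. The package reproduces this grouping
literally as the default (so results are comparable with the study that
used it) and ships a `strict-disjoint` alternative with temporal =
(T7 | T8) for users who prefer disjoint, homologous regions. The
whole-brain average includes all 19 channels, midline included; a flag
restricts it to mapped channels only.

HArS = (left − right)/(left + right) is computed per positionally-paired
homologous channels — (Fp1, Fp2), (F3, F4), (F7, F8); (P3, P4), (P7, P8)
— and averaged within multi-channel regions. For HFD confined to [1, 2]
the index is bounded by ±1/3; positive values mean left-dominant
complexity.

## Copper

Ceruloplasmin binds six structural copper atoms (≈ 0.3% by mass), so the
bound fraction is CB [μmol/L] = ceruloplasmin [mg/dL] · 10 · 0.0472, and
NCC = serum copper − CB. Negative NCC, which assay noise can produce, is
preserved and flagged rather than clipped.

## Statistical battery

* **Correlations** are normality-gated: a Shapiro–Wilk test per variable
  at α = .05 selects Pearson (both pass) or Spearman, and the gate's
  decision is recorded in the result. Significance is read at α = .05
  with a trend band up to .10.
* **Age curve**: least-squares parabola of whole-brain HFD on age over
  the healthy subjects, reporting R², the overall F test and the vertex
  age −b/(2a).
* **Partial correlation** by double residualisation (both variables
  regressed on the control), df = n − 3; it agrees with the textbook
  recursion formula to 1e−9.
* **Mixed-design repeated-measures ANOVA.** The full model has region
  (5) × hemisphere (2) as within-subject factors and group (YC/EC/AD) as
  a between factor. The engine projects each subject's 10 cells onto
  orthonormal Helmert contrasts per within effect; hypothesis sums of
  squares use unweighted group means (the conventional treatment of
  unbalanced groups), the error pools within-group scatter of the
  contrast scores, and the between test is a one-way ANOVA on the
  subject-mean score. Greenhouse–Geisser epsilon is
  tr(S)²/(d·tr(S²)) on the pooled within-group score covariance,
  applied whenever a within effect has more than one numerator df;
  corrected and uncorrected p are both reported. The engine reproduces
  pingouin's mixed ANOVA and statsmodels' AnovaRM exactly on their
  shared designs (pingouin estimates epsilon from the total rather than
  pooled covariance, so epsilons agree only approximately when groups
  differ).
* **Reduced models** per region (hemisphere × group) follow a
  significant interaction, with Bonferroni-corrected post-hoc t-tests
  restricted to the adjacent-group family YC–EC and EC–AD (m = 2; the
  YC–AD comparison is omitted as uninformative about either transition).
* **HArS** is analysed per region by one-way group ANOVA with the same
  post-hoc family, plus companion correlations of regional HArS with age
  (healthy subjects) and MMSE (elderly subjects).
* **Matching tests**: two-sample t-tests on age, education, MMSE and on
  sex coded 0/1 (mirroring common practice in this literature; a χ² on
  the 2×2 table is emitted alongside).

All p-values carry their correction label; Bonferroni-corrected
p = min(1, m·p_raw) with the family size logged.

## Synthetic data

**Signals.** Fractional Gaussian noise is synthesised by circulant
embedding with the exact autocovariance
γ(k) = ½(|k+1|^2H − 2|k|^2H + |k−1|^2H) (eigenvalues checked non-negative,
embedding padded if needed) and cumulated to fractional Brownian motion,
whose graph has fractal dimension exactly 2 − H. This is the ground-truth
family for estimator validation — the tests require the windowed estimate
to sit within ±0.15 of 2 − H for H ∈ {0.3, 0.5, 0.7} and within ±0.1 of
2 for white noise, and to decrease strictly in H. Ramps, constants and
sines cover the degenerate cases. All draws are deterministic per seed.

**Cohorts.** `make_cohort` draws 24 YC / 17 EC / 67 AD subjects with
group-typical age, sex and education distributions and per-channel FD
targets generated from:

| parameter | default | meaning |
|---|---|---|
| peak_fd | 1.945 | whole-brain FD at the age vertex |
| vertex_age | 60 y | peak of the inverted-U age curve |
| curvature | 2.0e−5 FD/y² | quadratic decline away from the vertex |
| subject_noise_sd / channel_noise_sd | 0.008 / 0.006 | between-subject and between-channel scatter |
| central_parietal_ageing_slope | 4e−4 FD/y past 60 | extra elderly decline, central + parietal |
| right_parietal_ageing_slope | 2.5e−4 FD/y past 20 | right-lateralised decline driving the positive parietal HArS–age correlation |
| ad_global_delta / ad_temporo_occipital_delta | −0.015 / −0.030 FD | AD deficit, diffuse + temporo-occipital |
| mmse_fd_coupling | +160 points/FD | cognition tracks complexity |
| ncc_fd_coupling | −45 μmol/L per FD | free copper tracks parietal complexity inversely |

MMSE is rounded to integer points and truncated at the diagnostic bounds
(AD ≤ 24, EC ≥ 24), which also gives it the skewed, non-Gaussian shape
that triggers the Spearman gate. Copper is emitted as a serum
copper / ceruloplasmin pair constructed so that the pipeline's own NCC
computation recovers the generated free-copper values. Couplings act on
each subject's deviation from the deterministic prediction, so group
means stay on target. The noise scales and effect sizes were fixed once
to give clearly detectable effects at the default group sizes while
keeping whole-brain FD in the upper range typical of average-referenced
resting EEG.

One structural consequence of the symmetric inverted-U is worth noting:
with a vertex at 60, elderly controls (mean age ≈ 70) sit nearer the
peak than young controls (mean age ≈ 30), so the generated EC group mean
slightly exceeds the YC mean even though complexity declines within the
elderly range. Empirical cohorts in this field show the opposite group
ordering, implying an age curve that is flatter before 60 and steeper
after; a single quadratic cannot encode both, and the generator keeps
the quadratic because the recovery targets (negative curvature, AD < EC,
the coupling signs, the HArS–age correlation) do not depend on the
YC–EC ordering.

The fast path emits the generated per-channel FD values directly as the
"measured" HFD table; the slow path renders each channel as an
independent fBm recording with H = 2 − FD (targets clipped to
[1.05, 1.95] to keep the Hurst inversion away from estimator
saturation), and the two paths agree within the estimator tolerance
(±0.15). What the generator does **not** emulate: oscillatory rhythms
(alpha peaks, spindles), volume conduction or any cross-channel
covariance, artifacts, or non-stationarity beyond fBm's own. Passing
tests therefore demonstrate correctness of the estimator and statistics
under known fractal structure — not robustness to rhythmic or
artifactual real EEG.

## Numerical choices and degenerate inputs

* Subseries construction requires 1 ≤ m ≤ k < N and at least one
  increment (N ≥ 2k for the full L(k)); violations raise parameter
  errors naming the bound.
* Constant windows give L(k) = 0 and an undefined FD; single windows
  raise, windowed averages drop them with a warning.
* FD estimates are reported unclipped (white noise can land slightly
  above 2); the admissible test range is [1.0, 2.1].
* k_max selection resolves floating-point distance ties (within 1e−9)
  toward the smaller k_max.
* The quadratic fit rejects designs with fewer than 3 distinct ages or
  condition number above 1e12; a constant response returns zero
  coefficients, R² = 0, p = 1.
* Partial correlation treats a residual numerically zero relative to its
  source variable as exact collinearity (r = 0).
* The S1-style spreadsheet ingester matches headers case-insensitively
  against synonyms and the montage in either nomenclature; without a
  group column, groups are inferred as: no MMSE → YC, MMSE ≤ 24 → AD,
  else EC, with MMSE = 24 (which the rule assigns to AD) logged as
  ambiguous.

## Problem sizes in the test and acceptance runs

Estimator validation uses 220 two-second windows per Hurst exponent; the
k_max sweep checks use 6–8 subjects of 40–50 windows; the cohort
recovery battery runs the full 108-subject cohort over 100 seeds (tests)
or 50 seeds (acceptance script) and the null-spec type-I check over
500 (tests) or 200 (script) replicates; the slow signal path is
exercised on short (10–30 s) recordings, which the ±0.15 estimator
tolerance already accommodates.

## Known limitations

* The Higuchi estimate saturates near FD = 2; distinctions among
  near-white signals compress, and the k_max sweep is uninformative
  there.
* The band-pass and average reference slightly perturb fractal scaling
  at the window edges; effects are well inside the ±0.15 estimator
  tolerance but are not zero.
* The ANOVA engine covers the factorial designs used here (crossed
  within factors, one between factor); it is not a general linear-model
  replacement.
* Group inference from MMSE alone misclassifies any control subject
  scoring exactly 24 and any patient without a recorded score.
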