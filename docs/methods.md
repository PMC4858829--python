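# Methods

## Scope and model overview

`hrmquant` quantifies promoter methylation from high-resolution melt (HRM)
curves of bisulfite-converted amplicons and evaluates the resulting score
as a predictive biomarker on survival cohorts. Two simulators — a melt-curve
generator and a patient-cohort generator — stand in for the instrument and
the clinic, so every stage of the chain is testable against a known ground
truth.

## Melt model

Each molecular species (fully methylated / fully unmethylated amplicon)
melts as a two-state helix–coil transition with helicity

θ(T) = 1 / (1 + exp((T − Tm) / w)),

and fluoresces θ·L_pre(T) + (1−θ)·L_post(T) between two straight dye
baselines. A sample with methylated fraction f is the convex combination
f·F_meth + (1−f)·F_unmeth plus i.i.d. Gaussian read noise. This collapses
heteroduplexes and patchwork methylation onto a two-species mixture, which
matches how quantification standards are physically built (mixes of a fully
methylated and a fully unmethylated DNA) and gives closed-form oracles:
with zero noise the mixture is exactly affine in f at every temperature,
hence so is the melt AUC.

Defaults (all configurable on `MeltModelParams`):

| parameter | default | meaning |
|---|---|---|
| temp_grid | 70.0–90.0 °C, 0.2 °C steps | acquisition ramp, one read per 0.2 °C |
| tm_unmethylated | 78.0 °C | Tm of the fully converted (all-T) species |
| delta_tm_per_cpg | 0.25 °C | Tm gain per retained CpG cytosine |
| n_cpg | 12 | CpGs in the amplicon → methylated Tm 81.0 °C |
| transition_width | 0.7 °C | logistic width w |
| pre baseline | 4000 − 15·(T−70) RFU | double-stranded dye signal |
| post baseline | 400 − 2·(T−70) RFU | dissociated signal |
| noise_sd | 20 RFU | per-point read noise (~0.5 % of signal) |

The true Tm separation between methylated and unmethylated amplicons of a
real assay is not known here; Δtm is a free model parameter chosen to give
a clearly resolvable 3 °C separation for a 12-CpG amplicon, not a fitted
value.

## Quantification chain

**Normalization.** A straight line is least-squares fitted to the
fluorescence in a pre-melt and a post-melt window; the normalized signal is
100·(F−L_post)/(L_pre−L_post), evaluated pointwise, so the pre-melt plateau
reads 100 % and the post-melt plateau 0 %.

*Window width.* Default windows are the first and last **4.0 °C** of the
trace. This width is a numerical-conditioning choice: each fitted baseline
is extrapolated across the whole interval, and the variance of an
extrapolated regression line grows as σ²·d²/S_xx, with S_xx growing as the
cube of the window width. On the default grid a 1.5 °C window (8 points)
gives a slope standard error of ~15 RFU/°C — the same magnitude as the true
baseline slope — and inflates the melt-AUC standard deviation to ~28 %·°C,
degrading the standard-curve R² to a median of ~0.976. At 4 °C the AUC SD
drops to ~2 %·°C and the calibration R² stays above 0.99 across seeds,
while both windows remain ≥ 5.7 transition widths away from the nearer Tm
(pre ends at 74 °C vs Tm 78 °C; post starts at 86 °C vs Tm 81 °C), so
baseline fits see only ~0.3 % melt curvature. Windows are configurable for
instruments with different geometry.

**AUC.** Trapezoidal integral of the normalized curve over the full
normalized range (configurable interval), units % · °C. A later-melting
(methylated) sample stays high longer and accrues a larger AUC.

**Calibration.** Ordinary least squares of known methylation on the mean
replicate AUC of each standard, reported with R². The regression is
oriented as the direct interpolation map (methylation = a·AUC + b) rather
than fitting AUC on methylation and inverting, avoiding divide-by-slope
instability. Standards carry their *measured* methylation values — the
five-level series mixed from endpoints measuring 2.1 % and 90.8 % carries
2.1 / 24.3 / 46.4 / 68.6 / 90.8 % — not the theoretical 0/25/50/75/100.
`expected_mixture_methylation` encodes that arithmetic
(f·meth + (1−f)·unmeth, reported to one decimal with ties away from zero;
note the 50 % mix computes to 46.45 → 46.5, within rounding of the measured
46.4).

**Interpolation.** a·AUC + b clamped to [0, 100]; AUCs outside the range
spanned by the standards are flagged as extrapolated. Replicates are
aggregated by mean and range, with a discordance flag when the range
exceeds 10 percentage points (configurable).

AUC is computed on the normalized melt curve itself; a difference-curve
reference subtraction is deliberately not applied (the normalized-curve AUC
is already affine in the methylated fraction under the mixture model).

## Clinical-decision layer

* **IDH1 exclusion.** IDH1-mutant gliomas have distinctly better prognosis
  and co-methylated promoters; they are removed before survival modelling.
* **Dichotomization.** methylated ⇔ score ≥ cut-off (boundary inclusive —
  the convention is stated because published practice is silent). Default
  cut-offs: HRM 5 %, PSQ 8 %.
* **ROC of a binary call.** For an already-dichotomized predictor the ROC
  has one interior point, so AUC = (sensitivity + specificity)/2. Outcomes
  are the landmarks PFS ≥ 12 and OS ≥ 18 months; patients censored before a
  landmark without an event are excluded from that landmark's ROC (their
  outcome is unknowable; imputation was the rejected alternative).
* **Cut-off scan.** ROC AUC at each integer cut-off 1–15 % for both
  landmarks; the best cut-off maximizes the PFS AUC, with the OS AUC as
  tie-break and the smallest cut-off last (a sum-of-AUCs objective is
  available).
* **Survival.** Kaplan–Meier product-limit curves (median = first time
  S(t) ≤ 0.5; median CIs by inversion of the pointwise survival CI, the
  Brookmeyer–Crowley construction), two-sided log-rank with hypergeometric
  variance, and Cox proportional hazards with Efron tie handling (months-
  resolution data tie heavily) reporting hazard ratios with Wald 95 % CIs.
  These delegate to `lifelines` behind the module interface; the test suite
  cross-checks the Cox fit against a brute-force partial-likelihood
  maximization and the log-rank statistic against a hand implementation.
* No multiple-testing correction is applied across the scan or tables;
  p < 0.05 is reported as significant, matching common practice for this
  analysis style.

## Synthetic cohort generator

Per patient: a latent methylation class (default P(methylated) = 0.52);
HRM and PSQ scores drawn around a shared per-class latent level
(unmethylated ~ N(2, 1.5), methylated ~ N(30, 15), clipped to [0, 100]),
with the latent/noise variance split chosen so the within-class HRM–PSQ
Pearson correlation is 0.9; MSP status = the 5 % HRM call flipped with
probability 0.15. Overall survival is exponential with baseline median 10
months and a multiplicative class hazard (default HR 10/14 ≈ 0.71, echoing
14 vs 10 month medians), so proportional hazards hold by construction and
Cox recovery is a valid oracle. PFS is an independent exponential with its
own class hazard (baseline median 4 months, HR 4/6), truncated at OS so
PFS ≤ OS in every record; truncation keeps the PFS hazard ratio a genuine
generative parameter, which a deterministic OS-fraction coupling could not
provide. Censoring is one uniform follow-up clock per patient,
C ~ U(0, u) with u solved numerically so the expected OS-censoring fraction
equals the requested rate (default 20 %); the same clock censors PFS.

The reference 83-patient layout couples grade and IDH1 (23 grade III with
16 mutants; 60 grade IV with 2), lifts the scores of most IDH1-mutant
tumors above the 5 % cut-off (mutants are almost always co-methylated), and
starts from a base methylated fraction of 0.43 so the post-lift marginal
lands near 52 %. With `exact_margins=True` the grade × IDH1 counts are laid
out exactly and shuffled under the seed, which makes the bookkeeping
quantities (21.7 % mutant; 88.9 % of mutants grade III; 65 wild-type after
filtering) deterministic.

What the generator does *not* emulate: tumor heterogeneity and normal-cell
contamination of scores, time-varying hazards, second-line-therapy effects,
and non-exponential survival shapes. Passing tests therefore demonstrate
the correctness and calibration of the analysis chain under its stated
assumptions, not the clinical performance of any assay on real tissue.

## Problem sizes and test design

Simulation-backed checks use sizes chosen to make their Monte-Carlo noise
small relative to the tolerance they assert: 200 simulator seeds for
calibration quality and recovery error (mean absolute recovery error ≤ 3
percentage points; in practice ~1.1), 1000 null simulations for log-rank
type-I error (band 0.03–0.07), 100 seeds × n = 500 for Cox hazard-ratio
recovery (±0.1 around HR 0.5; measured mean ~0.55, the small attenuation
toward 1 coming from the ~5 % misclassification of the score
dichotomization relative to the latent class), and 50 seeds × n = 500 for
cut-off-scan recovery. The scan-recovery check generates cohorts whose
class score densities cross at exactly 5 % (N(3.5, 1) vs N(6.5, 1)); under
the default wide-gap score model the optimum cut-off is deliberately not
identifiable — any threshold inside the empty score interval classifies
identically — so recovery is only a meaningful property when the generative
boundary actually exists.

## Known limitations

* The melt model is empirical (two-state logistic), not nearest-neighbor
  thermodynamics; it reproduces curve shapes adequately for exercising the
  quantification chain but does not predict real Tm values.
* Baseline normalization assumes linear dye baselines; strongly curved
  baselines would need wider windows or a different baseline model.
* The binary-predictor ROC is the two-point trapezoid by design; it is not
  comparable to ROC AUCs of continuous predictors.
* Exact genomic coordinates of the target amplicon are not bundled, so the
  per-amplicon CpG count is an input, not a derived quantity.
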