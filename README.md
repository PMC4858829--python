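# hrmquant

Quantification of **MGMT promoter methylation** from high-resolution melt
(HRM) curves, plus the clinical-decision layer that turns the resulting
methylation scores into a predictive biomarker for high-grade glioma
therapy response.

## The problem

MGMT is a suicide DNA-repair enzyme that removes alkyl adducts from the O⁶
position of guanine, making tumor cells resistant to temozolomide.
Epigenetic silencing of MGMT via promoter CpG-island methylation therefore
predicts therapy response, and the methylation status is determined on
bisulfite-converted tumor DNA. HRM is a closed-tube alternative to
methylation-specific PCR (MSP) and pyrosequencing (PSQ): after bisulfite
conversion a methylated template retains its CpG cytosines, has higher GC
content, and melts at a higher temperature, so the shape of the fluorescence
melt curve encodes the methylation level quantitatively.

`hrmquant` implements the full chain:

1. **Assay design** (`sequence_tools`) — ATG-relative coordinate arithmetic
   (no position 0, so the −531..+231 island spans 762 bp), in-silico
   bisulfite conversion, CpG-island detection with
   Gardiner-Garden–Frommer-style criteria, and validation that primers are
   methylation independent (no CpG in the primer or under its binding site).
2. **Melt simulation** (`melt_simulator`) — a two-state (helix/coil)
   logistic melt model per species, θ(T) = 1/(1+exp((T−Tm)/w)); a sample is
   a two-species mixture of fully methylated and fully unmethylated
   molecules with sloped dye baselines and Gaussian read noise, acquired at
   one reading per 0.2 °C from 70–90 °C.
3. **Quantification** (`hrm_quantification`) — baseline normalization
   between fitted pre-/post-melt lines (100 %/0 %), trapezoidal area under
   the normalized melt curve (AUC, % · °C), ordinary-least-squares
   calibration of known methylation on standard AUC
   (methylation = a · AUC + b, with R²), interpolation of unknowns with
   clamping and extrapolation flags, and replicate aggregation. Standards
   are the classic five-level series mixed from measured endpoints
   (2.1 % and 90.8 %): 2.1 / 24.3 / 46.4 / 68.6 / 90.8 %.
4. **Clinical decisions** (`cohort_analysis`) — IDH1-mutant exclusion,
   dichotomization at a cut-off (methylated iff score ≥ cut-off, default
   5 %), ROC AUC of the binary call against the survival landmarks
   PFS ≥ 12 / OS ≥ 18 months ((sensitivity+specificity)/2), a cut-off scan
   over 1–15 %, Kaplan–Meier / log-rank group comparison, multivariable Cox
   regression (Efron ties, Wald CIs), Spearman/Pearson method comparison,
   and cohort characteristic tables.
5. **Synthetic cohorts** (`synthetic_cohort`) — generative patient cohorts
   with known class hazard ratios (exponential survival, proportional
   hazards by construction), correlated HRM/PSQ scores, noisy MSP calls,
   and uniform follow-up censoring, so every downstream estimate has a
   ground truth.

## Worked example

Simulate a standards plate with two unknown tumors, then quantify:

```
$ hrmquant simulate --out melt.csv --samples "tumorA=0.38,tumorB=0.02" --seed 7
wrote 14 curves to melt.csv
$ hrmquant quantify --melt melt.csv --out calls.csv
called 2 samples (calibration R^2 = 0.9993)
$ cat calls.csv
sample_id,assay,percent_methylation,status,cutoff,extrapolation_flag,replicate_range
tumorA,HRM,38.07109644676265,methylated,5.0,False,0.33253511635444966
tumorB,HRM,4.012160283186404,unmethylated,5.0,True,2.419833540545028
```

`tumorA` was simulated at a molecular methylated fraction of 0.38 and reads
back 38.1 % through the full normalize → AUC → calibrate → interpolate
chain (calibration R² 0.999); at the 5 % cut-off it is called methylated.
`tumorB` (2 %) is called unmethylated; its AUC fell below the lowest
standard, so the call carries an extrapolation flag.

Cohort-level analysis on a synthetic 83-patient glioma collection:

```
$ hrmquant cohort-sim --out cohort.csv --reference --seed 7
wrote 83 patients to cohort.csv
$ hrmquant survival --cohort cohort.csv --outdir surv
log-rank p: PFS 0.6845, OS 0.1533
```

The `survival` command first excludes IDH1-mutant patients, then writes
Kaplan–Meier curves, log-rank tests, Cox tables (hazard ratio, 95 % CI, p
per covariate), and characteristic/survival summary tables under `surv/`.
At n = 83 with a moderate generative effect the log-rank test is usually
not significant — exactly the sampling behavior a real cohort of this size
shows.

Other subcommands: `calibrate` (standard-curve report), `cutoff-scan`
(ROC AUC per cut-off 1–15 %), `design` (CpG islands + primer validation
from FASTA).

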