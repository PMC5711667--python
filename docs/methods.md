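# Methods

## The measurement model and the PT/INR line

A coagulation analyzer measures a prothrombin time PT (seconds) and reports
an INR through the conventional conversion INR = (PT/MNPT)^ISI, where MNPT
is the geometric-mean normal PT of the local system and ISI the
International Sensitivity Index of its thromboplastin.  When the locally
assigned ISI/MNPT pair deviates from the system's true calibration, the
reported INR acquires a method-specific power-law distortion: if PT is
generated by a true pair (ISI*, MNPT*) and reported through a labelled pair
(ISI, MNPT), then

    INR_reported = (MNPT*/MNPT)^ISI · INR_true^(ISI/ISI*) ,

so two analyzers disagree whenever their labelled/true ratios differ.  This
is the disagreement the PT/INR line removes: per analyzer, OLS of
y = ln(PT observed) on x = ln(INR certified) over a certified calibrant set
gives y = m·x + b, and inverting,

    INR_corrected = exp( (−b/m) + (1/m)·ln PT ) ,

assigns a harmonized INR directly from PT.  Natural logarithms are used
throughout; `correct_inr` and `predict_pt` are exact algebraic inverses and
are property-tested as such.  Under the conventional model the line's slope
is 1/ISI* and its intercept ln MNPT*, which the noiseless-simulation tests
confirm.  R² is computed as 1 − SS_resid/SS_total on the ln scale (the
scale on which the fit lives).

Replicate calibrant PTs are averaged on the seconds scale before the ln
transform by default (`fit_basis="replicate_means"`, matching a
duplicate-measurement calibration design); `"all_replicates"` is available.
A Monte-Carlo test confirms the means-based fit is no more variable than
single replicates at equal total point count.

Corrected INRs are rounded to 2 decimal places for reporting and binning —
the precision at which INRs are used clinically and at which the bundled
study's tables operate — with unrounded values available via
`rounding=None`.

## The bundled study

`ptinrline/data/study_samples.csv` holds a 120-sample four-analyzer
comparison: 20 control and 100 stabilized-warfarin subjects measured on a
whole-blood point-of-care coagulometer (CoaguChek XS, recombinant human
thromboplastin, labelled ISI 1.01) and three central-laboratory plasma
analyzers (two Stago Star Evolution with rabbit-brain thromboplastin,
labelled ISI 1.25 and 1.28; one Siemens BCS XP with recombinant human
thromboplastin, labelled ISI 1.02).  One BCS measurement (sample 9N) is
missing.  The point-of-care device reads whole blood and cannot be run
against plasma calibrants, so it is never corrected (`correctable=False`
is enforced for whole-blood methods).

The raw calibrant readings behind the study's published lines are not part
of the dataset (they were published separately), so the lines are
**back-derived**: every published corrected INR lies on its analyzer's line
by construction, and regressing ln(PT) on ln(corrected INR) over the table
recovers it with R² > 0.9999.  The back-derived lines regenerate all 359
published corrected values within ±0.01 after 2-dp rounding — which both
validates the approach and certifies the shipped table's internal
consistency.

`data/frequency_counts.csv` ships the study's published methods × INR-bin
frequency tables (before and after correction) verbatim.

### Data anomalies, shipped as printed

* Sample 86A on the UTMB analyzer prints PT 42.90 s beside a reported INR
  of 2.70; its corrected value 4.21 tracks the PT, so the reported INR (or
  the PT) is a transcription error.  `flag_pt_inr_outliers` detects it by
  its ln-scale residual (0.4, against a reporting-granularity ceiling of
  ~0.05) from the analyzer's own PT–INR relationship; the row is flagged,
  never altered.
* The published p = 0.00005 printed beside χ² = 33.36 is inconsistent with
  df = 12 (the correct p is 8.5e-4).  The χ² statistic is the reproduction
  target.

### Irreproducible published values

The published **after-correction inferential statistics are inconsistent
with the published corrected columns**.  Computed from the shipped
corrected data: the point-of-care-vs-BCS paired t gives p ≈ 1.5e-31
(published: 0.47), the GG-ANOVA gives p ≈ 4.2e-31 (published: 8.91e-14),
and re-binning the corrected columns yields a table (χ² = 48.25) that
matches neither the published after-table (χ² = 25.56) nor its cell counts
(e.g. the published after-table shows 11 BCS samples at INR ≥ 5; the
published corrected BCS column contains 1).  The published after-phase
counts imply a correction that stretched INRs upward, while the published
corrected columns shrink them by ~15–20%; the study's statistics were
evidently computed on a different corrected dataset than the one printed.
Consequently two acceptance tests assert the published after-phase values
and fail by design, the after-phase frequency table is shipped verbatim
(its χ² of 25.56 reproduces exactly from the shipped counts), and all
before-phase statistics reproduce: Mauchly p within 0.03 log10 units of
6.17e-59, GG-ANOVA p = 3.52e-24 to printed precision, paired t
point-of-care-vs-BCS p = 0.080.

## Agreement statistics

All test statistics are computed from their definitions; scipy supplies
only the χ²/F/t distribution functions.  pingouin and
`scipy.stats.chi2_contingency`/`ttest_rel` serve as independent
cross-checks in the test-suite.

* **Binning** uses edges 2/3/4/5 by default, half-open on the right, so an
  INR of exactly 2.00 falls in "2 ≤ INR < 3"; values are rounded to 2
  decimals first.  Under this rule the shipped raw columns reproduce the
  published before-table cell-for-cell.
* **Chi-squared homogeneity**: expected counts row·col/grand, no continuity
  correction.  Expected cells below 5 warn but do not fail (several of the
  study's expected cells are < 5 and its analysis evidently did not pool
  bins); a simulation shows the test still holds its nominal level (0.047
  at α = 0.05) at the study's margins and group size.  All-zero categories
  must be dropped explicitly (`drop_empty_columns`); an empty margin is a
  degenerate design, not a zero contribution.
* **Mauchly's W** = det(S_c) / (tr(S_c)/(k−1))^(k−1) on the
  contrast-transformed sample covariance S_c = CᵀSC, with the standard χ²
  approximation −(n−1)·d·ln W at df = k(k−1)/2 − 1.  C is a normalized
  Helmert basis; W and ε are invariant to the orthonormal basis chosen
  (tested with two bases).  Zero contrast variance is treated as trivially
  spherical (W = 1); a singular S_c with positive trace reports W at the
  machine floor with a warning.
* **Greenhouse–Geisser ε** = (tr S_c)² / ((k−1)·tr S_c²), clamped to
  [1/(k−1), 1]; identical to the eigenvalue form (Σλ)²/((k−1)Σλ²) and
  tested against it to machine precision.
* **Repeated-measures ANOVA**: classical within-subject decomposition with
  the residual SS computed directly from the interaction residuals (not by
  subtraction), so degenerate inputs with zero interaction give exactly
  F = 0 rather than 0/0 noise.  p_GG evaluates F at ε-deflated dfs.  Note
  the GG correction raises the p-value whenever F ≥ 1 but can lower it for
  F < 1; the monotonicity property is only asserted in the F ≥ 1 regime.
* **Paired t**: t = mean(d)/(sd(d)/√n) on differences, two-sided.
  p-values below 2.2e-16 are reported numerically and displayed as
  "<2e-16".

Missing-data policy: the k-method ANOVA and Mauchly test use complete cases
(n = 119 for the bundled study); pairwise t-tests use pairwise complete
cases (120 or 119).  No multiple-testing adjustment is applied to the
pairwise matrix (the published matrix reports raw p-values).

## The synthetic-data generator

Each subject has a latent true INR — controls Normal(1.0, 0.05), warfarin
subjects log-normal with σ = 0.35 and mode 2.5 (≈95% of draws in 1.4–5.6, a
right-skewed stabilized-anticoagulation-clinic distribution).  Each analyzer
observes PT = exp(m*·ln INR_true + b*)·exp(η), η ~ Normal(0, cv) — 
multiplicative log-normal noise, which keeps PT positive and makes the
ln-scale regression model exact, so noiseless fits recover generating lines
to machine precision — and reports INR through its labelled ISI/MNPT.
Default cohort cv = 0.03 (a realistic analyzer imprecision), calibrant
cv = 0.01 with 20 levels log-evenly spaced over certified INR 0.9–4.5 in
duplicate, matching the near-perfect (R² > 0.998) linearity of real
calibrant runs.

Default MNPTs (12.5 s rabbit-brain, 10.5 s recombinant-human plasma, 11.5 s
whole-blood device) are fixture choices mimicking the normal-sample PT
ranges of the bundled study, not published constants.

A key structural fact: if every analyzer's labelled ISI/MNPT equals its
true calibration, the INR conversion cancels and all methods agree
regardless of how different their ISIs are.  Inter-method discordance is
therefore simulated by mis-assigning labels (`true_calibrations`): the
default discordant scenario perturbs ISI by 5–8% and MNPT by ~2%, after
which the binned chi-squared rejects homogeneity in ~88% of
study-sized cohorts, and correcting with lines fitted from true-line
calibrants lowers the chi-squared in essentially every seed — the
qualitative conclusion of the bundled study, reproduced under a controlled
mechanism.

What the generator does **not** emulate: whole-blood matrix effects and
strip-lot variation in the point-of-care device, hematocrit or
anti-phospholipid interference, pre-analytical degradation, or
non-power-law distortions of the PT–INR relationship.  Passing synthetic
tests therefore demonstrate correctness of the statistical machinery and of
the correction under the stated model, not robustness to those real-world
effects.

## Numerical and design choices

* Problem sizes: Monte-Carlo checks use 1000 replicates for type-I error
  (binomial SE ≈ 0.007 at the 0.05 level, comfortably inside the asserted
  [0.03, 0.07] band), 100–300 seeds for recovery and benefit comparisons.
* Seeds are explicit everywhere (`numpy.random.default_rng`); the same seed
  gives bit-identical cohorts and reports.
* Binning uses `searchsorted` on 2-dp-rounded values; ties at an edge go
  up.
* The calibration fit refuses designs with fewer than 3 distinct certified
  levels; corrected-INR unit invariance holds iff the intercept is refit
  after rescaling PT (tested).
* Report JSON round-trips losslessly (floats via repr); contingency tables
  are additionally exported as CSV.

## Known limitations

* Back-deriving a line from corrected values is only available when a
  corrected column exists; it cannot audit the original calibrant fit
  itself (residuals at the calibrant level are unobservable here).
* The chi-squared test is asymptotic; with the study's sparse upper bins
  its level is adequate (simulated 0.047–0.06) but exact tests are not
  provided.
* Mauchly's test assumes multivariate normality; INR distributions are
  right-skewed, so its astronomically small p-values on the real data
  should be read qualitatively (sphericity is grossly violated), which is
  also why reproduction of extreme p-values is asserted on the log10 scale
  only.
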