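# Methods

## Scope and model

`nsdcog` operationalises a baseline cross-sectional analysis of cognition
in early neuronal α-synuclein disease (NSD): classify participants into
NSD-ISS stage 2 (2A/2B), build a regression-normed cognitive summary score
(CSS) against a robust healthy-control (HC) reference, and compare groups
with two-sample t-tests, chi-square tests and Cohen's d. Imaging and assay
quantification are out of scope: SAA status, the lowest putamen specific
binding ratio (SBR) and its age/sex-expected value, and the UPSIT
percentile arrive as inputs.

## Staging rules and thresholds

All cutoffs live in `StagingThresholds` (YAML-serialisable) with these
defaults:

| parameter | default | meaning |
|---|---|---|
| `upsit_percentile_cutoff` | 15 (inclusive) | hyposmia: UPSIT age/sex-adjusted percentile ≤ 15 |
| `dat_percent_expected_cutoff` | 75 (strict `<`) | DaT deficit: 100·SBR/expected < 75 |
| `rbdsq_cutoff` | 6 (`≥`) | RBDSQ screening evidence of RBD |
| `stage2_cognitive_updrs_value` / `stage2_cognitive_moca_min` | 1 / 26 | stage-2 cognitive: item 1.1 = 1 **and** MoCA > 25 |
| `stage3_cognitive_updrs_value` / `stage3_cognitive_moca_min` | 2 / 25 | stage-3 cognitive exclusion: item 1.1 = 2 and MoCA ≥ 25 |
| robust HC MoCA | ≥ 27 baseline, ≥ 26 year 1, drop ≤ 2 | norming reference |

Two wordings of the stage-2 cognitive MoCA bound circulate (≥ 25 vs > 25);
the default follows the stricter *> 25* used in the group-characteristic
tabulations, and the knob makes the other choice one line of YAML.
Stage-3+ status is accepted as input flags (any-track functional
impairment, plus the cognitive rule above) rather than re-deriving the full
staging criteria — that enumeration belongs to the staging system itself,
not to this analysis.

Confirmed iRBD requires polysomnography. *Any* RBD evidence additionally
counts RBDSQ ≥ 6, a self-reported RBD diagnosis without PSG confirmation,
or self-reported dream enactment; the hyposmia-only subgroup requires no
evidence at all, the iRBD subgroup requires confirmation, and participants
in between are excluded from both (subgroup "purity").

Exclusions are evaluated in a fixed order (SAA → DaT availability →
stage 3 → stage 2 → hyposmia → PD medication → battery completeness → RBD
purity; analogous ordered reasons on the control side), and only the first
failing reason is logged, so the audit trail is deterministic and the
manifest's counts always satisfy
`n_input = n_analysis + n_robust_hc + Σ exclusions`.

## Norming and the CSS

Per test, ordinary least squares of the raw score on age (years), male
indicator and education (years) with intercept, fit complete-case within
the robust HC reference (minimum 10 rows; degenerate designs raise an error
naming the offending column). The residual scale is the
degrees-of-freedom-corrected RMSE `sqrt(SSR/(n−4))`; a population-SD
variant (`1/n`) is available via `NormOptions`. z-scores are residuals in
reference-RMSE units; the CSS is the arithmetic mean of the six z-scores
and is *not evaluable* when any z is missing (missing raw score, or missing
education, which the prediction needs). No winsorisation or truncation of
z-scores is applied, no imputation is performed, and no age² or interaction
terms are entered — the analysis model is deliberately the plain
age/sex/education adjustment.

Consequences used as test invariants: within the fitting reference each z
has mean 0 and is exactly uncorrelated with each covariate; the reference
CSS mean is 0; the CSS is invariant to affine rescaling of any raw test's
units; increasing a raw score strictly increases its z and the CSS. Higher
raw scores mean better performance on all six scores, so more negative
CSS = worse cognition, with no sign flips.

## Comparison statistics

Default t-test is pooled-variance (consistent with the pooled-SD Cohen's d
and with the reported p-values); Welch is a flag. Chi-square is Pearson
without continuity correction. Cohen's d uses the (n−1)-weighted pooled SD
and is reported as a magnitude with the direction recorded separately. No
multiple-testing adjustment is applied. Every t statistic is computable
from sufficient statistics (mean, SD, n) as well as raw samples; the two
paths agree to machine precision, which is what makes published table cells
directly recomputable. Recomputing effect sizes from cells printed to two
decimals carries rounding error of about ±0.02 in d — the tolerance the
worked-example tests use.

## Synthetic-data generator

The generator emulates the *assumed* data-generating process, not the full
richness of real cohorts:

- Raw test score = intercept + age·slope + education·slope + sex·slope +
  residual_SD·(group shift + noise). Group shifts are expressed in
  residual-SD (z) units so a configured shift equals the expected CSS
  displacement after norming. Noise is Gaussian and, by default,
  independent across tests; a common-factor correlation knob shares a
  per-participant factor across the six tests (and couples MoCA to the same
  latent cognition).
- Default covariate effects are magnitudes typical of published norms for
  this battery (e.g. SDMT ≈ −0.45 points/year of age, +0.6 points/year of
  education); tests and scales are listed in `default_test_effects()`.
- Biomarkers and staging items are drawn from truncated distributions per
  group, which lets a group be constructed entirely on one side of a
  staging cutoff (deficit vs no deficit, hyposmic vs normosmic, robust-HC
  MoCA bands).
- Missingness is injected completely at random at configurable rates for
  education, year-1 MoCA and individual test scores.

The PPMI-like preset (`make_ppmi_like_cohort`) fixes group sizes
(158 robust HC; stage-2A hyposmia-only 58, +iRBD 43; stage-2B hyposmia-only
179, +iRBD 48), CSS shifts (0, +0.07, −0.26, −0.20, −0.47), ages
(HC younger: 59.0 ± 11.7 vs ≈ 65–67), ~61% male, and the known missingness
(three stage-2B hyposmia-only participants lose education, one HC loses a
test score). Its common-factor correlation is set to 0.30 so the composite
CSS has an SD near 0.65, matching the reported 0.60–0.72 (with independent
tests the CSS SD would be 1/√6 ≈ 0.41). Note the consequence: CSS-level
effect sizes scale as shift/SD(CSS), so a shift contrast of 0.33 appears as
d ≈ 0.5 on the composite — parameter-recovery checks therefore measure
*per-test* standardized differences, which equal the configured shifts
regardless of the correlation.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: instrument ceilings/floors on the raw test
scores (scores are unbounded linear-Gaussian, so ceiling-induced skew and
attenuation are absent), non-MCAR missingness, heterogeneous inter-test
correlation structure, practice effects, enrollment-cohort confounding, and
any real dependence of expected SBR on age/sex (the expected value is drawn
around a constant mean because only the ratio enters the rules).

## Numerical and design choices

- Sex enters the norm models as a single male = 1 indicator; covariates are
  uncentered. Coefficients are therefore not comparable across codings —
  only the z-scores and CSS, which are invariant to affine reparameterisation
  of the design, are meaningful outputs.
- Boundary semantics are verbatim from the rules: UPSIT percentile 15 *is*
  hyposmic; exactly 75% of expected SBR is *not* a deficit; a baseline→
  year-1 MoCA drop of exactly 2 keeps a control in the reference.
- Small-sample honesty in the validation suite: the pooled-t p is compared
  against a 10⁵-permutation oracle (agreement ~10⁻³ at n=15/group), and the
  asymptotic chi-square p against exhaustive multinomial enumeration at
  n=12, where the large-sample approximation itself deviates from the exact
  tail by up to several hundredths — the test budgets 0.08 for that
  approximation error, which is a property of the chi-square test at n=12,
  not of the implementation (the statistic matches the Pearson formula to
  1e−12 on every possible table).
- Monte-Carlo problem sizes: recovery checks run at n = 5,000 per group
  (SE of d ≈ 0.02, tested at ±0.05), marginal checks at n = 10,000 within
  3 standard errors, and null calibration at 1,000 replicates of n = 50 per
  arm (rejection rate tested at 0.05 ± 0.02).
- Pipeline determinism: one `numpy` Generator seeded from the config; rerun
  with the same config + seed reproduces every output byte for byte.
  Timestamps appear only in the log.

## Known limitations

- The generator's group shifts displace all six tests equally; real
  disease shifts are domain-heterogeneous (e.g. processing speed earlier
  than visuospatial function).
- Robust-HC selection here is purely rule-based on simulated MoCA values;
  in real data attrition and practice effects interact with the year-1
  requirement.
- The staging module covers exactly the rules this analysis needs; it is
  not a general NSD-ISS calculator (stage 3+ detail arrives as flags).
- CSS comparability across studies depends on the reference population; an
  internally-normed CSS is a within-study instrument.
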