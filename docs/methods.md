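# Methods

This note documents the statistical models implemented in `pvkit`, the
defaults chosen where the literature leaves room, and what the bundled
synthetic-data studies do and do not demonstrate.

## Data model and deduplication

A spontaneous-report database holds *case versions*: the same case
(CASEID) may be transmitted repeatedly with corrections. `pvkit`
retains one record per CASEID by (1) highest case version, (2) most
recent FDA receipt date, (3) fewest missing core fields (age, weight,
sex, occupation, country, event date), with remaining ties resolved
deterministically by keeping the last-seen record. Deduplication is
idempotent by construction.

Dates are carried as raw `YYYYMMDD` strings; a date that does not parse
to full calendar precision is treated as partial and is never imputed.
Age is normalized to years (decades ×10, months ÷12, days ÷365.25),
weight to kg (lb × 0.453592), with weights ≤ 0 or > 650 kg treated as
data-entry errors. Drug names are uppercased, whitespace-collapsed and
stripped of a short configurable list of trailing salt qualifiers; no
ingredient-dictionary mapping is attempted, so brand and generic names
remain distinct strings.

Cohort filtering keeps reports whose receipt date falls in the
configured year–quarter window, whose reporter occupation is in the
kept set (default: physicians, other health professionals, pharmacists,
consumers; lawyer and unknown excluded, but configurable because public
tabulations of this cohort still include lawyer-submitted reports), and
which carry at least one primary-suspect drug not on the exclusion
list. Progestogens and related contraceptive formulations are excluded
by default: they are prescribed *because of* threatened pregnancy loss,
so their association with miscarriage reporting is protopathic rather
than causal. Case status is an exact, case-folded match of a reaction
PT against the target set ("ABORTION SPONTANEOUS", "ABORTION"); no
substring matching, so "ABORTION INDUCED" is not a case.

## Disproportionality methods

All four statistics derive from the per-drug 2×2 table (a, b, c, d)
with N = a+b+c+d and expected count E = (a+b)(a+c)/N.

- **ROR** ad/bc, Woolf interval on the log scale. p-values come from
  the Pearson χ² (df 1, no continuity correction).
- **PRR** [a/(a+b)]/[c/(c+d)] with the same χ².
- **BCPNN IC** — the closed-form information component
  log₂[(a+0.5)/(E+0.5)] with the asymptotic expansion of the lower
  2.5% credibility bound, IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2).
  The original full-Bayes Dirichlet formulation (MCMC) is deliberately
  out of scope; the closed form is the dominant modern practice and is
  reproducible without sampling.
- **MGPS** — the gamma-Poisson shrinker. The relative reporting rate λ
  has the mixture prior P·Ga(α₁,β₁) + (1−P)·Ga(α₂,β₂) (shape/rate);
  marginally each count is negative-binomial, and the hyperparameters
  are fitted by maximizing the summed log marginal likelihood over the
  screening universe of tables with E > 0. The optimizer is L-BFGS-B on
  log-transformed gamma parameters (logit for P) from the customary
  initialization (0.2, 0.1, 2.0, 4.0, 1/3) with five jittered restarts;
  with fewer than 50 usable tables the default prior is returned with a
  warning. The posterior is the conjugate mixture
  Q·Ga(α₁+a, β₁+E) + (1−Q)·Ga(α₂+a, β₂+E); EBGM = exp(E[ln λ | a, E])
  via digamma closed forms, EB05 by Brent root-finding on the posterior
  CDF (tolerance 1e−8).

**Zero-cell policy.** When any cell is zero, the Haldane–Anscombe +0.5
correction is applied to all four cells for the ROR/PRR point estimates
and intervals only; the χ² is always computed on the raw cells, keeping
the test unbiased while the estimates stay finite. Tables with an empty
margin (no exposed reports, or no events) yield NaN markers rather than
exceptions, and NaN statistics never satisfy a threshold.

**Thresholds and consensus.** Defaults are the canonical literature
values: ROR — a ≥ 3 and CI lower bound > 1; PRR — PRR ≥ 2, χ² ≥ 4,
a ≥ 3; BCPNN — IC025 > 0; MGPS — EB05 ≥ 2. A drug is retained when the
ROR criterion plus at least one other is met (the consensus is
ROR-anchored). All thresholds are configurable. The p-values entering
the Benjamini–Hochberg step-up correction are the per-drug association
χ² p-values; q-values are order-preserving and capped at 1.

## Subgroup analysis

Reports are partitioned strictly at the cutpoint (age 35 years, weight
70 kg by default; the boundary value goes to the upper stratum) and
records missing the variable are excluded and counted. Within each
stratum the comparator is the stratum's own non-case remainder, so each
stratum is a self-contained 2×2 — an analysis choice; a published
analysis could equally use the pooled background, which changes the
magnitudes. Stratum estimates require a ≥ 3 exposed cases, and drugs
with fewer than 100 case reports overall are not sub-stratified (they
keep their overall signal only). The cross-stratum table reports the
log₂ ratio of RORs, each stratum's −log₁₀ p, and a flag for drugs
significant in exactly one stratum — the tidy inputs of forest and
volcano displays; rendering is out of scope.

## Time-to-onset

TTO is the interval in days from the earliest fully dated
primary-suspect therapy start to the fully dated event; partial dates
and intervals shorter than one day are exclusion signals. The
two-parameter Weibull f(t) = (α/β)(t/β)^(α−1)·exp(−(t/β)^α) is fitted
by maximum likelihood over (log α, log β) with BFGS from moment-based
start values (the log of a Weibull variate has standard deviation
π/(α√6)); 95% intervals are Wald intervals from the
observed-information covariance on the log scale, mapped back by
exponentiation so the bounds are positive. Gradient tolerance 1e−10;
a sample with no dispersion is rejected ("no dispersion").

Because TTOs are recorded in whole days (rounded up, minimum 1), the
continuous density over-weights the shortest intervals and biases the
shape upward by about +0.013 at shape 0.73 / scale 480 — enough to
break nominal CI coverage at n ≥ 5,000. `fit_weibull(day_rounded=True)`
therefore uses the interval likelihood P(T = t) = S(t−1) − S(t), which
restores nominal coverage (96% of 100 seeds at n = 1,000); it is the
default path wherever the sample is day-granular (the TTO tables and
the recovery studies). For genuinely continuous samples the plain
density is used.

Hazard-shape classification uses the unrounded shape CI: *early*
(decreasing hazard) when the upper bound is below 1, *degradation*
(increasing hazard) when the lower bound exceeds 1, *random* otherwise.
When classifying from bounds known only to printed precision, a
rounding tolerance of half the last printed digit resolves bounds
printed as exactly 1.00.

## Risk model

The feature matrix has one row per deduplicated report exposed to at
least one of the k selected drugs (default: the 30 most reported by
case count, ties lexicographic) and one binary primary-suspect
indicator per drug; the outcome is the miscarriage flag. Non-drug
covariates are deliberately excluded. The classifier is XGBoost with
fixed, documented defaults — depth 4, 200 rounds, learning rate 0.1,
logistic objective, histogram trees, `scale_pos_weight` = negatives /
positives — chosen for reproducibility over tuning; class imbalance is
handled by weighting, never resampling. Evaluation is seeded stratified
k-fold cross-validation (default 5 folds, configurable to 10) with
AUC per fold from the package's own Mann–Whitney rank-sum estimator
(half credit for ties) and pooled accuracy at the 0.5 threshold with a
normal-approximation binomial CI. Attributions come from the booster's
built-in TreeSHAP (`pred_contribs`); additivity (per-row attributions +
base value = margin) is enforced to 1e−4, and features are ranked by
mean |SHAP|, with mean signed SHAP among exposed rows giving the
direction. Total-gain importance is reported alongside as the auxiliary
view.

## Indication confounding

A drug is annotated "indication-confounded" when its mapped indication
categories intersect a five-category vocabulary of established
spontaneous-abortion risk factors: autoimmune disease, reproductive
tract infection, metabolic disorder, thyroid dysfunction, progestogen
use. Licensed terminology systems cannot be redistributed, so the map
is a user-editable YAML; the bundled file is a synthetic illustrative
example covering well-known drugs, and unmapped drugs are explicitly
noted rather than silently unflagged.

## Synthetic generator and what the studies show

The generator emulates the structure of quarterly extract data:
versioned duplicate case reports (forward-shifted receipt dates,
occasionally back-filled fields, so every dedup tie-break rule is
exercised), heavy non-random missingness (defaults: 45% of ages, 78% of
weights missing, matching the reporting patterns of large public
extracts), an occupation mix dominated by health professionals and
consumers, day-granular therapy/event dates, and per-drug Weibull
onset distributions. Events follow a Bernoulli model whose probability
is the base rate multiplied by the injected relative risk of each
exposed drug (capped at 1) — chosen so the implied 2×2 cell
probabilities are available in closed form for oracle tests. Reports
exposed to no configured drug receive one background filler drug so the
screening background is well defined. A single explicitly seeded
generator drives each cohort; identical configuration gives bitwise
identical output.

The seeded studies (in `pvkit.studies`, also run by
`scripts/acceptance.py`) measure, at sizes chosen to balance precision
against desk-scale runtimes: null-cohort ROR CI coverage pooled over
8 null drugs × 500 cohorts of 4,000 reports (~95.3%), the BH false
discovery rate on the same cohorts (≈ 1%), mixture-prior recovery on
5,000 simulated tables (measured on the moment-matched effective gamma
of the fitted mixture, since a two-component mixture fitted to
single-component truth is identifiable only as a distribution; errors
are a few percent), planted-signal recovery across 20
seeds of 200,000 reports (consensus flag and top SHAP rank, 100%), and
Weibull recovery on 10,000 day-rounded draws.

What passing these studies does **not** show: the generator draws
drugs, demographics and outcomes independently, so it cannot expose the
pipeline to confounding by indication, channeling, co-reporting
correlations between drugs, duplicated cases with *different* CASEIDs,
stimulated-reporting waves, or informative missingness — all present in
real spontaneous-report data. Calibration on synthetic nulls is
evidence of implementation correctness, not of unbiasedness on real
reports.

## Known limitations

- Disproportionality measures reporting associations, not incidence or
  causality; all outputs are hypothesis-generating signals.
- Drug-name normalization is string-level; ingredient mapping (RxNorm/
  ATC) and MedDRA hierarchy traversal are out of scope.
- Cross-CASEID probabilistic duplicate detection is not attempted.
- The Weibull model assumes a monotone (or constant) hazard; bathtub or
  mixture hazards and censoring/competing risks are not modelled.
- The risk model's discrimination depends on the real co-reporting
  structure; values obtained on synthetic cohorts characterize the
  implementation, not any real drug's risk.
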