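# Methods

## Liability-threshold model and scoring

The phenotype is an ordinal severity score with K categories (K = 4 by
default: none, mild, moderate, severe/recurrent). The scoring module
maps yes/no questionnaire answers onto these levels as a strict
hierarchy — self-report gates mild, a professional diagnosis gates
moderate, and defined medication or a repeated treated episode gates
severe *given* a diagnosis. Two conventions are deliberate:

* the severe level requires the moderate-level criteria in addition to
  its own, because the levels form an ordinal chain of increasing
  severity;
* depression occurring only after childbirth scores 0 regardless of
  the other answers, since the exclusion attaches to the gating
  question;
* missing answers exclude a record (with a counted, logged exclusion)
  rather than being imputed; the analysis is meant for complete paired
  responses.

Analysis assumes each score is a standard-normal liability cut at
thresholds τ = Φ⁻¹(cumulative prevalence). Thresholds are shared by
both twins and both zygosity groups, matching a single pooled
prevalence table (63/8/14/15% by default, giving τ ≈ 0.332, 0.553,
1.036 and an overall any-depression prevalence of 37%).

## Simulation

`simulate_pairs` draws each pair's liabilities directly from the
bivariate standard normal with correlation r_MZ = a²+c²+d² or
r_DZ = ½a²+c²+¼d², then discretizes at τ. This is distributionally
identical to summing separate A/C/D/E factor draws with the classical
cross-twin factor correlations (A: 1/½, D: 1/¼, C: 1/1, E: 0); the
factor-wise construction is retained as `method="components"` and the
equivalence is tested. One master seed feeds deterministic per-zygosity
substreams, so results are exactly reproducible and group sizes can be
changed independently.

What the generator emulates: the covariance structure and category
margins the biometric analysis assumes. What it does not: age and
cohort effects, sex limitation, assortative mating, measurement
non-invariance between zygosity groups, missingness, and any real-world
departure from bivariate normality of liability. Passing recovery tests
therefore demonstrates internal consistency of the estimators, not
robustness of the design to those violations.

## Polychoric estimation

Estimation is the standard two-stage procedure: thresholds from the
marginal cumulative proportions, then a one-dimensional maximization of
the multinomial log-likelihood Σ nᵢⱼ log pᵢⱼ(τ, ρ) over ρ ∈ (−0.999,
0.999) (bounded Brent, xatol 10⁻⁶; estimates reaching the bound are
clamped and flagged). Rectangle probabilities use the bivariate normal
CDF at absolute tolerance 10⁻⁸; cells are floored at 10⁻³⁰ inside the
log-likelihood. The standard error is the inverse square root of the
observed information, obtained by a central-difference second
derivative (step 10⁻⁴) of the profile log-likelihood.

Twins within a pair are interchangeable and no ordering convention is
assumed, so tables are double-entered (each pair counted at (s₁,s₂) and
(s₂,s₁)) before estimation. Double entry doubles the information in the
table, so the curvature is rescaled to the effective number of pairs;
the calibration of the resulting standard errors against the
replicate-to-replicate spread is covered by the simulation used in
development and by the likelihood-ratio size test in the suite.
Categories with empty margins are collapsed with a logged warning
rather than failing the pipeline. Polyserial (ordinal-continuous)
correlation is out of scope: every analysed variable here is ordinal.

## Model fitting and comparison

Fitting is weighted least squares on the two estimated correlations
rather than full raw-data categorical ML: every free model implies
(ρ_MZ, ρ_DZ) linearly in the variance proportions, and the fit
minimizes the se-weighted squared distance subject to non-negativity
and unit total variance. Saturated specs (ADE, ACE) are solved in
closed form — ADE: a² = 4r_DZ − r_MZ, d² = 2r_MZ − 4r_DZ; ACE:
a² = 2(r_MZ − r_DZ), c² = 2r_DZ − r_MZ; e² = 1 − r_MZ — with negative
solutions clipped to zero, flagged, and the remaining components
re-solved by bounded least squares. One- and two-parameter non-saturated
fits use the closed-form clipped WLS solution and SLSQP respectively,
and are verified against an exhaustive grid-search oracle.

Degrees of freedom are counted as fitted statistics (2) minus free
genetic/shared parameters not pinned at a boundary, so a saturated
interior fit has χ² = 0 on 0 df and the ACE fit at the c² ≥ 0 boundary
collapses exactly onto AE (equal χ², a structural pattern of the
design whenever r_DZ < r_MZ/2). Nested comparisons use the plain χ²
difference with df equal to the difference in free-parameter counts; no
50:50 boundary-mixture correction is applied, matching common usage of
the df = 1 test for ADE vs AE/DE. p-values are reported to two decimals
in the text report and kept at full precision internally. ACDE is
rejected as unidentified.

## Pipeline

The two-group analysis balances MZ and DZ pair counts by random
subsampling of the larger group (deterministic given the seed), then
estimates, fits and compares as above, and reports Falconer's
h² = 2(r_MZ − r_DZ) plus a counts ledger of every filtering step. The
severity-restricted arm drops every pair in which either twin scores in
the top category and re-estimates thresholds from the restricted sample
with K−1 categories; recoding severe down to moderate is available as
`severe_mode="recode"`. Dropping is the default because removing pairs,
not recoding individuals, is what a reduced pair count in the published
two-arm design implies. The preferred model is the most parsimonious
one whose absolute fit p-value is at least α (default 0.05).

## Power analysis

Power to reject the false AE model is estimated by simulation, not by
an analytic noncentrality argument: each replicate simulates a cohort,
estimates both polychoric correlations, fits AE and ADE and applies
the df = 1 difference test. Degenerate replicates (an empty margin in a
small dichotomous table) are resampled and counted. `required_n`
bisects on total pair count (equal MZ/DZ split) using common random
numbers across evaluated sizes, which makes the simulated power curve
effectively monotone; it returns the smallest evaluated n meeting the
target, with the power estimate and its Monte-Carlo standard error.
The MZ/DZ split and α = 0.05 are assumed where the design leaves them
open.

Under the reference truth a² = 0.30, d² = 0.30, e² = 0.40 with four
categories at the default prevalences, this simulation gives roughly
28% power at 1,449 pairs and needs roughly 5,500–6,200 total pairs for
80% power; with a dichotomous 10%-prevalence trait the requirement is
roughly 20,000–22,000 pairs. The often-quoted round figures of ~50%
power at this sample size and ~3,000 pairs for 80% correspond to about
twice the per-pair Fisher information that a four-category measure at
these prevalences actually carries — they are what one obtains for a
continuously measured liability (or, equivalently, from double-entered
tables without the information correction). The acceptance checks for
those two quantities therefore fail by design against the round
figures while the package reports the internally consistent simulated
values; the dichotomous requirement and the four-level-versus-
dichotomous power ordering reproduce as expected.

## Numerical choices and problem sizes

* Polychoric optimizer tolerance 10⁻⁶, verified within 10⁻³ of a
  step-10⁻³ grid oracle; WLS model fits verified within 10⁻⁴ of a grid
  oracle on the free simplex.
* Boundary detection threshold 10⁻⁷ on variance proportions; e² is kept
  strictly positive.
* Recovery tests use 20,000 pairs per group (3-standard-error bands);
  the acceptance script uses 50,000 pairs per group averaged over 10
  cohorts for parameter recovery, 100,000 individuals for prevalence
  calibration, 1,000 replicates for the study-size power estimate and
  500/300 replicates per bisection step for the required-n searches —
  sizes chosen so Monte-Carlo error is small relative to each stated
  tolerance while a full run stays in the minutes range on one CPU.

## Known limitations

Correlation-level WLS is not raw-data AGLS/ML: absolute fit χ² values
for non-saturated models are approximations and df bookkeeping ignores
threshold parameters, so published table-level χ² values from
raw-data fits are not reproduction targets. Standard errors treat the
two-stage thresholds as fixed. No age/sex moderation, no polyserial
variables, no ACDE. The severity-restricted arm assumes thresholds are
re-estimated from the restricted sample.
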