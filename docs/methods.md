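# Methods

## Measurement model

Test-weighing records the infant's mass immediately before and after every
feed (scale accuracy ±2 g) for 24 h plus one feed. Mass differences are
converted to volume at 1.03 g/mL. The first (anchor) feed defines the
start of the observation window and is excluded from every sum; T, the
elapsed time from the end of the anchor to the end of the last
milk-removal event (hours), rescales all totals to a 24 h day:

* production = Σ (breastfeed + pump-expression volumes after the anchor) · 24/T
* intake     = Σ (breastfeed + expressed-bottle + formula volumes after the anchor) · 24/T

The two ledgers are disjoint in kind but share the window: pump
expressions count as production but not intake; bottle-fed expressed milk
counts as intake but not production (it was produced, and weighed, at
expression or earlier). Applying the anchor exclusion to the intake ledger
as well is a package choice — only the production formula prescribes it —
made so both ledgers cover an identical span and conservation
(total = breast milk + formula) holds exactly.

Negative weight differences are clamped to zero with a data-quality
warning; they are never propagated as negative intake. Diaries whose span
falls outside [20 h, 30 h] are rejected (configurable).

Growth is expressed as weight-for-age z-scores via the lambda–mu–sigma
transform z = ((W/M)^L − 1)/(L·S) with linear interpolation of the L, M, S
parameters over a per-sex age grid. The bundled grid is **synthetic** — a
smooth median-growth curve with constant L and slowly declining S — not a
national standard; any reference in the same CSV layout can be
substituted, and no result here depends on the exact reference values.
Average daily weight gain divides by (age − 8 days) to discount the early
neonatal loss-and-regain period; within the first 8 days it is undefined.
The formula-to-growth ratio is 0 without supplementation and +∞ when a
supplemented infant fails to gain — the severest presentation, which must
rank above every finite value in ROC analyses.

Breast volume is a configurable (band, cup) → cm³ lookup; the bundled
table is a synthetic placeholder, and everything downstream depends only
on the volume change and its 100 cm³ threshold.

## Synthetic cohort

The generator emulates a 460-dyad cohort with four latent classes:

| class | share | production centre | intake centre | formula use | WAZ | ΔWAZ |
|---|---|---|---|---|---|---|
| adequate | 254/460 | 789 | 780 | 4% of dyads | −0.05 | −0.50 |
| oversupply | 30/460 | 1171 | 1032 | none | 0.26 | −0.25 |
| severe low supply | 56/460 | 427 | 410 | all, ~354 mL | −0.35 | −0.65 |
| slow growth | 120/460 | 604 | 590 | 10%, ~340 mL | −1.11 | −1.35 |

Production spread is 150 mL/24 h per class, fixed by requiring the pooled
mean ± SD to approximate 734 ± 228 mL/24 h; WAZ and ΔWAZ spreads (0.50,
0.45 z) were set so between-class separation reaches the ≥ 3 SD design
point at which mixture recovery is reliable; formula volumes among users
are log-normal (log-SD 0.35). The zero-inflation rates give ~83% fully
breastfeeding dyads overall, concentrated in the adequate and oversupply
classes. Risk flags are class-conditional Bernoulli draws at the published
class-wise prevalences; threshold-defined flags (overweight, advanced age,
minimal breast growth) are made consistent by drawing their source
covariates (BMI, age, breast-volume change) conditional on the flag.
Missingness is injected completely at random per variable (16.1%
breast-volume change, 11.1% BMI, smaller rates elsewhere); derived flags
inherit it. Class membership is multinomial by default;
`exact_class_counts=True` fixes the composition at the published counts,
emulating the single fixed cohort a study observes.

Diaries are generated backwards from the intended indicators: breastfeed
volumes are rescaled to hit the breast-milk intake target, a production
shortfall relative to intake becomes pump expressions, an excess becomes
expressed-milk bottles (stored milk), and formula bottles hit the formula
target, all to within weight-rounding error. What the generator does *not*
emulate: circadian feeding patterns, informative missingness, correlated
indicators within class, twins or preterm infants. Passing tests therefore
demonstrate correctness of the machinery under a clean version of the
assumed data-generating process, not robustness to real-world violations
of it.

## Latent profile analysis

Indicators with |skewness| > 1 are square-root transformed (after a shift
to non-negative support), then z-standardised; rows are complete cases.
The mixture is Gaussian with **class-varying diagonal covariances**. The
more common equal-variance default is implemented but not used: with a
formula indicator that is exactly zero for ~80% of dyads, a shared
variance must compromise between the spike and the users' spread, and the
likelihood then always prefers splitting formula users into strata over
recovering the intended classes (the gain is scale-invariant in the
spread, so no parameterisation escapes it). Class-varying variances
represent zero-inflation exactly — the spike class takes the variance
floor — and recover the four-class structure.

EM details: k-means++ initial assignment softened to 0.9/0.1
responsibilities, 20 random restarts by default, convergence at
log-likelihood improvement < 1e-8 (1e-6 inside bootstrap refits), cap
1000 iterations, variance floor 1e-4 on the standardised scale (tight
enough for an exact spike, large enough to avoid likelihood blow-ups on
near-duplicate points), component collapse below one expected member
aborts the restart. Log-likelihood monotonicity is asserted on every
iteration.

Model choice over K = 1..5 follows five criteria, each vacuous where
undefined (K = 1): BIC lower than at K−1; entropy
1 − Σ(−p log p)/(n log K) ≥ 0.8; BLRT of K vs K−1 significant at 0.05;
mean posterior ≥ 0.5 within every modally-assigned class; smallest class
> 5% of dyads. The selected model is the largest K passing all five.

The BLRT simulates from the fitted (K−1)-model and refits both models on
each replicate, p = (1 + #{boot LRT ≥ observed}) / (successes + 1); note
the smallest attainable p is 1/(n_boot+1), so testing at level α needs
n_boot ≥ 1/α (default 99). Bootstrap refits warm-start from the observed
fits' parameters plus random restarts: without the warm start, refits with
a small restart budget under-optimise, inflate the bootstrap LRT and make
the test conservative enough to miss true splits. The warm start is
mildly anti-conservative for the alternative fit; inside model selection
this is inconsequential because observed LRTs for real splits are orders
of magnitude above the null and spurious larger K is gated by the BIC and
class-share criteria. For calibration studies the symmetric protocol
(`warm_start=False` with equal restart budgets) is the right one; its
measured type-I rate at the 0.05 level is ≈ 0.04.

Fitted classes are relabelled canonically from their class means on the
original scale: the highest-production class with intake below production
is oversupply; of the rest, the lowest-production (and highest-formula)
class is severe low supply; of the remaining two the lower-WAZ class is
slow growth, the other adequate. Adequate + oversupply form the NMS
group, the others LMS. Posterior ties resolve to the lower canonical
label.

## ROC thresholds

Candidate thresholds are midpoints between consecutive distinct scores
plus sentinels beyond the finite range (so +∞ formula-to-growth markers
get their own operating point). AUC is computed by trapezoid and verified
against the tie-corrected Mann–Whitney statistic at 1e-9 on every call.
The optimal cut-off maximises Youden's J with ties broken toward
sensitivity — a missed low-supply case is the costlier error. Production,
breast-milk intake and daily weight gain are analysed on all dyads (lower
flags LMS); formula intake and formula-to-growth only among partially
breastfeeding dyads (higher flags LMS), flagged low-n below 20 dyads.
Thresholds are reported on the measurement scale, never the transformed
one.

## Risk models

The multinomial logit is fit by Newton iterations with step-halving on the
exact log-likelihood, a 1e-8 ridge on the observed information, internal
standardisation of continuous columns (estimates mapped back exactly
through the affine transform), convergence at score max-norm < 1e-6, and
Wald covariance/CIs. Coefficients above 15 in magnitude trigger a
separation warning. Complete-case rows per model.

Stability selection draws B bootstrap resamples (500 by default; resamples
missing an outcome level are redrawn), runs backward elimination over the
ten risk factors with the five confounders locked, and retains factors
selected by > 50% of resamples; the final model refits the original data
with retained factors plus confounders. The per-resample selector is
backward elimination minimising **BIC**. AIC (and its implicit χ² > 2·df
bar) was measured to retain the winner's-curse factor — the most
chance-associated of ten null candidates — in a majority of resamples in
most runs, which defeats the purpose of the 50% retention rule; the
ln(n)-scaled BIC bar keeps null selection frequencies well below 0.5 while
a genuinely strong factor (OR ≈ 4) is retained essentially always. AIC
remains available via `selector_criterion="aic"`.

Composite factors code two binary flags as neither/A-only/B-only/both with
"neither" as reference, adjusted for confounders and the previously
retained predictors (excluding the two sources); empty levels are dropped
and reported as undefined with their counts.

## Descriptive statistics

Continuous variables: mean ± SD (range); categorical: n (%) with
available-data denominators, missingness against the full cohort;
percentages rounded half-up to one decimal. Group contrasts: pairwise
Wilcoxon rank-sum (exact null for combined n ≤ 20 without ties; otherwise
normal approximation with tie and continuity corrections, p = 1 when U
equals its null mean) and two-sided Fisher's exact test by the
point-probability rule. Class prevalence tables use full class-size
denominators by default (a switch enables available-data denominators).

## Problem sizes in the test suite

The suite exercises the full pipeline at the study scale (n = 460,
BLRT reps 99, 20 model-selection replicates) and uses reduced replication
for the calibration studies: 100 null replicates at n = 120 with 39
bootstrap draws for the BLRT type-I check; 300 replicates at n = 800 for
Wald coverage; single stability runs at n = 2000 with B = 40–60. These
sizes are the package's chosen desk-scale defaults; the underlying
functions accept larger values.

## Known limitations

* The generator draws indicators independently within class; real feeding
  and growth data are correlated, so real-data entropy and AUCs will be
  less favourable than synthetic ones.
* The bundled growth reference and bra-volume tables are synthetic
  placeholders, adequate for testing the machinery but not for clinical
  use.
* Equal-variance profile models, though implemented, are unsuitable for
  the zero-inflated formula indicator (see above); results with
  `equal_variances=True` on such data should be treated as diagnostic
  only.
* Wald intervals undercover near separation; the ridge stabiliser keeps
  estimates finite but composite levels with very few dyads still yield
  wide, fragile CIs.
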