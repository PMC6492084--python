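# Methods

## Molecular sex from the Ry statistic

Reads mapping to X or Y are treated as n independent draws with
probability p of landing on Y, so the observed fraction
Ry = n_Y/(n_X+n_Y) carries a binomial standard error
sqrt(Ry(1-Ry)/n) and a 95% interval of ±1.96·SE. The decision
thresholds are 0.016 (upper bound for a confident XX) and 0.075 (lower
bound for a confident XY); the four rules are evaluated with strict
inequalities, in the order XX, XY, consistent-with-XX,
consistent-with-XY, falling through to Not Assigned. Exact equality
with a threshold therefore fails the rule — the literal reading of the
published rule text — and a sample with zero informative reads is Not
Assigned with a logged warning rather than an exception at the
pipeline level.

Both thresholds are configurable (`--lower/--upper`). For SAM input
only primary, mapped records with MAPQ ≥ 30 (configurable) are
counted; secondary, supplementary and unmapped records never count.
Chromosome names are normalized ("X" ≡ "chrX"); a label absent from
the header or count table is an error rather than a silent zero.
Counts are assumed to be post-deduplication; the package does no
duplicate removal itself.

## Trait harmonization and element estimates

Native scales map onto the common 1–5 scale by
three-point 1→1, 2→3, 3→5; WEA −2..+2 → 1..5; five-point identity.
Each map is a bijection on its domain and order-preserving, which the
property tests assert. Scale assignment per trait follows the scoring
standards each trait comes from: the three Phenice traits, forehead
inclination, frontal bossing and overall mandible shape are
three-point; arc compose, ilium shape and gonial flaring are WEA; the
rest are standard five-point. The catalogue is data
(`data/trait_catalog.yaml`) and can be replaced wholesale.

An element estimate is the mean of the harmonized scores, binned as
mean ≤ 1.5 → F; (1.5, 2.5] → PF; (2.5, 3.5) → I; [3.5, 4.5) → PM;
≥ 4.5 → M. The bins are symmetric around the integer anchors, so
mirroring every score about the neutral point flips F↔M and PF↔PM
exactly; they are configurable (`mean_bins`). Two deliberate
asymmetries sit on top of the mean:

* **Preauricular sulcus.** Its contribution to the mean is first passed
  through its presence/absence classification (harmonized 1–4
  contribute 1, 5 contributes 5), so a present sulcus — a female
  indicator at any expression — can never push the mean male-ward.
* **Phenice override.** If the os coxae mean lands in I, the majority
  direction of the observed Phenice traits (score 1 votes female, 5
  male, 3 abstains) replaces it; ties stay I. The override applies only
  at I: a mean already in PF/PM is a directional statement the
  low-resolution Phenice vote should not overturn. An optional strict
  mode (`strict_phenice`) demands at least two observable Phenice
  traits before overriding, reflecting that a single observable Phenice
  trait is where the reference cohort's one pelvic misclassification
  occurred.

The combined estimate gives the pelvis priority: a non-indeterminate
pelvis stands; an indeterminate or missing pelvis defers to the skull.
Missing traits are skipped, never imputed; a single-trait element
estimate is allowed (the trait count is reported alongside).

## Concordance statistics

Probable categories collapse to their definite side before comparison
(correct/incorrect is scored binarily); I counts as indeterminate.
Accuracy = 100·correct/(correct+incorrect); raw accuracy =
100·correct/(correct+indeterminate+incorrect); accuracy ≥ raw accuracy
with equality iff nothing was indeterminate. Pooled rates are
unweighted by default; `sex_weighted` replaces the pooled rate by the
mean of the two per-sex rates, protecting the minority sex in
unbalanced cohorts.

The McNemar test is the exact two-sided binomial on the b + c
discordant pairs: p = min(1, 2·P(X ≥ max(b,c))), X ~ Bin(b+c, ½), p = 1
when there are no discordant pairs. A continuity-corrected chi-square
variant exists behind `mcnemar_chi2` but is never the default. Cohen's
κ = (p_o − p_e)/(1 − p_e) is computed on the sexed-only 2×2 table —
indeterminates are excluded before the table is formed — and is
undefined (NaN) when chance agreement is 1. Agreement bands follow the
Watson–Petrie cut-points; because the cut-points are stated on a
two-decimal grid, κ is rounded half-up to two decimals before banding.
Reported precision is one decimal for percentages, three for κ and
p-values, all round-half-up. No multiple-testing correction is applied
to per-trait p-values; they are reported raw.

The Walker posterior P(F | score) = f/(f+m) uses the within-sex score
frequencies and implicitly equal priors; it is undefined where neither
sex ever produces the score, and P(F|s) + P(M|s) = 1 wherever defined.

## Reference cohort fixtures

The package ships the outcome counts of a reference cohort — a
genetically sexed medieval skeletal assemblage, 63 individuals
assessable macroscopically — as plain CSV: per-sex element summaries,
per-sex per-trait counts, and within-sex score distributions. Two
internal inconsistencies of the source tables are preserved as printed
and documented rather than repaired: the pooled combined and pooled os
coxae rows each count one more correct individual than their per-sex
rows sum to (the per-sex rows are treated as authoritative wherever a
2×2 table is needed), and one male score-distribution row sums well
above 100% from an evident transcription slip. The female os coxae
row's two printed rates are also swapped relative to its own counts;
the package always reports rates computed from counts.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not sequence-level reality: trait scores are drawn per individual from
per-sex categorical distributions over the harmonized scale (defaults:
the reference cohort's distributions, renormalized), observability is
Bernoulli per trait (defaults: the reference cohort's observed
fractions of 63), and read counts are binomial in a lognormal total
depth. Defaults: 66 individuals, 61.5% male, mean depth 10,000
informative reads with log-scale sigma 0.6 (ancient-DNA depth is
heavy-tailed), Y-read fraction 0.09 for males and 0.002 for females —
generator conveniences placed on either side of the 0.016/0.075
decision geometry, not empirical estimates — and zero contamination.
Contamination mixes the Y-read probability linearly toward the
contaminant sex. A single seed is split into one child stream per
individual (`numpy` SeedSequence spawning), so enlarging a cohort
leaves earlier individuals bit-identical.

What passing synthetic tests shows: the pipeline's bookkeeping,
thresholds and statistics behave correctly under the generating model
(separable distributions give 100% accuracy, identical ones give
chance-level κ, generated accuracies are recovered within binomial
error, deep uncontaminated cohorts are called >99% concordantly).
What it cannot show: robustness to correlated traits (scores are drawn
independently given sex), inter-observer scoring variation, reference
bias or damage in read mapping, or age-structured dimorphism — none of
which the generator models.

## Problem sizes and numerical choices

The acceptance script's synthetic checks use 1,000 individuals for
molecular concordance and 5,000 for parameter recovery — sizes at
which the 99% binomial band is a few tenths of a percent wide, keeping
the checks sharp while the whole script runs in seconds. All
percentages are exact rational arithmetic until the final rounding;
rounding is decimal round-half-up throughout so CSV/JSON outputs are
byte-stable across reruns. Degenerate inputs are reported as missing
(NaN accuracy when nothing was sexed, NaN κ at degenerate marginals,
NaN posterior at zero mass) rather than raised, except where an input
is unusable outright (empty tables, unknown trait or chromosome
labels).

## Known limitations

No κ confidence intervals or weighted/ordinal κ; no discriminant or
logistic modelling of trait combinations; no aneuploidy handling in
the molecular caller (an XXY individual would sit in the Not Assigned
band); no sequence-level simulation. The five-way molecular call is
collapsed to binary before concordance, so "consistent with" calls are
treated as full calls.
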