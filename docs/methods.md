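# Methods

This note documents the statistical procedures, the synthetic-data model and
the design choices behind `stressrank`.

## Dominance ranking

**Win definition.** Both agonistic behavior classes determine rank: a win of
*i* over *j* in one observation period is `agg[i→j] + sub[j→i]` (initiated
aggression plus the opponent's initiated submission), with both classes
weighted equally. Rationale: submission is as reliable a marker of the
dyadic relationship as aggression, and counting both keeps the win matrix
dense in groups that settle conflicts by avoidance.

**Dyadic index.** Two variants are implemented. `RAW` uses the plain win
proportion `P_ij = w_ij / n_ij`; `CHANCE_CORRECTED` (the default) uses
`D_ij = P_ij − (P_ij − 0.5)/(n_ij + 1)`, which shrinks sparse dyads toward
0.5 so that a single uncontested win does not read as total dominance. When
every dyad has the same number of interactions the two scores are exactly
proportional, so they induce the same ranking; they can differ when
interaction counts are very unbalanced across dyads.

**Zero-interaction dyads** contribute 0 to both directions by default (no
dominance information is invented); a configurable alternative assigns
0.5/0.5, which pulls both individuals toward the group mean.

**Normalization.** `DS'_i = DS_i + |DS_min|`, `normDS_i = DS'_i / DS'_max`.
Because genuine David's scores sum to zero, `DS_min ≤ 0` and the shift
equals subtracting the minimum; the implementation subtracts the minimum so
the [0, 1] bounds also hold for translated score vectors, and an all-equal
score vector raises a degenerate-hierarchy error rather than dividing by
zero.

**Classes and ties.** `normDS > 0.5` → HR, `< 0.5` → LR. Exactly 0.5 is a
BOUNDARY flag: the strict inequalities leave it undefined, so such subjects
are excluded from HR/LR contrasts with a logged warning (in an evenly spread
odd-sized group the middle animal can land exactly on 0.5). Ordinal ties in
normDS are broken by roster order, logged.

**Stability.** Two rankings on the same roster are compared with Kendall's τ
and Spearman's ρ on ordinal ranks; the "switched pairs" list enumerates all
pairs ordered oppositely in the two rankings (a single adjacent swap yields
exactly that pair).

## Longitudinal statistics

**Change scores** are signed proportions `(X_i − X_j)/X_j` (0.10 = +10%),
undefined for a zero reference; undefined entries propagate as missing with
a log entry, never as silent zeros.

**Mixed ANOVA.** The split-plot decomposition is computed from cell means:
between-subject variation splits into the grouping effect and
subjects-within-groups error; within-subject variation into the time effect,
the time × group interaction and the residual. Unequal group sizes are
handled as in a Type II decomposition (group means weighted by group size).
Mauchly's test and the Greenhouse–Geisser ε are computed on the pooled
subjects × levels covariance (the convention of the ezANOVA/pingouin
lineage, which also serves as the independent test oracle; SPSS instead
pools within-group covariances, which can differ slightly). The correction
is applied when Mauchly's p < 0.05 and the within factor has more than two
levels — with two levels sphericity is vacuous and ε = 1. Effect sizes are
partial η² = SS_effect/(SS_effect + SS_error). Units with any missing cell
are dropped listwise, logged. With a single between level the between row is
degenerate (NaN) and the time effect reduces to the one-way
repeated-measures ANOVA (F = t² for two levels).

**Post hoc contrasts** are paired two-tailed t-tests for every time-level
pair (or a supplied family), Holm–Bonferroni-adjusted within the family. One
family per measurement per analysis. Paired t was chosen over
estimated-marginal-means contrasts as the simplest procedure consistent with
reporting per-pair corrected p-values.

**Rank-collapsed correlation** compensates for colony-level differences in
scale: both variables are converted to within-group average ranks (ties
averaged), pooled across groups, and a two-tailed Pearson correlation is
computed on the pooled ranks. With a single group and no ties this is
exactly Spearman's ρ. "Social rank" as a correlate is coded as baseline
normDS, oriented so larger = higher status; since the procedure ranks within
groups anyway, any within-group monotone coding gives the same result.

**Partial correlation** uses the closed form
`r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))` with a two-tailed t test
on n − 3 degrees of freedom; |r_xz| = 1 or |r_yz| = 1 is a degenerate-control
error.

Missing values drop pairwise for correlations and listwise for ANOVA.

## Dyad analyses

Dyads are ordered (directed) throughout: behavior initiated by one animal
and received by another, n(n−1) per group. Crossing initiator and receiver
HR/LR classes gives LL/HL/LH/HH. Appearance strata are assigned per behavior
from the baseline observation only: ZERO (f = 0), LOW (0 < f < t), HIGH
(f ≥ t) — the half-open semantics match the study convention (aggression
t = 5, grooming t = 17). `AUTO` searches the observed nonzero frequencies
(plus one above the maximum) for the cut point minimizing the |LOW| − |HIGH|
imbalance, ties to the smaller threshold. Baseline-vs-change correlations
exclude non-existing pairs (baseline 0) before forming the relative change,
since the change score is undefined at 0.

## Synthetic studies

The generator emulates a two-colony isolation-stress design: groups of 7 and
6 adult females, three six-day observation periods (baseline; weeks 1 and 4
after return to social housing), three blood/hair/weight sample points
bracketing a four-week isolation, five weekly fecal samples.

**Behavior model.** Each group has a planted strict order; subjects are
named in rank order (A1 highest). Per unordered dyad and observation the
number of decided agonistic bouts is Poisson(`interactions_per_dyad`, default
25); the higher-planted animal wins each bout with `dominance_prob` (default
0.9). Every decided bout emits one aggressive event (winner→loser) and one
submissive event (loser→winner), so rank inference is exercised from both
behavior classes. Grooming and proximity are Poisson per directed dyad
(defaults 12 and 18 per observation). Counts are spread multinomially over
the six days. Post-stress observations multiply rates: LR–LR aggression
×0.4, LR–LR grooming ×2.0, proximity ×1.5 in all dyad types — the
qualitative group-level signature of the stressor (fewer fights, more
prosocial contact, driven by low-ranking animals). The planted HR class is
the top ⌈n/2⌉ ranks.

**Physiology model.** Noise-free trajectories per subject (planted normDS
= nd, analyte baseline b drawn log-normally around the population value with
σ = 0.10):

- HC (pg/mg, b = 50): S2 = b·(1 + 0.3 + 1.0·nd); S3 retains half the
  increment — stress raises cortisol in everyone, more in high-ranking
  animals, with partial recovery.
- OT (pg/mL, b = 100): baseline elevated by 0.5·nd; global +0.2·b at S2; a
  further S3 rise of b·(0.35 − 0.30·nd) — oxytocin keeps rising after
  release, more in low-ranking animals.
- AVP (pg/mL, b = 50): +0.4·b at S2; S3 falls by b·(0.10 + 0.30·nd) — the
  vasopressin response tracks cortisol and resolves faster in high-ranking
  animals.
- IgG/IgA (µg/g, b = 6/4): flat until the ramp-onset week (default 2), then
  elevated by b·(0.5 − 0.25·nd), halved at week 4 — a delayed immune
  response that partially adapts.
- Weight (kg, b = 5): flat through isolation, +4% at S3.

Multiplicative Gaussian noise per analyte (σ 0.05–0.06, weight 0.01). The
default effect sizes are deliberately larger than a 13-animal study could
resolve for subtler effects; they are chosen so that planted effects are
recoverable at desk scale, and the recovery bounds in the acceptance suite
(median planted-vs-recovered Spearman ≥ 0.95 over 100 seeds; positive
rank→ΔHC correlation in ≥ 95% of 200 replicates; the LR–LR grooming rise
detected as the largest type-wise increase in ≥ 90% of 100 replicates) were
verified by simulation at exactly these defaults.

**What the generator does not emulate:** real observation-time structure
(diurnal behavior rhythms), non-Poisson overdispersion of social behavior,
assay-specific error distributions, missing data, or coalition/kinship
structure in who grooms whom. Passing recovery tests therefore demonstrates
that the pipeline's inferences are faithful to its own model class, not that
the biological effect sizes are realistic.

**Reproducibility.** One global seed expands into fixed named substreams
(behavior, physiology), so regenerating either half of a study is
byte-identical and independent of whether the other half was drawn.

## Pipeline

`run_pipeline` chains: event-log read → interaction matrices → David's
scores per group × observation (baseline ranks and classes drive all
downstream splits, matching the finding that hierarchies persist) → mixed
time × rank ANOVAs on physiology and per-subject behavior totals → dyad
typing, appearance strata, time × type and time × appearance ANOVAs → post
hoc contrasts → the correlation battery (rank vs levels and changes;
dyad baseline vs change for aggression and grooming; initiated vs received
prosocial change, plain and controlling OT/AVP change). Outputs are TSVs
plus a JSON manifest (config hash, package version, seed, row counts);
identical config and inputs give byte-identical outputs. Correlations that
are undefined on a given dataset (constant vectors, too few pairs) are
skipped with a logged warning rather than aborting the run; ANOVA
preconditions, schema and validation failures abort with a stage-named
error.

## Numerical choices and degenerate inputs

- ΣDS = 0 is asserted to 1e-9 in tests; the identity is exact in exact
  arithmetic for any index matrix.
- Constant data in the ANOVA yields F = 0, p = 1, η² = 0 (not NaN).
- Mauchly's test on data with no within-subject variance returns p = 1
  (sphericity trivially unviolated).
- Holm adjustment enforces the cumulative maximum and caps at 1; it is
  permutation-invariant and never below the raw p-values.
- Rank-collapsed and Pearson correlations require ≥ 4 pooled observations
  and non-constant inputs.
- Simulated analyte values are clipped at a tiny positive floor so assay
  non-negativity always holds.

## Known limitations

- Hierarchy steepness/linearity statistics, Elo-type sequential ratings and
  network-level analyses are out of scope.
- The ANOVA assumes a balanced within factor; partially observed units are
  dropped rather than modeled (no mixed-effects fallback).
- The group covariate is not entered into the ANOVAs; colonies are pooled,
  with the rank-collapsed correlation procedure as the guard against
  colony-scale differences.
- Appearance thresholds are inferred from baseline data only; with heavily
  tied frequency distributions the AUTO split can be far from balanced.
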