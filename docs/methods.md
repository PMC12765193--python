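# Methods

This note documents the models, parameter choices and numerical
conventions behind `broadres`, and what the synthetic panel does and does
not establish about real screening data.

## Composite sensitivity score

Drug response enters as a compound × line matrix of viability log2 fold
changes (LFC; negative = killing), each compound annotated with one
mechanism-of-action (MoA) class. For line *i* and class *c* the class
median *m<sub>i,c</sub>* is taken over the compounds of *c* observed for
*i* (missing entries are legitimate — pooled screens are sparse — and are
skipped). The composite score is the unweighted mean of the class
medians. The defining property is invariance to within-class compound
multiplicity: screens over-represent some mechanisms by an order of
magnitude, and a global median inherits that imbalance while the composite
does not.

A line with *no* observed compound in some class is excluded from the
composite by default (reported, never imputed); `allow_partial_classes`
switches to averaging the classes the line does cover. Exclusion is the
conservative choice: averaging over fewer classes silently changes the
weighting.

Medians use the standard middle-of-two-order-statistics convention; all
ranks use average ranks on ties, which keeps them compatible with Spearman
correlation. The rank-stability diagnostic reports, per line, the sample
SD of its within-class ranks, and per class the Spearman correlation of
the class ranking with the composite ranking. Note that a class ranking is
*not* null against the composite it co-determines: with *k* independent
classes the expected concordance is ≈ 1/√k (Spearman ≈ 0.69 for k = 2),
and the test suite checks that analytic center.

## Cohort definitions

* **Decile**: k = ⌊0.10·n⌋ lines from each end of the composite ranking;
  ties break lexicographically by line id so the partition is
  deterministic.
* **Cluster-refined**: on the decile members, genes are prefiltered by
  |Pearson r| > 0.15 against the composite score, ranked by two-group
  ANOVA F, the top 250 retained (all retained, with a warning, when fewer
  survive), z-scored per gene, and the members clustered with Ward linkage
  on Euclidean distance. Every internal dendrogram node is scanned; for
  each phenotype the largest node whose leaves are 100% that phenotype
  (minimum size 3; ties broken by lower within-cluster variance) becomes
  the refined group. Scanning all nodes rather than a single cut height is
  a deliberate choice: it is parameter-free and the "largest pure
  cluster" objective does not depend on where a flat cut falls.
* **Lineage-balanced**: restrict to lineages present in both decile
  groups; per shared lineage take min(count in resistant, count in
  sensitive) lines per side, chosen by most extreme composite score. The
  two groups then have identical lineage multisets by construction.

The metadata covariate screen is univariate: one-way ANOVA across levels
for categorical covariates, a two-sided slope test for numeric ones,
BH-adjusted across all tested covariates; constant or singleton features
are skipped with a recorded reason.

## Differential analysis

Per-feature Welch (unequal-variance) t-tests on the matrix scale
(log2(TPM+1) for expression, normalized abundance for metabolites), effect
size = mean(resistant) − mean(sensitive), BH across features. Welch is the
robust default when group variances differ and the groups are small; the
choice is isolated in one function and swappable. Features constant and
equal in both groups get p = 1 (not an error); constant but unequal get
p = 0. Robust markers must be nominally significant (p < 0.05) with a
consistent direction in all three cohort definitions *and* survive the
score-correlation filter (|r| > 0.15 with BH q < 0.05). The correlation
filter is what keeps the cross-strategy intersection precise: the three
cohorts share many members, so their tests are strongly correlated and
nominal intersection alone does not control false positives.

Over-representation analysis is a one-sided Fisher exact test per library
set against an explicit universe, BH across the library. The joint
gene + metabolite variant simply pools both feature types into one query
and one mixed universe — pathway-topology impact weighting is out of
scope. The two-sided Fisher variant is reserved for validating the overlap
between resistance-up genes and treatment-down genes over a fixed
expressed-gene universe.

## Mutation statistics

Gene skew is the difference in percent mutated between the groups, in
percentage points ∈ [−100, 100]; the top-50 lists per direction feed
enrichment. Per-sample pathway burden tests each line's mutated gene set
against each pathway (one-sided Fisher over the mutation matrix's gene
universe by default) and stores −log10 p; a line with no mutations scores
0 everywhere. Pathway impact is (fraction of group lines with p < α) ×
(mean −log10 p over **all** group lines) — the mean is not restricted to
enriched lines — and group skew is the resistant − sensitive impact
difference. Fractions, not percents, enter the product so magnitudes are
comparable across α; reported tables carry both scales. Group membership
("50 most resistant/sensitive" vs deciles) is a caller choice, not baked
in.

## Reversal screening

Each perturbagen carries disjoint up/down signature sets. The screen
tests the repression arm (resistance-up vs drug-down) and the restoration
arm (resistance-down vs drug-up) with one-sided Fisher tests over the
library-covered gene universe and sums the two −log10 p values; an arm
whose query set is empty contributes 0 rather than a penalty, since
repression of over-expressed genes is the primary signal. This additive
combiner was chosen for symmetry and monotonicity; planted-reverser
recovery does not depend on the precise combination rule. BH q-values are
computed over the repression-arm p-values. Ranking ties break by
perturbagen id.

## The synthetic panel

`simulate_panel` draws, from one seeded generator stream in documented
order: a standard-normal latent resistance score per line; compound base
effects from N(−1.5, 0.5) so most compounds kill; drug LFC = base +
`resistance_effect`·z + N(0, `noise_sd`); expression = gene baseline
N(6, 1) + a small lineage offset N(0, 0.3) + noise, with the planted up
(default 50 genes, +`signature_effect`) and down (a quarter the size —
resistance programs in screens are dominated by up-regulation) programs
shifted in the truly resistant decile; metabolite shifts likewise; and
background mutations Bernoulli(0.01) per gene × line (the per-gene somatic
frequency of a typical gene across pan-cancer lines).

Defaults: 200 lines, 3 lineages, five MoA classes of 120/78/60/30/12
compounds (one class 10× another, so class weighting matters),
`resistance_effect`/`noise_sd` = 1.0/0.5, 2000 genes, 200 metabolites,
convergent set of 6 genes at 44% coverage, 200 perturbagens with one
reverser whose down-signature contains half the planted up program. The
lineage count is deliberately small: the lineage-balanced strategy keeps
min(resistant, sensitive) lines per shared lineage, so a desk-scale panel
needs a few well-populated lineages to leave balanced groups comparable to
the extremes — the scaled-down analogue of a large panel with dozens of
lineages.

Two constructions are exact by design rather than sampled:

* **Convergent mutations.** Exactly ⌊coverage·|resistant|⌉ truly
  resistant lines each receive exactly one convergent-set mutation, and
  the convergent genes receive no background mutations anywhere. Coverage
  therefore matches its target to rounding and exclusivity is 1.0 — the
  mutually exclusive convergence pattern the statistics are built to
  detect, in its idealized form.
* **Reverser overlap.** The reverser's down-signature contains exactly
  ⌊fraction·|up program|⌉ planted up-genes; its random filler avoids the
  remaining planted genes so the overlap is exact. All other perturbagens
  draw their signatures uniformly, so planted genes appear in them at
  background rates.

What the panel does **not** emulate: empirical LFC distributions beyond
qualitative shape, dose-response structure, expression covariance between
genes (genes are independent given lineage and phenotype), mutation
co-occurrence structure, batch effects, or any real cell-line identity.
Passing tests therefore demonstrate that the statistics recover planted
structure at realistic effect sizes and calibrate correctly under the
null — not that real screens contain such structure.

## Numerical conventions

* BH step-up via statsmodels; q ≥ p element-wise, order-preserving.
* Fisher tests via scipy's exact routine; the two-sided p sums point
  masses ≤ the observed one. Odds ratios are plain cross-products with
  +inf/0 for single zero cells and NaN when numerator and denominator both
  vanish — no Haldane correction, since inference rides on the p-value.
* Matrices are written with 12 significant digits; float round trips are
  good to better than 1e-9 relative, integer matrices are bit-exact, and
  pipeline reruns with identical config + seed are byte-identical.
* Identifiers are case-sensitive; ingestion trims whitespace and nothing
  else, to avoid silent symbol collisions.

## Problem sizes in the test and acceptance runs

Cohort, differential and reversal recovery run on the 200-line default
panel over 20 seeds; mutation statistics on a 500-line panel (50 lines per
extreme group, the scale at which mutation analyses are meaningful); the
differential null calibration pools 100-gene panels over 200 seeds (20k
null tests); the reversal null runs 200 constructed random libraries of
200 perturbagens. These sizes give tight binomial confidence bands while
keeping a full run in the low minutes on one CPU.

## Known limitations

* The per-sample burden test treats each line's mutated gene set as
  exchangeable draws from the universe; it ignores per-gene mutability
  differences, so on real data highly mutable genes inflate burden.
* The dendrogram-node scan for pure clusters can return small groups when
  transcriptomes separate poorly; the minimum-size-3 floor turns that
  into an explicit error rather than a silent degenerate cohort.
* MoA enrichment calibration depends on annotation granularity: a handful
  of very large classes makes chance concentration likely; libraries with
  many small classes (the realistic case) are well calibrated.
* No moderated-variance (empirical-Bayes) modeling, no pathway-topology
  impact scores, no network inference beyond descriptive degrees and ego
  neighborhoods.
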