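# Methods

This note documents the statistical models implemented in `lipidaxis`,
the parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical decisions that a
maintainer would otherwise have to reverse-engineer from the code.

## Study design assumed throughout

Two groups — depression-like (DL) and healthy control (HC) — of six
animals each, profiled in three brain regions (PFC, AMY, HIP) and plasma
for lipids, in feces for the metagenome, and observationally for five
behaviors (huddle, sit alone, locomotion, amicable, communication).
All group comparisons are unpaired; all thresholds below are the
pipeline's defaults and are overridable per call or via the CLI config.

## QC filtering and normalization

A lipid feature is retained iff `Rej == 0`, `PQ > 0.85`, `CV < 0.3` and
`|Δm| ≤ 5 ppm`. The peak-quality and CV bounds are strict inequalities
and the mass tolerance is inclusive — a literal reading of how such
criteria are conventionally stated ("higher than", "below", "tolerance
was"). Filtering precedes normalization by construction (the filter
refuses normalized input), and each sample column is then scaled to sum
to 100 (percent of total peak area). Normalizing to 100 rather than 1 is
cosmetic — every downstream statistic is scale-invariant per sample — but
fixed for reproducibility. When positive- and negative-mode tables are
both present they are filtered independently and concatenated before
normalization; duplicate species keep the copy with the higher mean
abundance (logged).

## Differential lipid analysis

*Subclass level.* Species abundances are summed per subclass; the fold
change is the DL mean over the HC mean of the per-sample sums, tested
with an unpaired two-sided Student (pooled-variance) t test. Welch's
variant is available by flag but off by default, matching the pooled
form implied by "Student's t test". A zero HC mean leaves the fold
change undefined and flags the row rather than failing the run.

*Structure level.* Within one subclass, species are binned by total
carbon count or total double-bond count (bins are exactly the observed
values) and each bin's per-sample sums are compared with the same t test.

*Species level.* PLS-DA uses scikit-learn's NIPALS implementation with
mean centering and unit-variance scaling (the SIMCA convention) on a 0/1
class dummy, two components by default (score plots of such studies are
two-dimensional; the component count is a parameter). VIP is computed
across all fitted components from the unit-norm x-weights and the
per-component explained response variance, which pins the mean squared
VIP at exactly 1 — an invariant the tests assert after every fit. Note
that the null VIP distribution is right-skewed: the mean square is 1 but
the median sits near 0.8, so "VIP ≈ 1" reasoning should use the mean
square, not the median. Discriminating species are exactly the features
with VIP > 1.0 *and* univariate two-sided t-test P < 0.05; the univariate
t test (not a PLS-internal P) is the conventional partner of the VIP
cutoff and is what this package pairs it with. No multiple-testing
correction is applied anywhere by default, matching the stated threshold
semantics; a Benjamini–Hochberg step can be added by the caller from
`statsmodels` if desired, but the package deliberately reports raw P
values.

Constant feature columns cannot be unit-variance scaled and are dropped
with a log message before the PLS fit.

## Reaction-network activity

The activity model treats each lipid-class transformation A_i → A_{i+1}
as an edge with per-sample weight ω_i = A_{i+1}/A_i, where A is the
class-level sum of normalized species abundances in that sample.
Class-level granularity is a modeling choice: the pathway diagrams this
reproduces are drawn over class nodes, and class sums make ω a single
per-sample scalar per edge. Because ω is a within-sample ratio, every
activity statistic is invariant to rescaling any sample's abundances —
the property suite asserts this.

For each edge, a one-sided pooled t test compares DL weights against HC
weights in the DL > HC direction, giving P⁺, and the score is
Z = Φ⁻¹(1 − P⁺). This single formula encodes the direction convention:
an HC-favored edge has P⁺ > 0.5 and a negative Z, so no second test or
explicit sign flip is needed. The t test runs on raw ω by default — a
deliberate literalism, since the method is defined on the weights
themselves — with a `log_weights` flag for the skew-robust variant.
Degrees of freedom are pooled (Student); Welch is a flag.

Pathway aggregation: Z_A = (1/√(k−1)) Σ Z_i over the k−1 edges of a
k-node chain. Under independent null edges Z_A is standard normal (the
Monte-Carlo test verifies this at 10,000 draws), so the same ±1.645
one-sided-0.05 critical value applies at both levels. Synthesis and
degradation scores for a class aggregate its incoming and outgoing edge
Z scores with the same formula.

The shipped default network is the union of six DG-centred chains
(LPC-PC-PA-DG-TG, LPC-PC-PA-LPA, LPC-LPA, DG-PC-LPC, DG-PA-PI-LPI,
LPA-PA-PG-LPG); arbitrary networks load from a four-column reaction TSV
(pathway_id, step_index, substrate, product). Pathway chains are read
left to right as substrate → product.

Numerical choices: one-sided P values are clipped to [1e-16, 1−1e-16]
before the inverse-normal transform, bounding |Z| ≈ 8.2 so degenerate
edges cannot inject infinities into pathway sums. Two groups with zero
variance and equal means give Z = 0 (ns). Samples with zero substrate
abundance are dropped for that edge with a warning (default) or raise
(`zero_policy="fail"`); edges whose classes are absent from the data are
skipped, and pathways containing skipped edges are renormalized over the
available edges and flagged `partial`.

## Two-class LEfSe

Stage 1 screens each taxon with a Kruskal–Wallis test at α = 0.05; with
two classes this is the Wilcoxon rank-sum test. Note a calibration
subtlety at n = 6 + 6: the rank statistic is discrete, so the exact
attainable level of the nominal-0.05 screen is ≈ 0.041 — the null
false-positive rate sits *below* 0.05, and the test suite checks it
against an exact enumeration of all C(12,6) rank assignments rather than
against 0.05 itself.

Stage 2 reimplements the canonical LEfSe effect size for the two-class
design: abundances are scaled to one million and floored at 1; over 30
bootstrap rounds, two-thirds of each class is subsampled and a linear
discriminant fitted; a taxon's per-round effect size is the average of
its raw class-mean difference and its share of the class-mean separation
along the unit discriminant direction; the LDA score is log10(1 + mean
effect). The all-against-all subclass Wilcoxon stage of canonical LEfSe
is omitted as vacuous here (two classes, no subclass factor). The pass
threshold defaults to 2.0 with 2.5 selectable. Degenerate bootstrap
rounds (singular discriminant) are skipped and logged. Classes are
ordered internally by the class of the first sample column rather than
by label name, which makes a pure label swap reuse the identical
bootstrap stream — scores are preserved exactly and enrichment labels
flip, a property the tests assert.

## Co-occurrence network

All pairwise Spearman correlations (midranks for ties) among the
assembled node blocks; an edge is retained when P < 0.05 and |ρ| > 0.70
(both strict, matching the threshold wording ">0.70 or <−0.70"). P
values use the t approximation by default; a seeded Monte-Carlo
permutation P (10,000 resamples) is available by flag for the small-n
regime — full enumeration at n = 12 (12! orderings) is not attempted.
Constant node vectors have undefined rank correlation and are excluded
with a warning. The retained graph is exported as GraphML with node-kind
and edge-ρ/P attributes; layout, styling, and cluster annotation are
left to external tools.

## Synthetic data generators

*Lipidome.* Species names are drawn per subclass from realistic total
carbon / double-bond ranges (diacyl classes 30–44 C; brain DG 34–40 C
with 2–6 double bonds; plasma DG 49–54 C with 0–3; TG 48–58 C; lyso
classes 14–24 C) and are guaranteed unique and parseable. Abundances are
lognormal: each feature gets a baseline log-mean (spread SD 1.0 across
features around a log-mean of 10) and each measurement a within-group
log-SD of 0.25 — about a 25% biological CV, a realistic magnitude for MS
peak areas of a lipid class across outbred animals. Group effects
multiply DL-sample abundances of the targeted subclass (optionally
restricted by total carbons or double bonds), so a planted fold change
is directly the expected DL/HC mean ratio. Exactly
`round(qc_fail_fraction · n_features)` features receive one failing QC
field each. Default inventory: ~2000 brain species across 13 subclasses
dominated by PE/PC/PS, thinned to 80% for plasma.

What the generator does *not* emulate: correlated species within a
subclass (real lipid species co-vary through shared enzymes), heavier
compositional coupling than total-area closure induces, batch or
injection-order drift, missing values, and ionization-mode structure.
Passing recovery tests therefore demonstrates that the statistics find
the effects they are defined to find under the stated noise model — not
that they are robust to every artifact of real LC-MS data.

*Microbiome.* Lognormal taxon abundances (between-taxon spread 1.5,
within-group log-SD 0.6), planted enrichments as multipliers, structural
zeros planted with the configured probability *before* closure, columns
closed to sum to exactly 1. Lineages are synthetic rank-prefixed strings
(phylum to species) that exercise the parser.

*Behaviors.* Durations are nonnegative; uncoupled behaviors draw from a
gamma distribution (shape 4, scale 15 — right-skewed, mean ≈ 60 s).
A coupling (behavior, feature, strength s) blends the feature's ranks
(reversed for s < 0) with independent noise ranks at weight |s|, so the
target Spearman sign is guaranteed for |s| = 1 (ρ is exactly ±1 when
`noise_sd = 0`) and the strength is interpretable as a rank-mixing
proportion. Gaussian measurement noise (`noise_sd`) is added on the
duration scale and clipped at zero.

All three generators are deterministic under a fixed seed; the CLI
derives per-table seeds as small fixed offsets of the run seed.

## Problem sizes used in the test suite

Replicated recovery tests use a compact subclass inventory (the ten
classes of the default reaction network, 89 species) at n = 6 per group
with 50 replicates; the subclass fold-change recovery check runs at
n = 100 per group; the null-calibration check of the activity call uses
5,000 simulated reactions in the test suite and 20,000 in
`scripts/acceptance.py`; pathway-score normality uses 10,000 Monte-Carlo
draws. These sizes give the binomial/Monte-Carlo standard errors the
assertions are stated against.

## Known limitations

- The reaction-activity t test on raw ω is anti-conservative in
  principle for heavily skewed weights; at the default noise level the
  empirical type-I error is ≈ 0.049 against a nominal 0.05, and the
  `log_weights` flag exists for heavier-tailed data.
- LEfSe scores depend (mildly) on the bootstrap stream; only seeded runs
  are exactly reproducible.
- The co-occurrence stage tests marginal pairwise associations only; it
  makes no claim about conditional independence or causal direction
  along the gut–brain axis.
- Sum-composition names ("PC(34:2)") carry no chain-level information;
  structure profiles treat them by their totals, which is the only
  information present.
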