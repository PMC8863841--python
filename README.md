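# lipidaxis

Analytics for microbiota–gut–brain (MGB) axis studies that combine brain
lipidomics, gut metagenomics, and behavioral phenotyping in a two-group
(case vs control) design. The package grew out of re-implementing, as
tested and reusable code, the computational pipeline of a depression-like
non-human primate study: LipidSearch-style lipid tables are QC-filtered
and normalized, lipid species are parsed into structured annotations,
groups are compared at subclass / structure / species level, a lipid
reaction network is scored for pathway activity, differential taxa are
called LEfSe-style, and everything is tied together in a thresholded
Spearman co-occurrence network. A seeded synthetic-data generator
reproduces the statistical structure of such a study so every stage is
testable without access to animal data.

## What it computes

**Lipid shorthand parsing.** Names like `DG(22:6/22:6)` or `PC(34:2)` are
parsed into subclass, per-chain (carbons : double bonds) composition, and
totals; subclasses map to molecular geometry (cone: DG, PA, TG; cylinder:
PC, PI; inverted cone: LPI, LPC).

**QC and normalization.** A feature is retained iff Rej = 0, PQ > 0.85,
CV < 0.3 and mass deviation ≤ 5 ppm; retained peak areas are normalized
per sample to percent of total peak area.

**Differential lipids.** Subclass fold changes (DL mean / HC mean) with
unpaired two-sided Student t tests; abundance profiles along total carbon
number and total unsaturation; PLS-DA (mean-centered, unit-variance,
0/1 class dummy) with the standard VIP statistic

    VIP_j = sqrt( p · Σ_a w_ja² · SSY_a / Σ_a SSY_a ),   mean_j VIP_j² = 1,

and the double cutoff VIP > 1.0 AND t-test P < 0.05 for discriminating
species.

**Reaction-network activity.** For a pathway A₁ → A₂ → … → A_k over lipid
classes, each edge's per-sample weight is ω_i = A_{i+1}/A_i (class-level
abundance ratio). A one-sided Student t test compares DL vs HC weights in
the DL > HC direction, and Z_i = Φ⁻¹(1 − P). Reactions more active in
control have P > 0.5 and come out negative automatically. Pathway scores
aggregate as

    Z_A = (1/√(k−1)) Σ_i Z_i,

standard normal under the null; |Z| > 1.645 (one-sided 0.05) calls a
reaction or pathway active/inactive. Class-level synthesis (incoming
edges) and degradation (outgoing edges) scores use the same formula.

**Differential taxa.** Two-class LEfSe: Kruskal–Wallis screen at 0.05,
then a bootstrapped linear-discriminant effect size on abundances scaled
to one million; taxa pass at log10 effect size (LDA score) > 2.0.

**Co-occurrence network.** All pairwise Spearman correlations among taxa,
lipid species, and behaviors; edges retained when P < 0.05 and
|ρ| > 0.70; exported as GraphML plus a flat edge TSV.

## Worked example

```python
import lipidaxis as lx
from lipidaxis.preprocess import normalize_total_area

cfg = lx.LipidomeSimConfig(
    tissues=("PFC",),
    n_species_per_subclass={"LPC": 8, "PC": 20, "PA": 15, "DG": 10, "TG": 8,
                            "LPA": 5, "PI": 8, "LPI": 5, "PG": 6, "LPG": 4},
    subclass_effects=(("PFC", "DG", 1.38),),   # plant a 1.38x DG increase in DL
    qc_fail_fraction=0.1,
    seed=42,
)
tl = lx.generate_lipidome(cfg).tissues["PFC"]
filtered, report = lx.apply_qc_filters(tl.table, tl.qc)
table = normalize_total_area(filtered)
mat = lx.subclass_abundance(table)
print(lx.subclass_test(mat, table.groups, tissue="PFC").query("subclass == 'DG'"))
_, pathways, acts = lx.evaluate_network(mat, table.groups)
syn, deg = lx.synthesis_degradation(lx.ReactionNetwork.default(), acts, "DG")
print(f"DG synthesis Z = {syn.z_a:.3f} ({syn.verdict}); "
      f"degradation Z = {deg.z_a:.3f} ({deg.verdict})")
```

prints (seed 42):

```
tissue subclass  fold_change  p_value  n_species  flagged
   PFC       DG     1.326487 0.005955          0    False
DG synthesis Z = 2.601 (active); degradation Z = -4.662 (inactive)
```

The planted 1.38× DG fold change is recovered as 1.33 (n = 6 per group,
so sampling noise of this size is expected) with P < 0.01. Because DG
abundance rises while its neighbors do not, ratios into DG increase and
ratios out of DG fall: the synthesis score is positive and the
degradation score strongly negative — the Z-score machinery attributes
the DG accumulation to suppressed degradation, which is exactly how the
planted effect propagates through ω.

The same flow runs from a shell:

```sh
lipidaxis --seed 42 --out-dir run all     # simulate → qc → lipids → pathways → taxa → network
```

writing plain TSV results, `network/network.graphml`, and a
`manifest.json` (config echo, seed, input checksums) into `run/`.

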