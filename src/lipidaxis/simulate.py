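"""Seeded synthetic lipidome, microbiome, and behavior generators.

These generators reproduce the *statistical structure* the analysis
assumes — two groups (DL vs HC) of six animals, four tissues
(PFC / AMY / HIP / plasma), roughly two thousand brain lipid species
(sixteen hundred in plasma) across thirteen subclasses, planted
multiplicative group effects, rank-prefixed taxon lineages with planted
enrichments, and behavior durations rank-coupled to molecular features —
so every downstream stage can be tested against known ground truth.

Peak areas are lognormal (strictly positive, right-skewed, like MS peak
areas); group effects are multiplicative fold changes, so the planted
effect size is directly the expected DL/HC mean ratio. Microbiome zeros
are structural (set before closure); lipid tables carry no zeros, since
QC-passing MS features are quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .nomenclature import (
    EXPECTED_CHAINS,
    SUBCLASSES,
    LipidAnnotation,
    parse_lipid_name,
)
from .tables import FeatureTable, QCTable, TaxonTable

__all__ = [
    "ConfigError",
    "LipidomeSimConfig",
    "MicrobiomeSimConfig",
    "BehaviorSimConfig",
    "TissueLipidome",
    "LipidomeDataset",
    "generate_lipidome",
    "generate_microbiome",
    "generate_behaviors",
    "null_reaction_abundances",
    "BEHAVIORS",
    "BRAIN_SPECIES_COUNTS",
]


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


#: Species counts per subclass for a brain tissue (~2000 total); PE, PC and
#: PS dominate, as they do in primate brain, and DG is a small class.
BRAIN_SPECIES_COUNTS: dict[str, int] = {
    "PE": 500, "PC": 460, "PS": 390, "SM": 120, "Cer": 110, "PA": 108,
    "PI": 90, "PG": 70, "TG": 60, "LPC": 40, "LPE": 30, "DG": 15, "So": 12,
}

#: (total carbon range, total double-bond range) per subclass. DG differs
#: between brain (34-40 C, 2-6 db) and plasma (49-54 C, 0-3 db).
_CHAIN_RANGES: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "PC": ((30, 44), (0, 8)), "PE": ((30, 44), (0, 8)), "PA": ((30, 44), (0, 8)),
    "PG": ((30, 44), (0, 8)), "PI": ((30, 44), (0, 8)), "PS": ((30, 44), (0, 8)),
    "SM": ((30, 42), (0, 4)), "Cer": ((30, 42), (0, 4)), "GM1": ((32, 42), (0, 4)),
    "TG": ((48, 58), (0, 8)), "DG": ((34, 40), (2, 6)), "MG": ((14, 24), (0, 6)),
    "LPC": ((14, 24), (0, 6)), "LPE": ((14, 24), (0, 6)), "LPA": ((14, 24), (0, 6)),
    "LPI": ((14, 24), (0, 6)), "LPG": ((14, 24), (0, 6)), "So": ((14, 22), (0, 2)),
}
_DG_PLASMA_RANGE = ((49, 54), (0, 3))

BEHAVIORS: tuple[str, ...] = (
    "huddle", "sit_alone", "locomotion", "amicable", "communication"
)


@dataclass(frozen=True)
class LipidomeSimConfig:
    """Configuration of the synthetic lipidome.

    Effects are triples/quadruples keyed on tissue and subclass:
    ``subclass_effects`` multiplies every DL-sample abundance of the
    subclass by ``fold_change``; ``chain_effects`` and ``unsat_effects``
    restrict the effect to species with the given total carbon count or
    double-bond count.
    """

    n_per_group: int = 6
    tissues: tuple[str, ...] = ("PFC", "AMY", "HIP", "plasma")
    n_species_per_subclass: Mapping[str, int] = field(
        default_factory=lambda: dict(BRAIN_SPECIES_COUNTS)
    )
    base_log_mean: float = 10.0
    base_log_sd: float = 0.25
    feature_log_sd: float = 1.0
    plasma_species_fraction: float = 0.8
    subclass_effects: tuple[tuple[str, str, float], ...] = ()
    chain_effects: tuple[tuple[str, str, int, float], ...] = ()
    unsat_effects: tuple[tuple[str, str, int, float], ...] = ()
    qc_fail_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 3:
            raise ConfigError("n_per_group must be >= 3")
        if not 0 <= self.qc_fail_fraction <= 1:
            raise ConfigError("qc_fail_fraction must be in [0, 1]")
        for sub in self.n_species_per_subclass:
            if sub not in SUBCLASSES:
                raise ConfigError(f"unknown subclass {sub!r} in species counts")
        for eff in self.subclass_effects:
            _, sub, fc = eff
            if sub not in SUBCLASSES:
                raise ConfigError(f"unknown subclass {sub!r} in subclass_effects")
            if fc <= 0:
                raise ConfigError(f"fold change must be > 0, got {fc}")
        for eff in list(self.chain_effects) + list(self.unsat_effects):
            _, sub, _, fc = eff
            if sub not in SUBCLASSES:
                raise ConfigError(f"unknown subclass {sub!r} in structure effect")
            if fc <= 0:
                raise ConfigError(f"fold change must be > 0, got {fc}")


@dataclass
class TissueLipidome:
    table: FeatureTable
    annotations: dict[str, LipidAnnotation]
    qc: QCTable


@dataclass
class LipidomeDataset:
    tissues: dict[str, TissueLipidome]
    config: LipidomeSimConfig


def _split_total(total: int, parts: int, rng: np.random.Generator) -> list[int]:
    """Split a total into `parts` nonnegative integers, roughly even."""
    if parts == 1:
        return [total]
    base = total // parts
    out = [base] * parts
    out[0] += total - base * parts
    # jitter while keeping nonnegative entries
    for i in range(parts - 1):
        shift = int(rng.integers(-2, 3))
        if out[i] + shift >= 0 and out[i + 1] - shift >= 0:
            out[i] += shift
            out[i + 1] -= shift
    return out


def _species_names(
    subclass: str,
    count: int,
    tissue: str,
    rng: np.random.Generator,
) -> list[str]:
    """Unique, parser-valid shorthand names for one subclass."""
    c_range, d_range = _CHAIN_RANGES[subclass]
    if subclass == "DG" and tissue == "plasma":
        c_range, d_range = _DG_PLASMA_RANGE
    k = 1 if subclass == "GM1" else EXPECTED_CHAINS[subclass]
    names: list[str] = []
    seen: set[str] = set()
    tries = 0
    while len(names) < count and tries < 400 * count:
        tries += 1
        tc = int(rng.integers(c_range[0], c_range[1] + 1))
        td = int(rng.integers(d_range[0], d_range[1] + 1))
        if k == 1:
            body = f"{tc}:{td}"
        else:
            cs = _split_total(tc, k, rng)
            ds = _split_total(td, k, rng)
            body = "/".join(f"{c}:{d}" for c, d in zip(cs, ds))
        name = f"{subclass}({body})"
        if name not in seen:
            seen.add(name)
            names.append(name)
    if len(names) < count:
        raise ConfigError(
            f"cannot generate {count} unique {subclass} species in range "
            f"C{c_range} / db{d_range}"
        )
    return names


def _sample_index(n_per_group: int) -> pd.Index:
    return pd.Index(
        [f"DL{i+1:02d}" for i in range(n_per_group)]
        + [f"HC{i+1:02d}" for i in range(n_per_group)],
        name="sample",
    )


def generate_lipidome(config: LipidomeSimConfig) -> LipidomeDataset:
    """Generate per-tissue feature tables with planted group effects.

    Per tissue: species names are drawn per subclass from realistic chain
    ranges (guaranteed parseable and unique), abundances are lognormal
    with a per-feature baseline, planted effects multiply DL samples, and
    exactly ``round(qc_fail_fraction * n_features)`` features receive a
    failing QC field. Fully deterministic under a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sample_ids = _sample_index(config.n_per_group)
    n = config.n_per_group
    tissues: dict[str, TissueLipidome] = {}
    for tissue in config.tissues:
        names: list[str] = []
        for sub, count in config.n_species_per_subclass.items():
            c = count
            if tissue == "plasma":
                c = max(1, round(count * config.plasma_species_fraction))
            names.extend(_species_names(sub, c, tissue, rng))
        annotations = {nm: parse_lipid_name(nm) for nm in names}
        p = len(names)

        mu = config.base_log_mean + rng.normal(0, config.feature_log_sd, p)
        logv = mu[:, None] + rng.normal(0, config.base_log_sd, (p, 2 * n))
        values = np.exp(logv)

        dl_mask = np.arange(2 * n) < n
        mult = np.ones(p)
        for t, sub, fc in config.subclass_effects:
            if t != tissue:
                continue
            sel = np.array([annotations[nm].subclass == sub for nm in names])
            mult[sel] *= fc
        for t, sub, tc, fc in config.chain_effects:
            if t != tissue:
                continue
            sel = np.array(
                [
                    annotations[nm].subclass == sub
                    and annotations[nm].total_carbons == tc
                    for nm in names
                ]
            )
            mult[sel] *= fc
        for t, sub, td, fc in config.unsat_effects:
            if t != tissue:
                continue
            sel = np.array(
                [
                    annotations[nm].subclass == sub
                    and annotations[nm].total_double_bonds == td
                    for nm in names
                ]
            )
            mult[sel] *= fc
        values[:, dl_mask] *= mult[:, None]

        n_fail = round(config.qc_fail_fraction * p)
        qc = pd.DataFrame(
            {
                "rej": np.zeros(p, dtype=int),
                "pq": rng.uniform(0.86, 1.0, p),
                "cv": rng.uniform(0.05, 0.29, p),
                "ppm_dev": rng.uniform(0.0, 5.0, p),
            },
            index=pd.Index(names, name="species"),
        )
        fail_idx = rng.choice(p, n_fail, replace=False)
        fail_mode = rng.integers(0, 4, n_fail)
        for idx, mode in zip(fail_idx, fail_mode):
            if mode == 0:
                qc.iloc[idx, qc.columns.get_loc("rej")] = 1
            elif mode == 1:
                qc.iloc[idx, qc.columns.get_loc("pq")] = rng.uniform(0.3, 0.85)
            elif mode == 2:
                qc.iloc[idx, qc.columns.get_loc("cv")] = rng.uniform(0.3, 0.8)
            else:
                qc.iloc[idx, qc.columns.get_loc("ppm_dev")] = rng.uniform(5.01, 12.0)

        samples = pd.DataFrame(
            {
                "group": ["DL"] * n + ["HC"] * n,
                "tissue": tissue,
            },
            index=sample_ids,
        )
        table = FeatureTable(
            pd.DataFrame(values, index=pd.Index(names, name="species"), columns=sample_ids),
            samples,
        )
        tissues[tissue] = TissueLipidome(table, annotations, QCTable(qc))
    return LipidomeDataset(tissues, config)


@dataclass(frozen=True)
class MicrobiomeSimConfig:
    """Configuration of the synthetic compositional taxon table.

    ``differential_taxa`` entries are ``(taxon_index, enriched_class,
    multiplier)``: abundances of that taxon are multiplied in the
    enriched class before closure.
    """

    n_per_group: int = 6
    n_taxa: int = 100
    lineage_depth: int = 6
    differential_taxa: tuple[tuple[int, str, float], ...] = ()
    zero_inflation: float = 0.0
    base_log_sd: float = 0.6
    feature_log_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 3:
            raise ConfigError("n_per_group must be >= 3")
        if not 2 <= self.lineage_depth <= 6:
            raise ConfigError("lineage_depth must be in 2..6 (phylum..species)")
        if not 0 <= self.zero_inflation < 1:
            raise ConfigError("zero_inflation must be in [0, 1)")
        if self.n_taxa < len(self.differential_taxa):
            raise ConfigError(
                f"n_taxa={self.n_taxa} smaller than number of differential "
                f"taxa ({len(self.differential_taxa)})"
            )
        for idx, cls, mult in self.differential_taxa:
            if not 0 <= idx < self.n_taxa:
                raise ConfigError(f"differential taxon index {idx} out of range")
            if cls not in ("DL", "HC"):
                raise ConfigError(f"enriched class must be DL or HC, got {cls!r}")
            if mult <= 0:
                raise ConfigError(f"effect multiplier must be > 0, got {mult}")


_PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria", "Uroviricota")
_RANK_PREFIXES = ("p", "c", "o", "f", "g", "s")


def _lineage(i: int, depth: int) -> str:
    phylum = _PHYLA[i % len(_PHYLA)]
    parts = [f"p__{phylum}"]
    stems = ("c", "o", "f", "g")
    for level, stem in enumerate(stems[: max(0, depth - 2)], start=1):
        parts.append(f"{stem}__{phylum}_{stem}{(i // (level * 3)) % 5}")
    if depth >= 2:
        parts.append(f"s__Taxon_{i:04d}")
    return ";".join(parts[:depth])


def generate_microbiome(config: MicrobiomeSimConfig) -> TaxonTable:
    """Generate a compositional taxon table with planted enrichments.

    Abundances are lognormal per taxon, structural zeros are planted with
    probability ``zero_inflation`` before closure, and columns are closed
    to sum exactly 1.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    sample_ids = _sample_index(n)
    mu = rng.normal(0, config.feature_log_sd, config.n_taxa)
    values = np.exp(
        mu[:, None] + rng.normal(0, config.base_log_sd, (config.n_taxa, 2 * n))
    )
    dl_mask = np.arange(2 * n) < n
    for idx, cls, mult in config.differential_taxa:
        mask = dl_mask if cls == "DL" else ~dl_mask
        values[idx, mask] *= mult
    if config.zero_inflation > 0:
        zeros = rng.random((config.n_taxa, 2 * n)) < config.zero_inflation
        values[zeros] = 0.0
    col_sums = values.sum(axis=0)
    if (col_sums <= 0).any():
        raise RuntimeError("a sample lost all taxa to zero inflation; lower it")
    values = values / col_sums
    lineages = [_lineage(i, config.lineage_depth) for i in range(config.n_taxa)]
    frame = pd.DataFrame(
        values, index=pd.Index(lineages, name="lineage"), columns=sample_ids
    )
    classes = pd.Series(
        ["DL"] * n + ["HC"] * n, index=sample_ids, name="class"
    )
    return TaxonTable(frame, classes)


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Configuration of per-animal behavior durations.

    ``couplings`` entries are ``(behavior, feature_id, strength)`` with
    strength in [-1, 1]: the behavior's ranks are a |strength|-weighted
    blend of the feature's ranks (reversed for negative strength) and
    independent noise ranks, so the target Spearman sign and rough
    magnitude are interpretable.
    """

    behaviors: tuple[str, ...] = BEHAVIORS
    couplings: tuple[tuple[str, str, float], ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for beh, _, strength in self.couplings:
            if beh not in self.behaviors:
                raise ConfigError(f"coupling names unknown behavior {beh!r}")
            if abs(strength) > 1:
                raise ConfigError(f"|strength| must be <= 1, got {strength}")
        seen = [b for b, _, _ in self.couplings]
        dup = {b for b in seen if seen.count(b) > 1}
        if dup:
            raise ConfigError(f"behavior(s) coupled more than once: {sorted(dup)}")


def generate_behaviors(
    config: BehaviorSimConfig, features: FeatureTable
) -> pd.DataFrame:
    """Per-animal behavior durations (seconds), rank-coupled to features.

    Returns an animals x behaviors DataFrame of nonnegative durations.
    Unknown coupled feature ids raise :class:`ConfigError` listing them.
    """
    from scipy.stats import rankdata

    config.validate()
    missing = [
        fid for _, fid, _ in config.couplings if fid not in features.features
    ]
    if missing:
        raise ConfigError(f"coupled feature id(s) not in table: {missing}")
    rng = np.random.default_rng(config.seed)
    animals = features.values.columns
    n = len(animals)
    coupled = {beh: (fid, s) for beh, fid, s in config.couplings}
    out = {}
    for beh in config.behaviors:
        if beh in coupled:
            fid, s = coupled[beh]
            r = rankdata(features.values.loc[fid].to_numpy(float))
            if s < 0:
                r = n + 1 - r
            w = abs(s)
            noise_r = rankdata(rng.normal(size=n))
            score = w * r + (1 - w) * noise_r
            dur = 10.0 * score
        else:
            dur = rng.gamma(4.0, 15.0, n)
        if config.noise_sd > 0:
            dur = dur + rng.normal(0, config.noise_sd, n)
        out[beh] = np.maximum(dur, 0.0)
    return pd.DataFrame(out, index=animals)


def null_reaction_abundances(
    rng: np.random.Generator,
    n_per_group: int = 6,
    base_log_mean: float = 10.0,
    base_log_sd: float = 0.25,
) -> tuple[pd.DataFrame, pd.Series]:
    """Substrate/product class abundances with no group effect.

    Both classes and both groups are drawn from one lognormal process —
    the null of the reaction-activity test. Returns a 2 x (2n) abundance
    matrix (rows ``A`` substrate, ``B`` product) and the group labels.
    """
    samples = _sample_index(n_per_group)
    values = np.exp(
        rng.normal(base_log_mean, base_log_sd, (2, 2 * n_per_group))
    )
    abundance = pd.DataFrame(values, index=["A", "B"], columns=samples)
    groups = pd.Series(
        ["DL"] * n_per_group + ["HC"] * n_per_group, index=samples, name="group"
    )
    return abundance, groups
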