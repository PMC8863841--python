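"""Plain-text TSV readers and writers for every pipeline interface.

Conventions: lipid feature TSVs carry columns ``name, Rej, PQ, CV, ppm``
followed by one column per sample; a sidecar sample map TSV carries
``sample, group, tissue``. Taxon TSVs carry ``lineage`` plus sample
columns. Leading ``#`` lines are comments (the generators record their
seed there) and are ignored on read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .tables import FeatureTable, QCTable, TaxonTable

__all__ = [
    "write_feature_tsv", "read_feature_tsv",
    "write_sample_map", "read_sample_map",
    "write_taxon_tsv", "read_taxon_tsv",
    "write_behavior_tsv", "read_behavior_tsv",
    "read_reaction_tsv",
]

_QC_COLS = {"rej": "Rej", "pq": "PQ", "cv": "CV", "ppm_dev": "ppm"}


def _write_with_header(frame: pd.DataFrame, path, header_lines: list[str]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_feature_tsv(
    table: FeatureTable, path, qc: QCTable | None = None, seed: int | None = None
) -> None:
    out = pd.DataFrame({"name": table.features})
    if qc is not None:
        qc = qc.aligned_to(table.features)
        for attr, col in _QC_COLS.items():
            out[col] = qc.fields[attr].to_numpy()
    out = pd.concat([out, table.values.reset_index(drop=True)], axis=1)
    header = [] if seed is None else [f"seed: {seed}"]
    if table.normalized:
        header.append("normalized: percent of total peak area")
    _write_with_header(out, path, header)


def read_feature_tsv(path, sample_map: pd.DataFrame) -> tuple[FeatureTable, QCTable | None]:
    """Read a feature TSV; QC columns are optional. ``sample_map`` is the
    frame from :func:`read_sample_map` restricted to this table's samples."""
    raw = pd.read_csv(path, sep="\t", comment="#")
    raw = raw.set_index("name")
    raw.index.name = "species"
    has_qc = all(c in raw.columns for c in _QC_COLS.values())
    qc = None
    if has_qc:
        qc = QCTable(
            pd.DataFrame(
                {attr: raw[col] for attr, col in _QC_COLS.items()}, index=raw.index
            )
        )
        raw = raw.drop(columns=list(_QC_COLS.values()))
    normalized = False
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "normalized" in line:
                normalized = True
    samples = sample_map.loc[raw.columns]
    return FeatureTable(raw, samples, normalized=normalized), qc


def write_sample_map(samples: pd.DataFrame, path) -> None:
    samples.rename_axis("sample").reset_index().to_csv(path, sep="\t", index=False)


def read_sample_map(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return frame.set_index("sample")


def write_taxon_tsv(table: TaxonTable, path, seed: int | None = None) -> None:
    out = table.values.rename_axis("lineage").reset_index()
    _write_with_header(out, path, [] if seed is None else [f"seed: {seed}"])


def read_taxon_tsv(path, sample_map: pd.DataFrame) -> TaxonTable:
    raw = pd.read_csv(path, sep="\t", comment="#").set_index("lineage")
    classes = sample_map.loc[raw.columns, "group"].rename("class")
    return TaxonTable(raw, classes)


def write_behavior_tsv(behaviors: pd.DataFrame, path, seed: int | None = None) -> None:
    out = behaviors.rename_axis("sample").reset_index()
    _write_with_header(out, path, [] if seed is None else [f"seed: {seed}"])


def read_behavior_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#").set_index("sample")


def read_reaction_tsv(path) -> pd.DataFrame:
    """Read a reaction table: columns pathway_id, step_index, substrate, product."""
    return pd.read_csv(path, sep="\t", comment="#")
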