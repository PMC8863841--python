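"""Quality-control filtering and total-area normalization of lipid tables.

MS lipid features arrive with per-feature QC fields; a feature is kept only
if the reject flag is 0, peak quality exceeds 0.85, the coefficient of
variation across pooled-QC injections is below 0.3, and the mass deviation
is within 5 ppm. Retained peak areas are then normalized per sample to
percent of the total peak area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .tables import FeatureTable, QCTable

__all__ = [
    "QCThresholds",
    "apply_qc_filters",
    "normalize_total_area",
    "concat_modes",
    "NormalizationError",
]

log = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class QCThresholds:
    """Retention criteria. A feature is retained iff
    ``rej == rej_eq AND pq > pq_gt AND cv < cv_lt AND ppm_dev <= ppm_le``.

    Peak quality and CV bounds are strict inequalities; the ppm mass
    tolerance is inclusive.
    """

    rej_eq: int = 0
    pq_gt: float = 0.85
    cv_lt: float = 0.3
    ppm_le: float = 5.0


def apply_qc_filters(
    table: FeatureTable,
    qc: QCTable,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[FeatureTable, pd.DataFrame]:
    """Retain features passing all four QC criteria, preserving order.

    Returns the filtered table plus a per-criterion rejection report
    (one row per criterion with the number of features it rejects; a
    feature failing several criteria counts under each).

    Raises
    ------
    AlignmentError
        If the QC rows do not align 1:1 with the feature table rows.
    ValueError
        If the table is already normalized (filtering must precede
        normalization so percentages stay consistent).
    """
    if table.normalized:
        raise ValueError("apply QC filters before normalization")
    qc = qc.aligned_to(table.features)
    f = qc.fields
    crit = pd.DataFrame(
        {
            "rej": f["rej"] == thresholds.rej_eq,
            "pq": f["pq"] > thresholds.pq_gt,
            "cv": f["cv"] < thresholds.cv_lt,
            "ppm_dev": f["ppm_dev"] <= thresholds.ppm_le,
        },
        index=table.features,
    )
    keep = crit.all(axis=1)
    report = pd.DataFrame(
        {
            "criterion": crit.columns,
            "removed": [int((~crit[c]).sum()) for c in crit.columns],
        }
    )
    report.loc[len(report)] = ["any", int((~keep).sum())]
    for _, row in report.iterrows():
        log.info("QC criterion %-8s removed %d features", row["criterion"], row["removed"])
    filtered = table.with_values(table.values.loc[keep.to_numpy()])
    return filtered, report


def normalize_total_area(table: FeatureTable) -> FeatureTable:
    """Scale each sample column to percent of its total peak area.

    Every value becomes ``100 * value / column_sum``, so columns sum to
    100. Raises :class:`NormalizationError` on an already-normalized table
    (double-normalization guard) or a zero-sum sample (named in the
    message).
    """
    if table.normalized:
        raise NormalizationError("table is already normalized")
    sums = table.values.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise NormalizationError(
            f"zero total peak area in sample(s): {', '.join(map(str, zero.index))}"
        )
    values = 100.0 * table.values / sums
    return table.with_values(values, normalized=True)


def concat_modes(
    tables: dict[str, FeatureTable],
) -> tuple[FeatureTable, pd.DataFrame]:
    """Concatenate independently QC-filtered ionization-mode tables.

    Species named in more than one mode are resolved by keeping the copy
    with the higher mean abundance; the returned report lists every
    dropped duplicate (species, kept mode, dropped mode).
    """
    if not tables:
        raise ValueError("no mode tables given")
    items = list(tables.items())
    ref = items[0][1]
    for _, t in items[1:]:
        if not t.values.columns.equals(ref.values.columns):
            raise ValueError("mode tables must share the same samples")
        if t.normalized or ref.normalized:
            raise ValueError("concatenate raw mode tables, then normalize the union")
    best: dict[str, tuple[float, str, pd.Series]] = {}
    order: list[str] = []
    dropped = []
    for mode, t in items:
        for name, row in t.values.iterrows():
            mean = float(row.mean())
            if name not in best:
                best[name] = (mean, mode, row)
                order.append(name)
            elif mean > best[name][0]:
                dropped.append((name, mode, best[name][1]))
                best[name] = (mean, mode, row)
            else:
                dropped.append((name, best[name][1], mode))
    values = pd.DataFrame(
        {name: best[name][2] for name in order}
    ).T
    values.columns = ref.values.columns
    report = pd.DataFrame(dropped, columns=["species", "kept_mode", "dropped_mode"])
    for _, r in report.iterrows():
        log.info("duplicate species %s: kept %s mode", r["species"], r["kept_mode"])
    return ref.with_values(values), report
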