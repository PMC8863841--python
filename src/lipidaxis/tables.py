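"""In-memory containers shared across pipeline stages.

Feature matrices are plain pandas DataFrames (features as rows, samples as
columns) wrapped with just enough metadata — group and tissue labels per
sample, a ``normalized`` flag — to let each stage validate its contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "QCTable", "TaxonTable", "AlignmentError"]

GROUPS = ("DL", "HC")

#: Column-sum tolerance for a percent-normalized table.
NORMALIZED_ATOL = 1e-6


class AlignmentError(ValueError):
    """Raised when row/column metadata does not line up with a matrix."""


@dataclass
class FeatureTable:
    """Nonnegative feature x sample abundance matrix with sample labels.

    Parameters
    ----------
    values:
        DataFrame, rows = feature ids (lipid species names), columns =
        sample ids. Peak areas before normalization, percent of total
        peak area after.
    samples:
        DataFrame indexed by sample id with columns ``group`` (DL/HC)
        and ``tissue``.
    normalized:
        True once columns have been scaled to sum to 100.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if not self.values.columns.equals(pd.Index(self.samples.index)):
            raise AlignmentError(
                "sample columns of `values` do not match `samples` index"
            )
        if "group" not in self.samples.columns:
            raise AlignmentError("`samples` needs a 'group' column")
        bad = set(self.samples["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        arr = self.values.to_numpy()
        if arr.size and np.nanmin(arr) < 0:
            raise ValueError("feature table contains negative values")
        if self.normalized:
            sums = arr.sum(axis=0)
            if not np.allclose(sums, 100.0, atol=NORMALIZED_ATOL):
                raise ValueError(
                    "normalized table columns must sum to 100 "
                    f"(got range {sums.min():.6g}..{sums.max():.6g})"
                )

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def groups(self) -> pd.Series:
        """Sample id -> DL/HC label."""
        return self.samples["group"]

    def group_columns(self, group: str) -> list[str]:
        return list(self.samples.index[self.samples["group"] == group])

    def with_values(self, values: pd.DataFrame, *, normalized: bool | None = None) -> "FeatureTable":
        return FeatureTable(
            values,
            self.samples,
            self.normalized if normalized is None else normalized,
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.samples.copy(), self.normalized)


@dataclass
class QCTable:
    """Per-feature quality-control fields from a LipidSearch-style export.

    Columns: ``rej`` (integer reject flag), ``pq`` (peak quality in [0,1]),
    ``cv`` (coefficient of variation across pooled-QC injections) and
    ``ppm_dev`` (absolute mass deviation, ppm). Rows align 1:1 with the
    feature table.
    """

    fields: pd.DataFrame

    REQUIRED = ("rej", "pq", "cv", "ppm_dev")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.fields.columns]
        if missing:
            raise AlignmentError(f"QC table missing columns: {missing}")

    def aligned_to(self, features: pd.Index) -> "QCTable":
        if len(self.fields) != len(features) or not self.fields.index.equals(features):
            raise AlignmentError("QC rows do not align with feature table rows")
        return self


@dataclass
class TaxonTable:
    """Relative-abundance taxon x sample matrix with two-class labels.

    Rows are rank-prefixed lineage strings (``p__...;s__...``); values are
    relative abundances in [0, 1] with sample columns summing to <= 1.
    """

    values: pd.DataFrame
    classes: pd.Series = field(default_factory=pd.Series)

    def __post_init__(self) -> None:
        if not self.values.columns.equals(pd.Index(self.classes.index)):
            raise AlignmentError("sample columns do not match class labels")
        arr = self.values.to_numpy()
        if arr.size:
            if arr.min() < 0 or arr.max() > 1 + 1e-9:
                raise ValueError("taxon abundances must lie in [0, 1]")
            if (arr.sum(axis=0) > 1 + 1e-9).any():
                raise ValueError("taxon table columns must sum to <= 1")

    @property
    def taxa(self) -> pd.Index:
        return self.values.index
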