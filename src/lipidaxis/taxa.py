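"""Two-class LEfSe-style differential abundance of taxa.

Stage 1 screens each taxon with a Kruskal-Wallis rank test at alpha = 0.05
(with exactly two classes this reduces to a Wilcoxon rank-sum test).
Stage 2 estimates an effect size for the survivors: abundances are put on
the canonical LEfSe scale (relative abundances scaled to one million,
floored at 1), and over bootstrap rounds a two-class linear discriminant
is fitted to 2/3 class subsamples; each taxon's per-round effect size is
the average of its raw class-mean difference and its share of the
class-mean separation along the discriminant direction. The reported LDA
score is log10 of the bootstrap-averaged effect size, and a taxon passes
when the screen P < 0.05 and the LDA score exceeds the threshold
(2.0 by default; 2.5 selectable).

The canonical all-against-all subclass Wilcoxon stage is omitted: with
exactly two classes and no subclass factor it is vacuous.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .tables import TaxonTable

__all__ = ["RANKS", "parse_lineage", "LineageError", "lefse_two_class"]

log = logging.getLogger(__name__)

#: Recognized rank prefixes in lineage order ('d' and 'k' both denote the
#: top rank, as NCBI and GTDB dialects differ).
RANKS: tuple[tuple[str, str], ...] = (
    ("d", "domain"), ("k", "kingdom"), ("p", "phylum"), ("c", "class"),
    ("o", "order"), ("f", "family"), ("g", "genus"), ("s", "species"),
)
_RANK_ORDER = {prefix: i for i, (prefix, _) in enumerate(RANKS)}
_RANK_NAME = dict(RANKS)

#: LEfSe abundance scale: relative abundances are multiplied up to a
#: per-million scale and floored at 1 before the discriminant fit.
LEFSE_SCALE = 1e6


class LineageError(ValueError):
    """Raised on an unparseable rank-prefixed lineage string."""


def parse_lineage(text: str) -> dict[str, str]:
    """Parse ``"p__Firmicutes;c__Bacilli;...;s__X"`` into rank -> name.

    Missing trailing ranks are allowed; unknown prefixes, duplicate or
    out-of-order ranks, and empty strings raise :class:`LineageError`.
    """
    if not text or not text.strip():
        raise LineageError("empty lineage string")
    out: dict[str, str] = {}
    last = -1
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if len(chunk) < 3 or chunk[1:3] != "__":
            raise LineageError(f"missing rank prefix in segment {chunk!r}")
        prefix, name = chunk[0], chunk[3:]
        if prefix not in _RANK_ORDER:
            raise LineageError(f"unknown rank prefix {prefix!r} in {chunk!r}")
        rank = _RANK_NAME[prefix]
        if rank in out:
            raise LineageError(f"duplicate rank {rank!r} in {text!r}")
        if _RANK_ORDER[prefix] <= last:
            raise LineageError(f"out-of-order rank {rank!r} in {text!r}")
        last = _RANK_ORDER[prefix]
        out[rank] = name
    if not out:
        raise LineageError(f"no ranks found in {text!r}")
    return out


@dataclass(frozen=True)
class LefseRecord:
    taxon: str
    kw_p: float
    lda_score: float
    enriched_class: str
    passes: bool


def lefse_two_class(
    table: TaxonTable,
    threshold: float = 2.0,
    n_boot: int = 30,
    seed: int | None = None,
    *,
    alpha: float = 0.05,
    subsample_fraction: float = 2 / 3,
) -> pd.DataFrame:
    """LEfSe effect sizes for a two-class taxon table.

    Returns one row per taxon surviving the Kruskal-Wallis screen, sorted
    by signed LDA score (positive scores enriched in the first class by
    name order is *not* assumed — ``enriched_class`` carries the label).
    Bootstrap rounds with a degenerate subsample are skipped and logged.
    """
    classes = sorted(set(table.classes))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    # order classes by sample position, not label name, so a pure label
    # swap reuses the identical bootstrap stream and preserves scores
    c0 = table.classes.iloc[0]
    c1 = next(c for c in classes if c != c0)
    cols0 = table.classes.index[table.classes == c0]
    cols1 = table.classes.index[table.classes == c1]
    if len(cols0) < 3 or len(cols1) < 3:
        raise ValueError("need >= 3 samples per class")
    rng = np.random.default_rng(seed)

    # stage 1: rank-based screen
    survivors: list[str] = []
    kw_p: dict[str, float] = {}
    for taxon, row in table.values.iterrows():
        x0 = row[cols0].to_numpy(float)
        x1 = row[cols1].to_numpy(float)
        if np.all(x0 == x0[0]) and np.all(x1 == x1[0]) and x0[0] == x1[0]:
            p = 1.0
        else:
            _, p = stats.kruskal(x0, x1)
        kw_p[taxon] = float(p)
        if p < alpha:
            survivors.append(taxon)
    if not survivors:
        return pd.DataFrame(
            columns=["taxon", "kw_p", "lda_score", "enriched_class", "passes"]
        )

    # stage 2: bootstrapped linear-discriminant effect size on the LEfSe scale
    X = table.values.loc[survivors].T.to_numpy(float) * LEFSE_SCALE
    X = np.maximum(X, 1.0)
    y = (table.classes == c1).to_numpy(int)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    m0 = math.ceil(subsample_fraction * len(idx0))
    m1 = math.ceil(subsample_fraction * len(idx1))
    eff_sum = np.zeros(len(survivors))
    used = 0
    lda = LinearDiscriminantAnalysis(solver="svd", tol=1e-10)
    for _ in range(n_boot):
        sel = np.concatenate(
            [rng.choice(idx0, m0, replace=False), rng.choice(idx1, m1, replace=False)]
        )
        Xb, yb = X[sel], y[sel]
        if np.all(Xb.std(axis=0) == 0):
            log.warning("skipping degenerate LEfSe bootstrap round")
            continue
        try:
            lda.fit(Xb, yb)
        except Exception as err:  # singular within-class scatter etc.
            log.warning("skipping LEfSe bootstrap round: %s", err)
            continue
        w = lda.coef_[0]
        norm = np.linalg.norm(w)
        if norm == 0 or not np.isfinite(norm):
            log.warning("skipping LEfSe bootstrap round: null discriminant")
            continue
        wu = w / norm
        means = lda.means_  # class order follows lda.classes_ = [0, 1]
        ld_sep = abs(float((means[1] - means[0]) @ wu))
        eff = 0.5 * (np.abs(means[1] - means[0]) + np.abs(wu * ld_sep))
        eff_sum += eff
        used += 1
    if used == 0:
        raise RuntimeError("every LEfSe bootstrap round was degenerate")
    scores = np.log10(1.0 + eff_sum / used)

    mean_diff = (
        table.values.loc[survivors, cols1].mean(axis=1)
        - table.values.loc[survivors, cols0].mean(axis=1)
    )
    rows = []
    for i, taxon in enumerate(survivors):
        enriched = c1 if mean_diff[taxon] > 0 else c0
        rows.append(
            {
                "taxon": taxon,
                "kw_p": kw_p[taxon],
                "lda_score": float(scores[i]),
                "enriched_class": enriched,
                "passes": bool(kw_p[taxon] < alpha and scores[i] > threshold),
            }
        )
    out = pd.DataFrame(rows)
    sign = np.where(out["enriched_class"] == c1, 1.0, -1.0)
    out = out.assign(_signed=sign * out["lda_score"]).sort_values(
        "_signed", ascending=False, ignore_index=True
    ).drop(columns="_signed")
    return out
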