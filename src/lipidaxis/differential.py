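"""Differential lipid analysis between DL and HC groups.

Three levels of resolution:

* subclass — summed normalized abundance per subclass, fold change
  (DL mean / HC mean) and an unpaired two-sided Student t test;
* structure — abundance profiles along total carbon-chain length or total
  unsaturation within one subclass, with per-bin t tests;
* species — PLS-DA on the full species matrix with the standard VIP
  (variable importance in projection) statistic, and the double cutoff
  VIP > 1.0 and univariate t-test P < 0.05 for discriminating species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .nomenclature import LipidAnnotation, parse_lipid_name
from .tables import FeatureTable

__all__ = [
    "subclass_abundance",
    "subclass_test",
    "structure_profile",
    "PlsdaModel",
    "plsda_fit",
    "discriminating_species",
    "two_sample_t",
]

log = logging.getLogger(__name__)


def _annotation_map(
    features: pd.Index,
    annotations: Mapping[str, LipidAnnotation] | None,
    on_unparseable: str,
) -> dict[str, LipidAnnotation]:
    """Resolve an annotation per feature, parsing names when not supplied."""
    out: dict[str, LipidAnnotation] = {}
    for name in features:
        ann = annotations.get(name) if annotations is not None else None
        if ann is None:
            try:
                ann = parse_lipid_name(name)
            except ValueError:
                if on_unparseable == "skip":
                    log.warning("skipping unparseable feature %r", name)
                    continue
                raise
        out[name] = ann
    return out


def subclass_abundance(
    table: FeatureTable,
    annotations: Mapping[str, LipidAnnotation] | None = None,
    on_unparseable: str = "error",
) -> pd.DataFrame:
    """Sum normalized abundances per subclass: subclass x sample matrix.

    When the subclasses partition the feature set, columns conserve the
    per-sample total (100 for a normalized table).
    """
    if on_unparseable not in ("error", "skip"):
        raise ValueError("on_unparseable must be 'error' or 'skip'")
    anns = _annotation_map(table.features, annotations, on_unparseable)
    labels = pd.Series({n: a.subclass for n, a in anns.items()})
    sub = table.values.loc[labels.index]
    out = sub.groupby(labels).sum()
    out.index.name = "subclass"
    return out


def two_sample_t(
    x: np.ndarray, y: np.ndarray, *, welch: bool = False, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Unpaired t test (Student pooled-variance by default, Welch by flag).

    Returns ``(t, p)``. Identical degenerate groups (zero variance, equal
    means) yield ``(0, 1)`` for a two-sided test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, p = stats.ttest_ind(x, y, equal_var=not welch, alternative=alternative)
    if np.isnan(t):
        # zero variance in both groups
        if np.isclose(x.mean(), y.mean()):
            return 0.0, 1.0 if alternative == "two-sided" else 0.5
        t = np.inf if x.mean() > y.mean() else -np.inf
        if alternative == "two-sided":
            p = 0.0
        elif alternative == "greater":
            p = 0.0 if t > 0 else 1.0
        else:
            p = 0.0 if t < 0 else 1.0
    return float(t), float(p)


@dataclass(frozen=True)
class SubclassResult:
    tissue: str
    subclass: str
    fold_change: float
    p_value: float
    n_species: int


def subclass_test(
    matrix: pd.DataFrame,
    groups: pd.Series,
    *,
    tissue: str = "",
    n_species: Mapping[str, int] | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-subclass fold change (DL mean / HC mean) and two-sided t test.

    ``matrix`` is the subclass x sample output of
    :func:`subclass_abundance`; ``groups`` maps sample id -> DL/HC.
    A zero HC mean leaves the fold change NaN and sets ``flagged``.
    """
    dl_cols = groups.index[groups == "DL"]
    hc_cols = groups.index[groups == "HC"]
    if len(dl_cols) < 2 or len(hc_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    rows = []
    for subclass, row in matrix.iterrows():
        dl = row[dl_cols].to_numpy(float)
        hc = row[hc_cols].to_numpy(float)
        hc_mean = hc.mean()
        fc = np.nan if hc_mean == 0 else dl.mean() / hc_mean
        _, p = two_sample_t(dl, hc, welch=welch)
        rows.append(
            {
                "tissue": tissue,
                "subclass": subclass,
                "fold_change": fc,
                "p_value": p,
                "n_species": int(n_species.get(subclass, 0)) if n_species else 0,
                "flagged": hc_mean == 0,
            }
        )
    return pd.DataFrame(rows)


def structure_profile(
    table: FeatureTable,
    annotations: Mapping[str, LipidAnnotation] | None,
    subclass: str,
    axis: str,
    groups: pd.Series | None = None,
    *,
    tissue: str = "",
    welch: bool = False,
) -> pd.DataFrame:
    """Abundance profile of one subclass along a structural axis.

    ``axis`` is ``total_carbons`` or ``double_bonds``. Species are summed
    within each observed bin of the axis and each bin is compared between
    groups with a two-sided t test. An empty subclass yields an empty
    profile (with a warning).
    """
    if axis not in ("total_carbons", "double_bonds"):
        raise ValueError("axis must be 'total_carbons' or 'double_bonds'")
    anns = _annotation_map(table.features, annotations, "error")
    members = {
        n: a for n, a in anns.items() if a.subclass == subclass
    }
    if not members:
        log.warning("no species of subclass %s in table", subclass)
        return pd.DataFrame(
            columns=["tissue", "subclass", "axis", "bin", "dl_mean", "hc_mean", "p_value"]
        )
    key = {
        n: (a.total_carbons if axis == "total_carbons" else a.total_double_bonds)
        for n, a in members.items()
    }
    labels = pd.Series(key)
    binned = table.values.loc[labels.index].groupby(labels).sum()
    if groups is None:
        groups = table.groups
    dl_cols = groups.index[groups == "DL"]
    hc_cols = groups.index[groups == "HC"]
    rows = []
    for b, row in binned.iterrows():
        dl = row[dl_cols].to_numpy(float)
        hc = row[hc_cols].to_numpy(float)
        _, p = two_sample_t(dl, hc, welch=welch)
        rows.append(
            {
                "tissue": tissue,
                "subclass": subclass,
                "axis": axis,
                "bin": int(b),
                "dl_mean": dl.mean(),
                "hc_mean": hc.mean(),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).sort_values("bin", ignore_index=True)


@dataclass
class PlsdaModel:
    """Fitted two-class PLS-DA model with VIP scores.

    Data are mean-centered and unit-variance scaled before fitting; the
    class response is a 0/1 dummy. ``vip`` follows the standard definition
    across all fitted components and satisfies mean(VIP^2) = 1.
    """

    n_components: int
    features: pd.Index
    scores: pd.DataFrame
    weights: pd.DataFrame
    loadings: pd.DataFrame
    explained_y_variance: np.ndarray
    vip: pd.Series
    dropped_features: list[str] = field(default_factory=list)


def plsda_fit(
    table: FeatureTable,
    groups: pd.Series | None = None,
    n_components: int = 2,
) -> PlsdaModel:
    """Fit PLS-DA (NIPALS PLS1 on a 0/1 class dummy) and compute VIP.

    Constant feature columns cannot be unit-variance scaled and are
    dropped with a log message before fitting.
    """
    if groups is None:
        groups = table.groups
    X = table.values.T  # samples x features
    y = (groups.loc[X.index] == "DL").to_numpy(float)
    if len(np.unique(y)) != 2:
        raise ValueError("need both DL and HC samples")
    sd = X.std(axis=0, ddof=1)
    dropped = list(X.columns[sd == 0])
    if dropped:
        log.info("dropping %d constant feature(s) before PLS-DA", len(dropped))
        X = X.loc[:, sd > 0]
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples-1, features)={min(n - 1, p)}"
        )
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(X.to_numpy(), y)
    W = pls.x_weights_       # p x A, unit-norm columns
    T = pls.x_scores_        # n x A
    Q = pls.y_loadings_      # 1 x A
    ssy = (Q[0] ** 2) * np.einsum("ij,ij->j", T, T)  # response SS per component
    vip = np.sqrt(p * (W ** 2 @ (ssy / ssy.sum())))
    return PlsdaModel(
        n_components=n_components,
        features=X.columns,
        scores=pd.DataFrame(T, index=X.index, columns=[f"t{a+1}" for a in range(n_components)]),
        weights=pd.DataFrame(W, index=X.columns, columns=[f"w{a+1}" for a in range(n_components)]),
        loadings=pd.DataFrame(
            pls.x_loadings_, index=X.columns, columns=[f"p{a+1}" for a in range(n_components)]
        ),
        explained_y_variance=ssy / ssy.sum(),
        vip=pd.Series(vip, index=X.columns, name="vip"),
        dropped_features=dropped,
    )


def discriminating_species(
    table: FeatureTable,
    groups: pd.Series | None = None,
    model: PlsdaModel | None = None,
    *,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Species passing the double cutoff VIP > 1.0 and t-test P < 0.05.

    Direction is ``up_in_DL``/``down_in_DL`` by the sign of the DL-HC mean
    difference. Returns a DataFrame sorted by descending VIP.
    """
    if groups is None:
        groups = table.groups
    if model is None:
        model = plsda_fit(table, groups)
    dl_cols = groups.index[groups == "DL"]
    hc_cols = groups.index[groups == "HC"]
    rows = []
    for name in model.features:
        vip = float(model.vip[name])
        if vip <= vip_threshold:
            continue
        dl = table.values.loc[name, dl_cols].to_numpy(float)
        hc = table.values.loc[name, hc_cols].to_numpy(float)
        _, p = two_sample_t(dl, hc, welch=welch)
        if p >= alpha:
            continue
        rows.append(
            {
                "species": name,
                "vip": vip,
                "p_value": p,
                "direction": "up_in_DL" if dl.mean() > hc.mean() else "down_in_DL",
            }
        )
    return (
        pd.DataFrame(rows, columns=["species", "vip", "p_value", "direction"])
        .sort_values("vip", ascending=False, ignore_index=True)
    )
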