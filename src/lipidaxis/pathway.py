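"""Lipid reaction-network activity scoring.

A lipid pathway is an ordered chain of subclasses A_1 -> A_2 -> ... -> A_k;
each edge is a class-level transformation. Per sample, the reaction weight
of an edge is the product/substrate abundance ratio
``omega_i = A_{i+1} / A_i``. For each edge a one-sided Student t test
compares DL against HC weights (direction DL > HC) and the one-sided P is
mapped through the inverse standard-normal CDF, ``Z_i = Phi^{-1}(1 - P)``.
Because P > 0.5 yields a negative Z, reactions more active in HC come out
negative without a second test — the sign convention is built in. A
reaction is called active when Z_i exceeds the critical value
Phi^{-1}(0.95) ~ 1.645 and inactive below its negative.

Pathway-level activity sums the edge scores with a 1/sqrt(k-1) scaling::

    Z_A = (1 / sqrt(k - 1)) * sum_i Z_i

which is standard normal under the null of independent null edges, so the
same +/-1.645 cutoff applies. Class-level synthesis (incoming edges) and
degradation (outgoing edges) scores use the same aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .differential import subclass_abundance, two_sample_t
from .nomenclature import LipidAnnotation
from .tables import FeatureTable

__all__ = [
    "ReactionNetwork",
    "ReactionWeight",
    "ReactionActivity",
    "PathwayActivity",
    "DEFAULT_PATHWAYS",
    "critical_z",
    "class_abundance",
    "reaction_weights",
    "reaction_z",
    "pathway_z",
    "synthesis_degradation",
    "evaluate_network",
]

log = logging.getLogger(__name__)

#: Default pathway chains (substrate -> product read left to right) for the
#: DG-centred glycerophospholipid network.
DEFAULT_PATHWAYS: dict[str, tuple[str, ...]] = {
    "LPC-PC-PA-DG-TG": ("LPC", "PC", "PA", "DG", "TG"),
    "LPC-PC-PA-LPA": ("LPC", "PC", "PA", "LPA"),
    "LPC-LPA": ("LPC", "LPA"),
    "DG-PC-LPC": ("DG", "PC", "LPC"),
    "DG-PA-PI-LPI": ("DG", "PA", "PI", "LPI"),
    "LPA-PA-PG-LPG": ("LPA", "PA", "PG", "LPG"),
}

#: Z magnitudes are clipped so degenerate P values (0 or 1) stay finite.
_P_FLOOR = 1e-16


def critical_z(alpha: float = 0.05) -> float:
    """One-sided critical value ``Phi^{-1}(1 - alpha)`` (1.645 at 0.05)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(norm.isf(alpha))


@dataclass(frozen=True)
class ReactionNetwork:
    """Directed lipid-class graph induced by named pathway chains."""

    pathways: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for name, chain in self.pathways.items():
            if len(chain) < 2:
                raise ValueError(f"pathway {name!r} needs >= 2 nodes")
            for a, b in zip(chain, chain[1:]):
                if a == b:
                    raise ValueError(f"self-loop {a}->{b} in pathway {name!r}")

    @classmethod
    def default(cls) -> "ReactionNetwork":
        return cls(dict(DEFAULT_PATHWAYS))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReactionNetwork":
        """Build from a table with columns pathway_id, step_index, substrate, product."""
        required = {"pathway_id", "step_index", "substrate", "product"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"reaction table missing columns: {sorted(missing)}")
        pathways: dict[str, tuple[str, ...]] = {}
        for pid, grp in frame.groupby("pathway_id", sort=False):
            grp = grp.sort_values("step_index")
            chain = [grp.iloc[0]["substrate"]]
            for _, row in grp.iterrows():
                if row["substrate"] != chain[-1]:
                    raise ValueError(
                        f"pathway {pid!r}: step {row['step_index']} substrate "
                        f"{row['substrate']!r} does not chain onto {chain[-1]!r}"
                    )
                chain.append(row["product"])
            pathways[str(pid)] = tuple(chain)
        return cls(pathways)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Unique directed edges in first-appearance order."""
        seen: dict[tuple[str, str], None] = {}
        for chain in self.pathways.values():
            for e in zip(chain, chain[1:]):
                seen.setdefault(e, None)
        return list(seen)

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for chain in self.pathways.values():
            for n in chain:
                seen.setdefault(n, None)
        return list(seen)

    def pathway_edges(self, name: str) -> list[tuple[str, str]]:
        chain = self.pathways[name]
        return list(zip(chain, chain[1:]))

    def incoming(self, node: str) -> list[tuple[str, str]]:
        return [e for e in self.edges if e[1] == node]

    def outgoing(self, node: str) -> list[tuple[str, str]]:
        return [e for e in self.edges if e[0] == node]


@dataclass(frozen=True)
class ReactionWeight:
    """Per-sample product/substrate abundance ratio for one edge."""

    edge: tuple[str, str]
    omega: pd.Series  # indexed by sample id, strictly positive

    @property
    def samples(self) -> pd.Index:
        return self.omega.index


@dataclass(frozen=True)
class ReactionActivity:
    edge: tuple[str, str]
    t_statistic: float
    one_sided_p: float
    z: float
    verdict: str  # active | inactive | ns


@dataclass(frozen=True)
class PathwayActivity:
    name: str
    k: int
    z_a: float
    verdict: str


def class_abundance(
    table: FeatureTable,
    annotations: Mapping[str, LipidAnnotation] | None = None,
    on_unparseable: str = "error",
) -> pd.DataFrame:
    """Class-level per-sample abundance A_i: sum of the class's species.

    Thin alias of :func:`lipidaxis.differential.subclass_abundance`; the
    pathway machinery consumes its rows as the A_i vectors.
    """
    return subclass_abundance(table, annotations, on_unparseable)


def reaction_weights(
    abundance: pd.DataFrame,
    edge: tuple[str, str],
    zero_policy: str = "drop",
) -> ReactionWeight:
    """Elementwise omega = A_product / A_substrate across samples.

    Samples with zero substrate abundance are dropped with a warning
    under the default policy, or raise under ``zero_policy='fail'``.
    Classes absent from the matrix raise ``KeyError``.
    """
    substrate, product = edge
    for cls in edge:
        if cls not in abundance.index:
            raise KeyError(f"class {cls!r} absent from abundance matrix")
    a = abundance.loc[substrate]
    b = abundance.loc[product]
    zero = a[a <= 0].index
    if len(zero):
        if zero_policy == "fail":
            raise ValueError(
                f"zero substrate abundance for edge {substrate}->{product} "
                f"in sample(s): {', '.join(map(str, zero))}"
            )
        log.warning(
            "edge %s->%s: dropping %d zero-substrate sample(s)",
            substrate, product, len(zero),
        )
        keep = a.index.difference(zero, sort=False)
        a, b = a[keep], b[keep]
    return ReactionWeight(edge, (b / a).rename(f"{substrate}->{product}"))


def reaction_z(
    w_dl: ReactionWeight | pd.Series | np.ndarray,
    w_hc: ReactionWeight | pd.Series | np.ndarray,
    *,
    alpha: float = 0.05,
    welch: bool = False,
    log_weights: bool = False,
    edge: tuple[str, str] | None = None,
) -> ReactionActivity:
    """One-sided t test on reaction weights and conversion to a Z score.

    The test is computed once in the DL > HC direction giving P+; then
    ``Z = Phi^{-1}(1 - P+)``. Reactions more active in HC have P+ > 0.5
    and therefore a negative Z, so a single formula carries the sign
    convention. Verdict: active if Z > Phi^{-1}(1 - alpha), inactive if
    Z < -Phi^{-1}(1 - alpha), else ns.

    ``log_weights`` tests log(omega) instead of raw omega (ratios are
    right-skewed; off by default).
    """
    def _vals(w):
        if isinstance(w, ReactionWeight):
            return np.asarray(w.omega, dtype=float)
        return np.asarray(w, dtype=float)

    dl, hc = _vals(w_dl), _vals(w_hc)
    if len(dl) < 2 or len(hc) < 2:
        raise ValueError("need >= 2 weights per group")
    if log_weights:
        dl, hc = np.log(dl), np.log(hc)
    if edge is None and isinstance(w_dl, ReactionWeight):
        edge = w_dl.edge
    t, p_plus = two_sample_t(dl, hc, welch=welch, alternative="greater")
    z = float(norm.isf(np.clip(p_plus, _P_FLOOR, 1 - 1e-16)))
    crit = critical_z(alpha)
    verdict = "active" if z > crit else "inactive" if z < -crit else "ns"
    return ReactionActivity(edge or ("?", "?"), t, float(p_plus), z, verdict)


def pathway_z(
    activities: Sequence[ReactionActivity],
    k: int | None = None,
    *,
    name: str = "",
    alpha: float = 0.05,
    allow_partial: bool = False,
) -> PathwayActivity:
    """Aggregate edge Z scores: ``Z_A = sum(Z_i) / sqrt(k - 1)``.

    ``k`` is the pathway node count; exactly ``k - 1`` activities are
    expected. When edges were skipped upstream, pass ``allow_partial=True``
    to renormalize by the available edge count (logged); otherwise a
    mismatch raises.
    """
    if not activities:
        raise ValueError(f"pathway {name!r}: no reaction activities")
    m = len(activities)
    if k is None:
        k = m + 1
    if m != k - 1:
        if not allow_partial:
            raise ValueError(
                f"pathway {name!r}: expected {k - 1} edge activities, got {m}"
            )
        log.warning(
            "pathway %r: renormalizing Z_A over %d of %d edges", name, m, k - 1
        )
    z_a = float(sum(a.z for a in activities) / np.sqrt(m))
    crit = critical_z(alpha)
    verdict = "active" if z_a > crit else "inactive" if z_a < -crit else "ns"
    return PathwayActivity(name, k, z_a, verdict)


def synthesis_degradation(
    network: ReactionNetwork,
    activities: Mapping[tuple[str, str], ReactionActivity],
    target_class: str,
    *,
    alpha: float = 0.05,
) -> tuple[PathwayActivity, PathwayActivity]:
    """Class-level synthesis and degradation scores.

    Synthesis aggregates the Z scores of the target class's incoming
    edges, degradation its outgoing edges, each with the pathway formula
    (k - 1 = number of edges). A side with no edges raises.
    """
    results = []
    for label, edges in (
        ("synthesis", network.incoming(target_class)),
        ("degradation", network.outgoing(target_class)),
    ):
        acts = [activities[e] for e in edges if e in activities]
        if not acts:
            raise ValueError(f"{target_class}: no evaluable {label} edges")
        results.append(
            pathway_z(acts, name=f"{target_class}_{label}", alpha=alpha)
        )
    return results[0], results[1]


def evaluate_network(
    abundance: pd.DataFrame,
    groups: pd.Series,
    network: ReactionNetwork | None = None,
    *,
    alpha: float = 0.05,
    welch: bool = False,
    log_weights: bool = False,
    zero_policy: str = "drop",
) -> tuple[pd.DataFrame, pd.DataFrame, dict[tuple[str, str], ReactionActivity]]:
    """Score every edge and pathway of a network on a class matrix.

    Returns (reactions frame, pathways frame, edge -> activity map).
    Edges whose classes are missing from the matrix are skipped with a
    warning; pathways containing a skipped edge are renormalized over the
    evaluable edges and flagged ``partial``.
    """
    if network is None:
        network = ReactionNetwork.default()
    dl_cols = groups.index[groups == "DL"]
    hc_cols = groups.index[groups == "HC"]
    activities: dict[tuple[str, str], ReactionActivity] = {}
    rows = []
    for edge in network.edges:
        try:
            w = reaction_weights(abundance, edge, zero_policy=zero_policy)
        except KeyError as err:
            log.warning("skipping edge %s->%s: %s", edge[0], edge[1], err)
            continue
        act = reaction_z(
            w.omega[w.samples.intersection(dl_cols)],
            w.omega[w.samples.intersection(hc_cols)],
            alpha=alpha, welch=welch, log_weights=log_weights, edge=edge,
        )
        activities[edge] = act
        rows.append(
            {
                "substrate": edge[0],
                "product": edge[1],
                "t": act.t_statistic,
                "one_sided_p": act.one_sided_p,
                "z": act.z,
                "verdict": act.verdict,
            }
        )
    prows = []
    for name in network.pathways:
        edges = network.pathway_edges(name)
        acts = [activities[e] for e in edges if e in activities]
        k = len(network.pathways[name])
        if not acts:
            log.warning("pathway %r not evaluable: all edges skipped", name)
            continue
        pa = pathway_z(acts, k, name=name, alpha=alpha, allow_partial=True)
        prows.append(
            {
                "pathway": name,
                "k": k,
                "n_edges_used": len(acts),
                "z_a": pa.z_a,
                "verdict": pa.verdict,
                "partial": len(acts) < k - 1,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(prows), activities
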