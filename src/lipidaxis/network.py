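"""Thresholded Spearman co-occurrence network across omics blocks.

Nodes are differential taxa, selected lipid species, and behavioral
durations measured on the same animals. All pairwise Spearman rank
correlations (midranks for ties) are computed; an edge is retained when
P < alpha AND |rho| > rho_threshold (both strict per the thresholds'
wording). The retained graph is exported as GraphML plus a flat edge-list
TSV; layout and styling are left to external tools.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["NodeSet", "CorrelationGraph", "spearman_edges", "export_graph"]

log = logging.getLogger(__name__)

NODE_KINDS = ("bacterium", "virus", "lipid", "behavior")


@dataclass
class NodeSet:
    """Aligned per-animal measurements for a heterogeneous node collection.

    ``values``: samples x nodes DataFrame (all blocks share sample order);
    ``kinds``: node id -> one of bacterium / virus / lipid / behavior.
    """

    values: pd.DataFrame
    kinds: pd.Series

    def __post_init__(self) -> None:
        missing = self.values.columns.difference(self.kinds.index)
        if len(missing):
            raise ValueError(f"nodes without a kind: {list(missing)}")
        bad = set(self.kinds.loc[self.values.columns]) - set(NODE_KINDS)
        if bad:
            raise ValueError(f"unknown node kinds: {sorted(bad)}")

    @classmethod
    def from_blocks(cls, blocks: dict[str, pd.DataFrame]) -> "NodeSet":
        """Assemble from kind -> (samples x nodes) blocks, outer-validated
        to share identical sample ordering."""
        frames, kinds = [], {}
        ref_index = None
        for kind, frame in blocks.items():
            if kind not in NODE_KINDS:
                raise ValueError(f"unknown node kind {kind!r}")
            if ref_index is None:
                ref_index = frame.index
            elif not frame.index.equals(ref_index):
                raise ValueError(f"block {kind!r} samples differ from first block")
            frames.append(frame)
            kinds.update({c: kind for c in frame.columns})
        values = pd.concat(frames, axis=1)
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()]
            raise ValueError(f"duplicate node ids across blocks: {list(dup)}")
        return cls(values, pd.Series(kinds))


@dataclass
class CorrelationGraph:
    """All pairwise Spearman edges plus the retained thresholded subset."""

    nodes: pd.Series  # node id -> kind
    edges: pd.DataFrame  # columns: a, b, rho, p_value, retained
    rho_threshold: float
    alpha: float
    excluded_nodes: list[str] = field(default_factory=list)

    @property
    def retained(self) -> pd.DataFrame:
        return self.edges[self.edges["retained"]].reset_index(drop=True)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node, kind in self.nodes.items():
            g.add_node(node, kind=kind)
        for _, e in self.retained.iterrows():
            g.add_edge(e["a"], e["b"], rho=float(e["rho"]), p_value=float(e["p_value"]))
        return g


def _spearman_perm_p(x: np.ndarray, y: np.ndarray, rho: float,
                     n_resamples: int, rng: np.random.Generator) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    null = np.empty(n_resamples)
    for i in range(n_resamples):
        null[i] = np.corrcoef(rx, rng.permutation(ry))[0, 1]
    return float((np.sum(np.abs(null) >= abs(rho) - 1e-12) + 1) / (n_resamples + 1))


def spearman_edges(
    nodes: NodeSet,
    rho_threshold: float = 0.70,
    alpha: float = 0.05,
    *,
    p_method: str = "t-approx",
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> CorrelationGraph:
    """All pairwise Spearman correlations with double-threshold retention.

    Edges (undirected, canonical a < b order) are retained when
    ``p < alpha`` and ``|rho| > rho_threshold``. Constant node vectors
    have undefined rank correlation and are excluded with a warning.
    ``p_method='permutation'`` replaces the t-approximation P value with a
    seeded Monte-Carlo permutation P (useful at the small n of primate
    designs, where the t approximation is crude).
    """
    if p_method not in ("t-approx", "permutation"):
        raise ValueError("p_method must be 't-approx' or 'permutation'")
    values = nodes.values
    if len(values) < 5:
        raise ValueError("need >= 5 aligned samples")
    arr = values.to_numpy(float)
    constant = values.columns[arr.std(axis=0) == 0]
    if len(constant):
        log.warning(
            "excluding %d constant node(s): %s", len(constant), list(constant)
        )
        values = values.drop(columns=constant)
        arr = values.to_numpy(float)
    cols = list(values.columns)
    rng = np.random.default_rng(seed)

    if len(cols) >= 2:
        rho_mat, p_mat = stats.spearmanr(arr)
        if np.ndim(rho_mat) == 0:  # spearmanr collapses the 2-column case
            rho_mat = np.array([[1.0, rho_mat], [rho_mat, 1.0]])
            p_mat = np.array([[0.0, p_mat], [p_mat, 0.0]])
    rows = []
    for i, j in itertools.combinations(range(len(cols)), 2):
        rho = float(rho_mat[i, j])
        if p_method == "permutation":
            p = _spearman_perm_p(arr[:, i], arr[:, j], rho, n_resamples, rng)
        else:
            p = float(p_mat[i, j])
        a, b = sorted((cols[i], cols[j]))
        rows.append(
            {
                "a": a,
                "b": b,
                "rho": rho,
                "p_value": p,
                "retained": bool(p < alpha and abs(rho) > rho_threshold),
            }
        )
    edges = pd.DataFrame(rows, columns=["a", "b", "rho", "p_value", "retained"])
    edges = edges.sort_values(["a", "b"], ignore_index=True)
    return CorrelationGraph(
        nodes=nodes.kinds.loc[cols],
        edges=edges,
        rho_threshold=rho_threshold,
        alpha=alpha,
        excluded_nodes=list(constant),
    )


def export_graph(
    graph: CorrelationGraph,
    graphml_path,
    edges_tsv_path=None,
) -> None:
    """Write the retained graph as GraphML (node ``kind`` attribute, edge
    ``rho``/``p_value`` attributes) and optionally a flat edge-list TSV."""
    nx.write_graphml(graph.to_networkx(), graphml_path)
    if edges_tsv_path is not None:
        graph.retained.to_csv(edges_tsv_path, sep="\t", index=False)
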