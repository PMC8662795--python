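"""Paralog clustering: similarity graph construction and Markov clustering.

Polyploid genomes carry many near-identical paralogs; before dating genes
the paralogous copies are collapsed into clusters and one representative
(the longest protein) is searched per cluster.  Clustering follows the MCL
algorithm (flow expansion / inflation on the column-stochastic similarity
matrix) with inflation 1.5, the setting commonly used for protein families.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "build_similarity_graph",
    "markov_cluster",
    "choose_representatives",
    "ParalogClusterSet",
]

EVALUE_FLOOR = 1e-180  # zero e-values clamp here so -log10 stays finite


@dataclass
class ParalogClusterSet:
    """A partition of genes into paralog clusters.

    Attributes
    ----------
    clusters : dict
        cluster id -> sorted list of member gene ids.  Clusters are a
        partition: disjoint and covering the input gene set.
    representative : dict
        cluster id -> representative gene id (a member).
    converged : bool
        False when MCL stopped at ``max_iter`` without reaching ``tol``.
    """

    clusters: dict[str, list[str]]
    representative: dict[str, str] = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self):
        members = [g for ms in self.clusters.values() for g in ms]
        if len(members) != len(set(members)):
            raise ValueError("clusters overlap: not a partition")
        for cid, rep in self.representative.items():
            if rep not in self.clusters[cid]:
                raise ValueError(
                    f"representative {rep!r} not a member of cluster {cid!r}"
                )

    @property
    def genes(self) -> list[str]:
        return sorted(g for ms in self.clusters.values() for g in ms)

    def cluster_of(self) -> dict[str, str]:
        """gene id -> cluster id."""
        return {
            g: cid for cid, members in self.clusters.items() for g in members
        }

    def sizes(self) -> pd.Series:
        return pd.Series({c: len(m) for c, m in self.clusters.items()},
                         name="size")

    def __len__(self) -> int:
        return len(self.clusters)


def build_similarity_graph(
    hits: pd.DataFrame,
    evalue_cutoff: float = 1e-4,
    evalue_floor: float = EVALUE_FLOOR,
    genes: Sequence[str] | None = None,
) -> nx.Graph:
    """Build the undirected paralog-similarity graph from all-vs-all hits.

    An edge joins two genes when at least one directed hit between them
    passes the e-value cutoff; its weight is ``-log10(max(evalue, floor))``
    of the best such hit, so stronger similarity means larger weight.
    Self-hits are ignored.  Genes listed in ``genes`` but absent from any
    hit become isolated nodes (future singletons).
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue cutoff must be positive")
    g = nx.Graph()
    if genes is not None:
        g.add_nodes_from(genes)
    if len(hits) == 0:
        return g
    subject_col = "subject" if "subject" in hits else "subject_genome"
    if (hits["evalue"] < 0).any():
        raise ValueError("negative e-values in hit table")
    g.add_nodes_from(hits["query"].astype(str))
    g.add_nodes_from(hits[subject_col].astype(str))
    keep = hits["evalue"] <= evalue_cutoff
    a = hits.loc[keep, "query"].astype(str).to_numpy()
    b = hits.loc[keep, subject_col].astype(str).to_numpy()
    evals = hits.loc[keep, "evalue"].to_numpy()
    for qi, si, ev in zip(a, b, evals):
        if qi == si:
            continue
        w = -math.log10(max(float(ev), evalue_floor))
        if g.has_edge(qi, si):
            if w > g[qi][si]["weight"]:
                g[qi][si]["weight"] = w
        else:
            g.add_edge(qi, si, weight=w)
    return g


def markov_cluster(
    graph: nx.Graph,
    inflation: float = 1.5,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-8,
) -> ParalogClusterSet:
    """Cluster a weighted similarity graph with the MCL algorithm.

    Alternates expansion (matrix power ``expansion``) and inflation
    (entry-wise power ``inflation`` followed by column re-normalisation)
    on the column-stochastic adjacency matrix with self-loops, until the
    matrix changes by less than ``tol`` or ``max_iter`` is hit.  Clusters
    are read off as connected components of the converged flow's support,
    which coincides with the attractor systems for converged runs.

    Deterministic given node insertion order; isolated nodes come out as
    singletons.  Non-convergence returns the current clustering with
    ``converged=False`` and a warning.
    """
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    nodes = list(graph.nodes())
    if not nodes:
        return ParalogClusterSet(clusters={})
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError("negative edge weight")
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    # self-loops damp oscillation; weight = max incident weight (or 1)
    diag = m.max(axis=0)
    np.fill_diagonal(m, np.where(diag > 0, diag, 1.0))

    m /= m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > prune)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    comps = sorted(
        (sorted(nodes[i] for i in comp) for comp in
         nx.connected_components(support)),
        key=lambda ms: ms[0],
    )
    clusters = {f"C{i + 1:05d}": members for i, members in enumerate(comps)}
    return ParalogClusterSet(clusters=clusters, converged=converged)


def choose_representatives(
    clusters: ParalogClusterSet,
    protein_lengths: Mapping[str, int],
) -> ParalogClusterSet:
    """Pick each cluster's representative: the longest protein.

    Ties on length are broken by lexicographically smallest gene id, so
    the choice is deterministic.  Genes missing from ``protein_lengths``
    are rejected by name.
    """
    reps: dict[str, str] = {}
    for cid, members in clusters.clusters.items():
        missing = [g for g in members if g not in protein_lengths]
        if missing:
            raise KeyError(
                f"no protein length for {missing[0]!r} in cluster {cid!r}"
            )
        reps[cid] = min(members, key=lambda g: (-protein_lengths[g], g))
    return ParalogClusterSet(
        clusters=clusters.clusters,
        representative=reps,
        converged=clusters.converged,
    )
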