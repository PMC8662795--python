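"""Phylostratum assignment and gene-age bookkeeping.

A gene's age is the oldest stratum (minimum rank) containing at least one
qualifying homology hit; genes without any qualifying hit outside the focal
species are assigned the youngest, species-specific rank K.  Ages are
assigned to cluster representatives and propagated to all cluster members.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cluster import ParalogClusterSet
from .ladder import PhylostratumLadder

__all__ = [
    "assign_stratum",
    "assign_strata",
    "propagate_ages",
    "fixation_rate",
    "stratum_census",
]

COPY_CLASSES = ("singleton", "two-gene", "multigene")


def _copy_class(size: int) -> str:
    if size == 1:
        return "singleton"
    if size == 2:
        return "two-gene"
    return "multigene"


def assign_stratum(
    rep_hits: pd.DataFrame,
    ladder: PhylostratumLadder,
    evalue_cutoff: float = 1e-4,
) -> int:
    """Date one gene: minimum stratum rank with a qualifying hit.

    Hits to the focal species' own genome are ignored (paralogy is handled
    by clustering, not dating).  With no qualifying hit the gene is
    species-specific: rank K.

    Parameters
    ----------
    rep_hits : DataFrame
        Hit frame for a single query (columns ``subject_genome``,
        ``evalue``); an empty frame is allowed.
    """
    best = ladder.max_rank
    if len(rep_hits) == 0:
        return best
    for genome, ev in zip(rep_hits["subject_genome"], rep_hits["evalue"]):
        if ev < 0:
            raise ValueError(f"negative e-value for subject {genome!r}")
        rank = ladder.rank_of(genome)  # raises KeyError naming the genome
        if genome in ladder.focal_genomes:
            continue
        if ev <= evalue_cutoff and rank < best:
            best = rank
    return best


def assign_strata(
    hits: pd.DataFrame,
    ladder: PhylostratumLadder,
    queries: Iterable[str] | None = None,
    evalue_cutoff: float = 1e-4,
) -> pd.Series:
    """Vectorised stratum assignment for a whole hit table.

    Parameters
    ----------
    hits : DataFrame
        Hit frame with ``query, subject_genome, evalue`` columns.
    queries : iterable of str, optional
        Full query universe; queries without hits get rank K.  Defaults to
        the queries present in the table.

    Returns
    -------
    Series
        gene id -> rank, named ``rank``.
    """
    genome_rank = ladder.genome_ranks
    unknown = set(hits["subject_genome"]) - set(genome_rank)
    if unknown:
        raise KeyError(f"subject genome {sorted(unknown)[0]!r} is not in the ladder")
    focal = ladder.focal_genomes
    ok = (hits["evalue"] <= evalue_cutoff) & ~hits["subject_genome"].isin(focal)
    if (hits["evalue"] < 0).any():
        raise ValueError("negative e-values in hit table")
    sub = hits.loc[ok, ["query", "subject_genome"]].copy()
    sub["rank"] = sub["subject_genome"].map(genome_rank)
    best = sub.groupby("query")["rank"].min()
    if queries is None:
        queries = hits["query"].unique()
    ranks = best.reindex(pd.Index(queries, name="gene")).fillna(
        ladder.max_rank
    ).astype(int)
    ranks.name = "rank"
    return ranks


def propagate_ages(
    clusters: ParalogClusterSet,
    rep_ranks: Mapping[str, int] | pd.Series,
) -> pd.DataFrame:
    """Spread each representative's rank to its whole cluster.

    Parameters
    ----------
    clusters : ParalogClusterSet
        Must carry representatives.
    rep_ranks : mapping
        representative gene id (or cluster id) -> assigned rank.

    Returns
    -------
    DataFrame indexed by gene with columns ``rank``, ``cluster``,
    ``copy_number_class``, ``is_representative`` — the gene-age table.
    """
    rows = []
    for cid, members in clusters.clusters.items():
        rep = clusters.representative.get(cid)
        if rep is None:
            raise KeyError(f"cluster {cid!r} has no representative")
        if rep in rep_ranks:
            rank = int(rep_ranks[rep])
        elif cid in rep_ranks:
            rank = int(rep_ranks[cid])
        else:
            raise KeyError(
                f"no rank for representative {rep!r} of cluster {cid!r}"
            )
        klass = _copy_class(len(members))
        for g in members:
            rows.append((g, rank, cid, klass, g == rep))
    table = pd.DataFrame(
        rows,
        columns=["gene", "rank", "cluster", "copy_number_class",
                 "is_representative"],
    ).set_index("gene").sort_index()
    return table


def fixation_rate(n_clusters: int, duration_my: float) -> float:
    """Cluster fixation rate r = N / T, in clusters per million years."""
    if duration_my <= 0:
        raise ValueError(f"duration must be positive, got {duration_my}")
    if n_clusters < 0:
        raise ValueError("cluster count cannot be negative")
    return n_clusters / duration_my


def stratum_census(
    ages: pd.DataFrame | pd.Series,
    young_ranks: Sequence[int] = (),
    max_rank: int | None = None,
) -> dict:
    """Summarise a gene-age table per stratum.

    Returns a dict with

    ``counts``
        Series rank -> gene count (all ranks 1..K present, zero-filled).
    ``orphan_total``
        Total genes in the user-designated young ranks.
    ``copy_class_proportions``
        DataFrame rank x copy-number class, rows summing to 1 (only when
        the input carries a ``copy_number_class`` column).
    """
    if isinstance(ages, pd.DataFrame):
        ranks = ages["rank"]
    else:
        ranks = ages
    if len(ranks) == 0:
        raise ValueError("empty gene-age table")
    k = int(max_rank if max_rank is not None else ranks.max())
    counts = (
        ranks.value_counts().reindex(range(1, k + 1), fill_value=0).sort_index()
    )
    counts.index.name = "rank"
    counts.name = "n_genes"
    out = {
        "counts": counts,
        "orphan_total": int(counts.reindex(list(young_ranks), fill_value=0).sum()),
    }
    if isinstance(ages, pd.DataFrame) and "copy_number_class" in ages:
        tab = (
            ages.groupby(["rank", "copy_number_class"], observed=False)
            .size()
            .unstack(fill_value=0)
            .reindex(columns=list(COPY_CLASSES), fill_value=0)
        )
        out["copy_class_proportions"] = tab.div(tab.sum(axis=1), axis=0)
    return out
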