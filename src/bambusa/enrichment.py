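"""Specifically expressed genes (SEGs) and enrichment statistics.

A SEG is a gene whose expression is confined to one tissue: here called
with a tau / dominance rule (tissue-specificity tau above a floor, the top
tissue expressed above an FPKM floor and dominating the runner-up by a
fixed factor).  On top of SEG calls the module builds per-stratum censuses,
tags shoot-biased whole-genome-duplication duplicates (SBW) from a supplied
duplicate-class table, and runs the 2x2 enrichment statistics
(Yates-corrected chi-square and Fisher's exact test).
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .indices import aggregate_tissues, tissue_specificity_tau

__all__ = [
    "call_segs",
    "seg_census",
    "balanced_seg_census",
    "chi_square_yates",
    "fisher_exact",
    "read_duplicate_classes",
    "wgd_gene_set",
    "tag_shoot_biased_wgd",
    "ancestral_state_comparison",
]

DUPLICATE_CLASSES = ("WGD", "tandem", "proximal", "transposed", "dispersed")


def call_segs(
    expr: pd.DataFrame,
    tissue_map: Mapping[str, str],
    tau_min: float = 0.85,
    expr_floor: float = 1.0,
    dominance: float = 2.0,
) -> pd.DataFrame:
    """Call specifically expressed genes with a tau / dominance rule.

    A gene is specific to its highest-expressed tissue t when (i) its
    tissue-specificity tau is at least ``tau_min``, (ii) expression in t
    is at least ``expr_floor`` FPKM, and (iii) expression in t is at least
    ``dominance`` times the second-highest tissue.  At most one specific
    tissue per gene by construction.

    Returns a DataFrame indexed by gene with columns ``tissue`` (NaN when
    not specific), ``tau`` and ``value`` (expression in the called tissue).
    """
    agg = aggregate_tissues(expr, tissue_map)
    if agg.shape[1] < 2:
        raise ValueError("SEG calling needs at least two tissues")
    tau = tissue_specificity_tau(agg)
    x = agg.to_numpy(dtype=float)
    order = np.argsort(x, axis=1)
    top_idx = order[:, -1]
    top = x[np.arange(len(x)), top_idx]
    second = x[np.arange(len(x)), order[:, -2]]
    ok = (
        (tau.to_numpy() >= tau_min)
        & (top >= expr_floor)
        & (top >= dominance * second)
    )
    tissue = np.where(ok, agg.columns.to_numpy()[top_idx], None)
    return pd.DataFrame(
        {"tissue": tissue, "tau": tau.to_numpy(), "value": np.where(ok, top, np.nan)},
        index=agg.index,
    )


def seg_census(
    segs: pd.DataFrame,
    ages: pd.Series,
    tissues: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cross-tabulate SEG calls: strata in rows, tissues in columns.

    Adds a ``Total`` row and column; cell counts sum to the number of
    called SEGs.
    """
    called = segs.dropna(subset=["tissue"])
    ranks = ages.reindex(called.index)
    tab = (
        pd.crosstab(ranks, called["tissue"])
        .reindex(columns=list(tissues) if tissues else None, fill_value=0)
    )
    tab.index = tab.index.astype(int)
    tab.index.name = "stratum"
    all_ranks = range(int(ages.min()), int(ages.max()) + 1)
    tab = tab.reindex(all_ranks, fill_value=0)
    tab["Total"] = tab.sum(axis=1)
    tab.loc["Total"] = tab.sum(axis=0)
    return tab


def balanced_seg_census(
    expr: pd.DataFrame,
    tissue_map: Mapping[str, str],
    ages: pd.Series,
    multi_stage_tissue: str,
    stage: str,
    **seg_kwargs,
) -> pd.DataFrame:
    """SEG census with the multi-stage tissue reduced to one chosen stage.

    Tissues sampled over many developmental stages accumulate more SEG
    calls than single-stage tissues; for a fair per-tissue comparison the
    multi-stage tissue is represented by the single ``stage`` column only
    and all other samples are kept as they are.
    """
    stage_cols = [c for c, t in tissue_map.items()
                  if t == multi_stage_tissue and c in expr.columns]
    if stage not in stage_cols:
        raise KeyError(
            f"stage {stage!r} is not a column of tissue {multi_stage_tissue!r}"
        )
    keep = [c for c in expr.columns
            if tissue_map[c] != multi_stage_tissue or c == stage]
    segs = call_segs(expr[keep], tissue_map, **seg_kwargs)
    return seg_census(segs, ages)


# -- 2x2 statistics --------------------------------------------------------

def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("negative cell counts")
    return arr


def chi_square_yates(table) -> tuple[float, float]:
    """Yates-continuity-corrected chi-square for a 2x2 table.

    statistic = sum over cells of (|O - E| - 0.5)^2 / E with df = 1, E
    the usual product-of-margins expectation.  Zero margins are rejected.
    Returns (statistic, p).
    """
    arr = _as_table(table)
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin in contingency table")
    expected = np.outer(rows, cols) / arr.sum()
    stat = float((((np.abs(arr - expected) - 0.5) ** 2) / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table."""
    arr = _as_table(table).astype(int)
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


# -- duplicate classes and SBW ---------------------------------------------

def read_duplicate_classes(path: str | Path) -> pd.DataFrame:
    """Read a duplicate-class table: geneA, geneB, class[, Ks] (TSV).

    Pair order is not meaningful; classes must come from the closed
    five-label set (WGD, tandem, proximal, transposed, dispersed).
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["gene_a", "gene_b", "dup_class", "ks"],
                     usecols=[0, 1, 2, 3], engine="python")
    return validate_duplicate_classes(df)


def validate_duplicate_classes(df: pd.DataFrame) -> pd.DataFrame:
    bad = set(df["dup_class"]) - set(DUPLICATE_CLASSES)
    if bad:
        raise ValueError(f"unknown duplicate class {sorted(bad)[0]!r}")
    return df


def wgd_gene_set(dup: pd.DataFrame) -> set[str]:
    """All genes participating in at least one WGD-class pair."""
    w = dup.loc[dup["dup_class"] == "WGD"]
    return set(w["gene_a"]).union(w["gene_b"])


def tag_shoot_biased_wgd(
    segs: pd.DataFrame,
    dup: pd.DataFrame,
    target_tissue: str,
    omega: pd.Series | None = None,
) -> dict:
    """Tag WGD-derived duplicates specifically expressed in one tissue.

    SBW genes are the SEGs of ``target_tissue`` that belong to at least
    one WGD-class pair.  The summary reports the WGD-derived fraction of
    the tissue's SEGs, the fraction of SBW pairs with both copies
    specific to the tissue, and — when per-gene Ka/Ks values are given —
    the fraction of SBW genes with omega >= 1.
    """
    dup = validate_duplicate_classes(dup)
    target_segs = set(segs.index[segs["tissue"] == target_tissue])
    wgd_genes = wgd_gene_set(dup)
    sbw = sorted(target_segs & wgd_genes)
    sbw_set = set(sbw)
    w = dup.loc[dup["dup_class"] == "WGD"]
    pair_mask = w["gene_a"].isin(sbw_set) | w["gene_b"].isin(sbw_set)
    pairs = w.loc[pair_mask]
    both = (
        pairs["gene_a"].isin(target_segs) & pairs["gene_b"].isin(target_segs)
    )
    out = {
        "sbw_genes": sbw,
        "n_sbw": len(sbw),
        "n_target_segs": len(target_segs),
        "wgd_fraction_of_segs": (
            len(sbw) / len(target_segs) if target_segs else float("nan")
        ),
        "both_copies_specific_fraction": (
            float(both.mean()) if len(pairs) else float("nan")
        ),
    }
    if omega is not None:
        om = omega.reindex(sbw)
        out["high_omega_fraction"] = (
            float((om >= 1).sum() / len(sbw)) if sbw else float("nan")
        )
        out["n_high_omega"] = int((om >= 1).sum())
    return out


def ancestral_state_comparison(
    sbw_genes: Iterable[str],
    ortholog_map: pd.DataFrame,
    outgroup_expr: pd.DataFrame,
    outgroup_tissue_map: Mapping[str, str],
    **seg_kwargs,
) -> dict:
    """Classify outgroup orthologs of SBW genes: broad vs tissue-specific.

    ``ortholog_map`` holds columns ``focal`` and ``ortholog`` (one row per
    mapped pair, e.g. from a synteny screen).  Orthologs present in the
    outgroup expression matrix are SEG-called there; orthologs missing
    from the matrix are counted as unassessed.  specific + broad +
    unassessed always equals the number of mapped orthologs.
    """
    sbw_set = set(sbw_genes)
    mapped = ortholog_map.loc[ortholog_map["focal"].isin(sbw_set), "ortholog"]
    mapped = pd.unique(mapped)
    present = [g for g in mapped if g in outgroup_expr.index]
    absent = [g for g in mapped if g not in outgroup_expr.index]
    segs = call_segs(outgroup_expr, outgroup_tissue_map, **seg_kwargs)
    calls = segs.loc[present, "tissue"]
    n_specific = int(calls.notna().sum())
    by_tissue = calls.dropna().value_counts().to_dict()
    return {
        "mapped": len(mapped),
        "specific": n_specific,
        "broad": len(present) - n_specific,
        "unassessed": len(absent),
        "specific_by_tissue": by_tissue,
    }
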