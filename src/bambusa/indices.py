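"""Phylotranscriptomic indices over gene x sample expression matrices.

The transcriptome age index (TAI) of a sample is the expression-weighted
mean phylostratum rank; the transcriptome divergence index (TDI) is the
expression-weighted mean Ka/Ks.  Both are high when young / fast-evolving
genes dominate the transcriptome.  The module also provides relative
expression profiles per stratum, expression preference of highly expressed
genes, the tau tissue-specificity score, expressed-gene fractions, and a
permutation "flat line" test of whether an index profile deviates from a
constant one.

Expression matrices are plain pandas DataFrames: rows genes, columns
samples (tissues or developmental stages, order meaningful), values FPKM.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "compute_tai",
    "compute_tdi",
    "relative_expression",
    "flat_line_test",
    "expression_preference",
    "tissue_specificity_tau",
    "aggregate_tissues",
    "expressed_fraction",
    "IndexProfile",
]


def _validate_expr(expr: pd.DataFrame) -> None:
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative values")
    if expr.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression matrix")


def _weighted_profile(expr: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Expression-weighted mean of per-gene weights, one value per sample.

    Genes with undefined weight (NaN) are excluded from numerator and
    denominator.  All-zero (or empty) columns yield NaN.
    """
    w = weights.reindex(expr.index)
    keep = w.notna()
    e = expr.loc[keep].to_numpy(dtype=float)
    wv = w.loc[keep].to_numpy(dtype=float)
    denom = e.sum(axis=0)
    num = wv @ e
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0),
                        np.nan)
    return pd.Series(vals, index=expr.columns, name="index")


def compute_tai(expr: pd.DataFrame, ages: pd.Series) -> pd.Series:
    """Transcriptome age index per sample.

    TAI_s = sum_i e_is * ps_i / sum_i e_is over all genes i; bounded by the
    oldest and youngest rank present.  Genes with positive expression but
    no age are an error; all-zero samples come back NaN.
    """
    _validate_expr(expr)
    ages = ages.reindex(expr.index)
    orphaned = ages.isna() & (expr.sum(axis=1) > 0)
    if orphaned.any():
        raise ValueError(
            f"expressed gene without age: {expr.index[orphaned][0]!r}"
        )
    return _weighted_profile(expr, ages).rename("TAI")


def compute_tdi(expr: pd.DataFrame, omega: pd.Series) -> pd.Series:
    """Transcriptome divergence index per sample.

    Expression-weighted mean of per-gene Ka/Ks; genes whose omega is
    undefined (NaN, e.g. Ks = 0) are excluded from both sums.  Samples
    with no qualifying expression come back NaN.
    """
    _validate_expr(expr)
    prof = _weighted_profile(expr, omega.reindex(expr.index)).rename("TDI")
    if prof.isna().all():
        raise ValueError("no gene with defined Ka/Ks and expression")
    return prof


def relative_expression(expr: pd.DataFrame, ages: pd.Series) -> pd.DataFrame:
    """Relative expression of each stratum across stages, in [0, 1].

    Per gene, expression is first turned into a partial concentration over
    stages (each row divided by its row sum); these are averaged within a
    stratum to give f-bar(ps, s) and min-max scaled per stratum:
    RE = (f-bar - min) / (max - min).  A stratum whose average profile is
    constant across stages has no meaningful scaling and is returned as a
    NaN row.
    """
    if expr.shape[1] < 2:
        raise ValueError("relative expression needs at least two stages")
    _validate_expr(expr)
    totals = expr.sum(axis=1)
    conc = expr.loc[totals > 0].div(totals[totals > 0], axis=0)
    fbar = conc.groupby(ages.reindex(conc.index)).mean()
    fbar.index.name = "stratum"
    lo = fbar.min(axis=1)
    hi = fbar.max(axis=1)
    span = hi - lo
    re = fbar.sub(lo, axis=0).div(span.where(span > 0), axis=0)
    return re


@dataclass
class IndexProfile:
    """Result of the permutation flat-line test on an index profile."""

    profile: pd.Series
    perm_mean: pd.Series
    perm_sd: pd.Series
    p_value: float
    n_permutations: int
    seed: int | None
    statistic: float

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"IndexProfile(p={self.p_value:.4g}, "
            f"n_perm={self.n_permutations}, len={len(self.profile)})"
        )


def flat_line_test(
    expr: pd.DataFrame,
    labels: pd.Series,
    n_perm: int = 1000,
    seed: int | None = None,
) -> IndexProfile:
    """Permutation test of whether an index profile is flat across samples.

    The observed statistic is the variance of the expression-weighted index
    profile (TAI when ``labels`` are ranks, TDI when they are Ka/Ks)
    across samples.  The null distribution is built by permuting the
    per-gene labels ``n_perm`` times; the p-value uses the add-one
    estimator p = (1 + #{perm >= obs}) / (1 + n_perm).  ``perm_mean`` and
    ``perm_sd`` give the per-sample permutation band.
    """
    if expr.shape[1] < 2:
        raise ValueError("flat-line test needs at least two samples")
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    _validate_expr(expr)
    labels = labels.reindex(expr.index)
    keep = labels.notna()
    e = expr.loc[keep].to_numpy(dtype=float)
    lv = labels.loc[keep].to_numpy(dtype=float)
    denom = e.sum(axis=0)
    if (denom <= 0).any():
        raise ValueError("all-zero sample column in flat-line test")
    obs = lv @ e / denom
    stat = float(np.var(obs))

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, len(lv)))
    for i in range(n_perm):
        perms[i] = rng.permutation(lv)
    null_profiles = perms @ e / denom  # n_perm x n_samples
    null_stats = null_profiles.var(axis=1)
    p = (1.0 + np.sum(null_stats >= stat)) / (1.0 + n_perm)
    return IndexProfile(
        profile=pd.Series(obs, index=expr.columns, name="index"),
        perm_mean=pd.Series(null_profiles.mean(axis=0), index=expr.columns),
        perm_sd=pd.Series(null_profiles.std(axis=0), index=expr.columns),
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        statistic=stat,
    )


def expression_preference(
    expr: pd.DataFrame,
    ages: pd.Series,
    k: int = 1000,
) -> pd.DataFrame:
    """Expression preference (EP) of the top-k expressed genes per sample.

    Within each sample's k highest-expressed genes, a stratum's EP is its
    share of the set's total expression divided by its share of the gene
    count; 1 means neutral, >1 means the stratum's genes are preferentially
    highly expressed.  Strata absent from a top-k set are NaN.

    Returns a DataFrame strata x samples.
    """
    _validate_expr(expr)
    ages = ages.reindex(expr.index)
    strata = sorted(ages.dropna().unique())
    out = pd.DataFrame(index=pd.Index(strata, name="stratum"),
                       columns=expr.columns, dtype=float)
    for col in expr.columns:
        vals = expr[col]
        positive = vals[vals > 0]
        if len(positive) < k:
            raise ValueError(
                f"sample {col!r} has only {len(positive)} expressed genes, "
                f"cannot take top {k}"
            )
        top = positive.sort_values(ascending=False, kind="stable").iloc[:k]
        total = top.sum()
        grp = top.groupby(ages.reindex(top.index))
        expr_share = grp.sum() / total
        gene_share = grp.size() / k
        out[col] = (expr_share / gene_share).reindex(out.index)
    return out


def aggregate_tissues(
    expr: pd.DataFrame, tissue_map: Mapping[str, str]
) -> pd.DataFrame:
    """Average stage columns of the same tissue into one column per tissue.

    ``tissue_map`` maps sample (column) ids to tissue names; column order
    of first appearance is preserved.
    """
    missing = [c for c in expr.columns if c not in tissue_map]
    if missing:
        raise KeyError(f"sample {missing[0]!r} missing from tissue map")
    tissues = pd.Series({c: tissue_map[c] for c in expr.columns})
    agg = expr.T.groupby(tissues, sort=False).mean().T
    return agg


def tissue_specificity_tau(
    expr: pd.DataFrame,
    tissue_map: Mapping[str, str] | None = None,
) -> pd.Series:
    """Per-gene tissue-specificity score tau in [0, 1].

    tau = sum_j (1 - x_j / x_max) / (N - 1) over N tissues: 0 for uniform
    (housekeeping-like) expression, 1 for single-tissue expression.  Stage
    columns are averaged per tissue first when a tissue map is given.
    All-zero genes have no defined tau and come back NaN.
    """
    _validate_expr(expr)
    if tissue_map is not None:
        expr = aggregate_tissues(expr, tissue_map)
    if expr.shape[1] < 2:
        raise ValueError("tau needs at least two tissues")
    x = expr.to_numpy(dtype=float)
    xmax = x.max(axis=1)
    n = x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1.0 - x / xmax[:, None]).sum(axis=1) / (n - 1)
    tau = np.where(xmax > 0, tau, np.nan)
    return pd.Series(tau, index=expr.index, name="tau")


def expressed_fraction(
    expr: pd.DataFrame,
    threshold: float = 1.0,
    ages: pd.Series | None = None,
) -> dict:
    """Fraction of genes expressed at >= threshold in at least one sample.

    With ``threshold=0`` a gene counts if it has any positive value.
    Returns ``fraction``, ``count``, ``total`` and, when ages are given,
    a per-stratum breakdown of expressed fractions.
    """
    _validate_expr(expr)
    if threshold > 0:
        hit = (expr >= threshold).any(axis=1)
    else:
        hit = (expr > 0).any(axis=1)
    out = {
        "fraction": float(hit.mean()),
        "count": int(hit.sum()),
        "total": int(len(hit)),
    }
    if ages is not None:
        grp = hit.groupby(ages.reindex(hit.index))
        out["per_stratum"] = pd.DataFrame(
            {"expressed": grp.sum().astype(int), "fraction": grp.mean()}
        )
    return out
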