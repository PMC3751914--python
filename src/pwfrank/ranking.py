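"""Proportion-weighted F (PWF) ranking and companion matrix utilities.

Ranking transcripts by raw F does not single out genes that depend on
one factor specifically: a gene with large F for every term outranks a
gene that responds to exactly one.  The proportion-weighted F for term
t weights each term's F by its share of the gene's total F across the
three terms::

    PWF_t = F_t * F_t / (F_sorted + F_treatment + F_interaction)

so a single-factor gene keeps its full F for that factor, while genes
dominated by a different factor are de-emphasized.  PWF never exceeds
F, and the terms' PWF values sum to at most the largest F.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .model import TERMS

__all__ = [
    "compute_pwf",
    "pwf_from_f",
    "top_genes",
    "zscore_matrix",
    "differential_mirna",
]


def pwf_from_f(f_values: np.ndarray) -> np.ndarray:
    """PWF for an array of F triples (… x 3); zero where all F are zero."""
    f = np.asarray(f_values, dtype=float)
    total = f.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pwf = f * f / total
    return np.where(total > 0, pwf, 0.0)


def compute_pwf(term_stats: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Rank genes per term by proportion-weighted F.

    Degenerate genes (no F values) are placed after all rankable genes
    and excluded from the denominator N, so quantiles reflect rankable
    genes only.  Ties break by descending PWF then ascending gene id,
    making ranks reproducible across platforms.

    Returns a mapping term -> DataFrame (ordered by rank) with columns
    ``F_<term>``, ``pwf``, ``rank``, ``quantile``, ``fit_method``.
    """
    ok = ~term_stats["degenerate"].to_numpy(dtype=bool)
    f = term_stats[[f"F_{t}" for t in TERMS]].to_numpy(dtype=float)
    pwf_all = np.full_like(f, np.nan)
    pwf_all[ok] = pwf_from_f(f[ok])

    rankings: dict[str, pd.DataFrame] = {}
    n_ok = int(ok.sum())
    for j, term in enumerate(TERMS):
        frame = pd.DataFrame(
            {
                f"F_{term}": f[:, j],
                "pwf": pwf_all[:, j],
                "fit_method": term_stats["fit_method"],
            },
            index=term_stats.index.copy(),
        )
        rankable = frame[ok]
        # deterministic tie-break: descending pwf, then ascending gene id
        order = np.lexsort(
            (rankable.index.to_numpy(), -rankable["pwf"].to_numpy())
        )
        rankable = rankable.iloc[order].copy()
        rankable["rank"] = np.arange(1, n_ok + 1)
        rankable["quantile"] = rankable["rank"] / n_ok
        rest = frame[~ok].copy()
        rest["rank"] = np.nan
        rest["quantile"] = np.nan
        rankings[term] = pd.concat([rankable, rest.sort_index()])
    return rankings


def top_genes(ranking: pd.DataFrame, k: int) -> list[str]:
    """First ``k`` rankable genes in rank order."""
    n = int(ranking["rank"].notna().sum())
    if k < 0 or k > n:
        raise IndexError(f"k must be in [0, {n}], got {k}")
    ordered = ranking[ranking["rank"].notna()].sort_values("rank")
    return list(ordered.index[:k])


def zscore_matrix(expr: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """Row-standardized (rescaled Z) expression for heat-map display.

    Each selected gene's profile is centred and scaled to unit SD across
    samples; a zero-variance gene is an error naming the gene.
    """
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes not in expression matrix: {missing}")
    sub = expr.loc[genes]
    sd = sub.std(axis=1, ddof=0)
    bad = sd.index[sd == 0]
    if len(bad):
        raise ValueError(f"zero-variance gene(s) cannot be Z-scored: {list(bad)}")
    return sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)


def differential_mirna(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    fold_threshold: float = 2.0,
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """One-way ANOVA screen of miRNA expression on sorted status.

    Fold change is the signed ratio implied by the difference of group
    means on the log2 scale (positive-sorted minus negative-sorted; a
    negative value means lower expression in the positive-sorted cells).
    ``pass_flag`` requires |FC| strictly above ``fold_threshold`` AND
    p strictly below ``p_threshold``.
    """
    from .concordance import signed_fold_change

    design = design.loc[expr.columns]
    pos = design.index[design["sorted"] == "pos"]
    neg = design.index[design["sorted"] == "neg"]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            "each sorted group needs >= 2 samples for the ANOVA screen"
        )
    a = expr[pos].to_numpy(dtype=float)
    b = expr[neg].to_numpy(dtype=float)
    f_stat, p = stats.f_oneway(a, b, axis=1)
    delta = a.mean(axis=1) - b.mean(axis=1)
    fc = np.array([signed_fold_change(d) for d in delta])
    p = np.where(np.isfinite(p), p, 1.0)
    return pd.DataFrame(
        {
            "p_value": p,
            "fold_change": fc,
            "pass_flag": (np.abs(fc) > fold_threshold) & (p < p_threshold),
        },
        index=expr.index.copy(),
    )
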