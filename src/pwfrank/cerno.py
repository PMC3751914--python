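"""CERNO rank-based gene-set enrichment with BH FDR.

CERNO (Coincident Extreme Ranks in Numerical Observations) asks
whether a gene set's members sit at unusually extreme positions of a
genome-wide ranking.  It Fisher-combines each member's rank fraction::

    S = -2 * sum_i ln(rank_i / N)

which under a uniform-rank null is chi-square with 2k degrees of
freedom (k = members with measured ranks).  Being a function of ranks
only, it needs no per-gene p-values and is insensitive to the scale of
the underlying statistic.  Set-level p-values are corrected with the
Benjamini-Hochberg step-up across all testable sets of a catalog.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import GeneSetCatalog

__all__ = ["cerno_test", "bh_fdr", "select_for_dsm"]


def cerno_test(ranking: pd.DataFrame, catalog: GeneSetCatalog) -> pd.DataFrame:
    """Score every set of a catalog against a PWF ranking.

    Set members absent from the ranking (or degenerate) are dropped from
    k.  Sets left with k = 0 are flagged untestable and excluded from
    the BH family.

    Returns a DataFrame indexed by set name with columns ``k``, ``S``,
    ``df``, ``p``, ``q`` and ``testable``.
    """
    rankable = ranking[ranking["rank"].notna()]
    n = len(rankable)
    rank_of = rankable["rank"]

    rows = []
    for name, members in catalog:
        present = rank_of.reindex(pd.unique(pd.Series(members))).dropna()
        k = len(present)
        if k == 0:
            rows.append({"set": name, "k": 0, "S": np.nan, "df": 0,
                         "p": np.nan, "testable": False})
            continue
        s = float(-2.0 * np.log(present.to_numpy() / n).sum())
        p = float(stats.chi2.sf(s, 2 * k))
        rows.append({"set": name, "k": k, "S": s, "df": 2 * k,
                     "p": max(p, np.nextafter(0, 1)), "testable": True})
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = np.nan
    testable = out["testable"]
    if testable.any():
        out.loc[testable, "q"] = bh_fdr(out.loc[testable, "p"].to_numpy())
    return out


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_for_dsm(
    results: pd.DataFrame,
    ranking: pd.DataFrame,
    catalog: GeneSetCatalog,
    set_q_max: float = 1e-4,
    gene_quantile_max: float = 0.01,
) -> tuple[list[str], list[str]]:
    """Select sets and genes for the design structure matrix.

    Sets with BH-adjusted q strictly below ``set_q_max`` are kept; genes
    must belong to at least one kept set and have a PWF quantile
    strictly below ``gene_quantile_max``.  An empty selection is
    returned (with a warning) rather than raised, so callers can relax
    thresholds.
    """
    import warnings

    testable = results[results["testable"].astype(bool)]
    selected_sets = list(testable.index[testable["q"] < set_q_max])
    if not selected_sets:
        warnings.warn(
            f"no gene set passed q < {set_q_max}; selection is empty",
            stacklevel=2,
        )
        return [], []
    member_union: set[str] = set()
    for name in selected_sets:
        member_union.update(catalog.sets[name])
    quant = ranking["quantile"]
    eligible = quant[quant < gene_quantile_max].index
    selected_genes = sorted(member_union.intersection(eligible))
    return selected_sets, selected_genes
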