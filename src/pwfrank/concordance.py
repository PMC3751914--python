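"""Cross-platform validation arithmetic.

Signed fold-change conventions, qPCR delta-delta-Ct relative
quantification, the microarray-vs-qPCR log-log regression, per-gene
direction-of-change concordance, and the phosphoprotein ratio filter.

Signed fold changes write x-fold down-regulation as -x, so the open
interval (-1, 1) contains no valid value; the mapping to a log2
difference is ``delta >= 0 -> 2**delta``, ``delta < 0 -> -2**(-delta)``
and round-trips exactly.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "signed_fold_change",
    "signed_fc_to_log2",
    "signed_log10",
    "delta_delta_ct",
    "crossplatform_regression",
    "direction_concordance",
    "phospho_ratio_filter",
    "load_validation_table",
    "validation_regression_inputs",
    "validation_direction_inputs",
]


def signed_fold_change(delta_log2: float) -> float:
    """Signed fold change implied by a log2 difference."""
    d = float(delta_log2)
    if not np.isfinite(d):
        raise ValueError("log2 difference must be finite")
    return 2.0 ** d if d >= 0 else -(2.0 ** (-d))


def signed_fc_to_log2(fc: float) -> float:
    """Inverse of :func:`signed_fold_change`; |fc| must be >= 1."""
    f = float(fc)
    if abs(f) < 1:
        raise ValueError(f"signed fold change must satisfy |fc| >= 1, got {f}")
    return np.log2(f) if f > 0 else -np.log2(-f)


def signed_log10(fc: float) -> float:
    """sign(fc) * log10(|fc|) -- the axis transform of the cross-platform plot."""
    f = float(fc)
    if abs(f) < 1:
        raise ValueError(f"signed fold change must satisfy |fc| >= 1, got {f}")
    return float(np.sign(f) * np.log10(abs(f)))


def delta_delta_ct(
    ct: pd.DataFrame,
    gene: str,
    condition: str,
    reference_condition: str,
    reference_gene: str = "GAPDH",
) -> dict[str, float]:
    """Relative expression by the delta-delta-Ct method.

    dCt = Ct_gene - Ct_reference per condition; ddCt is the difference
    of dCt between condition and reference condition; the relative
    quantity is 2**(-ddCt) under the exact-doubling assumption, and the
    signed fold change follows the package-wide convention.

    ``ct`` is a long table with columns ``gene``, ``condition``, ``ct``.
    """
    def lookup(g: str, cond: str) -> float:
        hit = ct[(ct["gene"] == g) & (ct["condition"] == cond)]["ct"]
        if len(hit) == 0:
            raise KeyError(f"no Ct value for gene {g!r} in condition {cond!r}")
        return float(hit.mean())

    d_cond = lookup(gene, condition) - lookup(reference_gene, condition)
    d_ref = lookup(gene, reference_condition) - lookup(reference_gene, reference_condition)
    ddct = d_cond - d_ref
    rq = 2.0 ** (-ddct)
    return {
        "ddct": ddct,
        "relative_quantity": rq,
        "fold_change": signed_fold_change(-ddct),
    }


def crossplatform_regression(
    x_fc: pd.Series | dict[str, float],
    y_fc: pd.Series | dict[str, float],
) -> dict[str, float]:
    """OLS of signed-log10 fold changes of platform y on platform x.

    Both inputs map gene -> signed fold change; only shared genes enter.
    Where one x key carries several values (a Series with duplicated
    index, e.g. two array probes for one qPCR assay), their transformed
    values are averaged before pairing.  Requires >= 3 pairs.

    Returns slope, intercept (log10 units), r_squared, p_value, n_points.
    """
    def collapse(fc) -> pd.Series:
        s = pd.Series(fc, dtype=float)
        t = s.map(signed_log10)
        return t.groupby(t.index).mean()

    tx, ty = collapse(x_fc), collapse(y_fc)
    shared = tx.index.intersection(ty.index)
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 paired fold changes, got {len(shared)}"
        )
    res = stats.linregress(tx[shared].to_numpy(), ty[shared].to_numpy())
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "n_points": int(len(shared)),
    }


def direction_concordance(
    a: pd.Series | dict[str, float | str],
    b: pd.Series | dict[str, float | str],
) -> pd.DataFrame:
    """Per-gene sign agreement between two fold-change records.

    Entries may be numeric signed fold changes or direction arrows
    ("up"/"down").  Missing or non-determined ("ND") entries are
    skipped.  Returns a frame indexed by shared gene with ``sign_a``,
    ``sign_b`` and ``concordant``.
    """
    def sign_of(v) -> float | None:
        if v is None:
            return None
        if isinstance(v, str):
            token = v.strip().lower()
            if token in ("up", "+", "↑"):
                return 1.0
            if token in ("down", "-", "↓"):
                return -1.0
            if token in ("nd", "na", ""):
                return None
            raise ValueError(f"unrecognized direction marker {v!r}")
        if not np.isfinite(v):
            return None
        return float(np.sign(v))

    a = pd.Series(a)
    b = pd.Series(b)
    rows = []
    for g in a.index.intersection(b.index):
        sa, sb = sign_of(a[g]), sign_of(b[g])
        if sa is None or sb is None:
            continue
        rows.append({"gene": g, "sign_a": sa, "sign_b": sb,
                     "concordant": sa == sb})
    return pd.DataFrame(rows).set_index("gene")


def phospho_ratio_filter(
    ratios: pd.Series | dict[str, float], threshold_pct: float = 20.0
) -> list[str]:
    """Proteins whose signal ratio changed by more than ``threshold_pct``.

    The bound is symmetric on the multiplicative scale: a ratio passes
    iff it is strictly above 1 + threshold/100 or strictly below its
    reciprocal.
    """
    ratios = pd.Series(ratios, dtype=float)
    if (ratios <= 0).any():
        bad = list(ratios.index[ratios <= 0])
        raise ValueError(f"ratios must be positive; offending: {bad}")
    hi = 1.0 + threshold_pct / 100.0
    lo = 1.0 / hi
    mask = (ratios > hi) | (ratios < lo)
    return list(ratios.index[mask])


def load_validation_table() -> pd.DataFrame:
    """The bundled 14-gene microarray/qPCR/protein validation panel.

    Columns: ``gene``, ``probe`` (microarray probe label where a gene
    has several), ``microarray`` and ``qpcr`` signed fold changes
    (NaN where not determined), ``protein`` direction arrow.
    """
    with resources.files("pwfrank.data").joinpath(
        "validation_fold_changes.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def validation_regression_inputs(
    table: pd.DataFrame | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Microarray/qPCR pairing of the validation panel for the regression.

    One point per qPCR value: probes sharing a qPCR assay keep the assay
    gene id (their transformed microarray values are averaged inside
    :func:`crossplatform_regression`); rows without a numeric qPCR value
    are excluded.
    """
    t = load_validation_table() if table is None else table
    t = t[t["qpcr"].notna() & t["microarray"].notna()]
    x = pd.Series(t["microarray"].to_numpy(), index=t["gene"].to_numpy())
    y = t.drop_duplicates("gene")
    y = pd.Series(y["qpcr"].to_numpy(), index=y["gene"].to_numpy())
    return x, y


def validation_direction_inputs(
    table: pd.DataFrame | None = None,
) -> dict[str, pd.Series]:
    """Per-gene platform records of the validation panel.

    Multi-probe genes are collapsed to the sign-preserving mean of their
    signed-log10 microarray values, mapped back to a signed fold change.
    Returns ``{"microarray": ..., "qpcr": ..., "protein": ...}``.
    """
    t = load_validation_table() if table is None else table

    def collapse_micro(group: pd.DataFrame) -> float:
        mean_t = group["microarray"].map(signed_log10).mean()
        return float(np.sign(mean_t) * 10 ** abs(mean_t)) if mean_t != 0 else 1.0

    micro = t.groupby("gene", sort=False).apply(collapse_micro, include_groups=False)
    per_gene = t.drop_duplicates("gene").set_index("gene")
    return {
        "microarray": micro,
        "qpcr": per_gene["qpcr"],
        "protein": per_gene["protein"],
    }
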