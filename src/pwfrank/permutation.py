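"""Permutation null envelopes for PWF-by-rank curves.

To judge whether the observed PWF ranking carries more signal than
chance, the sample labels are permuted many times (default 500); for
each permutation the per-term F statistics and PWF are recomputed and
sorted descending, giving one null curve of PWF against rank position.
The envelope aggregates these curves rank-wise: the mean and the
empirical 95th percentile (nearest-rank) at each rank.  An observed
curve lying above the 95th-percentile curve over a long prefix of ranks
indicates genuine factor-specific structure; on exchangeable null data
the observed curve exceeds the envelope at about 5% of ranks.

Labels are permuted *within* experiment blocks so the block structure
the random effect conditions on is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import TERMS, fit_all_transcripts
from .ranking import pwf_from_f

__all__ = [
    "permute_design",
    "build_envelope",
    "summarize_exceedance",
    "PermutationEnvelope",
]


@dataclass
class PermutationEnvelope:
    """Rank-wise null summary of PWF curves, one frame per term.

    ``curves[term]`` has columns ``rank``, ``mean_pwf``, ``pct95_pwf``
    (non-increasing in rank, inherited from the sorted null curves).
    """

    curves: dict[str, pd.DataFrame]
    n_permutations: int
    seed: int
    n_degenerate_redraws: int = 0
    fit_method: str = "blocked"

    def __post_init__(self) -> None:
        if self.n_permutations < 2:
            raise ValueError("n_permutations must be >= 2")


def permute_design(design: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Permute (sorted, treatment) label pairs within each experiment block.

    The multiset of label pairs within every block -- and the experiment
    assignment itself -- is conserved; a single-sample block is left
    unchanged (its only arrangement).
    """
    out = design.copy()
    for _, idx in design.groupby("experiment", observed=True).groups.items():
        idx = list(idx)
        perm = rng.permutation(len(idx))
        out.loc[idx, ["sorted", "treatment"]] = (
            design.loc[idx, ["sorted", "treatment"]].to_numpy()[perm]
        )
    return out


def _design_complete(design: pd.DataFrame) -> bool:
    return design.groupby(["sorted", "treatment"], observed=True).ngroups == 4


def build_envelope(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    n_permutations: int = 500,
    seed: int = 0,
    fit_method: str = "blocked",
) -> PermutationEnvelope:
    """Build per-term permutation envelopes of the PWF-by-rank curve.

    Permutations that leave a (sorted, treatment) cell unpopulated
    globally are rejected and redrawn (counted in the result).  The
    95th percentile is the nearest-rank empirical quantile, avoiding
    interpolation ambiguity.
    """
    if n_permutations < 2:
        raise ValueError("n_permutations must be >= 2")
    design = design.loc[expr.columns]
    rng = np.random.default_rng(seed)
    n_genes = expr.shape[0]
    store = {t: np.empty((n_permutations, n_genes), dtype=np.float32) for t in TERMS}

    redraws = 0
    for b in range(n_permutations):
        while True:
            permuted = permute_design(design, rng)
            if _design_complete(permuted):
                break
            redraws += 1
        stats_b = fit_all_transcripts(expr, permuted, method=fit_method)
        ok = ~stats_b["degenerate"].to_numpy(dtype=bool)
        f = stats_b[[f"F_{t}" for t in TERMS]].to_numpy(dtype=float)[ok]
        pwf = pwf_from_f(f)
        for j, term in enumerate(TERMS):
            curve = np.sort(pwf[:, j])[::-1]
            padded = np.concatenate([curve, np.zeros(n_genes - len(curve))])
            store[term][b] = padded

    k95 = int(np.ceil(0.95 * n_permutations)) - 1  # nearest-rank index
    curves = {}
    for term in TERMS:
        mat = store[term]
        mean = mat.mean(axis=0, dtype=np.float64)
        pct95 = np.sort(mat, axis=0)[k95].astype(np.float64)
        curves[term] = pd.DataFrame(
            {
                "rank": np.arange(1, n_genes + 1),
                "mean_pwf": mean,
                "pct95_pwf": pct95,
            }
        )
    return PermutationEnvelope(
        curves=curves,
        n_permutations=n_permutations,
        seed=seed,
        n_degenerate_redraws=redraws,
        fit_method=fit_method,
    )


def summarize_exceedance(
    observed: pd.DataFrame, envelope_curve: pd.DataFrame
) -> dict[str, int]:
    """Compare an observed PWF ranking against one term's envelope curve.

    Returns the number of rank positions where the observed PWF strictly
    exceeds the 95th-percentile curve, and the length of the contiguous
    run of exceedances starting at rank 1.
    """
    obs = (
        observed[observed["rank"].notna()]
        .sort_values("rank")["pwf"]
        .to_numpy(dtype=float)
    )
    env = envelope_curve.sort_values("rank")["pct95_pwf"].to_numpy(dtype=float)
    if len(obs) != len(env):
        raise ValueError(
            f"rank count mismatch: observed {len(obs)}, envelope {len(env)}"
        )
    exceed = obs > env
    run = 0
    for flag in exceed:
        if not flag:
            break
        run += 1
    return {"n_exceed": int(exceed.sum()), "contiguous_from_top": run}
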