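"""Synthetic factorial expression data with ground truth.

Emulates a sorted-cell microarray study design: a 2x2 factorial
(sorted status x culture treatment) replicated across independent
experiments, with one array per condition cell per experiment.  Gene
effects are attributable to exactly one of four classes -- ``sorted``,
``treatment``, ``interaction`` or ``null`` -- on the log2 scale, with a
shared additive per-experiment intercept and Gaussian noise.

The generator is the test bed for the ranking / enrichment pipeline:
every dataset carries a :class:`SyntheticTruth` so recovery can be
scored against the generating model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "GeneSetCatalog",
    "simulate_expression",
    "simulate_gene_sets",
    "simulate_ct_table",
]

EFFECT_CLASSES = ("sorted", "treatment", "interaction", "null")
SORTED_LEVELS = ("pos", "neg")
TREATMENT_LEVELS = ("treated", "untreated")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the factorial expression simulation.

    Defaults reproduce the study conditions the pipeline targets: three
    independent experiments, one array per 2x2 condition cell (12 samples),
    log2-scale effects of about 2 units on a RMA-like baseline near 7, and
    modest experiment-to-experiment and residual noise.

    Parameters
    ----------
    n_genes
        Number of simulated genes.
    n_experiments
        Independent experiment blocks; each contributes all four
        condition cells.
    proportions
        Fraction of genes in the ``sorted``, ``treatment`` and
        ``interaction`` effect classes (in that order).  The remainder
        are null genes.
    effect_mean, effect_sd
        Mean and spread (log2 units) of the absolute effect size of a
        non-null gene; either scalars applied to all classes or
        per-class mappings.  Signs are random per gene.
    experiment_sd
        SD (log2 units) of the shared additive per-experiment intercept.
    noise_sd
        Residual Gaussian SD (log2 units).
    baseline_mean
        Grand mean of the log2 intensities.
    seed
        RNG seed; identical configs with identical seeds give
        byte-identical outputs.
    """

    n_genes: int
    n_experiments: int = 3
    proportions: tuple[float, float, float] = (0.10, 0.05, 0.02)
    effect_mean: float | Mapping[str, float] = 2.0
    effect_sd: float | Mapping[str, float] = 0.25
    experiment_sd: float = 0.25
    noise_sd: float = 0.25
    baseline_mean: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_experiments < 2:
            raise ConfigurationError("n_experiments must be >= 2")
        p = self.proportions
        if len(p) != 3 or any(x < 0 for x in p) or sum(p) > 1 + 1e-12:
            raise ConfigurationError(
                "proportions must be 3 non-negative fractions summing to <= 1"
            )
        for name in ("experiment_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def class_effect(self, cls: str) -> tuple[float, float]:
        """(mean, sd) of the absolute effect size for an effect class."""
        mean = self.effect_mean[cls] if isinstance(self.effect_mean, Mapping) else self.effect_mean
        sd = self.effect_sd[cls] if isinstance(self.effect_sd, Mapping) else self.effect_sd
        return float(mean), float(sd)


@dataclass
class SyntheticTruth:
    """Generating-model ground truth for a simulated dataset.

    ``genes`` has one row per gene (``effect_class``, signed
    ``effect_size`` in log2 units); ``sets`` is filled in by
    :func:`simulate_gene_sets` with the per-set enrichment label.
    """

    genes: pd.DataFrame
    sets: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["enriched", "target_class"])
    )

    def genes_of_class(self, cls: str) -> list[str]:
        return list(self.genes.index[self.genes["effect_class"] == cls])


@dataclass
class GeneSetCatalog:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def _design_frame(n_experiments: int) -> pd.DataFrame:
    rows = []
    for e in range(1, n_experiments + 1):
        for s in SORTED_LEVELS:
            for t in TREATMENT_LEVELS:
                rows.append(
                    {
                        "sample": f"E{e}_{s}_{t}",
                        "experiment": f"E{e}",
                        "sorted": s,
                        "treatment": t,
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def simulate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw an expression matrix, its sample design and the ground truth.

    Value model, per gene g and sample in experiment e with factor
    levels (s, t)::

        y = baseline + b_e + fixed(g; s, t) + N(0, noise_sd)

    where ``b_e ~ N(0, experiment_sd)`` is shared by all genes on the
    arrays of experiment e, and ``fixed`` applies the gene's signed
    effect: sorted genes get +/- effect/2 by sorted level, treatment
    genes by treatment level, and interaction genes receive the full
    effect in the (pos, treated) cell only -- the "contrast of treatment
    effect between subpopulations" pattern.

    Returns
    -------
    (expr, design, truth)
        ``expr`` is a genes x samples DataFrame of log2 intensities,
        ``design`` the per-sample factor sheet, ``truth`` the
        generating-model labels.
    """
    rng = np.random.default_rng(config.seed)
    design = _design_frame(config.n_experiments)
    n_samples = len(design)
    n = config.n_genes

    counts = [int(round(p * n)) for p in config.proportions]
    while sum(counts) > n:  # rounding overshoot
        counts[int(np.argmax(counts))] -= 1
    classes = np.array(
        ["sorted"] * counts[0]
        + ["treatment"] * counts[1]
        + ["interaction"] * counts[2]
        + ["null"] * (n - sum(counts))
    )
    rng.shuffle(classes)

    width = max(5, len(str(n)))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, n + 1)]

    effects = np.zeros(n)
    for cls in ("sorted", "treatment", "interaction"):
        mask = classes == cls
        if not mask.any():
            continue
        mean, sd = config.class_effect(cls)
        mag = np.abs(rng.normal(mean, sd, mask.sum()))
        sign = rng.choice([-1.0, 1.0], mask.sum())
        effects[mask] = sign * mag

    exp_intercepts = rng.normal(0.0, config.experiment_sd, config.n_experiments)
    exp_index = design["experiment"].map(
        {f"E{e + 1}": e for e in range(config.n_experiments)}
    ).to_numpy()
    s_half = np.where(design["sorted"].to_numpy() == "pos", 0.5, -0.5)
    t_half = np.where(design["treatment"].to_numpy() == "treated", 0.5, -0.5)
    pos_treated = ((s_half > 0) & (t_half > 0)).astype(float)

    fixed = np.zeros((n, n_samples))
    fixed[classes == "sorted"] = np.outer(effects[classes == "sorted"], s_half)
    fixed[classes == "treatment"] = np.outer(effects[classes == "treatment"], t_half)
    fixed[classes == "interaction"] = np.outer(
        effects[classes == "interaction"], pos_treated
    )

    values = (
        config.baseline_mean
        + exp_intercepts[exp_index][None, :]
        + fixed
        + rng.normal(0.0, config.noise_sd, (n, n_samples))
    )

    expr = pd.DataFrame(values, index=gene_ids, columns=design.index)
    truth = SyntheticTruth(
        genes=pd.DataFrame(
            {"effect_class": classes, "effect_size": effects}, index=gene_ids
        )
    )
    return expr, design, truth


def simulate_gene_sets(
    truth: SyntheticTruth,
    n_sets: int,
    set_size: int,
    n_enriched: int,
    seed: int,
    target_class: str = "sorted",
    enriched_fraction: float = 0.8,
) -> GeneSetCatalog:
    """Draw a gene-set catalog; the first ``n_enriched`` sets are planted.

    Enriched sets draw ``enriched_fraction`` of their members (at least
    half) from genes of ``target_class``; the remaining sets are uniform
    draws over all genes.  Membership labels are recorded in
    ``truth.sets``.
    """
    if n_enriched > n_sets:
        raise ConfigurationError("n_enriched cannot exceed n_sets")
    if enriched_fraction < 0.5 or enriched_fraction > 1:
        raise ConfigurationError("enriched_fraction must be in [0.5, 1]")
    universe = np.array(truth.genes.index)
    if set_size > len(universe):
        raise ConfigurationError("set_size cannot exceed the number of genes")
    class_pool = np.array(truth.genes_of_class(target_class))

    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    labels = []
    for i in range(1, n_sets + 1):
        name = f"SET{i:04d}"
        enriched = i <= n_enriched
        if enriched:
            k_cls = min(math.ceil(enriched_fraction * set_size), len(class_pool))
            if k_cls < math.ceil(0.5 * set_size):
                raise ConfigurationError(
                    f"not enough {target_class}-class genes to plant an enriched set"
                )
            members = list(rng.choice(class_pool, k_cls, replace=False))
            rest = np.setdiff1d(universe, members, assume_unique=False)
            members += list(rng.choice(rest, set_size - k_cls, replace=False))
        else:
            members = list(rng.choice(universe, set_size, replace=False))
        sets[name] = members
        labels.append(
            {
                "set": name,
                "enriched": enriched,
                "target_class": target_class if enriched else "",
            }
        )
    truth.sets = pd.DataFrame(labels).set_index("set")
    return GeneSetCatalog(
        sets=sets,
        descriptions={name: ("planted" if lab["enriched"] else "background")
                      for name, lab in zip(sets, labels)},
    )


def simulate_ct_table(
    fold_changes: Mapping[str, float] | Sequence[tuple[str, float]],
    reference_gene: str = "GAPDH",
    base_ct: float = 20.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    condition: str = "pos",
    reference_condition: str = "neg",
) -> pd.DataFrame:
    """Build a qPCR Ct table realizing requested signed fold changes.

    Under the exact-doubling assay model, a relative quantity RQ between
    ``condition`` and ``reference_condition`` corresponds to
    delta-delta-Ct = -log2(RQ).  With ``noise_sd == 0`` the concordance
    module recovers each requested fold change exactly.

    Signed convention: FC >= +1 means RQ = FC; FC <= -1 means
    RQ = 1/|FC|.  Values in (-1, 1) are rejected.
    """
    items = list(fold_changes.items()) if isinstance(fold_changes, Mapping) else list(fold_changes)
    rng = np.random.default_rng(seed)
    rows = [
        {"gene": reference_gene, "condition": cond, "ct": base_ct + rng.normal(0, noise_sd)}
        for cond in (reference_condition, condition)
    ]
    for gene, fc in items:
        if abs(fc) < 1:
            raise ValueError(
                f"signed fold change for {gene!r} must satisfy |FC| >= 1, got {fc}"
            )
        rq = fc if fc > 0 else 1.0 / abs(fc)
        ddct = -math.log2(rq)
        # gene Ct in the reference condition sits 3 cycles above the
        # reference gene; the condition Ct realizes the requested ddCt
        ct_ref_cond = base_ct + 3.0
        rows.append(
            {
                "gene": gene,
                "condition": reference_condition,
                "ct": ct_ref_cond + rng.normal(0, noise_sd),
            }
        )
        rows.append(
            {
                "gene": gene,
                "condition": condition,
                "ct": ct_ref_cond + ddct + rng.normal(0, noise_sd),
            }
        )
    return pd.DataFrame(rows)
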