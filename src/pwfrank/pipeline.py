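"""End-to-end pipeline: rank -> permutation test -> CERNO -> DSM.

`run_all` binds the stages over files on disk and writes a manifest of
every output with content hashes; identical config and seed give an
identical manifest, which is the pipeline's reproducibility contract.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .cerno import cerno_test, select_for_dsm
from .dsm import EmptySelectionError, build_membership, order_dsm
from .model import TERMS, fit_all_transcripts
from .permutation import build_envelope, summarize_exceedance
from .ranking import compute_pwf, differential_mirna

logger = logging.getLogger("pwfrank")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (YAML-mappable)."""

    expression: str
    design: str
    out_dir: str
    gmt: str | None = None
    terms: tuple[str, ...] = TERMS
    fit_method: str = "mixed"
    n_permutations: int = 500
    set_q_max: float = 1e-4
    gene_quantile_max: float = 0.01
    fold_threshold: float = 2.0
    p_threshold: float = 1e-4
    phospho_threshold_pct: float = 20.0
    seed: int = 0
    run_permtest: bool = True
    run_cerno: bool = True
    run_dsm: bool = True
    run_mirna: bool = False
    dsm_term: str = "sorted"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "terms" in raw:
            raw["terms"] = tuple(raw["terms"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute the configured stages; return the output manifest.

    Any stage failure is re-raised annotated with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stage = "setup"
    try:
        stage = "read-inputs"
        expr = pio.read_expression_tsv(config.expression)
        design = pio.read_design_tsv(config.design)
        if config.run_cerno and config.gmt is None:
            raise ValueError("cerno stage enabled but no GMT catalog configured")

        stage = "rank"
        logger.info("rank: %d genes, %d samples, method=%s, seed=%d",
                    *expr.shape, config.fit_method, config.seed)
        stats = fit_all_transcripts(expr, design, method=config.fit_method)
        rankings = compute_pwf(stats)
        for term in config.terms:
            path = out_dir / f"ranking_{term}.tsv"
            pio.write_table_tsv(rankings[term], path, f"ranking-{term}",
                                index_label="gene")
            outputs.append(path)

        if config.run_mirna:
            stage = "mirna"
            mirna = differential_mirna(
                expr, design,
                fold_threshold=config.fold_threshold,
                p_threshold=config.p_threshold,
            )
            path = out_dir / "mirna_results.tsv"
            pio.write_table_tsv(mirna, path, "mirna", index_label="mirna")
            outputs.append(path)

        if config.run_permtest:
            stage = "permtest"
            logger.info("permtest: %d permutations, seed=%d",
                        config.n_permutations, config.seed)
            env = build_envelope(
                expr, design,
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            rows = []
            for term in config.terms:
                path = out_dir / f"envelope_{term}.tsv"
                pio.write_table_tsv(env.curves[term], path,
                                    f"envelope-{term}", index=False)
                outputs.append(path)
                summary = summarize_exceedance(rankings[term], env.curves[term])
                rows.append({"term": term, **summary})
            path = out_dir / "exceedance_summary.tsv"
            pio.write_table_tsv(pd.DataFrame(rows), path, "exceedance",
                                index=False)
            outputs.append(path)

        selection = None
        if config.run_cerno:
            stage = "cerno"
            catalog = pio.read_gmt(config.gmt)
            results = cerno_test(rankings[config.dsm_term], catalog)
            path = out_dir / f"cerno_{config.dsm_term}.tsv"
            pio.write_table_tsv(results, path, "cerno", index_label="set")
            outputs.append(path)
            sel_sets, sel_genes = select_for_dsm(
                results, rankings[config.dsm_term], catalog,
                set_q_max=config.set_q_max,
                gene_quantile_max=config.gene_quantile_max,
            )
            selection = (sel_sets, sel_genes, catalog)
            path = out_dir / "selection.tsv"
            pio.write_table_tsv(
                pd.DataFrame(
                    [{"kind": "set", "id": s} for s in sel_sets]
                    + [{"kind": "gene", "id": g} for g in sel_genes]
                ),
                path, "selection", index=False,
            )
            outputs.append(path)

        if config.run_dsm and selection is not None:
            stage = "dsm"
            sel_sets, sel_genes, catalog = selection
            if sel_sets and sel_genes:
                matrix = order_dsm(build_membership(sel_sets, sel_genes, catalog))
                path = out_dir / "dsm_membership.tsv"
                pio.write_table_tsv(matrix.ordered, path, "dsm",
                                    index_label="set")
                outputs.append(path)
            else:
                logger.warning("dsm: empty selection, stage skipped")

        stage = "manifest"
        manifest = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()},
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
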