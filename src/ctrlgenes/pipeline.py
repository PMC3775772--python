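"""End-to-end orchestration of the control-gene screen.

``run_screen`` drives the full discovery workflow over one or more
expression datasets:

1. ingest the datasets (or generate a synthetic study),
2. compute a stability table per dataset, plus one for the pooled
   combination of all datasets,
3. select stratified candidates (CV/MFC criteria) in the discovery
   dataset — by convention the FIRST configured dataset, mirroring the
   screen-in-one-cohort / validate-in-the-rest study design,
4. score the candidates across all datasets,
5. compute transcriptome CV quantile curves on the combined matrix, and
6. summarise any user-supplied gene panels.

Everything is written as plain TSV plus one JSON manifest that records
inputs, parameters, package version and seed, so a run can be reproduced
bit for bit. All randomness (synthetic steps only) flows from the
configured seed.

``run_validation`` covers the qPCR side: GeNorm M values for a candidate
panel, RNA-seq/qPCR Spearman concordance per control gene, and RQ spread
statistics for chosen target/control pairs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .genorm import m_values, write_m_values
from .io import CtTable, ExpressionMatrix, combine_datasets, read_matrix
from .qpcr import correlation_validation, rq_panel
from .selection import (
    SelectionCriteria,
    score_across_datasets,
    select_candidates,
    write_scorecard,
)
from .stability import (
    panel_summary,
    quantile_curves,
    stability_table,
    write_quantile_curves,
    write_stability_table,
)

logger = logging.getLogger("ctrlgenes")


@dataclass
class RunConfig:
    """Configuration of one screening run."""

    datasets: list[tuple[str, str]]  # (path, label) pairs
    output_dir: str
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    panels: dict[str, list[str]] = field(default_factory=dict)
    dialect: str = "tab"
    decimal_mark: str = "point"
    quantile_window: int = 2000
    quantile_step: int = 1
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("need at least one dataset")


def _manifest(config, outputs: dict[str, str]) -> dict:
    cfg = dataclasses.asdict(config)
    cfg["criteria"] = dataclasses.asdict(config.criteria)
    manifest = {
        "software": "ctrlgenes",
        "version": __version__,
        "config": cfg,
        "outputs": outputs,
    }
    # normalise tuples to lists so the in-memory dict equals its JSON form
    return json.loads(json.dumps(manifest))


def run_screen(
    config: RunConfig, matrices: list[ExpressionMatrix] | None = None
) -> dict:
    """Run the full screen; returns the manifest dict.

    ``matrices`` may be passed directly (e.g. a synthetic study); when
    None, datasets are read from the configured paths.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    if matrices is None:
        matrices = []
        for path, label in config.datasets:
            logger.info("stage ingest: reading %s (%s)", path, label)
            matrices.append(
                read_matrix(
                    path,
                    dialect=config.dialect,
                    decimal_mark=config.decimal_mark,
                    label=label,
                )
            )
    for m in matrices:
        logger.info(
            "stage ingest: %s has %d genes x %d samples",
            m.label, m.n_genes, m.n_samples,
        )

    tables = []
    for m in matrices:
        t = stability_table(m)
        tables.append(t)
        p = outdir / f"stability_{m.label}.tsv"
        write_stability_table(t, p)
        outputs[f"stability:{m.label}"] = str(p)
    logger.info("stage stability: %d per-dataset tables", len(tables))

    combined = combine_datasets(matrices, label="combined")
    combined_table = stability_table(combined)
    p = outdir / "stability_combined.tsv"
    write_stability_table(combined_table, p)
    outputs["stability:combined"] = str(p)

    discovery = tables[0]
    candidates = {}
    for stratum in ("high", "mid"):
        sel = select_candidates(discovery, config.criteria, stratum)
        candidates[stratum] = sel
        p = outdir / f"candidates_{stratum}.tsv"
        write_stability_table(sel, p)
        outputs[f"candidates:{stratum}"] = str(p)
        logger.info(
            "stage selection (%s): %d candidates from %s",
            stratum, len(sel), discovery.attrs.get("dataset_label"),
        )

    candidate_genes = pd.concat(
        [candidates["high"]["gene"], candidates["mid"]["gene"]]
    ).tolist()
    if candidate_genes:
        scorecard = score_across_datasets(tables, config.criteria, candidate_genes)
        p = outdir / "scorecard.tsv"
        write_scorecard(scorecard, p)
        outputs["scorecard"] = str(p)
        logger.info("stage scoring: %d genes scored", len(scorecard))
    else:
        scorecard = None
        logger.info("stage scoring: skipped, no candidates selected")

    if combined.n_genes >= config.quantile_window:
        curves = quantile_curves(
            combined, window=config.quantile_window, step=config.quantile_step
        )
        p = outdir / "quantile_curves.tsv"
        write_quantile_curves(curves, p)
        outputs["quantile_curves"] = str(p)
    else:
        logger.info(
            "stage quantiles: skipped, %d genes < window %d",
            combined.n_genes, config.quantile_window,
        )

    panel_rows = []
    for name, genes in config.panels.items():
        for t in [*tables, combined_table]:
            s = panel_summary(t, genes)
            panel_rows.append(
                {
                    "panel": name,
                    "dataset": t.attrs.get("dataset_label"),
                    "median_cv": s.median_cv,
                    "cv_min": s.cv_range[0],
                    "cv_max": s.cv_range[1],
                    "median_mfc": s.median_mfc,
                    "mfc_min": s.mfc_range[0],
                    "mfc_max": s.mfc_range[1],
                }
            )
    if panel_rows:
        p = outdir / "panel_summaries.tsv"
        pd.DataFrame(panel_rows).to_csv(p, sep="\t", index=False)
        outputs["panel_summaries"] = str(p)

    manifest = _manifest(config, outputs)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run complete: %d outputs in %s", len(outputs), outdir)
    return manifest


def run_validation(
    matrix: ExpressionMatrix,
    ct: CtTable,
    target: str,
    controls: list[str],
    calibrator_samples: list[str],
    output_dir: str | None = None,
) -> dict:
    """qPCR validation bundle: GeNorm M, concordance rho, RQ spread.

    The Ct table is treated directly as relative quantities for GeNorm via
    the standard efficiency-2 transform; correlation and RQ statistics are
    computed per control gene against ``target``.
    """
    from .genorm import ct_to_quantity

    logger.info("stage genorm: %d genes", len(ct.gene_ids))
    quantities = ct_to_quantity(ct)
    gn = m_values(quantities)

    logger.info("stage correlation: target %s vs %d controls", target, len(controls))
    reports = correlation_validation(matrix, ct, target, controls)

    rq_stats = {}
    for control in controls:
        panel = rq_panel(ct, target, control, calibrator_samples)
        rq_stats[control] = {"cv_percent": panel.cv_percent, "mfc": panel.mfc}

    result = {
        "genorm_m": gn.m_values.to_dict(),
        "correlation": {r.control_gene_id: {"rho": r.rho, "n": r.n} for r in reports},
        "rq": rq_stats,
    }
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_m_values(gn, outdir / "genorm_m.tsv")
        with open(outdir / "validation.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
    return result
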