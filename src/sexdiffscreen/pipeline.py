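"""End-to-end orchestration: harmonize -> screen -> window -> eQTL
annotation -> tissue DE -> single-cell DE -> bulk t-tests, from one YAML
config.

Stages are optional; a partial config runs a partial pipeline.  Every
stage's outputs are written before the next stage begins, and the run
report (JSON) records the package version, thresholds, input digests and
per-stage record counts and top hits, so a run is reproducible from the
report plus the inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError

from . import __version__
from .errors import ConfigurationError, SexdiffError
from .eqtl import annotate_tissues, read_eqtl_table, summarize_annotation
from .gwas_io import extract_window, harmonize_pair, read_gwas_summary, read_snp_panel
from .screen import count_suggestive, screen_panel
from .singlecell import (
    bulk_ttest,
    cell_level_de_all,
    composition_compare,
    expression_compare,
    load_dataset,
    normalize_counts,
    summarize_samples,
)
from .tissue import read_tpm_matrix, sex_anova_per_tissue

logger = logging.getLogger("sexdiffscreen")


class _StageModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GwasStage(_StageModel):
    female: Path
    male: Path
    panel: Path
    ambiguous_policy: str = "keep"
    m_tests: Optional[int] = None


class WindowStage(_StageModel):
    center: str
    width: float = Field(default=1_000_000, gt=0)
    maf_min: float = Field(default=0.05, ge=0, lt=0.5)
    suggestive_p: float = Field(default=1e-3, gt=0, le=1)


class EqtlStage(_StageModel):
    records: Path
    risk_allele_is_effect_allele: bool = True
    m_cutoff: float = Field(default=0.5, ge=0, le=1)


class TissueStage(_StageModel):
    matrix: Path
    attributes: Path
    gene: str
    transform: str = "log2p1"


class SingleCellStage(_StageModel):
    counts: Path
    cells: Path
    genes: Optional[Path] = None
    gene: str
    scale: float = Field(default=10_000, gt=0)
    min_cells: int = Field(default=100, ge=0)
    exclude_low: bool = False


class BulkStage(_StageModel):
    table: Path
    n_tests: Optional[int] = None


class RunConfig(_StageModel):
    """Validated YAML run configuration; every stage is optional."""

    out_dir: Path = Path("sexdiff_out")
    seed: int = 0
    alpha: float = Field(default=0.05, gt=0, lt=1)
    gwas: Optional[GwasStage] = None
    window: Optional[WindowStage] = None
    eqtl: Optional[EqtlStage] = None
    tissue: Optional[TissueStage] = None
    singlecell: Optional[SingleCellStage] = None
    bulk: Optional[BulkStage] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(payload)
        except PydanticValidationError as exc:
            raise ConfigurationError(str(exc)) from exc


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage in order and return the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "inputs": {},
        "stages": {},
    }
    paired = None

    if config.gwas is not None:
        stage = config.gwas
        logger.info("stage gwas: reading and harmonizing summary statistics")
        for key in ("female", "male", "panel"):
            report["inputs"][f"gwas.{key}"] = _digest(getattr(stage, key))
        female = read_gwas_summary(stage.female)
        male = read_gwas_summary(stage.male)
        panel = read_snp_panel(stage.panel)
        paired = harmonize_pair(female, male, ambiguous_policy=stage.ambiguous_policy)
        screen = screen_panel(
            paired, panel, alpha=config.alpha, m_tests=stage.m_tests
        )
        screen.results.to_csv(out / "screen_results.tsv", sep="\t", index=False)
        top = screen.results.head(5)
        report["stages"]["gwas"] = {
            "n_pairs": len(paired),
            "n_dropped_female": len(paired.dropped_female),
            "n_dropped_male": len(paired.dropped_male),
            "n_flipped": paired.n_flipped,
            "m_tests": screen.m_tests,
            "threshold": screen.threshold,
            "n_significant": int(screen.results["significant"].sum()),
            "significant_snps": screen.significant["snp_id"].tolist(),
            "top_hits": top[["snp_id", "delta_z", "p_diff"]].to_dict("records"),
        }

        if config.window is not None:
            w = config.window
            logger.info("stage window: local signals around %s", w.center)
            counts = {}
            for sex in ("female", "male"):
                stratum = paired.stratum(sex)
                win = extract_window(
                    stratum, center=w.center, width=w.width, maf_min=w.maf_min
                )
                win.to_csv(out / f"window_{sex}.tsv", sep="\t", index=False)
                counts[sex] = {
                    "n_records": len(win),
                    "n_suggestive": count_suggestive(win, p_max=w.suggestive_p),
                }
            report["stages"]["window"] = {
                "center": w.center,
                "width": w.width,
                "maf_min": w.maf_min,
                "suggestive_p": w.suggestive_p,
                **counts,
            }
    elif config.window is not None:
        raise ConfigurationError("window stage requires the gwas stage")

    if config.eqtl is not None:
        stage = config.eqtl
        logger.info("stage eqtl: annotating tissues")
        report["inputs"]["eqtl.records"] = _digest(stage.records)
        recs = read_eqtl_table(stage.records)
        annotated = annotate_tissues(
            recs,
            risk_allele_is_effect_allele=stage.risk_allele_is_effect_allele,
            alpha=config.alpha,
            m_cutoff=stage.m_cutoff,
        )
        annotated.to_csv(out / "eqtl_annotated.tsv", sep="\t", index=False)
        report["stages"]["eqtl"] = summarize_annotation(annotated)

    if config.tissue is not None:
        stage = config.tissue
        logger.info("stage tissue: per-tissue sex ANOVA for %s", stage.gene)
        report["inputs"]["tissue.matrix"] = _digest(stage.matrix)
        mat = read_tpm_matrix(stage.matrix, stage.attributes)
        table = sex_anova_per_tissue(
            mat, gene=stage.gene, transform=stage.transform, alpha=config.alpha
        )
        table.to_csv(out / "tissue_sex_anova.tsv", sep="\t", index=False)
        report["stages"]["tissue"] = {
            "gene": stage.gene,
            "n_tissues": len(table),
            "n_tested": int(table.attrs["n_tested"]),
            "threshold": float(table.attrs["threshold"]),
            "significant_adjusted": table.loc[
                table["significant_adjusted"].fillna(False), "tissue"
            ].tolist(),
            "significant_nominal": table.loc[
                table["significant_nominal"].fillna(False), "tissue"
            ].tolist(),
        }

    if config.singlecell is not None:
        stage = config.singlecell
        logger.info("stage singlecell: dual-level DE for %s", stage.gene)
        report["inputs"]["singlecell.counts"] = _digest(stage.counts)
        ds = load_dataset(stage.counts, stage.cells, stage.genes)
        normalize_counts(ds, scale=stage.scale)
        summaries = summarize_samples(
            ds, stage.gene, min_cells=stage.min_cells, exclude_low=stage.exclude_low
        )
        summaries.to_csv(out / "sc_sample_summaries.tsv", sep="\t", index=False)
        expr_cmp = expression_compare(summaries, alpha=config.alpha)
        expr_cmp.to_csv(out / "sc_sample_expression_tukey.tsv", sep="\t", index=False)
        comp_frames = []
        for metric in ("n_cells", "pct_of_sample", "n_expressing", "pct_expressing"):
            comp_frames.append(composition_compare(summaries, metric, alpha=config.alpha))
        comp = pd.concat(comp_frames, ignore_index=True)
        comp.to_csv(out / "sc_composition_tukey.tsv", sep="\t", index=False)
        cell_de = cell_level_de_all(ds, stage.gene, alpha=config.alpha)
        cell_de.to_csv(out / "sc_cell_level_de.tsv", sep="\t", index=False)
        report["stages"]["singlecell"] = {
            "gene": stage.gene,
            "n_cells": ds.n_cells,
            "n_samples": int(ds.adata.obs["sample_id"].nunique()),
            "expressed_cell_types": cell_de.attrs["expressed_cell_types"],
            "n_comparisons": int(cell_de.attrs["n_comparisons"]),
            "cell_level_threshold": float(cell_de.attrs["threshold"]),
            "cell_level_significant": cell_de.loc[
                cell_de["significant"], ["cell_type", "group_a", "group_b"]
            ].to_dict("records"),
            "sample_level_significant": expr_cmp.loc[
                expr_cmp["significant"], ["cell_type", "group_a", "group_b"]
            ].to_dict("records"),
        }

    if config.bulk is not None:
        stage = config.bulk
        logger.info("stage bulk: infected-vs-mock t-tests")
        report["inputs"]["bulk.table"] = _digest(stage.table)
        table = pd.read_csv(stage.table, sep="\t")
        res = bulk_ttest(table, alpha=config.alpha, n_tests=stage.n_tests)
        res.to_csv(out / "bulk_ttests.tsv", sep="\t", index=False)
        report["stages"]["bulk"] = {
            "n_contrasts": len(res),
            "threshold": float(res.attrs["threshold"]),
            "significant_contrasts": res.loc[res["significant"], "contrast"].tolist(),
        }

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def run_from_yaml(path: str | Path) -> dict:
    return run_pipeline(RunConfig.from_yaml(path))
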