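"""End-to-end study pipeline: ingest/simulate → QC → normalize → test →
ROC/panel → pathways, with a single JSON report plus flat TSV side files.

The report is deterministic for a fixed config (including the seed): it
carries a provenance block (config hash, seed, package version) and no
timestamps, so two runs of the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .errors import InsufficientDataError, MirpanelError
from . import pathways as pw
from . import qpcr, roc, simulate
from .groupstats import adjust_pvalues, mann_whitney_u

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class PipelineConfig(BaseModel):
    """Everything a pipeline run needs; exactly one of ``ct_table`` /
    ``cohort`` supplies the input wells."""

    ct_table: Optional[str] = None
    cohort: Optional[simulate.CohortSpec] = None
    spikein_assay: str = simulate.DEFAULT_SPIKEIN_ASSAY
    qc_threshold: float = Field(default=qpcr.DEFAULT_QC_THRESHOLD, gt=0)
    rq_method: str = "pooled"
    p_adjust: str = "none"
    roc_polarity: str = "auto"
    panel_tolerance: float = Field(default=0.01, ge=0)
    targets_path: Optional[str] = None
    genesets_path: Optional[str] = None
    categories_path: Optional[str] = None
    pathway_scope: str = "pooled"
    out_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _one_input(self) -> "PipelineConfig":
        if (self.ct_table is None) == (self.cohort is None):
            raise ValueError("provide exactly one of ct_table or cohort")
        if self.rq_method not in ("pooled", "per_sample_mean"):
            raise ValueError("rq_method must be pooled or per_sample_mean")
        return self

    def config_hash(self) -> str:
        # hash the analysis-relevant fields only: where outputs land and how
        # chattily we log must not change the report bytes
        payload = self.model_dump(exclude={"out_dir", "log_level"})
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _load_records(config: PipelineConfig) -> pd.DataFrame:
    if config.ct_table is not None:
        return qpcr.read_ct_table(config.ct_table)
    spec = config.cohort
    if spec.seed != config.seed:
        spec = spec.model_copy(update={"seed": config.seed})
    return simulate.generate_cohort(spec)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the report dict (also written to
    ``config.out_dir`` when set)."""
    logging.basicConfig(level=config.log_level)
    records = _load_records(config)

    collapsed, qc_exclusions = qpcr.qc_filter_replicates(records, config.qc_threshold)
    expr, spike_drops = qpcr.normalize_to_spikein(collapsed, config.spikein_assay)
    frames = [f for f in (qc_exclusions, spike_drops) if len(f)]
    exclusions = (
        pd.concat(frames, ignore_index=True) if frames
        else qc_exclusions.iloc[0:0].copy()
    )

    marker_names = [a for a in records["assay"].unique() if a != config.spikein_assay]
    marker_section: dict[str, dict] = {}
    excluded_markers: dict[str, str] = {}
    utests = []
    testable: list[str] = []
    for marker in marker_names:
        try:
            comparison = qpcr.relative_quantity(expr, marker, method=config.rq_method)
        except InsufficientDataError as exc:
            excluded_markers[marker] = str(exc)
            continue
        other = "per_sample_mean" if config.rq_method == "pooled" else "pooled"
        alt = qpcr.relative_quantity(expr, marker, method=other)
        sub = expr[expr["marker"] == marker]
        case = sub.loc[sub["group"] == simulate.GROUP_CASE, "delta_ct"].to_numpy()
        control = sub.loc[sub["group"] == simulate.GROUP_CONTROL, "delta_ct"].to_numpy()
        utests.append(mann_whitney_u(case, control, marker=marker))
        testable.append(marker)
        entry = comparison.as_dict()
        entry[f"rq_{other}"] = alt.rq
        entry["ddct_ci95"] = qpcr.delta_delta_ct_interval(expr, marker)
        entry["roc"] = roc.roc_summary(case, control, polarity=config.roc_polarity).as_dict()
        marker_section[marker] = entry

    for res in adjust_pvalues(utests, method=config.p_adjust) if utests else []:
        marker_section[res.marker]["utest"] = res.as_dict()

    panel_section: dict = {}
    if len(testable) >= 1:
        wide = expr[expr["marker"].isin(testable)].pivot_table(
            index=["sample_id", "group"], columns="marker", values="delta_ct"
        ).reset_index()
        labels = wide["group"].to_numpy()
        matrix = wide[testable]
        model, trace = roc.select_panel(
            matrix, labels, tolerance=config.panel_tolerance
        )
        panel_section = {"model": model.as_dict(), "trace": trace}

    pathway_section: dict = {}
    if config.targets_path and config.genesets_path:
        targets = pw.read_target_lists(config.targets_path)
        db = pw.read_gmt(config.genesets_path)
        overlap = pw.target_overlap_summary(targets)
        pooled = pw.pathway_hits(targets, db, scope="pooled")
        per_mirna = pw.pathway_hits(targets, db, scope="per_mirna")
        pathway_section = {
            "overlap": overlap.as_dict(),
            "pooled": {
                "genes_in_pathways": pooled.genes_in_pathways,
                "pathways_hit": pooled.pathways_hit,
                "table": pooled.to_frame().to_dict(orient="records"),
            },
            "per_mirna": {
                m: {
                    "genes_in_pathways": t.genes_in_pathways,
                    "pathways_hit": t.pathways_hit,
                    "table": t.to_frame().to_dict(orient="records"),
                }
                for m, t in per_mirna.items()
            },
        }
        if config.categories_path:
            cats = pw.read_category_map(config.categories_path)
            pathway_section["category_rollup"] = pw.category_rollup(pooled, cats)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
        },
        "n_qc_exclusions": int(len(exclusions)),
        "markers": marker_section,
        "excluded_markers": excluded_markers,
        "panel": panel_section,
        "pathways": pathway_section,
    }
    report = _jsonable(report)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        try:
            (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
            expr.to_csv(out / "delta_ct.tsv", sep="\t", index=False)
            exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
            if marker_section:
                flat = []
                for m, entry in marker_section.items():
                    row = {
                        k: v for k, v in entry.items()
                        if not isinstance(v, (dict, list))
                    }
                    row.update({f"roc_{k}": v for k, v in entry["roc"].items()})
                    if "utest" in entry:
                        row.update({f"utest_{k}": v for k, v in entry["utest"].items()})
                    flat.append(row)
                pd.DataFrame(flat).to_csv(out / "markers.tsv", sep="\t", index=False)
        except Exception:
            # do not leave half-written outputs around
            for name in ("report.json", "delta_ct.tsv", "exclusions.tsv", "markers.tsv"):
                p = out / name
                if p.exists():
                    p.unlink()
            raise
    return report
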