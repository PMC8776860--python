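"""End-to-end orchestration of the paired-slide proximity analysis.

The pipeline mirrors the clinical workflow: per-slide quantification
(densities, frequencies, pairing statistics) -> per-patient pre/post log2
fold-changes -> paired Wilcoxon tests (post vs pre for each metric) ->
Spearman correlation of each fold-change metric with progression-free
survival. The report is a plain dict (JSON-serializable) in which every
number carries the name of the operation that produced it, and a rerun
with the same inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._errors import DegenerateStatisticError, ValidationError
from .io import (DEFAULT_PANEL, PatientPairRecord, SlideCellTable,
                 link_cohort, read_cell_tables, read_clinical_table)
from .proximity import (ANY_RADIUS, FoldChangeRecord, compute_metrics,
                        fold_change_records, metric_names)
from .stats import spearman, wilcoxon_signed_rank

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for the end-to-end run; loadable from YAML/JSON."""

    cell_table_path: str | None = None
    clinical_path: str | None = None
    panel: tuple[str, ...] = DEFAULT_PANEL
    target_marker: str = "SOX10"
    reference_marker: str = "CD8"
    radii: tuple = (45.0, ANY_RADIUS)
    microns_per_pixel: float = 1.0
    pseudocount: float | None = None
    pairing_mode: str = "cells"
    seed: int = 0

    def __post_init__(self) -> None:
        for r in self.radii:
            if r != ANY_RADIUS and not (isinstance(r, (int, float)) and r > 0):
                raise ValidationError(f"radius must be > 0 or 'any': {r!r}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        if "radii" in data:
            data["radii"] = tuple(data["radii"])
        if "panel" in data:
            data["panel"] = tuple(data["panel"])
        return cls(**data)


def run_mxihc_pipeline(
    config: PipelineConfig,
    slides: dict[str, SlideCellTable] | None = None,
    clinical: list[PatientPairRecord] | None = None,
) -> dict:
    """Run the full paired-slide analysis and return the report dict.

    ``slides`` / ``clinical`` may be passed in memory (e.g. from the
    simulator); otherwise they are read from the configured paths.
    """
    if slides is None:
        if config.cell_table_path is None:
            raise ValidationError("no slides given and no cell_table_path set")
        slides = read_cell_tables(config.cell_table_path, config.panel,
                                  config.microns_per_pixel)
    if clinical is None:
        if config.clinical_path is None:
            raise ValidationError("no clinical table given or configured")
        clinical = read_clinical_table(config.clinical_path)
    link_cohort(slides, clinical)

    used_ids = sorted({r.pre_slide_id for r in clinical}
                      | {r.post_slide_id for r in clinical})
    metrics = {
        sid: compute_metrics(slides[sid], config.target_marker,
                             config.reference_marker, config.radii,
                             mode=config.pairing_mode)
        for sid in used_ids
    }
    names = metric_names(config.target_marker, config.radii)
    fcs = fold_change_records(metrics, clinical, names, config.pseudocount)

    report: dict = {
        "config": {
            "target_marker": config.target_marker,
            "reference_marker": config.reference_marker,
            "radii": [str(r) for r in config.radii],
            "pairing_mode": config.pairing_mode,
            "pseudocount": config.pseudocount,
        },
        "per_slide": {
            sid: {
                "density_per_mm2": m.density_per_mm2,
                "frequency_pct": m.frequency_pct,
                "pair_stats": {
                    k: {"paired_count": p.paired_count,
                        "reference_count": p.reference_count,
                        "statistic": p.statistic}
                    for k, p in m.pair_stats.items()},
                "provenance": "compute_metrics",
            } for sid, m in metrics.items()
        },
        "fold_changes": [
            {"patient_id": r.patient_id, "metric": r.metric,
             "pre": r.pre_value, "post": r.post_value, "log2_fc": r.log2_fc,
             "provenance": "log2_fold_change"}
            for r in fcs
        ],
        "wilcoxon_pre_vs_post": {},
        "spearman_fc_vs_pfs": {},
    }

    pfs = {r.patient_id: r.pfs_months for r in clinical}
    by_metric: dict[str, list[FoldChangeRecord]] = {n: [] for n in names}
    for r in fcs:
        by_metric[r.metric].append(r)

    for name in names:
        recs = by_metric[name]
        pre = [r.pre_value for r in recs]
        post = [r.post_value for r in recs]
        entry: dict
        if any(v is None for v in pre + post):
            entry = {"skipped": "undefined pre/post values present"}
        else:
            try:
                w = wilcoxon_signed_rank(pre, post)
                entry = {"statistic": w.statistic, "p_value": w.p_value,
                         "n_used": w.n_used, "method": w.method}
            except DegenerateStatisticError as e:
                entry = {"degenerate": str(e)}
        entry["provenance"] = "wilcoxon_signed_rank"
        report["wilcoxon_pre_vs_post"][name] = entry

        fc = [r.log2_fc for r in recs]
        pfs_v = [pfs[r.patient_id] for r in recs]
        n_excluded = sum(v is None for v in fc)
        try:
            s = spearman(fc, pfs_v)
            centry = {"rho": s.rho, "p_value": s.p_value, "n_used": s.n,
                      "n_excluded": n_excluded, "method": s.method}
        except (DegenerateStatisticError, ValidationError) as e:
            centry = {"skipped": str(e), "n_excluded": n_excluded}
        centry["provenance"] = "spearman"
        report["spearman_fc_vs_pfs"][name] = centry
        if n_excluded:
            logger.info("metric %s: excluded %d undefined fold-changes from "
                        "correlation", name, n_excluded)

    report["digest"] = report_digest(report)
    return report


def report_json(report: dict) -> str:
    """Canonical JSON serialization (sorted keys, fixed separators)."""
    return json.dumps(report, sort_keys=True, indent=2, allow_nan=False,
                      default=_jsonable)


def _jsonable(x):
    import numpy as np
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def report_digest(report: dict) -> str:
    """SHA-256 of the canonical JSON, excluding the digest field itself."""
    body = {k: v for k, v in report.items() if k != "digest"}
    return hashlib.sha256(report_json(body).encode()).hexdigest()


def write_report(report: dict, out_dir) -> None:
    """Write report.json plus flat TSVs of the per-slide metrics and
    per-patient fold-changes."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_json(report) + "\n")

    rows = []
    for sid, m in report["per_slide"].items():
        for marker, v in m["density_per_mm2"].items():
            rows.append({"slide_id": sid, "metric": f"density:{marker}",
                         "value": v})
        for marker, v in m["frequency_pct"].items():
            rows.append({"slide_id": sid, "metric": f"frequency:{marker}",
                         "value": v})
        for r, p in m["pair_stats"].items():
            rows.append({"slide_id": sid, "metric": f"pairstat:{r}",
                         "value": p["statistic"]})
    pd.DataFrame(rows).to_csv(out / "per_slide_metrics.tsv", sep="\t",
                              index=False, lineterminator="\n")
    pd.DataFrame(report["fold_changes"]).to_csv(
        out / "fold_changes.tsv", sep="\t", index=False, lineterminator="\n")
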