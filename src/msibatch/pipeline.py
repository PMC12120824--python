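"""Two-part pipeline orchestration.

Part 1 evaluates intrabatch and interbatch variation from the QCS spots
(CV% grids, Kruskal-Wallis batch tests, outlier-slide flags, drift) and
raises an advisory warning status when outlier slides are detected.
Part 2 applies the configured correction-method grid, re-evaluates each
corrected table with the QCS metrics and the multivariate tissue metrics,
and assembles the method-comparison report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .correction import apply_corrections
from .datamodel import FeatureTable, PipelineConfig
from .multivariate import (
    intergroup_distance,
    intragroup_distance,
    pca_scores,
    plsda_vip,
    qcs_proximity,
    robust_feature_comparison,
)
from .qc import QCReport, cv_percent, qcs_cv_report

__all__ = ["ComparisonReport", "run_part1", "run_part2"]

NA = float("nan")


@dataclass
class ComparisonReport:
    """Method x metric grid plus VIP robustness sets and run metadata."""

    grid: pd.DataFrame  # rows = methods, columns = metrics
    vip_grid: pd.DataFrame | None
    robust_features: list
    dropped_features: list
    qc_reports: dict
    metadata: dict = field(default_factory=dict)

    def grid_csv(self) -> str:
        """Deterministic CSV body of the method grid (fixed float format)."""
        return self.grid.to_csv(float_format="%.6f", lineterminator="\n")

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "comparison_grid.csv").write_text(self.grid_csv())
        if self.vip_grid is not None:
            (out_dir / "vip_grid.csv").write_text(
                self.vip_grid.to_csv(lineterminator="\n")
            )
        (out_dir / "run_metadata.json").write_text(
            json.dumps(
                {
                    **self.metadata,
                    "robust_features": self.robust_features,
                    "dropped_features": self.dropped_features,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


def _config_hash(config: PipelineConfig) -> str:
    data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in config.__dict__.items()}
    blob = yaml.safe_dump(data, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_part1(
    table: FeatureTable,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[QCReport, bool]:
    """Part 1: QCS-based evaluation. Returns (report, clean_flag).

    ``clean_flag`` is False when outlier slides were flagged -- an advisory
    signal to inspect sample preparation/measurement before correction.
    """
    config = config or PipelineConfig()
    if not (table.obs_meta["region_type"] == config.qcs_region).any():
        raise ValueError("table has no QCS observations; Part 1 needs QCS spots")
    if (table.obs_meta["day"].astype(str) == "").any():
        raise ValueError("observations lack day labels (metadata column 'day')")
    report = qcs_cv_report(
        table, config.analyte_feat_id, method="raw", outlier_k=config.outlier_k
    )
    clean = not bool(report.outlier_slides["flagged"].any())
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_frame().to_csv(out_dir / "part1_cv.csv", float_format="%.6f")
        report.per_slide_cv.to_csv(out_dir / "part1_per_slide_cv.csv", float_format="%.6f")
        report.outlier_slides.to_csv(out_dir / "part1_outliers.csv", index=False)
        status = {"outliers_flagged": not clean,
                  "flagged_slides": report.outlier_slides.loc[
                      report.outlier_slides["flagged"], "slide_id"].tolist()}
        (out_dir / "part1_status.json").write_text(json.dumps(status, indent=2) + "\n")
    return report, clean


def _tissue_metrics(table: FeatureTable, vip_threshold: float):
    """PCA distances and median feature CV on the tissue observations."""
    res = pca_scores(table, n_components=2)
    tissue_mask = (table.obs_meta["region_type"] == "tissue").to_numpy()
    groups = table.obs_meta.loc[tissue_mask, "group"].to_numpy()
    t_scores = res.scores[tissue_mask]
    _, intra = intragroup_distance(t_scores, groups)
    _, inter = intergroup_distance(t_scores, groups)
    tissue = table.tissue_only()
    feat_cv = []
    for j, role in enumerate(tissue.feat_meta["role"]):
        if role != "tissue_feature":
            continue
        vals = tissue.intensities[:, j]
        if len(vals) >= 2 and vals.mean() != 0:
            feat_cv.append(cv_percent(vals))
    median_cv = float(np.median(feat_cv)) if feat_cv else NA
    vip = plsda_vip(tissue, threshold=vip_threshold)
    return intra, inter, median_cv, vip


def run_part2(
    table: FeatureTable,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    skip_part1: bool = False,
) -> ComparisonReport:
    """Part 2: apply the method grid and evaluate each cell pre/post.

    Every configured method yields one grid row with the QCS intraday/
    interday CVs, the QCS PCA-proximity distance, the tissue intragroup/
    intergroup distances, the median tissue-feature CV and the VIP
    selection; per-cell failures are recorded, the rest of the grid
    completes.  The IS row's full-feature metrics are not applicable
    (IS normalization transforms only the analyte) and are reported NA.
    """
    config = config or PipelineConfig()
    if not skip_part1:
        run_part1(table, config)

    methods = ["raw"] + [m for m in config.methods if m != "raw"]
    results = apply_corrections(
        table,
        methods,
        batch_key=config.batch_key,
        order_key=config.order_key,
        analyte_feat=config.analyte_feat_id,
        is_feat=config.is_feat_id,
        method_params=dict(config.method_params),
        random_state=config.seed,
    )

    rows = {}
    vip_by_method = {}
    qc_reports = {}
    failures = {}
    day_levels = [str(d) for d in pd.unique(table.obs_meta["day"])]
    for res in results:
        label = res.method
        row = {}
        try:
            qc = qcs_cv_report(
                res.table, config.analyte_feat_id, method=label, outlier_k=config.outlier_k
            )
            qc_reports[label] = qc
            for d in day_levels:
                row[f"intraday_{d}_cv"] = qc.per_day_cv.get(d, NA)
            row["interday_cv"] = qc.interday_cv
            if res.table.provenance == "is":
                # full-feature metrics undefined: only the analyte was ratioed
                row["pca_distance"] = NA
                row["tissue_intragroup"] = NA
                row["tissue_intergroup"] = NA
                row["tissue_median_cv"] = NA
            else:
                row["pca_distance"] = qcs_proximity(res.table)
                intra, inter, med_cv, vip = _tissue_metrics(
                    res.table, config.vip_threshold
                )
                row["tissue_intragroup"] = intra
                row["tissue_intergroup"] = inter
                row["tissue_median_cv"] = med_cv
                vip_by_method[label] = vip
        except Exception as exc:  # per-cell failure: record, keep going
            failures[label] = f"{type(exc).__name__}: {exc}"
            row = {c: NA for c in row} or {"interday_cv": NA}
        rows[label] = row
    grid = pd.DataFrame.from_dict(rows, orient="index")

    vip_grid = None
    robust: list = []
    dropped: list = []
    if len(vip_by_method) >= 2:
        vip_grid = robust_feature_comparison(vip_by_method, raw_method="raw")
        robust = list(vip_grid.index[vip_grid["robust"]])
        if "dropped" in vip_grid.columns:
            dropped = list(vip_grid.index[vip_grid["dropped"]])

    report = ComparisonReport(
        grid=grid,
        vip_grid=vip_grid,
        robust_features=robust,
        dropped_features=dropped,
        qc_reports=qc_reports,
        metadata={
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "methods": list(methods),
            "failures": failures,
            "n_obs": table.n_obs,
            "n_feat": table.n_feat,
        },
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
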