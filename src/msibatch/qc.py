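"""Part 1 of the pipeline: QCS-based batch-effect evaluation.

Quantifies intraday and interday variation of the QCS analyte via CV%,
tests batch differences with the Kruskal-Wallis rank test, flags outlier
slides with a robust MAD rule, and profiles acquisition-order drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import FeatureTable

__all__ = [
    "QCReport",
    "cv_percent",
    "qcs_cv_report",
    "kruskal_wallis_batch_test",
    "detect_outlier_slides",
    "drift_profile",
    "DriftProfile",
]

#: explicit not-available marker used in CV grids (never a silent drop)
NA = float("nan")


def cv_percent(values) -> float:
    """Coefficient of variation as a percentage: 100 * sd / mean.

    Sample standard deviation (denominator n-1).  Requires at least two
    values and a nonzero mean.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("cv_percent requires >= 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("cv_percent undefined for zero mean")
    return 100.0 * values.std(ddof=1) / mean


def _cv_or_na(values) -> float:
    values = np.asarray(values, dtype=float)
    if len(values) < 2 or values.mean() == 0:
        return NA
    return cv_percent(values)


@dataclass
class QCReport:
    """Per-batch-level variation summary for one method/normalization.

    Machine twin of the printed intraday/interday CV grid: per-day,
    per-slide and per-slide-row CV% of the QCS analyte, Kruskal-Wallis
    batch-difference tests, flagged outlier slides and the acquisition
    drift summary.
    """

    method: str
    analyte_feat: str
    per_day_cv: pd.Series
    per_slide_cv: pd.Series
    per_row_cv: pd.Series
    interday_cv: float
    kw_interday: tuple[float, float]
    kw_intraday: dict[str, tuple[float, float]]
    outlier_slides: pd.DataFrame
    drift: "DriftProfile"

    def to_frame(self) -> pd.DataFrame:
        """One-row frame in the printed-table shape (intraday CVs then interday)."""
        row = {f"intraday_{d}_cv": v for d, v in self.per_day_cv.items()}
        row["interday_cv"] = self.interday_cv
        row["kw_interday_p"] = self.kw_interday[1]
        return pd.DataFrame([row], index=[self.method])


def kruskal_wallis_batch_test(values, labels) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H test of batch differences.

    Returns ``(H, p)`` with p from the chi-square approximation on k-1
    degrees of freedom.  Degenerate total-tie input (every value equal)
    is defined as no evidence of difference: ``(0.0, 1.0)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def detect_outlier_slides(
    table: FeatureTable, analyte_feat: str, k: float = 3.5
) -> pd.DataFrame:
    """Flag slides whose QCS analyte level deviates robustly from the rest.

    Per-slide medians of the QCS analyte are taken on the log scale
    (intensities are multiplicative) and centered on their day cohort's
    median, so that ordinary day-level batch shifts do not mask a
    within-day slide anomaly (the matrix-sprayer failure mode).  Slide s
    is flagged when ``|centered_s| / (1.4826 * MAD(centered)) > k``.
    If the MAD is zero (all but possibly one slide identical) the rule
    falls back to flagging any slide whose centered median differs
    exactly from zero.

    Returns a frame with columns ``slide_id``, ``score``, ``flagged``.
    """
    qcs = table.qcs_only()
    values = qcs.feature_values(analyte_feat)
    slides = qcs.obs_meta["slide_id"].to_numpy()
    slide_ids = pd.unique(slides)
    if len(slide_ids) < 3:
        raise ValueError("outlier rule undefined for < 3 slides")
    if (values <= 0).any():
        raise ValueError("outlier rule requires positive analyte intensities")
    day_of_slide = {
        s: qcs.obs_meta.loc[(slides == s), "day"].iloc[0] for s in slide_ids
    }
    medians = pd.Series(
        [np.median(np.log(values[slides == s])) for s in slide_ids], index=slide_ids
    )
    day_center = medians.groupby(pd.Series(day_of_slide)).median()
    centered = np.array(
        [medians[s] - day_center[day_of_slide[s]] for s in slide_ids]
    )
    mad = np.median(np.abs(centered - np.median(centered))) * 1.4826
    if mad == 0:
        flagged = centered != 0
        scores = np.where(flagged, np.inf, 0.0)
    else:
        scores = np.abs(centered - np.median(centered)) / mad
        flagged = scores > k
    return pd.DataFrame(
        {"slide_id": slide_ids, "score": scores, "flagged": flagged}
    )


@dataclass
class DriftProfile:
    """Mean analyte intensity versus acquisition order, with drift summaries."""

    order: np.ndarray
    values: np.ndarray
    slope: float  # least-squares slope of intensity vs order
    log_slope: float  # slope of log-intensity vs order (multiplicative drift)
    per_slide_contrast: pd.Series  # mean(QCS after tissue) - mean(QCS before)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"measurement_order": self.order, "value": self.values})


def drift_profile(table: FeatureTable, analyte_feat: str) -> DriftProfile:
    """Profile acquisition drift of the QCS analyte.

    Returns the QCS analyte intensity versus global measurement order, the
    least-squares drift slope (raw and log scale), and a per-slide paired
    contrast: mean of QCS spots acquired after the slide's tissue regions
    minus mean of those acquired before (NA when a slide lacks one side).
    """
    qcs = table.qcs_only()
    if qcs.n_obs == 0:
        raise ValueError("no QCS observations")
    order = qcs.obs_meta["measurement_order"].to_numpy()
    values = qcs.feature_values(analyte_feat)
    idx = np.argsort(order)
    order, values = order[idx], values[idx]
    slope = float(np.polyfit(order, values, 1)[0]) if len(order) > 1 else 0.0
    if (values > 0).all() and len(order) > 1:
        log_slope = float(np.polyfit(order, np.log(values), 1)[0])
    else:
        log_slope = NA

    tissue = table.tissue_only()
    contrasts = {}
    for slide in pd.unique(qcs.obs_meta["slide_id"]):
        q_mask = (qcs.obs_meta["slide_id"] == slide).to_numpy()
        q_order = qcs.obs_meta.loc[q_mask, "measurement_order"].to_numpy()
        q_vals = qcs.feature_values(analyte_feat)[q_mask]
        t_order = tissue.obs_meta.loc[
            tissue.obs_meta["slide_id"] == slide, "measurement_order"
        ].to_numpy()
        if len(t_order) == 0 or len(q_order) < 2:
            contrasts[slide] = NA
            continue
        before = q_vals[q_order < t_order.min()]
        after = q_vals[q_order > t_order.max()]
        if len(before) == 0 or len(after) == 0:
            contrasts[slide] = NA
        else:
            contrasts[slide] = float(after.mean() - before.mean())
    return DriftProfile(order, values, slope, log_slope, pd.Series(contrasts))


def qcs_cv_report(
    table: FeatureTable,
    analyte_feat: str,
    method: str = "raw",
    outlier_k: float = 3.5,
) -> QCReport:
    """Build the full Part-1 QC report for one method/normalization.

    Intraday CV% pools all QCS analyte values of a day across that day's
    slides; interday CV% pools the whole experiment.  Per-slide and
    per-row CVs are reported alongside (the slide-row breakdown exists
    only when the layout declares ``row_id``).  Grouping levels with
    fewer than two observations are reported as NA, never dropped.
    """
    qcs = table.qcs_only()
    if qcs.n_obs == 0:
        raise ValueError("no QCS observations in table")
    values = qcs.feature_values(analyte_feat)
    meta = qcs.obs_meta
    days = meta["day"].to_numpy()
    for day in pd.unique(days):
        if (days == day).sum() < 2:
            raise ValueError(f"day {day!r} has < 2 QCS observations")

    per_day = pd.Series(
        {d: _cv_or_na(values[days == d]) for d in pd.unique(days)}, name="cv"
    )
    slides = meta["slide_id"].to_numpy()
    per_slide = pd.Series(
        {s: _cv_or_na(values[slides == s]) for s in pd.unique(slides)}, name="cv"
    )
    rows = meta["row_id"].astype(str).to_numpy()
    row_levels = [r for r in pd.unique(rows) if r != ""]
    per_row = pd.Series(
        {r: _cv_or_na(values[rows == r]) for r in row_levels},
        name="cv",
        dtype=float,
    )
    interday = cv_percent(values)

    if len(pd.unique(days)) >= 2:
        kw_inter = kruskal_wallis_batch_test(values, days)
    else:
        kw_inter = (NA, NA)
    kw_intra = {}
    for d in pd.unique(days):
        mask = days == d
        if len(pd.unique(slides[mask])) >= 2:
            kw_intra[d] = kruskal_wallis_batch_test(values[mask], slides[mask])
        else:
            kw_intra[d] = (NA, NA)

    if len(pd.unique(slides)) >= 3 and (values > 0).all():
        outliers = detect_outlier_slides(table, analyte_feat, k=outlier_k)
    else:
        outliers = pd.DataFrame(columns=["slide_id", "score", "flagged"])

    drift = drift_profile(table, analyte_feat)
    return QCReport(
        method=method,
        analyte_feat=analyte_feat,
        per_day_cv=per_day,
        per_slide_cv=per_slide,
        per_row_cv=per_row,
        interday_cv=interday,
        kw_interday=kw_inter,
        kw_intraday=kw_intra,
        outlier_slides=outliers,
        drift=drift,
    )
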