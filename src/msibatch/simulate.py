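"""Synthetic batch-experiment generator with ground truth.

Emulates the statistical structure of a multi-day MALDI-MSI batch
experiment: 3 tissue groups x 6 replicate slides measured over 3 days
(six slides per day, slide order randomized within day), six QCS spots
per slide surrounding a few tissue regions, ~200 tissue features plus the
QCS analyte (propranolol) and its internal standard (propranolol-d7).

Intensity model (log scale, natural log):

    log x_of = mu_{g(o), f} + b_{s(o)} + c_{d(o)} + beta_f * order(o)
               + u_{s(o)} * 1[outlier slide] + eps_of

with log-normal slide effects b_s ~ N(0, sigma_slide^2), day effects
c_d ~ N(0, sigma_day^2), per-feature acquisition drift beta_f on the
"lipid-like" features (m/z > 700), a designated outlier slide attenuated
by u (the matrix-sprayer failure mode), and independent residual noise
eps ~ N(0, sigma_resid^2).  QCS spots share b, c and u with their slide;
the internal standard shares every slide/day/outlier factor with the
analyte but has its own residual, so the analyte/IS ratio cancels all
shared multiplicative structure exactly and its CV depends only on the
residual sigma.

Everything is reproducible bit-exactly from (config, seed) and the
realized effects are returned as :class:`SyntheticTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    FeatureTable,
    ROLE_ANALYTE,
    ROLE_INTERNAL_STANDARD,
    ROLE_TISSUE_FEATURE,
    REGION_QCS,
    REGION_TISSUE,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_batch_experiment",
    "inject_known_effect",
    "lognormal_cv_percent",
    "recover_slide_effect_slope",
    "recover_drift_slopes",
]


def lognormal_cv_percent(sigma: float) -> float:
    """Closed-form CV%% of a log-normal with log-scale sd ``sigma``."""
    return 100.0 * np.sqrt(np.exp(sigma**2) - 1.0)


@dataclass
class SimulationConfig:
    """Study-design parameters; defaults are the emulated experiment."""

    n_days: int = 3
    slides_per_day: int = 6
    qcs_per_slide: int = 6
    tissue_per_slide: int = 4  # measured tissue-region observations per slide
    groups: tuple = ("goat_liver", "chicken_liver", "chicken_heart")
    n_tissue_features: int = 200
    lipid_fraction: float = 0.3  # drift-prone features, tagged m/z > 700
    sigma_slide: float = 0.3  # sd of log-normal slide effect
    sigma_day: float = 0.2  # sd of log-normal day effect
    sigma_resid: float = 0.1  # residual log-scale noise
    drift_slope_range: tuple = (-0.006, -0.002)  # per order unit, log scale
    outlier_slides: dict = field(default_factory=lambda: {"S4": -1.5})
    n_markers_per_group: int = 10
    marker_log_effect: float = 1.0
    analyte_level: float = 1000.0  # linear-scale QCS analyte baseline
    is_level: float = 500.0  # IS spiked at half the analyte amount
    tissue_feature_level: float = 500.0
    qcs_background_factor: float = 0.05  # tissue features at baseline in QCS

    def __post_init__(self) -> None:
        for name in ("sigma_slide", "sigma_day", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.slides_per_day % len(self.groups) != 0:
            raise ValueError(
                "slides_per_day must be divisible by the number of groups "
                "for a balanced day/group design"
            )


@dataclass
class SyntheticTruth:
    """Realized ground-truth effects behind a simulated table."""

    slide_effects: pd.Series  # b_s
    day_effects: pd.Series  # c_d
    drift_slopes: pd.Series  # beta_f per feature (0 for non-drifting)
    outlier_offsets: pd.Series  # u_s (log attenuation) for outlier slides
    group_markers: dict  # group -> list of marker feat_ids
    marker_log_effect: float
    config: SimulationConfig
    seed: int


def _feature_panel(config: SimulationConfig, rng: np.random.Generator):
    n_lipid = int(round(config.lipid_fraction * config.n_tissue_features))
    n_other = config.n_tissue_features - n_lipid
    mz = np.concatenate(
        [
            rng.uniform(100.0, 700.0, size=n_other),
            rng.uniform(700.5, 1000.0, size=n_lipid),
        ]
    )
    mz = np.sort(np.round(mz, 4))
    # resolve (rare) collisions after rounding so feat_ids stay unique
    for i in range(1, len(mz)):
        if mz[i] <= mz[i - 1]:
            mz[i] = mz[i - 1] + 0.0001
    feat_ids = [f"mz{v:.4f}" for v in mz]
    return feat_ids, mz


def generate_batch_experiment(
    config: SimulationConfig | None = None, seed: int = 0
) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate one multi-day batch experiment; returns (table, truth)."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)

    n_slides = config.n_days * config.slides_per_day
    slide_ids = [f"S{i + 1}" for i in range(n_slides)]
    day_of_slide = {
        s: f"day{i // config.slides_per_day + 1}" for i, s in enumerate(slide_ids)
    }
    days = [f"day{d + 1}" for d in range(config.n_days)]

    for s in config.outlier_slides:
        if s not in slide_ids:
            raise ValueError(f"outlier slide {s!r} not in design")

    # balanced group assignment: within each day the slides cycle the groups
    slides_per_group_day = config.slides_per_day // len(config.groups)
    if config.slides_per_day % len(config.groups) != 0:
        raise ValueError("slides_per_day must be divisible by the group count")
    group_of_slide = {}
    for d in range(config.n_days):
        block = slide_ids[d * config.slides_per_day : (d + 1) * config.slides_per_day]
        for i, s in enumerate(block):
            group_of_slide[s] = config.groups[i // slides_per_group_day]

    # effects
    b = pd.Series(rng.normal(0.0, config.sigma_slide, n_slides), index=slide_ids)
    c = pd.Series(rng.normal(0.0, config.sigma_day, config.n_days), index=days)
    u = pd.Series(
        {s: float(off) for s, off in config.outlier_slides.items()}, dtype=float
    )

    feat_ids, mz = _feature_panel(config, rng)
    baselines = np.log(config.tissue_feature_level) + rng.normal(
        0.0, 0.5, size=config.n_tissue_features
    )
    lipid_mask = mz > 700.0
    beta = np.zeros(config.n_tissue_features)
    lo, hi = config.drift_slope_range
    beta[lipid_mask] = rng.uniform(lo, hi, size=lipid_mask.sum())

    # group markers: distinct features per group, drawn without replacement
    marker_pool = rng.permutation(config.n_tissue_features)
    group_markers = {}
    pos = 0
    for g in config.groups:
        group_markers[g] = [feat_ids[i] for i in marker_pool[pos : pos + config.n_markers_per_group]]
        pos += config.n_markers_per_group

    # acquisition schedule: days in blocks, slide order randomized within day,
    # per slide: half the QCS spots, then the tissue regions, then the rest
    obs_rows = []
    order = 0
    for d in range(config.n_days):
        block = slide_ids[d * config.slides_per_day : (d + 1) * config.slides_per_day]
        for s in rng.permutation(block):
            day = day_of_slide[s]
            n_before = config.qcs_per_slide // 2
            for i in range(config.qcs_per_slide):
                phase = "pre" if i < n_before else "post"
                obs_rows.append((s, day, REGION_QCS, "", i, phase))
            for i in range(config.tissue_per_slide):
                obs_rows.append((s, day, REGION_TISSUE, group_of_slide[s], i, "mid"))

    # interleave: pre-QCS, tissue, post-QCS per slide, in acquisition order
    records = []
    by_slide: dict[str, list] = {}
    for row in obs_rows:
        by_slide.setdefault(row[0], []).append(row)
    seen = []
    for row in obs_rows:
        if row[0] not in seen:
            seen.append(row[0])
    for s in seen:
        rows = by_slide[s]
        ordered = (
            [r for r in rows if r[5] == "pre"]
            + [r for r in rows if r[5] == "mid"]
            + [r for r in rows if r[5] == "post"]
        )
        for r in ordered:
            order += 1
            s_, day, region, group, i, phase = r
            if region == REGION_QCS:
                obs_id = f"{s_}_qcs{i + 1}"
                row_id = f"r{i % 3 + 1}"
            else:
                obs_id = f"{s_}_t{i + 1}"
                row_id = ""
            records.append(
                {
                    "obs_id": obs_id,
                    "slide_id": s_,
                    "day": day,
                    "measurement_order": order,
                    "region_type": region,
                    "group": group,
                    "row_id": row_id,
                }
            )
    obs_meta = pd.DataFrame(records)

    # feature metadata: analyte + IS first, then tissue features
    feat_meta = pd.DataFrame(
        {
            "feat_id": ["propranolol", "propranolol_d7"] + feat_ids,
            "mz": [260.16, 267.21] + list(mz),
            "role": [ROLE_ANALYTE, ROLE_INTERNAL_STANDARD]
            + [ROLE_TISSUE_FEATURE] * config.n_tissue_features,
        }
    )
    n_obs = len(obs_meta)
    n_feat = len(feat_meta)
    log_x = np.zeros((n_obs, n_feat))

    marker_set = {
        g: set(ids) for g, ids in group_markers.items()
    }
    tissue_beta = np.concatenate([[0.0, 0.0], beta])  # analyte/IS do not drift
    truth_beta = pd.Series(tissue_beta, index=feat_meta["feat_id"].to_list())

    for o, rec in obs_meta.iterrows():
        s = rec["slide_id"]
        shared = b[s] + c[rec["day"]] + (u[s] if s in u.index else 0.0)
        ordr = rec["measurement_order"]
        if rec["region_type"] == REGION_QCS:
            mu = np.concatenate(
                [
                    [np.log(config.analyte_level), np.log(config.is_level)],
                    baselines + np.log(config.qcs_background_factor),
                ]
            )
        else:
            g = rec["group"]
            marker_boost = np.array(
                [
                    config.marker_log_effect if fid in marker_set[g] else 0.0
                    for fid in feat_ids
                ]
            )
            mu = np.concatenate(
                [
                    # analyte/IS present only at trace level in tissue
                    [
                        np.log(config.analyte_level * 0.01),
                        np.log(config.is_level * 0.01),
                    ],
                    baselines + marker_boost,
                ]
            )
        eps = rng.normal(0.0, config.sigma_resid, size=n_feat)
        log_x[o] = mu + shared + tissue_beta * ordr + eps

    table = FeatureTable(np.exp(log_x), obs_meta, feat_meta, provenance="raw")
    truth = SyntheticTruth(
        slide_effects=b,
        day_effects=c,
        drift_slopes=truth_beta,
        outlier_offsets=u,
        group_markers=group_markers,
        marker_log_effect=config.marker_log_effect,
        config=config,
        seed=seed,
    )
    return table, truth


def recover_slide_effect_slope(table: FeatureTable, truth: SyntheticTruth) -> float:
    """Regress per-slide QCS log-means on the true slide effects b_s.

    The known day effects and outlier attenuations from ``truth`` are
    subtracted first (they are separate model terms, shared within a day
    or specific to the flagged slide); the QCS analyte and internal
    standard are averaged since both carry the slide effect.  An unbiased
    generator yields a slope of 1.
    """
    qcs = table.qcs_only()
    slides = qcs.obs_meta["slide_id"].to_numpy()
    log_a = np.log(qcs.feature_values("propranolol"))
    log_i = np.log(qcs.feature_values("propranolol_d7"))
    day_of = dict(zip(qcs.obs_meta["slide_id"], qcs.obs_meta["day"]))
    slide_ids = list(truth.slide_effects.index)
    y = []
    for s in slide_ids:
        m = slides == s
        level = 0.5 * (log_a[m].mean() + log_i[m].mean())
        level -= truth.day_effects[day_of[s]]
        level -= float(truth.outlier_offsets.get(s, 0.0))
        y.append(level)
    b = truth.slide_effects.to_numpy()
    slope = np.polyfit(b, np.asarray(y), 1)[0]
    return float(slope)


def recover_drift_slopes(table: FeatureTable, truth: SyntheticTruth) -> pd.Series:
    """Per-feature OLS drift slopes of the drifting features, after removing
    the known slide/day/outlier terms from the log intensities.

    Returns the estimated slope per drifting feature (same index subset of
    ``truth.drift_slopes``); an unbiased generator recovers beta_f.
    """
    tis = table.tissue_only()
    order = tis.obs_meta["measurement_order"].to_numpy().astype(float)
    shared = np.array(
        [
            truth.slide_effects[s]
            + truth.day_effects[d]
            + float(truth.outlier_offsets.get(s, 0.0))
            for s, d in zip(tis.obs_meta["slide_id"], tis.obs_meta["day"])
        ]
    )
    est = {}
    for fid, beta in truth.drift_slopes.items():
        if beta == 0.0:
            continue
        resid = np.log(tis.feature_values(fid)) - shared
        est[fid] = float(np.polyfit(order, resid, 1)[0])
    return pd.Series(est, name="drift_slope")


def inject_known_effect(
    table: FeatureTable,
    scope: str,
    key,
    multiply: float = 1.0,
    log_slope: float = 0.0,
    features: list | None = None,
) -> tuple[FeatureTable, dict]:
    """Perturb a copy of the table with an exactly recorded effect.

    Parameters
    ----------
    scope : {"slide", "day", "order_range"}
        What the effect attaches to.
    key :
        A slide id, a day label, or an (lo, hi) inclusive order window.
    multiply :
        Multiplicative factor applied to the targeted cells.
    log_slope :
        Additional per-order-unit drift applied on the log scale
        (``x * exp(log_slope * order)``) to the targeted cells.
    features :
        Feature ids to perturb (default: all features).

    Returns the perturbed table and a record of what was injected.
    """
    meta = table.obs_meta
    if scope == "slide":
        if key not in set(meta["slide_id"]):
            raise ValueError(f"unknown slide {key!r}")
        obs_mask = (meta["slide_id"] == key).to_numpy()
    elif scope == "day":
        if key not in set(meta["day"]):
            raise ValueError(f"unknown day {key!r}")
        obs_mask = (meta["day"] == key).to_numpy()
    elif scope == "order_range":
        lo, hi = key
        obs_mask = meta["measurement_order"].between(lo, hi).to_numpy()
    else:
        raise ValueError(f"unknown scope {scope!r}")

    if features is None:
        feat_idx = np.arange(table.n_feat)
    else:
        feat_idx = np.array([table.feature_index(f) for f in features])

    out = table.intensities.copy()
    sub = out[np.ix_(obs_mask, feat_idx)]
    if multiply != 1.0:
        sub = sub * multiply
    if log_slope != 0.0:
        orders = meta.loc[obs_mask, "measurement_order"].to_numpy()
        sub = sub * np.exp(log_slope * orders)[:, None]
    out[np.ix_(obs_mask, feat_idx)] = sub
    record = {
        "scope": scope,
        "key": key,
        "multiply": multiply,
        "log_slope": log_slope,
        "features": None if features is None else list(features),
        "n_obs_affected": int(obs_mask.sum()),
    }
    return table.with_intensities(out), record
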