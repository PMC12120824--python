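"""Feature-table data model and CSV I/O.

The single currency of the package is the :class:`FeatureTable`: a wide
observations x features intensity matrix (one row per measured region --
a QCS spot or a tissue section -- one column per m/z feature) together
with observation metadata (slide, day, acquisition order, region type,
tissue group) and feature metadata (m/z, role).

Canonical on-disk format: RFC-4180 CSV, UTF-8, "." decimal separator.
Reserved headers: ``obs_id, slide_id, day, measurement_order, region_type,
group, row_id``; every other column is a feature named by its feat_id.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FeatureTable",
    "PipelineConfig",
    "FeatureTableError",
    "read_feature_table",
    "write_feature_table",
    "REGION_QCS",
    "REGION_TISSUE",
]

REGION_QCS = "qcs"
REGION_TISSUE = "tissue"
_VALID_REGIONS = frozenset({REGION_QCS, REGION_TISSUE})

#: metadata columns, in canonical file order
META_COLUMNS = (
    "obs_id",
    "slide_id",
    "day",
    "measurement_order",
    "region_type",
    "group",
    "row_id",
)

#: feature roles
ROLE_ANALYTE = "analyte"
ROLE_INTERNAL_STANDARD = "internal_standard"
ROLE_TISSUE_FEATURE = "tissue_feature"
_VALID_ROLES = frozenset({ROLE_ANALYTE, ROLE_INTERNAL_STANDARD, ROLE_TISSUE_FEATURE})


class FeatureTableError(ValueError):
    """Raised on any violation of the feature-table contract."""


@dataclass
class FeatureTable:
    """Wide intensity matrix with observation and feature metadata.

    Parameters
    ----------
    intensities : ndarray of shape (n_obs, n_feat)
        Non-negative peak abundances on the raw (linear) scale.
    obs_meta : DataFrame
        One row per observation; must carry the reserved metadata columns
        (``row_id`` optional).  Indexed positionally, aligned with
        ``intensities`` rows.
    feat_meta : DataFrame
        One row per feature with columns ``feat_id``, ``mz``, ``role``.
    provenance : str
        Normalization/correction provenance tag (``raw`` for untouched
        tables; normalizers and correctors set their own tags).
    """

    intensities: np.ndarray
    obs_meta: pd.DataFrame
    feat_meta: pd.DataFrame
    provenance: str = "raw"
    is_pair: tuple[str, str] | None = None  # (analyte, IS) for provenance "is"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise FeatureTableError("intensities must be a 2-D matrix")
        self.obs_meta = self.obs_meta.reset_index(drop=True)
        self.feat_meta = self.feat_meta.reset_index(drop=True)
        if "row_id" not in self.obs_meta.columns:
            self.obs_meta = self.obs_meta.assign(row_id="")
        self._validate()

    # -- validation ---------------------------------------------------
    def _validate(self) -> None:
        n_obs, n_feat = self.intensities.shape
        if len(self.obs_meta) != n_obs:
            raise FeatureTableError(
                f"obs_meta has {len(self.obs_meta)} records for {n_obs} intensity rows"
            )
        if len(self.feat_meta) != n_feat:
            raise FeatureTableError(
                f"feat_meta has {len(self.feat_meta)} records for {n_feat} intensity columns"
            )
        missing = [c for c in META_COLUMNS if c not in self.obs_meta.columns]
        if missing:
            raise FeatureTableError(f"obs_meta missing columns: {missing}")
        for col in ("feat_id", "mz", "role"):
            if col not in self.feat_meta.columns:
                raise FeatureTableError(f"feat_meta missing column: {col}")

        if np.isnan(self.intensities).any():
            r, c = np.argwhere(np.isnan(self.intensities))[0]
            raise FeatureTableError(
                f"missing intensity at obs_id={self.obs_meta['obs_id'].iat[r]!r}, "
                f"feature={self.feat_meta['feat_id'].iat[c]!r}"
            )
        if (self.intensities < 0).any():
            r, c = np.argwhere(self.intensities < 0)[0]
            raise FeatureTableError(
                f"negative intensity at obs_id={self.obs_meta['obs_id'].iat[r]!r}, "
                f"feature={self.feat_meta['feat_id'].iat[c]!r}"
            )

        for name, series in (
            ("obs_id", self.obs_meta["obs_id"]),
            ("feat_id", self.feat_meta["feat_id"]),
            ("measurement_order", self.obs_meta["measurement_order"]),
        ):
            dup = series[series.duplicated()]
            if len(dup):
                raise FeatureTableError(f"duplicate {name}: {sorted(set(dup))}")

        orders = self.obs_meta["measurement_order"]
        if (orders.astype(int) != orders).any() or (orders < 1).any():
            raise FeatureTableError("measurement_order must be positive integers")

        bad_region = set(self.obs_meta["region_type"]) - _VALID_REGIONS
        if bad_region:
            raise FeatureTableError(
                f"unknown region_type label(s) {sorted(bad_region)}; "
                f"expected one of {sorted(_VALID_REGIONS)}"
            )
        bad_role = set(self.feat_meta["role"]) - _VALID_ROLES
        if bad_role:
            raise FeatureTableError(f"unknown feature role(s): {sorted(bad_role)}")

    # -- accessors ----------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_feat(self) -> int:
        return self.intensities.shape[1]

    @property
    def obs_ids(self) -> list[str]:
        return list(self.obs_meta["obs_id"])

    @property
    def feat_ids(self) -> list[str]:
        return list(self.feat_meta["feat_id"])

    def feature_index(self, feat_id: str) -> int:
        idx = np.flatnonzero((self.feat_meta["feat_id"] == feat_id).to_numpy())
        if len(idx) == 0:
            raise FeatureTableError(f"feature {feat_id!r} not in table")
        return int(idx[0])

    def feature_values(self, feat_id: str) -> np.ndarray:
        return self.intensities[:, self.feature_index(feat_id)]

    def subset_obs(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask)
        return replace(
            self,
            intensities=self.intensities[mask],
            obs_meta=self.obs_meta.loc[mask].reset_index(drop=True),
        )

    def qcs_only(self) -> "FeatureTable":
        return self.subset_obs((self.obs_meta["region_type"] == REGION_QCS).to_numpy())

    def tissue_only(self) -> "FeatureTable":
        return self.subset_obs((self.obs_meta["region_type"] == REGION_TISSUE).to_numpy())

    def with_intensities(self, intensities: np.ndarray, provenance: str | None = None) -> "FeatureTable":
        return replace(
            self,
            intensities=intensities,
            provenance=self.provenance if provenance is None else provenance,
        )

    def copy(self) -> "FeatureTable":
        return replace(
            self,
            intensities=self.intensities.copy(),
            obs_meta=self.obs_meta.copy(),
            feat_meta=self.feat_meta.copy(),
        )

    def equals(self, other: "FeatureTable") -> bool:
        return (
            np.array_equal(self.intensities, other.intensities)
            and self.obs_meta[list(META_COLUMNS)].astype(str).equals(
                other.obs_meta[list(META_COLUMNS)].astype(str)
            )
            and self.feat_meta[["feat_id", "role"]].astype(str).equals(
                other.feat_meta[["feat_id", "role"]].astype(str)
            )
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: metadata columns then feature columns, canonical order."""
        meta = self.obs_meta[list(META_COLUMNS)].copy()
        feats = pd.DataFrame(self.intensities, columns=self.feat_ids)
        return pd.concat([meta, feats], axis=1)


@dataclass
class PipelineConfig:
    """Run-wide configuration mirroring the YAML config file.

    Defaults follow the study conventions: the correction batch key is the
    day, the VIP distinctiveness threshold is 1.2, and the outlier rule is
    a robust z-score with cutoff 3.5 on scaled-MAD units.
    """

    analyte_feat_id: str = "propranolol"
    is_feat_id: str = "propranolol_d7"
    qcs_region: str = REGION_QCS
    batch_key: str = "day"
    order_key: str = "measurement_order"
    methods: Sequence[str] = ("tic", "is", "tic+combat", "tic+waveica", "combat", "waveica")
    method_params: Mapping[str, Mapping] = field(default_factory=dict)
    cv_grouping: Sequence[str] = ("day", "slide_id", "row_id")
    vip_threshold: float = 1.2
    outlier_k: float = 3.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vip_threshold <= 0:
            raise ValueError("vip_threshold must be > 0")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------

_FLOAT_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")


def read_feature_table(
    path: str | Path,
    analyte_feat_id: str | None = None,
    is_feat_id: str | None = None,
) -> FeatureTable:
    """Read and validate a wide-format feature table CSV.

    Feature roles are assigned from ``analyte_feat_id`` / ``is_feat_id``
    when given; every other feature is a ``tissue_feature``.  Feature m/z
    is parsed from column names of the form ``mz123.45`` when present,
    else left as NaN.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=None, engine="python")
    if "obs_id" not in df.columns:
        raise FeatureTableError(f"{path}: first column must be obs_id")
    present_meta = [c for c in META_COLUMNS if c in df.columns]
    required = {"obs_id", "slide_id", "day", "measurement_order", "region_type", "group"}
    missing = required - set(present_meta)
    if missing:
        raise FeatureTableError(f"{path}: missing metadata columns {sorted(missing)}")
    feat_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not feat_cols:
        raise FeatureTableError(f"{path}: no feature columns found")

    values = np.empty((len(df), len(feat_cols)), dtype=float)
    for j, col in enumerate(feat_cols):
        for i, cell in enumerate(df[col]):
            if not _FLOAT_RE.match(cell.strip()):
                raise FeatureTableError(
                    f"{path}: non-numeric or missing intensity at "
                    f"obs_id={df['obs_id'].iat[i]!r}, feature={col!r} (value {cell!r})"
                )
            values[i, j] = float(cell)

    obs_meta = df[present_meta].copy()
    if "row_id" not in obs_meta.columns:
        obs_meta["row_id"] = ""
    obs_meta["measurement_order"] = obs_meta["measurement_order"].astype(int)

    roles, mzs = [], []
    for col in feat_cols:
        if analyte_feat_id is not None and col == analyte_feat_id:
            roles.append(ROLE_ANALYTE)
        elif is_feat_id is not None and col == is_feat_id:
            roles.append(ROLE_INTERNAL_STANDARD)
        else:
            roles.append(ROLE_TISSUE_FEATURE)
        m = re.match(r"^mz(\d+(\.\d+)?)$", col)
        mzs.append(float(m.group(1)) if m else np.nan)
    feat_meta = pd.DataFrame({"feat_id": feat_cols, "mz": mzs, "role": roles})
    return FeatureTable(values, obs_meta, feat_meta)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a table as canonical CSV: metadata then features, full precision.

    ``read_feature_table(write_feature_table(t))`` reproduces ``t`` exactly
    (float values round-trip through ``repr``).
    """
    df = table.to_frame()
    for col in table.feat_ids:
        df[col] = [repr(float(v)) for v in df[col]]
    df.to_csv(path, index=False, lineterminator="\n")
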