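"""Normalization modes: none, TIC, internal standard; plus z-scoring.

TIC (total ion current) normalization divides each observation's feature
abundances by their sum over all feature columns of the table -- a ratio
correction for global intensity differences between spots, sections and
slides.  Internal-standard (IS) normalization ratios the analyte
(propranolol) against its isotope-labelled analogue (propranolol-d7),
cancelling every multiplicative artifact the two share (matrix spraying,
ionization efficiency, detector drift).

The array-level workhorses are sklearn-style transformers; the
FeatureTable-level functions below them are the package interface.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datamodel import FeatureTable, FeatureTableError

__all__ = [
    "TICNormalizer",
    "tic_normalize",
    "is_normalize",
    "zscore_by_feature",
]


class TICNormalizer(TransformerMixin, BaseEstimator):
    """Scale each row to unit sum (total-ion-current normalization).

    Stateless; ``fit`` only validates.  Rows with zero sum are rejected,
    never silently turned into NaN.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        sums = X.sum(axis=1)
        bad = np.flatnonzero(sums <= 0)
        if len(bad):
            raise ValueError(f"zero-sum observation(s) at row index {bad.tolist()}")
        return X / sums[:, None]


def tic_normalize(table: FeatureTable) -> FeatureTable:
    """TIC-normalize a feature table: x~_ij = x_ij / sum_j x_ij.

    The sum runs over all feature columns present in the supplied table
    (region-scoped: pass the QCS-region table to normalize QCS spots
    against the QCS spectrum sum).  Metadata are unchanged; provenance
    becomes ``tic``.
    """
    sums = table.intensities.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if len(bad):
        ids = [table.obs_ids[i] for i in bad]
        raise FeatureTableError(f"zero-sum observation(s): {ids}")
    return table.with_intensities(table.intensities / sums[:, None], provenance="tic")


def is_normalize(table: FeatureTable, analyte_feat: str, is_feat: str) -> FeatureTable:
    """Replace the analyte column with the analyte/IS abundance ratio.

    Only the declared analyte is transformed; tissue features are left
    untouched (an isotope-labelled standard exists only for the spiked
    analyte, not for endogenous panels).  Provenance becomes ``is``.
    """
    a = table.feature_index(analyte_feat)
    s = table.feature_index(is_feat)
    is_values = table.intensities[:, s]
    bad = np.flatnonzero(is_values <= 0)
    if len(bad):
        ids = [table.obs_ids[i] for i in bad]
        raise FeatureTableError(
            f"internal standard {is_feat!r} non-positive at obs_id(s): {ids}"
        )
    out = table.intensities.copy()
    out[:, a] = out[:, a] / is_values
    new = table.with_intensities(out, provenance="is")
    new.is_pair = (analyte_feat, is_feat)
    return new


def zscore_by_feature(values: np.ndarray) -> np.ndarray:
    """Z-score a vector over the full pooled set: (x - mean) / sd, sample sd.

    Pooling across all slides keeps slide-level shifts visible when the
    z-scores are plotted per slide (the violin-plot display convention).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need a 1-D vector with at least 2 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread: z-score undefined for a constant vector")
    return (values - values.mean()) / sd
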