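"""Batch-effect correction: empirical-Bayes location-scale (ComBat) and
wavelet+ICA drift removal (WaveICA), behind one pluggable interface.

Both correctors are applied unsupervised -- no biological covariates --
to the full observation set (QCS spots and tissue sections together), the
convention of the study design they serve.  Intensities are corrected on
the log scale (``log(x + eps)`` with ``eps`` half the smallest positive
value in the table) because the batch structure of MSI abundances is
multiplicative; the ratio normalizations (TIC, IS) only cancel
multiplicative artifacts, and the correctors adopt the same working model.

The array-level estimators (:class:`CombatCorrector`,
:class:`WaveICACorrector`) follow the sklearn fit/transform protocol with
the batch labels passed as ``y``; they operate in-sample, as batch
correction does.  The FeatureTable-level functions wrap them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_array, check_is_fitted

from ._modwt import imodwt, max_level, modwt
from .datamodel import FeatureTable
from .normalization import tic_normalize

__all__ = [
    "CombatCorrector",
    "WaveICACorrector",
    "CorrectionResult",
    "combat_correct",
    "waveica_correct",
    "apply_corrections",
    "register_correction",
    "METHOD_GRID",
]


# ---------------------------------------------------------------------
# ComBat: empirical-Bayes location-scale batch adjustment
# ---------------------------------------------------------------------


class CombatCorrector(TransformerMixin, BaseEstimator):
    """Empirical-Bayes location/scale batch correction (parametric ComBat).

    Models each feature g in batch i as having a batch location shift
    gamma_ig and scale delta_ig on top of a grand mean alpha_g and pooled
    variance sigma2_g.  Per-batch estimates are shrunk toward batch-level
    priors -- Normal for locations, inverse-gamma for scales, with
    hyperparameters from the method of moments -- by iterating the
    conditional posterior means to convergence, then the data are
    standardized, adjusted, and restored.

    Parameters
    ----------
    parametric : bool
        Only the parametric EB variant is implemented.
    tol, max_iter :
        Convergence tolerance (max absolute change of the shrunk
        estimates) and iteration cap for the EB fixed point.

    Attributes (fitted)
    -------------------
    grand_mean_ : (n_feat,) alpha_g
    pooled_var_ : (n_feat,) sigma2_g
    gamma_hat_, gamma_star_ : (n_batch, n_feat) raw and EB-shrunk locations
    delta_sq_hat_, delta_sq_star_ : (n_batch, n_feat) raw and shrunk scales
    gamma_bar_, tau_sq_bar_, lambda_bar_, theta_bar_ : per-batch priors
    skipped_features_ : indices of zero-variance features left untouched
    n_iter_, converged_ : EB iteration diagnostics
    """

    def __init__(self, parametric: bool = True, tol: float = 1e-4, max_iter: int = 100):
        self.parametric = parametric
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y=None, **fit_params):
        if not self.parametric:
            raise ValueError("only the parametric EB variant is implemented")
        X = check_array(X, ensure_min_samples=2)
        if y is None:
            raise ValueError("batch labels must be passed as y")
        batches = np.asarray(y)
        if len(batches) != X.shape[0]:
            raise ValueError("batch label length mismatch")
        levels = pd.unique(batches)
        n_i = np.array([(batches == b).sum() for b in levels])
        if (n_i < 2).any() and len(levels) > 1:
            small = [str(b) for b, n in zip(levels, n_i) if n < 2]
            raise ValueError(f"batch(es) with a single observation: {small}")
        self.batch_levels_ = levels
        self.batches_ = batches
        self.n_batches_ = len(levels)
        self.n_features_in_ = X.shape[1]

        if len(levels) == 1:
            # nothing to equalize; identity by construction
            self.corrected_ = X.copy()
            self.skipped_features_ = np.array([], dtype=int)
            self.converged_ = True
            self.n_iter_ = 0
            return self.corrected_

        N = X.shape[0]
        masks = [batches == b for b in levels]
        batch_means = np.vstack([X[m].mean(axis=0) for m in masks])
        alpha = (n_i[:, None] * batch_means).sum(axis=0) / N
        row_batch = np.empty(N, dtype=int)
        for i, m in enumerate(masks):
            row_batch[m] = i
        resid = X - batch_means[row_batch]
        sigma2 = (resid**2).mean(axis=0)
        keep = sigma2 > 0
        self.skipped_features_ = np.flatnonzero(~keep)
        sigma = np.sqrt(np.where(keep, sigma2, 1.0))

        Z = (X - alpha) / sigma
        gamma_hat = np.vstack([Z[m].mean(axis=0) for m in masks])
        delta_sq_hat = np.vstack([Z[m].var(axis=0, ddof=1) for m in masks])

        gamma_bar = gamma_hat[:, keep].mean(axis=1)
        tau_sq_bar = gamma_hat[:, keep].var(axis=1, ddof=1)
        d_bar = delta_sq_hat[:, keep].mean(axis=1)
        d_s2 = delta_sq_hat[:, keep].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            lambda_bar = (2 * d_s2 + d_bar**2) / d_s2
            theta_bar = (d_bar * d_s2 + d_bar**3) / d_s2
        # moment priors need spread across features; without it, fall back
        # to no shrinkage for that batch
        eb_ok = (
            np.isfinite(lambda_bar) & np.isfinite(theta_bar) & np.isfinite(tau_sq_bar)
        )

        gamma_star = gamma_hat.copy()
        delta_sq_star = delta_sq_hat.copy()
        self.converged_ = False
        self.n_iter_ = 0
        for it in range(self.max_iter):
            change = 0.0
            for i, m in enumerate(masks):
                if not eb_ok[i]:
                    continue
                g_new = (
                    n_i[i] * tau_sq_bar[i] * gamma_hat[i] + delta_sq_star[i] * gamma_bar[i]
                ) / (n_i[i] * tau_sq_bar[i] + delta_sq_star[i])
                sum2 = ((Z[m] - g_new) ** 2).sum(axis=0)
                d_new = (theta_bar[i] + 0.5 * sum2) / (n_i[i] / 2.0 + lambda_bar[i] - 1.0)
                change = max(
                    change,
                    np.abs(g_new - gamma_star[i])[keep].max(initial=0.0),
                    np.abs(d_new - delta_sq_star[i])[keep].max(initial=0.0),
                )
                gamma_star[i] = g_new
                delta_sq_star[i] = d_new
            self.n_iter_ = it + 1
            if change < self.tol:
                self.converged_ = True
                break

        corrected = np.empty_like(X)
        for i, m in enumerate(masks):
            adj = sigma / np.sqrt(delta_sq_star[i]) * (Z[m] - gamma_star[i]) + alpha
            corrected[m] = adj
        corrected[:, ~keep] = X[:, ~keep]

        self.grand_mean_ = alpha
        self.pooled_var_ = np.where(keep, sigma2, 0.0)
        self.gamma_hat_ = gamma_hat
        self.gamma_star_ = gamma_star
        self.delta_sq_hat_ = delta_sq_hat
        self.delta_sq_star_ = delta_sq_star
        self.gamma_bar_ = gamma_bar
        self.tau_sq_bar_ = tau_sq_bar
        self.lambda_bar_ = lambda_bar
        self.theta_bar_ = theta_bar
        self.batch_sizes_ = n_i
        self.corrected_ = corrected
        return corrected

    def transform(self, X, y=None):
        """Return the batch-adjusted matrix for the fitted observations."""
        check_is_fitted(self, "corrected_")
        X = check_array(X)
        if X.shape != self.corrected_.shape:
            raise ValueError("ComBat adjusts the observations it was fitted on")
        return self.corrected_


# ---------------------------------------------------------------------
# WaveICA: per-wavelet-level ICA with batch-associated component removal
# ---------------------------------------------------------------------


def _batch_r2(scores: np.ndarray, batches: np.ndarray, levels) -> float:
    """Fraction of a component score vector's variance explained by batch."""
    total = ((scores - scores.mean()) ** 2).sum()
    if total <= 0:
        return 0.0
    between = 0.0
    for b in levels:
        m = batches == b
        between += m.sum() * (scores[m].mean() - scores.mean()) ** 2
    return float(between / total)


class WaveICACorrector(TransformerMixin, BaseEstimator):
    """Wavelet + ICA batch/drift correction along acquisition order.

    Each feature's intensity series (rows already sorted by measurement
    order) is decomposed with the shift-invariant MODWT into detail levels
    plus the final smooth; independent components are extracted per level
    (FastICA, deflation-mode negentropy, fixed seed) and any component
    whose score vector is batch-associated (R^2 against batch indicators
    at or above ``t_threshold``) is subtracted before inverting the
    transform.  A threshold above 1 removes nothing and reconstructs the
    input exactly.

    Attributes (fitted)
    -------------------
    level_r2_ : list of per-level arrays of component batch-R^2 scores
    removed_ : list of (level, component) pairs that were subtracted
    n_levels_ : wavelet depth J = floor(log2 n)
    """

    def __init__(
        self,
        wavelet: str = "haar",
        n_components: int | None = None,
        t_threshold: float = 0.05,
        random_state: int = 0,
        max_iter: int = 1000,
    ):
        self.wavelet = wavelet
        self.n_components = n_components
        self.t_threshold = t_threshold
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y=None, **fit_params):
        X = check_array(X, ensure_min_samples=8)
        if y is None:
            raise ValueError("batch labels must be passed as y")
        batches = np.asarray(y)
        if len(batches) != X.shape[0]:
            raise ValueError("batch label length mismatch")
        levels = pd.unique(batches)
        n, p = X.shape
        K = self.n_components if self.n_components is not None else min(20, n - 1, p)
        if K < 1:
            raise ValueError("need at least one ICA component")
        self.n_levels_ = max_level(n)

        # reflection boundary: decompose the series extended by its mirror
        # image so the circular transform never wraps the last batch onto
        # the first; invert on the extended series and truncate
        X_ext = np.vstack([X, X[::-1]])
        batches_ext = np.concatenate([batches, batches[::-1]])
        details, smooth = modwt(X_ext, self.wavelet, self.n_levels_)
        matrices = details + [smooth]
        self.level_r2_ = []
        self.removed_ = []
        cleaned = []
        for lev, M in enumerate(matrices):
            if np.allclose(M.var(axis=0), 0):
                self.level_r2_.append(np.zeros(0))
                cleaned.append(M)
                continue
            # effective dimension: whitening numerically tiny directions up
            # to unit variance would dilute a dominant batch pattern across
            # components, so only directions carrying real variance enter ICA
            sv = np.linalg.svd(M - M.mean(axis=0), compute_uv=False)
            frac = np.cumsum(sv**2) / np.sum(sv**2)
            k_eff = int(np.searchsorted(frac, 0.99) + 1)
            k_lev = min(K, k_eff)
            if k_lev < 1:
                self.level_r2_.append(np.zeros(0))
                cleaned.append(M)
                continue
            ica = FastICA(
                n_components=k_lev,
                algorithm="deflation",
                fun="logcosh",
                whiten="unit-variance",
                random_state=self.random_state,
                max_iter=self.max_iter,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                S = ica.fit_transform(M)
            A = ica.mixing_  # (p, k)
            r2 = np.array(
                [_batch_r2(S[:, k], batches_ext, levels) for k in range(S.shape[1])]
            )
            self.level_r2_.append(r2)
            remove = np.flatnonzero(r2 >= self.t_threshold)
            M_clean = M
            if len(remove):
                M_clean = M - S[:, remove] @ A[:, remove].T
                self.removed_.extend((lev, int(k)) for k in remove)
            cleaned.append(M_clean)

        recon = imodwt(cleaned[:-1], cleaned[-1], self.wavelet)
        # average the two mirror copies: any asymmetric removal artifact is
        # split between them, and with nothing removed both halves equal X
        self.corrected_ = 0.5 * (recon[:n] + recon[n:][::-1])
        self.n_features_in_ = p
        return self.corrected_

    def transform(self, X, y=None):
        check_is_fitted(self, "corrected_")
        X = check_array(X)
        if X.shape != self.corrected_.shape:
            raise ValueError("WaveICA adjusts the observations it was fitted on")
        return self.corrected_


# ---------------------------------------------------------------------
# FeatureTable-level interface
# ---------------------------------------------------------------------


@dataclass
class CorrectionResult:
    """A corrected table plus the fitted model and a decision log."""

    table: FeatureTable
    model: object
    method: str
    params: dict
    log: list = field(default_factory=list)


def _log_offset(X: np.ndarray) -> float:
    pos = X[X > 0]
    if len(pos) == 0:
        raise ValueError("table has no positive intensities")
    return float(pos.min()) * 0.5


def combat_correct(
    table: FeatureTable, batch_key: str = "day", parametric: bool = True
) -> CorrectionResult:
    """Run parametric ComBat on ``log(x + eps)`` and back-transform."""
    batches = table.obs_meta[batch_key].to_numpy()
    eps = _log_offset(table.intensities)
    Y = np.log(table.intensities + eps)
    model = CombatCorrector(parametric=parametric)
    corrected = model.fit_transform(Y, batches)
    out = np.clip(np.exp(corrected) - eps, 0.0, None)
    log = []
    if len(model.skipped_features_):
        ids = [table.feat_ids[i] for i in model.skipped_features_]
        log.append(f"zero-variance features left untouched: {ids}")
    if not model.converged_:
        log.append("EB iteration hit the cap without reaching tolerance")
    return CorrectionResult(
        table=table.with_intensities(out, provenance=f"{table.provenance}+combat"),
        model=model,
        method="combat",
        params={"batch_key": batch_key, "parametric": parametric, "log_offset": eps},
        log=log,
    )


def waveica_correct(
    table: FeatureTable,
    order_key: str = "measurement_order",
    batch_key: str = "day",
    wavelet: str = "haar",
    n_components: int | None = None,
    t_threshold: float = 0.05,
    random_state: int = 0,
) -> CorrectionResult:
    """Run WaveICA on ``log(x + eps)`` along measurement order and back-transform."""
    order = table.obs_meta[order_key].to_numpy()
    if len(np.unique(order)) != len(order):
        raise ValueError("measurement order must be unique per observation")
    sort_idx = np.argsort(order)
    inverse = np.argsort(sort_idx)
    batches = table.obs_meta[batch_key].to_numpy()[sort_idx]
    eps = _log_offset(table.intensities)
    Y = np.log(table.intensities + eps)[sort_idx]
    model = WaveICACorrector(
        wavelet=wavelet,
        n_components=n_components,
        t_threshold=t_threshold,
        random_state=random_state,
    )
    corrected = model.fit_transform(Y, batches)[inverse]
    out = np.clip(np.exp(corrected) - eps, 0.0, None)
    log = [f"removed {len(model.removed_)} batch-associated components: {model.removed_}"]
    return CorrectionResult(
        table=table.with_intensities(out, provenance=f"{table.provenance}+waveica"),
        model=model,
        method="waveica",
        params={
            "order_key": order_key,
            "batch_key": batch_key,
            "wavelet": wavelet,
            "t_threshold": t_threshold,
            "random_state": random_state,
            "log_offset": eps,
        },
        log=log,
    )


# -- pluggable registry ------------------------------------------------

_REGISTRY: dict[str, Callable] = {
    "combat": combat_correct,
    "waveica": waveica_correct,
}


def register_correction(name: str, fn: Callable) -> None:
    """Register an external correction (e.g. a wrapper that ingests the
    output table of a deep-learning corrector trained elsewhere)."""
    _REGISTRY[name.lower()] = fn


#: the study's method grid (printed row labels keyed by method spec string)
METHOD_GRID = {
    "raw": "raw",
    "tic": "TIC",
    "is": "IS",
    "tic+combat": "TIC + Combat",
    "tic+waveica": "TIC + WaveICA",
    "combat": "Combat",
    "waveica": "WaveICA",
}


def apply_corrections(
    table: FeatureTable,
    method_specs: list[str],
    batch_key: str = "day",
    order_key: str = "measurement_order",
    analyte_feat: str | None = None,
    is_feat: str | None = None,
    method_params: dict | None = None,
    random_state: int = 0,
) -> list[CorrectionResult]:
    """Run each configured (pre-normalization, method) cell of the grid.

    ``method_specs`` entries are of the form ``"combat"``, ``"waveica"``,
    ``"tic+combat"``, ... plus the pseudo-methods ``"raw"``, ``"tic"`` and
    ``"is"``; labels follow the printed-table convention ("TIC + Combat").
    QCS and tissue observations are corrected together in one matrix,
    unsupervised.
    """
    from .normalization import is_normalize  # local: avoids cycle at import

    method_params = method_params or {}
    results = []
    for spec_str in method_specs:
        key = spec_str.lower().replace(" ", "")
        label = METHOD_GRID.get(key, spec_str)
        parts = key.split("+")
        work = table
        if parts[0] == "tic":
            work = tic_normalize(table)
            parts = parts[1:]
        if parts == [] or parts == ["raw"]:
            results.append(
                CorrectionResult(table=work, model=None, method=label, params={})
            )
            continue
        if parts == ["is"]:
            if analyte_feat is None or is_feat is None:
                raise ValueError("IS normalization needs analyte and IS feature ids")
            results.append(
                CorrectionResult(
                    table=is_normalize(table, analyte_feat, is_feat),
                    model=None,
                    method=label,
                    params={"analyte": analyte_feat, "is": is_feat},
                )
            )
            continue
        (method,) = parts
        if method not in _REGISTRY:
            raise ValueError(
                f"unknown correction {method!r}; registered: {sorted(_REGISTRY)}"
            )
        params = dict(method_params.get(method, {}))
        if method == "combat":
            res = _REGISTRY[method](work, batch_key=batch_key, **params)
        elif method == "waveica":
            res = _REGISTRY[method](
                work,
                order_key=order_key,
                batch_key=batch_key,
                random_state=random_state,
                **params,
            )
        else:
            res = _REGISTRY[method](work, **params)
        res.method = label
        results.append(res)
    return results
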