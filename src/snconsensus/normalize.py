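"""Log-normalization and covariate regression + scaling.

``LogNormalizer`` rescales each nucleus to a common depth (by default
the median per-nucleus total) and log-transforms; ``CovariateScaler``
regresses each gene on technical covariates (nUMI, mitochondrial
fraction, sample of origin), then z-scores and clips the residuals.
Both are scikit-learn transformers over (n_cells, n_genes) arrays;
the module-level functions wrap them for the GeneExpressionMatrix
container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import GeneExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizationParams:
    scale_factor_mode: str = "median_total_counts"  # or "fixed"
    fixed_value: Optional[float] = None
    clip_value: float = 10.0

    def __post_init__(self) -> None:
        if self.scale_factor_mode not in ("median_total_counts", "fixed"):
            raise ValueError(f"unknown scale_factor_mode {self.scale_factor_mode!r}")
        if (self.scale_factor_mode == "fixed") != (self.fixed_value is not None):
            raise ValueError("fixed_value required iff scale_factor_mode='fixed'")
        if self.fixed_value is not None and self.fixed_value <= 0:
            raise ValueError("fixed_value must be positive")
        if self.clip_value <= 0:
            raise ValueError("clip_value must be positive")


@dataclass
class Covariates:
    """Per-nucleus technical covariates for the regression step."""

    n_umi: np.ndarray
    mito_fraction: np.ndarray
    sample_label: np.ndarray

    def __post_init__(self) -> None:
        self.n_umi = np.asarray(self.n_umi, dtype=float)
        self.mito_fraction = np.asarray(self.mito_fraction, dtype=float)
        self.sample_label = np.asarray(self.sample_label, dtype=object)
        n = len(self.n_umi)
        if len(self.mito_fraction) != n or len(self.sample_label) != n:
            raise ValueError("covariate arrays must have equal length")
        if np.any(~np.isfinite(self.n_umi)) or np.any(~np.isfinite(self.mito_fraction)):
            raise ValueError("covariates contain missing values")
        if np.any(self.n_umi <= 0):
            raise ValueError("nUMI must be positive")
        if np.any((self.mito_fraction < 0) | (self.mito_fraction > 1)):
            raise ValueError("mito_fraction must lie in [0, 1]")

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Intercept + nUMI + mito fraction + one-hot samples (reference dropped)."""
        cols = [np.ones(len(self.n_umi)), self.n_umi, self.mito_fraction]
        names = ["intercept", "n_umi", "mito_fraction"]
        levels = list(pd.unique(self.sample_label))
        for lev in levels[1:]:
            cols.append((self.sample_label == lev).astype(float))
            names.append(f"sample[{lev}]")
        return np.column_stack(cols), names


class LogNormalizer(TransformerMixin, BaseEstimator):
    """Depth-normalize and log-transform counts.

    transform(X) returns ``log(1 + x * s / T_c)`` per cell c, where
    ``T_c`` is the cell's total count and ``s`` the scale factor (the
    median of the fitted totals in median mode).  X is (n_cells,
    n_genes), dense or sparse.
    """

    def __init__(self, scale_factor: Optional[float] = None):
        self.scale_factor = scale_factor

    def fit(self, X, y=None):
        totals = self._totals(X)
        if np.any(totals == 0):
            bad = int(np.flatnonzero(totals == 0)[0])
            raise ValueError(f"cell at index {bad} has zero total count")
        self.scale_factor_ = (
            float(self.scale_factor)
            if self.scale_factor is not None
            else float(np.median(totals))
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        totals = self._totals(X)
        if np.any(totals == 0):
            bad = int(np.flatnonzero(totals == 0)[0])
            raise ValueError(f"cell at index {bad} has zero total count")
        if sp.issparse(X):
            X = sp.csr_matrix(X, dtype=float, copy=True)
            scale = self.scale_factor_ / totals
            X = sp.diags(scale) @ X
            X.data = np.log1p(X.data)
            return X
        X = np.asarray(X, dtype=float)
        return np.log1p(X * (self.scale_factor_ / totals)[:, None])

    @staticmethod
    def _totals(X) -> np.ndarray:
        if sp.issparse(X):
            return np.asarray(X.sum(axis=1)).ravel().astype(float)
        return np.asarray(X, dtype=float).sum(axis=1)


class CovariateScaler(TransformerMixin, BaseEstimator):
    """Per-gene OLS residualization on technical covariates, then z-score + clip.

    fit(X, covariates=...) estimates per-gene coefficients and residual
    moments; transform returns centered, unit-variance, clipped
    residuals.  Genes constant after regression are set to 0.
    """

    def __init__(self, clip_value: float = 10.0):
        self.clip_value = clip_value

    def fit(self, X, y=None, *, covariates: Covariates):
        X = self._dense(X)
        n_cells, n_genes = X.shape
        D, names = covariates.design_matrix()
        if D.shape[0] != n_cells:
            raise ValueError("covariate rows do not align with cells")
        # drop collinear columns (always keep the intercept)
        keep = [0]
        for j in range(1, D.shape[1]):
            trial = D[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
            else:
                logger.warning("dropping rank-deficient design column %r", names[j])
        D = D[:, keep]
        self.design_columns_ = [names[j] for j in keep]
        coef, *_ = np.linalg.lstsq(D, X, rcond=None)
        resid = X - D @ coef
        self.coef_ = coef
        self.resid_mean_ = resid.mean(axis=0)
        std = resid.std(axis=0, ddof=0)
        # residuals that are numerically zero (perfectly explained genes)
        scale = np.abs(X).max(axis=0)
        std[std <= 1e-10 * np.maximum(scale, 1.0)] = 0.0
        self.resid_std_ = std
        self.n_features_in_ = n_genes
        self._keep = keep
        self._fit_covariates = covariates
        return self

    def transform(self, X, covariates: Optional[Covariates] = None):
        check_is_fitted(self)
        X = self._dense(X)
        cov = covariates if covariates is not None else self._fit_covariates
        D, _ = cov.design_matrix()
        D = D[:, self._keep]
        resid = X - D @ self.coef_
        std = np.where(self.resid_std_ > 0, self.resid_std_, 1.0)
        z = (resid - self.resid_mean_) / std
        z[:, self.resid_std_ == 0] = 0.0
        return np.clip(z, -self.clip_value, self.clip_value)

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)

    @staticmethod
    def _dense(X) -> np.ndarray:
        if sp.issparse(X):
            return np.asarray(X.todense(), dtype=float)
        return np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# container-level wrappers


def log_normalize(
    m: GeneExpressionMatrix, p: NormalizationParams = NormalizationParams()
) -> GeneExpressionMatrix:
    """Log-normalize a counts-layer matrix (returns layer='normalized')."""
    if m.layer != "counts":
        raise ValueError("log_normalize expects a counts-layer matrix")
    totals = m.counts_per_cell()
    if np.any(totals == 0):
        bad = m.barcodes[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"nucleus {bad!r} has zero total count")
    s = p.fixed_value if p.scale_factor_mode == "fixed" else None
    norm = LogNormalizer(scale_factor=s).fit(m.values.T.tocsr())
    out = norm.transform(m.values.T.tocsr()).T.tocsr()
    result = m.with_values(out, layer="normalized")
    result.scale_factor = norm.scale_factor_  # type: ignore[attr-defined]
    return result


def regress_and_scale(
    m: GeneExpressionMatrix,
    cov: Covariates,
    p: NormalizationParams = NormalizationParams(),
) -> GeneExpressionMatrix:
    """Residualize normalized expression on covariates; z-score and clip."""
    if m.layer != "normalized":
        raise ValueError("regress_and_scale expects a normalized-layer matrix")
    scaler = CovariateScaler(clip_value=p.clip_value)
    z = scaler.fit_transform(m.values.T, covariates=cov)
    return m.with_values(sp.csr_matrix(z.T), layer="scaled")
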