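"""Mass-univariate GLM on rate maps.

The statistical core is :class:`MassUnivariateGLM`, a scikit-learn-style
estimator that fits one ordinary-least-squares model per voxel (``Y`` is
subjects x voxels) and evaluates t and F contrasts. On top of it sit the
three analyses used throughout the pipeline:

* a single-factor four-level ANCOVA across the HC / MCIs / MCIp / AD groups
  with age, sex, education years and total intracranial volume as nuisance
  covariates (cell-means coding, so contrasts are direct group-mean
  differences);
* per-group one-sample t-tests of the mean rate against zero, evaluated at
  the covariate means (covariates are mean-centered);
* conversion of t maps to z maps through the exact CDF composition
  ``z = Phi^-1(F_t(t; df))``, sign-preserving.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .cohort import COVARIATE_NAMES, GROUPS
from .grid import Grid
from .rates import AnalysisMask, RateMap

logger = logging.getLogger(__name__)

Z_CLAMP = 38.0
"""|z| ceiling for degenerate (zero-residual-variance) voxels."""

_T_DEGENERATE = 1e12  # placeholder t at zero-variance voxels; z-clamped later


@dataclass
class StatMap:
    """Voxel-wise statistic map with its degrees of freedom and provenance."""

    data: np.ndarray
    stat_kind: str  # "t", "F" or "z"
    df: float | tuple[float, float]
    contrast: str
    grid: Grid
    mask: AnalysisMask | None = None

    def __post_init__(self) -> None:
        if self.stat_kind not in ("t", "F", "z"):
            raise ValueError(f"stat_kind must be t/F/z, got {self.stat_kind!r}")
        self.data = np.asarray(self.data, dtype=float)
        self.grid.check_data(self.data)

    def in_mask(self) -> np.ndarray:
        if self.mask is None:
            return self.data.ravel()
        return self.data[self.mask.data]


@dataclass
class DesignMatrix:
    """Subjects-by-regressors design with named columns."""

    matrix: np.ndarray
    names: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("design matrix shape does not match column names")
        if self.matrix.shape[0] < self.matrix.shape[1] + 1:
            raise ValueError("need at least n_columns + 1 rows")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def contrast(self, spec: str | np.ndarray) -> np.ndarray:
        """Build a contrast vector from a string such as ``"MCIp-MCIs"``."""
        if not isinstance(spec, str):
            c = np.asarray(spec, dtype=float)
            if c.shape != (len(self.names),):
                raise ValueError("contrast length must equal number of columns")
            return c
        c = np.zeros(len(self.names))
        if "-" in spec:
            plus, minus = spec.split("-", 1)
            c[self.names.index(plus.strip())] = 1.0
            c[self.names.index(minus.strip())] = -1.0
        else:
            c[self.names.index(spec.strip())] = 1.0
        return c


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns that are (numerically) linear combinations of the others."""
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        fitted = others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
        scale = max(np.linalg.norm(X[:, j]), 1.0)
        if np.linalg.norm(X[:, j] - fitted) < 1e-8 * scale:
            bad.append(names[j])
    return bad


class MassUnivariateGLM(BaseEstimator):
    """Per-voxel OLS with t and F contrasts.

    Fit on a design ``X`` of shape (n_subjects, n_regressors) and data ``Y``
    of shape (n_subjects, n_voxels). Fitted attributes follow the
    scikit-learn convention (trailing underscore).
    """

    def __init__(self, column_names: list[str] | None = None):
        self.column_names = column_names

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "MassUnivariateGLM":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x regressors)")
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != X.shape[0]:
            raise ValueError("X and Y row counts differ")
        n, p = X.shape
        names = self.column_names or [f"x{j}" for j in range(p)]
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            raise ValueError(
                "rank-deficient design; collinear columns: "
                + ", ".join(_collinear_columns(X, names))
            )
        if n < p + 1:
            raise ValueError("need more subjects than regressors")
        self.X_ = X
        self.names_ = names
        self.xtx_inv_ = np.linalg.inv(X.T @ X)
        self.coef_ = self.xtx_inv_ @ (X.T @ Y)  # (p, v)
        self.residuals_ = Y - X @ self.coef_  # (n, v)
        self.df_resid_ = n - p
        self.sigma2_ = np.einsum("nv,nv->v", self.residuals_, self.residuals_) / self.df_resid_
        # float roundoff leaves ~(eps*|Y|)^2 in perfectly fit voxels; treat
        # residual variance below that scale as exactly zero
        self._degenerate_ = self.sigma2_ <= 1e-24 * np.mean(Y**2, axis=0)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")

    def t_contrast(self, c: np.ndarray) -> np.ndarray:
        """t statistic of the 1-df contrast ``c' beta`` per voxel."""
        self._check_fitted()
        c = np.asarray(c, dtype=float)
        effect = c @ self.coef_
        var_scale = float(c @ self.xtx_inv_ @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / np.sqrt(self.sigma2_ * var_scale)
        degenerate = self._degenerate_
        if degenerate.any():
            logger.warning(
                "%d voxels with zero residual variance; statistic clamped",
                int(degenerate.sum()),
            )
            t = np.where(degenerate, np.sign(effect) * _T_DEGENERATE, t)
        return np.nan_to_num(t, nan=0.0)

    def f_contrast(self, C: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        """F statistic of a k-df contrast matrix ``C`` (k x p) per voxel."""
        self._check_fitted()
        C = np.atleast_2d(np.asarray(C, dtype=float))
        k = C.shape[0]
        CB = C @ self.coef_  # (k, v)
        M = np.linalg.inv(C @ self.xtx_inv_ @ C.T)
        quad = np.einsum("kv,kl,lv->v", CB, M, CB)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = quad / (k * self.sigma2_)
        F = np.where(self._degenerate_, _T_DEGENERATE, F)
        return np.nan_to_num(F, nan=0.0), (k, self.df_resid_)


# ---------------------------------------------------------------------------
# design builders


def _centered_covariates(cov_df: pd.DataFrame) -> np.ndarray:
    cols = [cov_df[c].to_numpy(dtype=float) for c in COVARIATE_NAMES]
    arr = np.column_stack(cols)
    return arr - arr.mean(axis=0)


def make_ancova_design(cov_df: pd.DataFrame) -> DesignMatrix:
    """Cell-means group coding plus mean-centered nuisance covariates.

    ``cov_df`` needs a ``group`` column and the four nuisance covariates;
    rows are subjects (index = subject id).
    """
    groups_present = [g for g in GROUPS if (cov_df["group"] == g).any()]
    indicators = np.column_stack(
        [(cov_df["group"] == g).to_numpy(dtype=float) for g in groups_present]
    )
    X = np.hstack([indicators, _centered_covariates(cov_df)])
    names = list(groups_present) + list(COVARIATE_NAMES)
    return DesignMatrix(X, names, list(cov_df.index))


def make_one_sample_design(cov_df: pd.DataFrame) -> DesignMatrix:
    """Intercept plus mean-centered covariates (tests the covariate-mean rate)."""
    X = np.hstack([np.ones((len(cov_df), 1)), _centered_covariates(cov_df)])
    return DesignMatrix(X, ["intercept"] + list(COVARIATE_NAMES), list(cov_df.index))


def make_seed_design(seed_values: np.ndarray, cov_df: pd.DataFrame) -> DesignMatrix:
    """Intercept + centered seed regressor + centered nuisance covariates."""
    sv = np.asarray(seed_values, dtype=float)
    if sv.std() == 0:
        raise ValueError("zero-variance seed values")
    X = np.hstack(
        [np.ones((len(cov_df), 1)), (sv - sv.mean())[:, None], _centered_covariates(cov_df)]
    )
    return DesignMatrix(X, ["intercept", "seed"] + list(COVARIATE_NAMES), list(cov_df.index))


# ---------------------------------------------------------------------------
# map-level wrappers


def stack_in_mask(rate_maps: list[RateMap], mask: AnalysisMask) -> np.ndarray:
    """(n_subjects, n_mask_voxels) data matrix."""
    return np.stack([rm.data[mask.data] for rm in rate_maps])


def _embed(values: np.ndarray, mask: AnalysisMask) -> np.ndarray:
    out = np.full(mask.grid.shape, np.nan)
    out[mask.data] = values
    return out


def fit_ancova(
    rate_maps: list[RateMap],
    design: DesignMatrix,
    contrast: str | np.ndarray,
    mask: AnalysisMask,
    return_model: bool = False,
):
    """Voxel-wise ANCOVA t map for one contrast over the group factor."""
    if len(rate_maps) != design.n:
        raise ValueError("one rate map per design row required")
    Y = stack_in_mask(rate_maps, mask)
    model = MassUnivariateGLM(column_names=design.names).fit(design.matrix, Y)
    c = design.contrast(contrast)
    t = model.t_contrast(c)
    label = contrast if isinstance(contrast, str) else "custom contrast"
    smap = StatMap(_embed(t, mask), "t", model.df_resid_, f"ancova:{label}", mask.grid, mask)
    return (smap, model) if return_model else smap


def fit_f_omnibus(
    rate_maps: list[RateMap], design: DesignMatrix, mask: AnalysisMask
) -> StatMap:
    """Omnibus F over all between-group differences (cell-means coding)."""
    group_cols = [j for j, nm in enumerate(design.names) if nm in GROUPS]
    if len(group_cols) < 2:
        raise ValueError("omnibus F needs at least two group columns")
    C = np.zeros((len(group_cols) - 1, len(design.names)))
    for i in range(len(group_cols) - 1):
        C[i, group_cols[i]] = 1.0
        C[i, group_cols[i + 1]] = -1.0
    Y = stack_in_mask(rate_maps, mask)
    model = MassUnivariateGLM(column_names=design.names).fit(design.matrix, Y)
    F, df = model.f_contrast(C)
    return StatMap(_embed(F, mask), "F", df, "ancova:omnibus", mask.grid, mask)


def fit_one_sample(
    rate_maps: list[RateMap],
    cov_df: pd.DataFrame,
    mask: AnalysisMask,
    return_model: bool = False,
):
    """One-sample t map of the group-mean rate at covariate means."""
    if len(rate_maps) < 3:
        raise ValueError("one-sample test needs at least 3 subjects")
    design = make_one_sample_design(cov_df)
    Y = stack_in_mask(rate_maps, mask)
    model = MassUnivariateGLM(column_names=design.names).fit(design.matrix, Y)
    t = model.t_contrast(design.contrast("intercept"))
    smap = StatMap(_embed(t, mask), "t", model.df_resid_, "one-sample:mean-rate", mask.grid, mask)
    return (smap, model) if return_model else smap


def t_to_z(stat_map: StatMap) -> StatMap:
    """Exact t -> z conversion, sign-preserving and clamped to |z| <= 38."""
    if stat_map.stat_kind != "t":
        raise ValueError("t_to_z requires a t map")
    df = float(stat_map.df)
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    t = stat_map.data
    finite = np.isfinite(t)
    z = np.full_like(t, np.nan)
    tf = t[finite]
    # sf/isf composition keeps precision in the far tail; symmetric in sign
    zf = np.sign(tf) * stats.norm.isf(stats.t.sf(np.abs(tf), df))
    # degenerate (zero-residual-variance) voxels carry the placeholder t
    zf = np.where(np.abs(tf) >= _T_DEGENERATE, np.sign(tf) * Z_CLAMP, zf)
    z[finite] = np.clip(zf, -Z_CLAMP, Z_CLAMP)
    return StatMap(z, "z", df, stat_map.contrast, stat_map.grid, stat_map.mask)


def residual_rate_maps(model: MassUnivariateGLM, mask: AnalysisMask) -> list[np.ndarray]:
    """Per-subject residual maps (NaN outside mask), for smoothness estimation."""
    return [_embed(model.residuals_[i], mask) for i in range(model.residuals_.shape[0])]
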