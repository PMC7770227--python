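"""Association between network atrophy rate and cognitive decline.

Each subject's per-test cognitive slope (score units per year, OLS over
their serial scores) is related to their mean SDN atrophy rate by partial
Spearman correlation: all variables are rank-transformed, the ranked x and
y are residualized on the ranked covariates by OLS, and the Pearson
correlation of the residuals is taken. p-values use the t approximation
with df = n - 2 - n_covariates. Domain tests are Bonferroni-corrected
(default 6 tests, threshold 0.05/6 ~ 0.008); the MMSE counts as a separate
global test evaluated at the uncorrected alpha.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CognitiveRecord

logger = logging.getLogger(__name__)

DOMAIN_TESTS = ("CVVLT", "CFT_copy", "CFT_recall", "VFT", "BNT", "TMT_B")
"""The six domain-specific tests entering the Bonferroni family."""

GLOBAL_TEST = "MMSE"


@dataclass
class PartialCorrResult:
    test_name: str
    rho: float
    p: float
    n: int
    alpha_threshold: float | None = None
    significant: bool | None = None


def cognitive_slopes(records: list[CognitiveRecord]) -> pd.DataFrame:
    """Per-subject, per-test OLS slope of score on time (units per year).

    Records with fewer than two time points are excluded with a log entry.
    Returns a subjects x tests DataFrame of slopes.
    """
    rows: dict[str, dict[str, float]] = {}
    for rec in records:
        if len(rec.times) < 2:
            logger.info("excluding %s/%s: fewer than 2 time points", rec.subject_id, rec.test_name)
            continue
        tc = rec.times - rec.times.mean()
        slope = float(np.dot(tc, rec.scores - rec.scores.mean()) / np.dot(tc, tc))
        rows.setdefault(rec.subject_id, {})[rec.test_name] = slope
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    test_name: str = "",
) -> PartialCorrResult:
    """Partial Spearman rank correlation of x and y given covariates.

    Rank-transforms every variable, residualizes ranked x and ranked y on
    the ranked covariates (with intercept) by OLS, and correlates the
    residuals. With no covariates this equals the ordinary Spearman rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant x or y: rank correlation undefined")
    n = x.size
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
        if Z.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
    k = Z.shape[1]
    if n <= k + 3:
        raise ValueError("need n > n_covariates + 3 observations")
    rx, ry = _rank(x), _rank(y)
    rz = np.column_stack([np.ones(n)] + [_rank(Z[:, j]) for j in range(k)])
    beta_x, *_ = np.linalg.lstsq(rz, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(rz, ry, rcond=None)
    ex = rx - rz @ beta_x
    ey = ry - rz @ beta_y
    denom = np.sqrt(np.dot(ex, ex) * np.dot(ey, ey))
    if denom == 0:
        raise ValueError("residual variance is zero after covariate removal")
    rho = float(np.clip(np.dot(ex, ey) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrResult(test_name, rho, p, n)


def bonferroni(
    results: list[PartialCorrResult],
    alpha: float = 0.05,
    n_tests: int = len(DOMAIN_TESTS),
) -> list[PartialCorrResult]:
    """Annotate results with Bonferroni significance.

    Domain tests are significant when p < alpha / n_tests; the MMSE is a
    separate global test evaluated at the uncorrected alpha.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    out = []
    for r in results:
        thr = alpha if r.test_name == GLOBAL_TEST else alpha / n_tests
        out.append(
            PartialCorrResult(r.test_name, r.rho, r.p, r.n, thr, bool(r.p < thr))
        )
    return out
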