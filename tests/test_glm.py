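"""Mass-univariate GLM: ANCOVA contrasts, one-sample tests, t-to-z."""
import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize, stats

from sdnmap.glm import (
    MassUnivariateGLM,
    StatMap,
    Z_CLAMP,
    fit_ancova,
    fit_f_omnibus,
    fit_one_sample,
    make_ancova_design,
    t_to_z,
)
from sdnmap.grid import Grid
from sdnmap.rates import AnalysisMask, RateMap

GRID = Grid((4, 4, 4), 2.0)
FULL_MASK = AnalysisMask(np.ones(GRID.shape, bool), GRID)


def _cov_df(groups, rng):
    n = len(groups)
    return pd.DataFrame(
        {
            "group": groups,
            "age": rng.normal(76, 6, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.normal(12, 4, n),
            "tiv": rng.normal(1.46e6, 1e5, n),
        },
        index=[f"s{i}" for i in range(n)],
    )


def _rate_maps(values, groups):
    return [
        RateMap(f"s{i}", np.full(GRID.shape, v, float), GRID, group=g)
        for i, (v, g) in enumerate(zip(values, groups))
    ]


class TestAncova:
    def test_identical_groups_give_zero_t(self, rng):
        # two groups, no covariates, identical data in both groups -> t = 0
        X = np.repeat(np.eye(2), 5, axis=0)
        values = np.concatenate([np.arange(5.0), np.arange(5.0)])
        Y = np.outer(values, np.ones(7))
        model = MassUnivariateGLM(column_names=["HC", "AD"]).fit(X, Y)
        assert np.allclose(model.t_contrast([1.0, -1.0]), 0.0, atol=1e-10)

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        groups = ["HC"] * 4 + ["AD"] * 4
        cov = _cov_df(groups, rng)
        values = rng.standard_normal(8)
        maps = _rate_maps(values, groups)
        design = make_ancova_design(cov)
        smap = fit_ancova(maps, design, "HC-AD", FULL_MASK)
        fit = sm.OLS(values, design.matrix).fit()
        c = design.contrast("HC-AD")
        expected = float(np.squeeze(fit.t_test(c).tvalue))
        assert smap.data[0, 0, 0] == pytest.approx(expected, abs=1e-10)
        assert smap.df == fit.df_resid

    def test_rank_deficient_design_names_columns(self, rng):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        Y = rng.standard_normal((10, 3))
        model = MassUnivariateGLM(column_names=["intercept", "a", "twice_a"])
        with pytest.raises(ValueError, match="twice_a"):
            model.fit(X, Y)

    def test_invariant_to_covariate_rescaling(self, rng):
        groups = ["HC"] * 6 + ["MCIs"] * 6
        cov = _cov_df(groups, rng)
        maps = _rate_maps(rng.standard_normal(12), groups)
        t1 = fit_ancova(maps, make_ancova_design(cov), "HC-MCIs", FULL_MASK).data
        cov2 = cov.copy()
        cov2["age"] = cov2["age"] * 12.0 + 400.0
        cov2["tiv"] = cov2["tiv"] / 1e6
        t2 = fit_ancova(maps, make_ancova_design(cov2), "HC-MCIs", FULL_MASK).data
        assert np.allclose(t1, t2, atol=1e-8)

    def test_omnibus_f_equals_t_squared_for_two_groups(self, rng):
        groups = ["HC"] * 6 + ["AD"] * 6
        cov = _cov_df(groups, rng)
        maps = _rate_maps(rng.standard_normal(12), groups)
        design = make_ancova_design(cov)
        t = fit_ancova(maps, design, "HC-AD", FULL_MASK).data
        F = fit_f_omnibus(maps, design, FULL_MASK).data
        assert np.allclose(F, t**2, atol=1e-8)


class TestOneSample:
    def test_closed_form_t(self):
        # rates 1,2,3 at one voxel, no covariates: t = mean/(sd/sqrt(n))
        X = np.ones((3, 1))
        Y = np.array([[1.0], [2.0], [3.0]])
        model = MassUnivariateGLM().fit(X, Y)
        t = model.t_contrast([1.0])
        assert t[0] == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-12)

    def test_zero_rates_give_zero_t(self, rng):
        groups = ["AD"] * 6
        cov = _cov_df(groups, rng)
        maps = _rate_maps(np.zeros(6), groups)
        smap = fit_one_sample(maps, cov.drop(columns="group"), FULL_MASK)
        assert np.allclose(smap.data, 0.0)

    def test_zero_variance_nonzero_rates_clamped(self, rng):
        # constant nonzero rates: residual variance is exactly zero
        groups = ["AD"] * 6
        cov = _cov_df(groups, rng)
        maps = _rate_maps(np.full(6, -0.02), groups)
        smap = fit_one_sample(maps, cov.drop(columns="group"), FULL_MASK)
        z = t_to_z(smap)
        assert np.all(np.isfinite(z.data))
        assert np.allclose(z.data, -Z_CLAMP)

    def test_too_few_subjects_rejected(self, rng):
        groups = ["AD"] * 2
        cov = _cov_df(groups, rng)
        maps = _rate_maps([0.1, 0.2], groups)
        with pytest.raises(ValueError, match="at least 3"):
            fit_one_sample(maps, cov.drop(columns="group"), FULL_MASK)


class TestTtoZ:
    def _stat(self, t, df):
        data = np.full(GRID.shape, float(t))
        return StatMap(data, "t", df, "test", GRID, FULL_MASK)

    def test_zero_maps_to_zero(self):
        for df in (3, 10, 100):
            assert t_to_z(self._stat(0.0, df)).data[0, 0, 0] == 0.0

    def test_large_df_limit(self):
        z = t_to_z(self._stat(1.5, 1e6)).data[0, 0, 0]
        assert z == pytest.approx(1.5, abs=1e-3)

    def test_matches_quadrature_oracle(self):
        t_val, df = 2.5, 30
        z = t_to_z(self._stat(t_val, df)).data[0, 0, 0]
        # oracle: integrate the t density, then invert the normal CDF by root finding
        tail, _ = integrate.quad(lambda u: stats.t.pdf(u, df), t_val, np.inf)
        z_expected = optimize.brentq(lambda v: stats.norm.cdf(v) - (1 - tail), -10, 10, xtol=1e-12)
        assert z == pytest.approx(z_expected, abs=1e-8)

    def test_sign_symmetry(self):
        zp = t_to_z(self._stat(2.2, 14)).data[0, 0, 0]
        zn = t_to_z(self._stat(-2.2, 14)).data[0, 0, 0]
        assert zp == -zn

    def test_requires_positive_df(self):
        with pytest.raises(ValueError):
            t_to_z(self._stat(1.0, 0))


def test_voxelwise_false_positive_rate_calibrated(rng):
    """Under pure noise the fraction of |p|<0.005 voxels is ~0.005."""
    n, n_vox = 40, 30**3
    groups = ["HC"] * 20 + ["AD"] * 20
    X = np.column_stack([(np.array(groups) == "HC").astype(float),
                         (np.array(groups) == "AD").astype(float)])
    Y = rng.standard_normal((n, n_vox))
    model = MassUnivariateGLM(column_names=["HC", "AD"]).fit(X, Y)
    t = model.t_contrast([1.0, -1.0])
    p = 2 * stats.t.sf(np.abs(t), model.df_resid_)
    frac = float((p < 0.005).mean())
    se = np.sqrt(0.005 * 0.995 / n_vox)
    assert abs(frac - 0.005) < 3 * se
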