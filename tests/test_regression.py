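"""OLS/VIF, the space-time metric, local fits, AICc and bandwidth selection."""

import math

import numpy as np
import pytest

from stpanel.errors import DomainError, ParameterError, SingularDesignError
from stpanel.regression import (
    DesignMatrix,
    KernelSpec,
    aicc_value,
    build_design,
    collinearity_verdict,
    fit_local,
    fit_ols,
    select_bandwidth,
    st_distance2,
    vif,
)
from stpanel.synthetic import gen_varying_coefficient_panel, constant_truth_spec


def _design(y, Xc, names=None, coords=None, times=None):
    n = len(y)
    names = names or [f"x{i}" for i in range(Xc.shape[1])]
    X = np.column_stack([np.ones(n), Xc])
    return DesignMatrix(
        y=np.asarray(y, float), X=X, covariate_names=names,
        obs_keys=[(f"u{i}", 2011) for i in range(n)],
        coords=coords if coords is not None else np.zeros((n, 2)),
        times=times if times is not None else np.zeros(n),
    )


class TestOls:
    def test_exact_line(self):
        d = _design([1, 3, 5, 7], np.array([[0.0], [1.0], [2.0], [3.0]]))
        fit = fit_ols(d)
        assert fit.beta == pytest.approx([1.0, 2.0], abs=1e-12)
        assert fit.R2 == pytest.approx(1.0)
        assert fit.RSS == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(fit.residuals, 0.0, atol=1e-12)

    def test_matches_pinv_oracle(self):
        rng = np.random.default_rng(30)
        Xc = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        d = _design(y, Xc)
        fit = fit_ols(d)
        beta_pinv = np.linalg.pinv(d.X) @ y
        assert fit.beta == pytest.approx(beta_pinv, abs=1e-8)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(31)
        Xc = rng.normal(size=(40, 3))
        y = Xc @ [0.5, -1.0, 2.0] + rng.normal(size=40)
        d = _design(y, Xc)
        fit = fit_ols(d)
        ref = sm.OLS(y, d.X).fit()
        assert fit.beta == pytest.approx(ref.params, abs=1e-10)
        assert fit.se == pytest.approx(ref.bse, abs=1e-10)
        assert fit.R2 == pytest.approx(ref.rsquared, abs=1e-12)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(32)
        a = rng.normal(size=20)
        Xc = np.column_stack([a, 2 * a, rng.normal(size=20)])
        with pytest.raises(SingularDesignError):
            _design(np.zeros(20), Xc, names=["a", "a2", "b"])


class TestVif:
    def test_orthogonal_covariates_give_unit_vif(self):
        # centered, mutually orthogonal columns
        q, _ = np.linalg.qr(np.random.default_rng(33).normal(size=(20, 3)))
        Xc = q - q.mean(axis=0)
        q2, _ = np.linalg.qr(Xc)
        d = _design(np.random.default_rng(0).normal(size=20), q2)
        vifs, tols = vif(d)
        assert vifs == pytest.approx(np.ones(3), abs=1e-8)
        assert tols == pytest.approx(np.ones(3), abs=1e-8)

    def test_exact_correlation_08_gives_closed_form(self):
        rng = np.random.default_rng(34)
        n = 50
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal to a
        b /= b.std()
        x2 = 0.8 * a + math.sqrt(1 - 0.64) * b  # sample corr with a is exactly 0.8
        d = _design(rng.normal(size=n), np.column_stack([a, x2]))
        vifs, _ = vif(d)
        assert vifs == pytest.approx([1 / (1 - 0.64)] * 2, abs=1e-10)
        assert vifs[0] == pytest.approx(2.7778, abs=1e-4)

    def test_screening_verdict(self):
        # the screen needs BOTH all tolerances > 0.3 and all VIF < 5
        assert collinearity_verdict(np.array([1.2, 2.5, 3.0])) == "no collinearity"
        assert "suspected" in collinearity_verdict(np.array([1.2, 6.0]))
        assert "suspected" in collinearity_verdict(np.array([4.9]))  # tolerance 0.204

    def test_perfect_collinearity_flagged(self):
        rng = np.random.default_rng(35)
        a = rng.normal(size=20)
        X = np.column_stack([np.ones(20), a, 3 * a + 1])
        d = DesignMatrix.__new__(DesignMatrix)  # bypass rank check to reach vif
        d.y, d.X, d.covariate_names = np.zeros(20), X, ["a", "b"]
        d.obs_keys = [(f"u{i}", 2011) for i in range(20)]
        d.coords, d.times = np.zeros((20, 2)), np.zeros(20)
        with pytest.raises(SingularDesignError, match="collinear"):
            vif(d)


class TestStDistance:
    def test_temporal_component_arithmetic(self):
        d = _design(np.zeros(4), np.random.default_rng(1).normal(size=(4, 1)),
                    times=np.array([2011.0, 2013.0, 2011.0, 2011.0]))
        D2 = st_distance2(d, "gtwr", st_ratio=2500.0)
        assert D2[0, 1] == pytest.approx(2500.0 * 4.0)  # Δt=2 yr, τ=2500 km²/yr²

    def test_tau_zero_reduces_to_spatial(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(6, 2)) * 100
        d = _design(np.zeros(6), rng.normal(size=(6, 1)), coords=coords,
                    times=rng.normal(size=6))
        assert np.allclose(st_distance2(d, "gtwr", 0.0), st_distance2(d, "gwr"), atol=0)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        d = _design(np.zeros(8), rng.normal(size=(8, 1)),
                    coords=rng.normal(size=(8, 2)) * 50, times=rng.integers(0, 5, 8).astype(float))
        D2 = st_distance2(d, "gtwr", 1000.0)
        assert np.allclose(D2, D2.T, atol=0)

    def test_negative_tau_rejected(self):
        d = _design(np.zeros(5), np.random.default_rng(4).normal(size=(5, 1)))
        with pytest.raises(ParameterError):
            st_distance2(d, "gtwr", -1.0)


class TestLocalFitLimits:
    def test_infinite_bandwidth_recovers_ols(self, reference_design):
        d = reference_design
        spec = KernelSpec(model="gwr", kernel="gaussian",
                          bandwidth_mode="fixed_distance", bandwidth=1e9)
        local = fit_local(d, spec)
        ols = fit_ols(d)
        assert np.max(np.abs(local.beta_local - ols.beta)) < 1e-6
        assert local.trace_S == pytest.approx(d.k + 1, abs=1e-6)

    def test_gtwr_tau_zero_single_year_equals_gwr(self, reference_dataset):
        panel = reference_dataset.panel
        single = [o for o in panel.observations if o.year == 2011]
        from stpanel.panel import PanelTable
        d = build_design(PanelTable(panel.units, single, panel.covariate_names))
        a = fit_local(d, KernelSpec(model="gtwr", bandwidth=15, st_ratio=0.0))
        b = fit_local(d, KernelSpec(model="gwr", bandwidth=15))
        assert np.allclose(a.beta_local, b.beta_local, atol=0)
        assert a.AICc == b.AICc

    def test_colocated_units_gtwr_equals_twr(self):
        rng = np.random.default_rng(40)
        n = 40
        times = np.repeat([2011.0, 2013.0, 2015.0, 2018.0], 10)
        Xc = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        d = _design(y, Xc, coords=np.zeros((n, 2)), times=times)
        a = fit_local(d, KernelSpec(model="gtwr", bandwidth=20, st_ratio=1e4))
        b = fit_local(d, KernelSpec(model="twr", bandwidth=20))
        assert np.allclose(a.beta_local, b.beta_local, atol=1e-10)

    def test_hat_matrix_reproduces_fitted_values(self, reference_design):
        spec = KernelSpec(model="gwr", bandwidth=20)
        fit = fit_local(reference_design, spec, keep_hat_matrix=True)
        yhat = fit.hat_matrix @ reference_design.y
        assert np.max(np.abs(yhat - fit.yhat)) < 1e-8
        assert fit.trace_S == pytest.approx(np.trace(fit.hat_matrix), abs=1e-10)

    def test_pseudo_t_consistent_with_se(self, reference_design):
        fit = fit_local(reference_design, KernelSpec(model="gwr", bandwidth=25))
        mask = fit.se_local > 0
        assert np.allclose(fit.t_local[mask], (fit.beta_local / fit.se_local)[mask], atol=1e-12)


class TestAicc:
    def test_monotone_in_complexity(self):
        assert aicc_value(50, 2.0, 6.0) > aicc_value(50, 2.0, 5.0)

    def test_decreasing_in_rss(self):
        assert aicc_value(50, 1.0, 5.0) < aicc_value(50, 2.0, 5.0)

    def test_frozen_symbolic_value(self):
        # 2n ln(sigma) + n ln(2 pi) + n(n+trS)/(n-2-trS) at n=50, RSS=2, trS=5
        assert aicc_value(50, 2.0, 5.0) == pytest.approx(-5.09644955084974, abs=1e-10)

    def test_undefined_when_dof_exhausted(self):
        with pytest.raises(DomainError):
            aicc_value(10, 1.0, 8.0)


class TestBandwidthSelection:
    def test_golden_section_matches_grid(self, reference_design):
        for model, taus in (("gwr", None), ("gtwr", [1e4])):
            g = select_bandwidth(reference_design, model, search="golden_section", tau_grid=taus)
            e = select_bandwidth(reference_design, model, search="grid", tau_grid=taus)
            assert min(a for *_, a in g.evaluated) == pytest.approx(
                min(a for *_, a in e.evaluated), abs=1e-9)

    def test_chosen_attains_minimum_of_trace(self, reference_design):
        res = select_bandwidth(reference_design, "gwr")
        best = min(res.evaluated, key=lambda t: t[2])
        assert res.chosen.bandwidth == best[0]

    def test_constant_coefficients_no_spurious_localization(self):
        # flat AICc profile near q_max expected when nothing varies
        ok = 0
        for seed in range(10):
            ds = gen_varying_coefficient_panel(truth_spec=constant_truth_spec(), seed=3000 + seed)
            d = build_design(ds.panel)
            res = select_bandwidth(d, "gwr")
            by_q = {q: a for q, _, a in res.evaluated}
            q_max = max(by_q)
            a_min = min(by_q.values())
            if res.chosen.bandwidth == q_max or by_q[q_max] - a_min <= 3.0:
                ok += 1
        assert ok >= 8

    def test_varying_coefficients_localize(self, reference_design):
        res = select_bandwidth(reference_design, "gwr")
        assert res.chosen.bandwidth < reference_design.n

    def test_empty_range_rejected(self, reference_design):
        with pytest.raises(ParameterError):
            select_bandwidth(reference_design, "gwr", q_range=(50, 40))

    def test_too_small_local_window_is_singular(self):
        rng = np.random.default_rng(41)
        n = 30
        # bisquare with a 1 km fixed bandwidth leaves only the point itself
        coords = rng.normal(size=(n, 2)) * 500
        Xc = rng.normal(size=(n, 5))
        d = _design(rng.normal(size=n), Xc, coords=coords)
        spec = KernelSpec(model="gwr", kernel="bisquare",
                          bandwidth_mode="fixed_distance", bandwidth=1.0)
        with pytest.raises(SingularDesignError, match="bandwidth"):
            fit_local(d, spec)
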