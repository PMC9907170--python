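import numpy as np
import pytest

import phenoplate as pp
from phenoplate import growth_curves as gcm
from phenoplate import synthetic_plate as sp
from conftest import gompertz_curve


class TestSmoothSeries:
    def test_constant_unchanged(self):
        x = np.full(20, 0.3)
        np.testing.assert_array_equal(pp.smooth_series(x), x)

    def test_median_removes_singleton_spike(self):
        x = np.array([0.1, 0.1, 0.9, 0.1, 0.1])
        out = pp.smooth_series(x, despike_window=3, avg_window=1)
        np.testing.assert_allclose(out, 0.1)

    def test_linear_ramp_preserved_at_interior(self):
        x = 0.1 + 0.01 * np.arange(30)
        out = pp.smooth_series(x, despike_window=5, avg_window=3)
        np.testing.assert_allclose(out[2:-2], x[2:-2], atol=1e-12)

    def test_idempotent_on_linear_interior(self):
        x = 0.1 + 0.01 * np.arange(30)
        once = pp.smooth_series(x)
        twice = pp.smooth_series(once)
        np.testing.assert_allclose(twice[4:-4], once[4:-4], atol=1e-12)

    @pytest.mark.parametrize("despike,avg", [(4, 3), (5, 2), (31, 3)])
    def test_bad_windows_rejected(self, despike, avg):
        with pytest.raises(ValueError):
            pp.smooth_series(np.ones(20), despike, avg)


class TestLogTransform:
    def test_direct_logs(self):
        t = np.array([0.0, 10.0, 20.0])
        curve = pp.log_transform(np.array([0.1, 0.2, 0.4]), t, init_cycles=1)
        np.testing.assert_allclose(curve.log_ratio, [0.0, np.log(2), np.log(4)])

    def test_constant_series_flat(self):
        t = np.arange(4) * 10.0
        curve = pp.log_transform(np.full(4, 0.1), t, init_cycles=1)
        np.testing.assert_allclose(curve.log_ratio, 0.0)

    def test_init_mean_rule(self):
        t = np.arange(4) * 10.0
        curve = pp.log_transform(np.array([0.09, 0.10, 0.11, 0.2]), t, init_cycles=3)
        assert curve.od_init == pytest.approx(0.10)

    def test_all_zero_series_flagged_degenerate(self):
        t = np.arange(5) * 10.0
        curve = pp.log_transform(np.zeros(5), t)
        assert "degenerate_curve" in curve.flags
        np.testing.assert_allclose(curve.log_ratio, 0.0)


class TestEstimateTraits:
    def test_pure_exponential(self):
        t = np.arange(0, 1000, 10.0)
        od = 0.05 * np.exp(0.01 * t)
        curve = gcm.GrowthCurve(t, od, 0.05, 0.01 * t)
        traits = pp.estimate_traits(curve, 5)
        assert traits.mu_max == pytest.approx(0.01, abs=1e-10)
        assert traits.lag_lambda == pytest.approx(0.0, abs=1e-6)

    def test_flat_curve(self):
        t = np.arange(0, 200, 10.0)
        curve = pp.log_transform(np.full(len(t), 0.1), t, init_cycles=1)
        traits = pp.estimate_traits(curve, 5)
        assert traits.mu_max == 0.0
        assert traits.lag_lambda == 0.0
        assert traits.kappa == pytest.approx(0.1)

    def test_gompertz_single_point(self):
        spec = sp.WellSimSpec(lag_lambda=300.0, mu_max=0.012, asym_A=3.0)
        traits = pp.estimate_traits(gompertz_curve(spec), 5)
        assert traits.mu_max == pytest.approx(spec.mu_max, rel=0.02)
        assert traits.lag_lambda == pytest.approx(spec.effective_lag, rel=0.05)

    @pytest.mark.parametrize("lam", [60.0, 300.0, 600.0])
    @pytest.mark.parametrize("mu", [0.003, 0.01, 0.03])
    @pytest.mark.parametrize("A", [1.0, 2.5, 4.0])
    def test_gompertz_grid_recovery(self, lam, mu, A):
        """Trait recovery across the simulator parameter grid.

        Sampled at 2 min so the 5-point slope window resolves even the
        fastest rise (A=1, mu=0.03 climbs in ~30 min); the lag oracle is
        the tangent lag of the observed curve (see WellSimSpec.effective_lag).
        """
        spec = sp.WellSimSpec(lag_lambda=lam, mu_max=mu, asym_A=A)
        traits = pp.estimate_traits(gompertz_curve(spec, dt=2.0), 5)
        assert traits.mu_max == pytest.approx(mu, rel=0.02)
        assert traits.lag_lambda == pytest.approx(spec.effective_lag, rel=0.05)
        assert traits.kappa == pytest.approx(spec.kappa, rel=0.02)

    def test_too_short_curve_rejected(self):
        t = np.arange(3) * 10.0
        curve = pp.log_transform(np.array([0.1, 0.2, 0.3]), t, init_cycles=1)
        with pytest.raises(ValueError):
            pp.estimate_traits(curve, 5)


class TestAggregateReplicates:
    def _curve(self, L):
        t = np.arange(len(L)) * 10.0
        return gcm.GrowthCurve(t, 0.05 * np.exp(np.asarray(L)), 0.05, np.asarray(L, float))

    def test_identical_curves(self):
        c = self._curve([0.0, 1.0, 2.0])
        mean, sem = pp.aggregate_replicates([c, c])
        np.testing.assert_allclose(mean.log_ratio, c.log_ratio)
        np.testing.assert_allclose(sem, 0.0)

    def test_two_curve_sem(self):
        mean, sem = pp.aggregate_replicates([self._curve([1.0, 1.0]), self._curve([3.0, 3.0])])
        np.testing.assert_allclose(mean.log_ratio, 2.0)
        np.testing.assert_allclose(sem, 1.0)  # SD=sqrt(2), /sqrt(2)

    def test_single_curve_zero_sem(self):
        c = self._curve([0.0, 0.5])
        mean, sem = pp.aggregate_replicates([c])
        np.testing.assert_allclose(mean.log_ratio, c.log_ratio)
        np.testing.assert_allclose(sem, 0.0)

    def test_mismatched_grids_rejected(self):
        a = self._curve([0.0, 1.0])
        b = gcm.GrowthCurve([0.0, 20.0], [0.05, 0.1], 0.05, [0.0, 0.7])
        with pytest.raises(ValueError):
            pp.aggregate_replicates([a, b])


class TestFindPhi:
    def test_logistic_slope_below_threshold(self, logistic_reference):
        ref = logistic_reference
        traits = pp.estimate_traits(ref["curve"], 5)
        phi = pp.find_phi(ref["curve"], traits)
        assert phi.reached
        # instantaneous logistic log-slope at phi: r * (1 - N/K)
        n_phi = np.interp(phi.phi, ref["times"], ref["N"])
        inst = ref["r"] * (1 - n_phi / ref["K"])
        assert inst <= 0.05 * traits.mu_max * (1 + 1e-6)

    def test_logistic_density_fraction_at_phi(self, logistic_reference):
        ref = logistic_reference
        traits = pp.estimate_traits(ref["curve"], 5)
        phi = pp.find_phi(ref["curve"], traits)
        frac = np.interp(phi.phi, ref["times"], ref["N"]) / ref["K"]
        assert 0.94 <= frac <= 0.965

    def test_shift_capped_at_grid_end(self, logistic_reference):
        ref = logistic_reference
        traits = pp.estimate_traits(ref["curve"], 5)
        phi0 = pp.find_phi(ref["curve"], traits)
        phi1k = pp.find_phi(ref["curve"], traits, shift=1000.0)
        assert phi1k.phi == pytest.approx(min(phi0.phi + 1000.0, ref["times"][-1]))
        phi_huge = pp.find_phi(ref["curve"], traits, shift=1e6)
        assert phi_huge.phi == ref["times"][-1]

    def test_never_crossing_falls_back_with_warning(self):
        t = np.arange(0, 500, 10.0)
        curve = gcm.GrowthCurve(t, 0.05 * np.exp(0.01 * t), 0.05, 0.01 * t)
        traits = pp.estimate_traits(curve, 5)
        with pytest.warns(UserWarning, match="never fell"):
            phi = pp.find_phi(curve, traits)
        assert not phi.reached
        assert phi.phi == t[-1]

    def test_non_growing_reference_rejected(self):
        t = np.arange(0, 200, 10.0)
        curve = pp.log_transform(np.full(len(t), 0.1), t, init_cycles=1)
        traits = pp.estimate_traits(curve, 5)
        with pytest.raises(ValueError, match="undefined"):
            pp.find_phi(curve, traits)


class TestComputeAuc:
    def _flat(self, c, n=11):
        t = np.arange(n) * 10.0
        return gcm.GrowthCurve(t, np.full(n, 0.05 * np.exp(c)), 0.05, np.full(n, c))

    def test_rectangle(self):
        phi = gcm.PhiPoint(phi=80.0)
        res = pp.compute_auc(self._flat(2.0), phi)
        assert res.auc == pytest.approx(2.0 * 80.0)

    def test_triangle_with_partial_interval(self):
        t = np.arange(0, 110, 10.0)
        m = 0.02
        curve = gcm.GrowthCurve(t, 0.05 * np.exp(m * t), 0.05, m * t)
        phi = gcm.PhiPoint(phi=95.0)
        res = pp.compute_auc(curve, phi)
        assert res.auc == pytest.approx(m * 95.0**2 / 2, abs=1e-9)

    def test_negative_dip_clipped(self):
        t = np.arange(3) * 10.0
        curve = gcm.GrowthCurve(t, np.full(3, 0.05), 0.05, np.array([0.0, -0.1, 0.0]))
        res = pp.compute_auc(curve, gcm.PhiPoint(phi=20.0))
        assert res.auc == 0.0
        res_unclipped = pp.compute_auc(curve, gcm.PhiPoint(phi=20.0), clip_negative=False)
        assert res_unclipped.auc < 0.0

    def test_phi_beyond_grid_flagged(self):
        res = pp.compute_auc(self._flat(1.0), gcm.PhiPoint(phi=500.0))
        assert "phi_beyond_grid" in res.flags
        assert res.auc == pytest.approx(100.0)

    def test_auc_nondecreasing_in_phi(self, logistic_reference):
        curve = logistic_reference["curve"]
        aucs = [pp.compute_auc(curve, gcm.PhiPoint(phi=p)).auc for p in np.linspace(50, 2400, 24)]
        assert np.all(np.diff(aucs) >= -1e-12)


class TestRelativeAuc:
    def test_identical_curves_give_one(self, logistic_reference):
        curve = logistic_reference["curve"]
        phi = gcm.PhiPoint(phi=800.0)
        a = pp.compute_auc(curve, phi)
        assert pp.relative_auc(a, a) == pytest.approx(1.0)

    def test_zero_growth_treated(self, logistic_reference):
        t = logistic_reference["times"]
        flat = pp.log_transform(np.full(len(t), 0.05), t, init_cycles=1)
        phi = gcm.PhiPoint(phi=800.0)
        num = pp.compute_auc(flat, phi)
        den = pp.compute_auc(logistic_reference["curve"], phi)
        assert pp.relative_auc(num, den) == 0.0

    def test_near_zero_control_rejected(self):
        t = np.arange(5) * 10.0
        flat = pp.log_transform(np.full(5, 0.05), t, init_cycles=1)
        phi = gcm.PhiPoint(phi=40.0)
        a = pp.compute_auc(flat, phi)
        with pytest.raises(ZeroDivisionError):
            pp.relative_auc(a, a)

    def test_mismatched_phi_rejected(self, logistic_reference):
        curve = logistic_reference["curve"]
        a = pp.compute_auc(curve, gcm.PhiPoint(phi=500.0))
        b = pp.compute_auc(curve, gcm.PhiPoint(phi=600.0))
        with pytest.raises(ValueError):
            pp.relative_auc(a, b)


class TestPhiShiftScenarios:
    def test_lag_only_deficit_shrinks_with_shift(self):
        """A purely lag-shifted culture catches up once the control plateaus."""
        t = sp.default_time_grid()
        ctrl = sp.WellSimSpec(lag_lambda=250.0, mu_max=0.011, asym_A=4.0)
        lagged = sp.WellSimSpec(lag_lambda=900.0, mu_max=0.011, asym_A=4.0)
        cc = pp.log_transform(sp.true_od_series(ctrl, t), t, init_cycles=1)
        lc = pp.log_transform(sp.true_od_series(lagged, t), t, init_cycles=1)
        traits = pp.estimate_traits(cc, 5)
        deltas = []
        for shift in (0.0, 1000.0):
            phi = pp.find_phi(cc, traits, shift=shift)
            deltas.append(
                pp.relative_auc(pp.compute_auc(lc, phi), pp.compute_auc(cc, phi))
            )
        assert deltas[1] >= deltas[0]

    def test_dominated_curve_has_delta_at_most_one(self, logistic_reference):
        """If L_treated <= L_control pointwise then delta AUC <= 1."""
        ref = logistic_reference
        curve = ref["curve"]
        worse = gcm.GrowthCurve(
            curve.times, curve.od_corr, curve.od_init, curve.log_ratio * 0.8
        )
        phi = gcm.PhiPoint(phi=900.0)
        d = pp.relative_auc(pp.compute_auc(worse, phi), pp.compute_auc(curve, phi))
        assert d <= 1.0
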