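"""Clinical analytics: AUC, reference band, classification, decay fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from perfusense import simulate as sim
from perfusense.assess import (
    DEVIATING,
    DISCARD_CANDIDATE,
    INSUFFICIENT_DATA,
    KEEP,
    WITHIN,
    ReferenceBand,
    Trajectory,
    auc_trapezoid,
    classify_trajectory,
    correlation_report,
    discrete_protocol,
    fit_exponential_decay,
    graft_report,
    interpolate_at,
    reference_band,
    resample_to_grid,
)
from perfusense.errors import (
    InsufficientDataError,
    ProtocolViolationError,
    ValidationError,
)
from perfusense.seriesio import TimeSeries


def ts(times, values):
    return TimeSeries(np.asarray(times, float), np.asarray(values, float))


class TestAucTrapezoid:
    def test_constant_inr_over_24h(self):
        s = ts(np.arange(0.0, 25.0), np.ones(25))
        assert auc_trapezoid(s, 0.0, 24.0) == pytest.approx(24.0)

    def test_zero_series(self):
        s = ts([0, 30, 60], [0, 0, 0])
        assert auc_trapezoid(s, 0.0, 60.0) == 0.0

    def test_triangle_geometry(self):
        s = ts([0, 30, 60], [0, 2, 0])
        assert auc_trapezoid(s, 0.0, 60.0) == pytest.approx(60.0)

    def test_interpolated_endpoints(self):
        s = ts([0, 10], [0, 10])  # y = t
        assert auc_trapezoid(s, 2.0, 8.0) == pytest.approx((64 - 4) / 2.0)

    def test_additivity(self):
        rng = np.random.default_rng(2)
        s = ts(np.arange(0.0, 61.0), rng.uniform(0, 2, 61))
        whole = auc_trapezoid(s, 0.0, 60.0)
        split = auc_trapezoid(s, 0.0, 23.7) + auc_trapezoid(s, 23.7, 60.0)
        assert split == pytest.approx(whole, abs=1e-9)

    def test_refuses_no_coverage_and_extrapolation(self):
        s = ts([10, 20], [1, 1])
        with pytest.raises(InsufficientDataError):
            auc_trapezoid(s, 30.0, 40.0)
        with pytest.raises(InsufficientDataError):
            auc_trapezoid(s, 0.0, 15.0)


class TestResampleAndInterpolate:
    def test_grid_equals_timestamps(self):
        traj = Trajectory("g", [0, 5, 10], [1, 2, 3])
        assert np.array_equal(resample_to_grid(traj, [0, 5, 10]), [1, 2, 3])

    def test_midpoint(self):
        traj = Trajectory("g", [0, 10], [0, 10])
        assert resample_to_grid(traj, [5.0])[0] == pytest.approx(5.0)

    def test_outside_span_is_nan_not_error(self):
        traj = Trajectory("g", [10, 20], [1, 2])
        vals = resample_to_grid(traj, [0.0, 15.0, 30.0])
        assert np.isnan(vals[0]) and np.isnan(vals[2])
        assert vals[1] == pytest.approx(1.5)

    def test_matches_piecewise_linear_oracle(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, 60, 15))
        t += np.arange(15) * 1e-6
        y = rng.uniform(0, 2, 15)
        traj = Trajectory("g", t, y)
        grid = rng.uniform(t[0], t[-1], 40)
        vals = resample_to_grid(traj, grid)
        for g, v in zip(grid, vals):
            i = np.searchsorted(t, g)
            if i == 0:
                expect = y[0]
            else:
                w = (g - t[i - 1]) / (t[i] - t[i - 1])
                expect = y[i - 1] * (1 - w) + y[i] * w
            assert v == pytest.approx(expect, abs=1e-12)

    def test_interpolate_at(self):
        s = ts([24.0, 72.0], [40.0, 80.0])
        assert interpolate_at(s, 48.0) == pytest.approx(60.0)
        assert interpolate_at(s, 24.0) == 40.0
        with pytest.raises(ValidationError):
            interpolate_at(s, 100.0)


class TestReferenceBand:
    def test_identical_trajectories_zero_width(self):
        cohort = [Trajectory(f"g{i}", [0, 30, 60], [1, 2, 3]) for i in range(4)]
        band = reference_band(cohort, [0, 30, 60])
        assert np.allclose(band.mean, [1, 2, 3])
        assert np.allclose(band.lower, band.upper)

    def test_mean_of_two_constants(self):
        cohort = [Trajectory("a", [0, 60], [1, 1]),
                  Trajectory("b", [0, 60], [3, 3])]
        band = reference_band(cohort, [0, 30, 60])
        assert np.allclose(band.mean, 2.0)

    def test_lower_clipped_at_zero(self):
        cohort = [Trajectory("a", [0, 60], [0.0, 0.1]),
                  Trajectory("b", [0, 60], [0.2, 0.3])]
        band = reference_band(cohort, [0, 60])
        assert np.all(band.lower >= 0)

    def test_permutation_invariance_and_affine_equivariance(self):
        cohort = sim.make_graft_cohort(6, 0, seed=4).good
        grid = np.arange(0.0, 61.0, 5.0)
        band = reference_band(cohort, grid)
        perm = reference_band(cohort[::-1], grid)
        assert np.allclose(band.mean, perm.mean)
        assert np.allclose(band.upper, perm.upper)
        scaled = [Trajectory(t.graft_id, t.timestamps_min, 2.0 * t.concentrations)
                  for t in cohort]
        band2 = reference_band(scaled, grid)
        assert np.allclose(band2.mean, 2.0 * band.mean)
        assert np.allclose(band2.upper, 2.0 * band.upper)

    def test_monte_carlo_coverage(self):
        """Pointwise Gaussian cohort: held-out coverage near the 95% level."""
        rng = np.random.default_rng(123)
        grid = np.arange(10.0, 61.0, 2.0)
        scn = sim.good_graft_scenario()
        mean_curve = np.array([sim.true_hope_concentration(scn, t) for t in grid])
        sigma = 0.004

        def draw():
            return Trajectory("g", grid,
                              np.clip(mean_curve + rng.normal(0, sigma, grid.shape),
                                      0, None))

        band = reference_band([draw() for _ in range(200)], grid)
        inside = []
        for _ in range(400):
            v = draw().concentrations
            inside.append(np.mean((v >= band.lower) & (v <= band.upper)))
        assert 0.93 <= float(np.mean(inside)) <= 0.97

    def test_insufficient_cohort(self):
        with pytest.raises(InsufficientDataError):
            reference_band([Trajectory("a", [0, 60], [1, 1])], [0, 60])


class TestClassify:
    @pytest.fixture()
    def band(self):
        cohort = sim.make_graft_cohort(19, 0, seed=1)
        return reference_band(cohort.good, np.arange(0.0, 61.0, 1.0))

    def test_band_mean_is_within(self, band):
        traj = Trajectory("mean", band.grid_min, band.mean)
        assert classify_trajectory(traj, band).state == WITHIN

    def test_double_upper_bound_deviates_by_excursion(self, band):
        traj = Trajectory("high", band.grid_min,
                          2.0 * band.upper + 1e-6)
        res = classify_trajectory(traj, band)
        assert res.state == DEVIATING
        assert res.above_fraction > 0.2

    def test_cohort_separation(self, band):
        cohort = sim.make_graft_cohort(19, 7, seed=1)
        held_out = sim.make_graft_cohort(20, 0, seed=1001)
        for bad in cohort.bad:
            assert classify_trajectory(bad, band).state == DEVIATING
        states = [classify_trajectory(g, band).state for g in held_out.good]
        assert sum(s == WITHIN for s in states) >= 0.9 * len(states)

    def test_monotone_in_pointwise_raise(self, band):
        cohort = sim.make_graft_cohort(3, 1, seed=7)
        for traj in cohort.all:
            base = classify_trajectory(traj, band).state
            raised = Trajectory(traj.graft_id, traj.timestamps_min,
                                traj.concentrations + 0.05)
            if base == DEVIATING:
                assert classify_trajectory(raised, band).state == DEVIATING

    def test_short_trajectory_inconclusive(self, band):
        traj = Trajectory("short", [0.0, 10.0, 20.0], [0.0, 0.01, 0.02])
        assert classify_trajectory(traj, band).state == INSUFFICIENT_DATA


class TestDiscreteProtocol:
    def test_low_readings_keep(self):
        samples = {t: 500.0 for t in (5.0, 10.0, 15.0, 30.0, 60.0)}
        verdict, triggers = discrete_protocol(samples)
        assert verdict == KEEP and triggers == []

    def test_high_30min_discards(self):
        samples = {5.0: 100, 10.0: 200, 15.0: 800, 30.0: 3500, 60.0: 3600}
        verdict, triggers = discrete_protocol(samples)
        assert verdict == DISCARD_CANDIDATE and 30.0 in triggers

    def test_boundary_triggers_at_60(self):
        samples = {5.0: 100, 10.0: 200, 15.0: 400, 30.0: 2999, 60.0: 3001}
        verdict, triggers = discrete_protocol(samples)
        assert verdict == DISCARD_CANDIDATE and triggers == [60.0]

    def test_missing_30min_sample(self):
        with pytest.raises(ProtocolViolationError):
            discrete_protocol({5.0: 100, 60.0: 100})


class TestExponentialDecay:
    def test_noiseless_recovery(self):
        t = np.arange(0.0, 7.0)
        for k in (0.05, 0.5, 2.0):
            y = 1000.0 * np.exp(-k * t) + 50.0
            fit = fit_exponential_decay(ts(t, y))
            assert fit.amplitude == pytest.approx(1000.0, rel=1e-6)
            assert fit.rate == pytest.approx(k, rel=1e-6)
            assert fit.baseline == pytest.approx(50.0, rel=1e-5, abs=1e-4)
            assert not fit.degenerate

    def test_constant_series_degenerate(self):
        fit = fit_exponential_decay(ts(np.arange(5.0), np.full(5, 80.0)))
        assert fit.degenerate
        assert fit.rate == 0.0 and fit.baseline == pytest.approx(80.0)

    def test_noisy_rate_recovery(self):
        """5% multiplicative noise: median relative error of k < 10%."""
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 7.0)
        errs = []
        for _ in range(100):
            y = (1000.0 * np.exp(-0.5 * t) + 50.0) * rng.lognormal(0, 0.05, t.shape)
            fit = fit_exponential_decay(ts(t, y))
            errs.append(abs(fit.rate - 0.5) / 0.5)
        assert float(np.median(errs)) < 0.10

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_exponential_decay(ts([0, 1, 2], [3, 2, 1]))


class TestCorrelation:
    def test_perfect_linear_pearson(self):
        x = np.arange(10.0)
        rep = correlation_report(x, 2 * x + 1, method="pearson")
        assert rep.r == pytest.approx(1.0)

    def test_monotone_nonlinear_spearman(self):
        x = np.linspace(0.1, 3.0, 12)
        rep = correlation_report(x, np.exp(x), method="spearman")
        assert rep.r == pytest.approx(1.0)

    def test_known_coupling_recovery(self):
        """Outcome = α·AUC + noise at ρ=0.8, n=19: r inside the Fisher interval."""
        rng = np.random.default_rng(19)
        cohort = sim.make_graft_cohort(19, 0, seed=19)
        aucs = np.array([auc_trapezoid(t.as_series(), 0.0, 60.0)
                         for t in cohort.good])
        z = (aucs - aucs.mean()) / aucs.std()
        rho = 0.8
        outcome = rho * z + np.sqrt(1 - rho ** 2) * rng.normal(size=z.shape)
        rep = correlation_report(aucs, outcome, method="pearson")
        zr, z0 = np.arctanh(rep.r), np.arctanh(rho)
        assert abs(zr - z0) < 1.96 / np.sqrt(19 - 3)

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            correlation_report([1, 2], [1, 2])


class TestGraftReport:
    def band(self):
        cohort = sim.make_graft_cohort(19, 0, seed=1)
        return reference_band(cohort.good, np.arange(0.0, 61.0, 1.0))

    def test_zero_trajectory(self):
        traj = Trajectory("zero", np.arange(0.0, 61.0), np.zeros(61))
        rep = graft_report(traj, self.band(),
                           {t: 100.0 for t in (5.0, 10.0, 15.0, 30.0, 60.0)})
        assert rep.auc_0_60 == 0.0
        assert rep.classification.state == WITHIN
        assert rep.discrete_verdict == KEEP

    def test_constant_one_auc(self):
        traj = Trajectory("c", np.arange(0.0, 61.0), np.ones(61))
        rep = graft_report(traj)
        assert rep.auc_0_60 == pytest.approx(60.0)
        assert rep.fmn_30min == pytest.approx(1.0)

    def test_bad_graft_flagged_with_slope_reason(self):
        cohort = sim.make_graft_cohort(19, 7, seed=1)
        rep = graft_report(cohort.bad[0], self.band())
        assert rep.state == DEVIATING
        assert any("slope" in r for r in rep.classification.reasons)

    def test_short_trajectory_insufficient(self):
        traj = Trajectory("s", [0.0, 10.0], [0.0, 0.1])
        rep = graft_report(traj)
        assert rep.state == INSUFFICIENT_DATA
        assert rep.fmn_30min is None

    def test_document_round_trip_fields(self):
        traj = Trajectory("c", np.arange(0.0, 61.0), np.ones(61))
        d = graft_report(traj, self.band()).to_dict()
        assert d["graft_id"] == "c"
        assert "auc_0_60" in d and "classification" in d
        assert "discrete_verdict" not in d  # absent, not fabricated


@settings(derandomize=True, max_examples=25)
@given(c=st.floats(0.01, 10.0), t_span=st.floats(1.0, 100.0))
def test_constant_auc_equals_c_times_span(c, t_span):
    s = TimeSeries(np.array([0.0, t_span / 2, t_span]), np.full(3, c))
    assert auc_trapezoid(s, 0.0, t_span) == pytest.approx(c * t_span, rel=1e-12)
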