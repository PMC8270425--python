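"""Two-segment labeling-curve fits and derived cell-cycle parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stemcycle as sc
from stemcycle.kinetics import (NoRiseError, TwoLineFit, TwoSegmentRegression,
                                derive_kinetics, fit_two_segment,
                                forward_model)
from stemcycle.simulate import KineticsSimSpec, simulate_labeling

# Rise-line coefficients reported for wild-type and knockout NSPCs:
# y = m*t + b with the plateau reached at t_star hours.
WT = dict(m=0.6133, b=7.996, t_star=13.47)
KO = dict(m=1.165, b=7.406, t_star=13.24)


def noiseless_timecourse(GF, Tc, Ts, times=None):
    times = np.arange(0, 25, 2.0) if times is None else np.asarray(times)
    k = sc.CycleKinetics(GF=GF, Tc=Tc, Ts=Ts, Li0=GF * Ts / Tc)
    return times, forward_model(k, times)


def brute_force_two_segment(t, li, min_rise=3, min_plateau=2):
    """Independently coded exhaustive breakpoint search."""
    distinct = np.unique(t)
    results = []
    for bp in 0.5 * (distinct[:-1] + distinct[1:]):
        rise = t <= bp
        if rise.sum() < min_rise or (~rise).sum() < min_plateau:
            continue
        if np.unique(t[rise]).size < 2:
            continue
        (m, b), rss_r = _brute_ols(t[rise], li[rise])
        if m <= 0:
            continue
        plateau = li[~rise].mean()
        sse = rss_r + float(((li[~rise] - plateau) ** 2).sum())
        results.append((sse, bp, m, b, plateau))
    return min(results, key=lambda r: (r[0], r[1]))


def _brute_ols(x, y):
    m, b = np.polyfit(x, y, 1)
    resid = y - (m * x + b)
    return (m, b), float(resid @ resid)


class TestFitTwoSegment:
    def test_recovers_reported_wt_line_from_noiseless_data(self):
        gf = WT["m"] * WT["t_star"] + WT["b"]
        t, li = noiseless_timecourse(gf, gf / WT["m"], WT["b"] / WT["m"],
                                     np.arange(2, 25, 2.0))
        fit = fit_two_segment((t, li))
        assert fit.slope == pytest.approx(WT["m"], abs=1e-6)
        assert fit.intercept == pytest.approx(WT["b"], abs=1e-6)
        assert fit.plateau == pytest.approx(gf, abs=1e-6)
        assert fit.t_star == pytest.approx(13.47, abs=1e-4)
        assert fit.sse == pytest.approx(0.0, abs=1e-18)

    def test_piecewise_linear_input_has_zero_sse(self):
        t, li = noiseless_timecourse(20.0, 25.0, 10.0)
        fit = fit_two_segment((t, li))
        assert fit.sse == pytest.approx(0.0, abs=1e-18)
        assert fit.r2_rise == pytest.approx(1.0)

    def test_grid_search_equals_independent_brute_force(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            t = np.repeat(np.arange(2, 25, 2.0), 2)
            li = np.clip(np.minimum(0.6 * t + 8, 16.3)
                         + rng.normal(0, 2.0, t.size), 0, 100)
            fit = fit_two_segment((t, li))
            sse, bp, m, b, plateau = brute_force_two_segment(t, li)
            assert fit.breakpoint == pytest.approx(bp)
            assert fit.sse == pytest.approx(sse)
            assert fit.slope == pytest.approx(m)

    def test_decreasing_timecourse_is_flagged(self):
        t = np.arange(2, 25, 2.0)
        with pytest.raises(NoRiseError):
            fit_two_segment((t, np.linspace(30, 10, t.size)))

    def test_too_few_distinct_times_rejected(self):
        with pytest.raises(ValueError):
            fit_two_segment((np.array([1.0, 2, 3]), np.array([1.0, 2, 3])))

    def test_estimator_interface_predicts_the_piecewise_curve(self):
        t, li = noiseless_timecourse(20.0, 25.0, 10.0)
        est = TwoSegmentRegression().fit(t, li)
        np.testing.assert_allclose(est.predict(t), li, atol=1e-9)
        assert est.get_params()["min_rise_points"] == 3


class TestDeriveKinetics:
    @pytest.mark.parametrize("line,exp", [
        (WT, dict(GF=16.26, Tc=26.5, Ts=13.0)),
        (KO, dict(GF=22.83, Tc=19.6, Ts=6.4)),
    ])
    def test_printed_lines_give_expected_parameters(self, line, exp):
        gf = line["m"] * line["t_star"] + line["b"]
        fit = TwoLineFit(slope=line["m"], intercept=line["b"], plateau=gf,
                         breakpoint=line["t_star"], t_star=line["t_star"],
                         sse=0.0, r2_rise=1.0, n_rise=7, n_plateau=5)
        k = derive_kinetics(fit)
        assert k.GF == pytest.approx(exp["GF"], abs=0.01)
        assert k.Tc == pytest.approx(exp["Tc"], abs=0.05)
        assert k.Ts == pytest.approx(exp["Ts"], abs=0.05)
        # defining identities
        assert k.Li0 == pytest.approx(k.GF * k.Ts / k.Tc, abs=1e-9)
        assert k.Tc - k.Ts == pytest.approx(line["t_star"], abs=1e-9)

    def test_zero_intercept_means_zero_s_phase(self):
        fit = TwoLineFit(slope=1.0, intercept=0.0, plateau=10.0,
                         breakpoint=10.0, t_star=10.0, sse=0.0, r2_rise=1.0,
                         n_rise=5, n_plateau=5)
        k = derive_kinetics(fit)
        assert k.Ts == 0.0 and k.Tc == pytest.approx(fit.t_star)

    def test_inconsistent_fits_rejected(self):
        bad = TwoLineFit(slope=1.0, intercept=20.0, plateau=10.0,
                         breakpoint=1.0, t_star=-10.0, sse=0.0, r2_rise=1.0,
                         n_rise=5, n_plateau=5)
        with pytest.raises(ValueError):
            derive_kinetics(bad)


class TestForwardModel:
    def test_intercept_and_plateau_values(self):
        k = sc.CycleKinetics(GF=16.3, Tc=26.5, Ts=13.0, Li0=8.0)
        assert forward_model(k, [0.0])[0] == pytest.approx(16.3 * 13.0 / 26.5)
        assert forward_model(k, [13.5, 20.0, 100.0]) == pytest.approx([16.3] * 3)
        with pytest.raises(ValueError):
            forward_model(k, [-1.0])

    @given(gf=st.floats(1.0, 100.0), tc=st.floats(8.0, 60.0),
           frac=st.floats(0.05, 0.95))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_roundtrip_recovers_parameters(self, gf, tc, frac):
        """forward model -> two-segment fit -> kinetics is the identity
        (2-h sampling; >= 3 rise and >= 2 plateau times sampled)."""
        ts = min(frac * tc, tc - 5.0)
        if ts <= 0:
            return
        t_star = tc - ts
        times = np.arange(0, t_star + 14, 2.0)
        k_in = sc.CycleKinetics(GF=gf, Tc=tc, Ts=ts, Li0=gf * ts / tc)
        li = forward_model(k_in, times)
        k_out = derive_kinetics(fit_two_segment((times, li)))
        assert k_out.GF == pytest.approx(gf, abs=1e-6)
        assert k_out.Tc == pytest.approx(tc, abs=1e-6)
        assert k_out.Ts == pytest.approx(ts, abs=1e-6)

    def test_scale_equivariance_in_time(self):
        t, li = noiseless_timecourse(16.3, 26.5, 13.0)
        base = fit_two_segment((t, li))
        c = 3.0
        scaled = fit_two_segment((c * t, li))
        assert scaled.slope == pytest.approx(base.slope / c)
        assert scaled.t_star == pytest.approx(c * base.t_star)
        assert scaled.plateau == pytest.approx(base.plateau)
        assert scaled.intercept == pytest.approx(base.intercept)

    def test_longer_s_phase_raises_li0_and_shortens_rise(self):
        k1 = sc.CycleKinetics(GF=16.3, Tc=26.5, Ts=10.0, Li0=16.3 * 10 / 26.5)
        k2 = sc.CycleKinetics(GF=16.3, Tc=26.5, Ts=14.0, Li0=16.3 * 14 / 26.5)
        assert forward_model(k2, [0.0])[0] > forward_model(k1, [0.0])[0]
        assert (k2.Tc - k2.Ts) < (k1.Tc - k1.Ts)


class TestBootstrap:
    def test_intervals_cover_noiseless_truth(self):
        tc = simulate_labeling(KineticsSimSpec(GF=16.3, Tc=26.5, Ts=13.0,
                                               cells_per_sample=2000,
                                               replicates=3, seed=2))
        boot = sc.bootstrap_kinetics(tc, n_boot=200, seed=3)
        assert boot.loc["GF", "ci_low"] <= 16.3 <= boot.loc["GF", "ci_high"]
        assert set(boot.index) == {"GF", "Tc", "Ts", "Li0"}

    def test_bootstrap_is_seed_deterministic(self):
        tc = simulate_labeling(KineticsSimSpec(seed=1))
        a = sc.bootstrap_kinetics(tc, n_boot=50, seed=5)
        b = sc.bootstrap_kinetics(tc, n_boot=50, seed=5)
        assert a.equals(b)
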