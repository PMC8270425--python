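"""Relative expression, trend smoothing, and stage-cutoff detection."""

import shutil
import subprocess

import numpy as np
import pytest

import stemcycle as sc
from stemcycle.simulate import GeneTrendSpec, simulate_trajectory
from stemcycle.trajectory import LocalPolynomialTrend, TrendFit


def profile_from_column(cpm, pseudotime=None, gene="g"):
    cpm = np.asarray(cpm, dtype=float)
    pt = np.linspace(0, 1, cpm.size) if pseudotime is None else pseudotime
    return sc.make_profile(cpm[:, None], [f"c{i}" for i in range(cpm.size)],
                           [gene], pt)


class TestRelativeExpression:
    def test_hand_computed_values(self):
        prof = profile_from_column([0.0, 1.0, 3.0])
        np.testing.assert_allclose(sc.relative_expression(prof, "g"),
                                   [0.0, 0.5, 1.0])

    def test_all_zero_gene_maps_to_zero_vector(self):
        prof = profile_from_column([0.0, 0.0, 0.0])
        np.testing.assert_array_equal(sc.relative_expression(prof, "g"),
                                      [0.0, 0.0, 0.0])

    def test_bounded_with_max_one(self):
        rng = np.random.default_rng(0)
        prof = profile_from_column(rng.gamma(2, 50, 100))
        rel = sc.relative_expression(prof, "g")
        assert rel.min() >= 0 and rel.max() == pytest.approx(1.0)

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError):
            sc.relative_expression(profile_from_column([1.0, 2.0]), "nope")


class TestLocalPolynomialTrend:
    def test_reproduces_constants(self):
        x = np.linspace(0, 1, 40)
        m = LocalPolynomialTrend(span=0.6).fit(x, np.full(40, 0.37))
        np.testing.assert_allclose(m.predict(np.linspace(0, 1, 25)), 0.37,
                                   atol=1e-9)

    def test_reproduces_lines_exactly(self):
        # A local quadratic with any weights is exact on polynomials
        # of degree <= 2, so noiseless linear data recovers the global
        # least-squares slope at every span.
        x = np.linspace(0, 2, 30)
        y = 1.5 * x + 0.2
        for span in (0.3, 0.75, 1.0):
            grid = np.linspace(0, 2, 21)
            fit = LocalPolynomialTrend(span=span).fit(x, y).predict(grid)
            np.testing.assert_allclose(fit, 1.5 * grid + 0.2, atol=1e-8)

    def test_matches_r_loess(self, tmp_path):
        """Independent oracle: R's loess (degree 2, direct surface)."""
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 1, 60))
        y = np.sin(2 * np.pi * x) * 0.4 + 0.5 + rng.normal(0, 0.05, 60)
        grid = np.linspace(0, 1, 41)
        fit = LocalPolynomialTrend(span=0.75).fit(x, y).predict(grid)
        np.savetxt(tmp_path / "xy.txt", np.column_stack([x, y]))
        np.savetxt(tmp_path / "grid.txt", grid)
        script = (
            'd <- read.table("xy.txt"); g <- scan("grid.txt");'
            'm <- loess(V2 ~ V1, data=d, span=0.75, degree=2,'
            '           family="gaussian", surface="direct");'
            'write(predict(m, newdata=data.frame(V1=g)), "rfit.txt", ncolumns=1)')
        subprocess.run([shutil.which("Rscript"), "-e", script],
                       cwd=tmp_path, check=True, capture_output=True)
        rfit = np.loadtxt(tmp_path / "rfit.txt")
        np.testing.assert_allclose(fit, rfit, atol=1e-6)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            LocalPolynomialTrend().fit(np.arange(5), np.arange(5))  # < 10 pts
        with pytest.raises(ValueError):
            LocalPolynomialTrend().fit(np.ones(20), np.arange(20))
        with pytest.raises(ValueError):
            LocalPolynomialTrend(span=1.5).fit(np.arange(20.0), np.arange(20.0))


class TestFitTrend:
    def test_constant_gene_fits_flat_with_valid_ci(self):
        prof = profile_from_column(np.full(50, 20.0))
        trend = sc.fit_trend(prof, "g")
        c = np.log2(21.0) / np.log2(21.0)  # relative expression of a constant
        np.testing.assert_allclose(trend.fitted, c, atol=1e-6)
        assert np.all(trend.ci_low <= trend.fitted + 1e-12)
        assert np.all(trend.fitted <= trend.ci_high + 1e-12)
        assert np.all(np.diff(trend.grid) > 0)

    def test_noiseless_sigmoid_fit_is_nondecreasing(self):
        spec = GeneTrendSpec("up", "increasing", baseline=1, amplitude=100,
                             inflection=0.5)
        prof = simulate_trajectory([spec], 120, seed=0)
        trend = sc.fit_trend(prof, "up", span=0.4)
        assert np.all(np.diff(trend.fitted) >= -1e-3)

    def test_n_grid_validated(self):
        prof = profile_from_column(np.arange(30.0))
        with pytest.raises(ValueError):
            sc.fit_trend(prof, "g", n_grid=5)


class TestStageCutoff:
    def grid_trend(self, fitted, grid=None):
        grid = np.linspace(0, 1, fitted.size) if grid is None else grid
        return TrendFit("g", grid, fitted, fitted, fitted, 0.75)

    def test_quadratic_minimum_recovered(self):
        grid = np.linspace(0, 1, 200)
        cut = sc.stage_cutoff(self.grid_trend((grid - 0.6) ** 2))
        assert abs(cut.cutoff - 0.6) <= grid[1] - grid[0]

    def test_monotone_curve_has_no_cutoff(self):
        grid = np.linspace(0, 1, 200)
        with pytest.raises(sc.NoCutoffError):
            sc.stage_cutoff(self.grid_trend(grid.copy()))

    def test_rightmost_of_two_minima_wins(self):
        grid = np.linspace(0, 1, 400)
        # Analytic derivative with sign pattern -,+,-,+ gives minima at
        # 0.3 and 0.7 and a final rise; the rightmost minimum wins.
        d = (grid - 0.3) * (grid - 0.5) * (grid - 0.7)
        dt = grid[1] - grid[0]
        f = np.concatenate([[0.0], np.cumsum((d[1:] + d[:-1]) / 2 * dt)])
        cut = sc.stage_cutoff(self.grid_trend(f, grid))
        assert abs(cut.cutoff - 0.7) <= 2 * dt

    def test_unimodal_turning_point_within_one_grid_step(self):
        spec = GeneTrendSpec("dip", "unimodal", baseline=100, amplitude=-90,
                             inflection=0.55, width=0.12)
        prof = simulate_trajectory([spec], 150, seed=0)
        trend = sc.fit_trend(prof, "dip", span=0.3, n_grid=200)
        step = trend.grid[1] - trend.grid[0]
        cut = sc.stage_cutoff(trend)
        assert abs(cut.cutoff - 0.55) <= step + 1e-12

    def test_cells_labeled_by_cutoff_with_le_convention(self):
        grid = np.linspace(0, 1, 200)
        fitted = (grid - 0.5) ** 2
        pt = np.array([0.1, 0.5, 0.9])
        trend = TrendFit("g", grid, fitted, fitted, fitted, 0.75,
                         cell_ids=np.array(["a", "b", "c"]),
                         cell_pseudotime=pt)
        cut = sc.stage_cutoff(trend)
        stages = cut.stage_of_cell
        assert stages["a"] == "T1"
        assert stages["c"] == "T2"
        # boundary convention: pseudotime == cutoff goes to T1
        s = sc.assign_stages([cut.cutoff], cut.cutoff)
        assert s.iloc[0] == "T1"


class TestCountPositiveByStage:
    def test_matches_brute_force_count(self, trajectory_profile):
        trend = sc.fit_trend(trajectory_profile, "Tbr2")
        cut = sc.stage_cutoff(trend)
        counts = sc.count_positive_by_stage(trajectory_profile, "H2-K1", cut)
        cpm = np.asarray(trajectory_profile[:, "H2-K1"].X).ravel()
        pt = np.asarray(trajectory_profile.obs["pseudotime"])
        t1 = pt <= cut.cutoff
        expected = [[int(((cpm > 0) & t1).sum()), int(((cpm == 0) & t1).sum())],
                    [int(((cpm > 0) & ~t1).sum()), int(((cpm == 0) & ~t1).sum())]]
        assert counts.table.tolist() == expected
        assert counts.table.sum() == trajectory_profile.n_obs

    def test_threshold_at_max_leaves_no_positives(self, trajectory_profile):
        cut = sc.StageCut(cutoff=0.5)
        cpm = np.asarray(trajectory_profile[:, "Gapdh"].X).ravel()
        counts = sc.count_positive_by_stage(trajectory_profile, "Gapdh", cut,
                                            positivity_threshold=cpm.max())
        assert counts.table[:, 0].sum() == 0
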