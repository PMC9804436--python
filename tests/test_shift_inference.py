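"""Annual statistics, trend fits, event-level bootstrap, multiplicity control,
composition trends, convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strandshift import shift_inference as si
from strandshift.strandings_io import default_registry
from strandshift.synthetic_data import SpeciesSimSpec, WorldSpec, build_world, gen_strandings


def records_from(years, dists, species="sp"):
    return pd.DataFrame({
        "species_id": species,
        "year": np.asarray(years, int),
        "poleward_distance_km": np.asarray(dists, float),
    })


class TestAnnualStatistic:
    def test_mean_of_three(self):
        s = si.annual_statistic(records_from([2000] * 3, [100, 200, 300]), "mean")
        assert s.values[0] == 200.0

    def test_q05_interpolated_order_statistic(self):
        vals = np.arange(10, 1001, 10)  # 10, 20, ..., 1000
        s = si.annual_statistic(records_from([2000] * 100, vals), "q05")
        assert s.values[0] == pytest.approx(59.5)

    def test_q05_single_value_degenerate(self):
        s = si.annual_statistic(records_from([2000], [123.0]), "q05")
        assert s.values[0] == 123.0

    def test_years_without_events_absent(self):
        s = si.annual_statistic(records_from([2000, 2002], [1.0, 2.0]), "mean")
        assert list(s.years) == [2000, 2002]

    def test_mean_dominates_q05_every_year(self):
        rng = np.random.default_rng(8)
        years = np.repeat(np.arange(1996, 2021), 30)
        d = rng.normal(500, 200, years.size)
        mean_s = si.annual_statistic(records_from(years, d), "mean")
        q_s = si.annual_statistic(records_from(years, d), "q05")
        assert (mean_s.values >= q_s.values).all()


class TestFitTrend:
    def test_exact_line(self):
        years = np.arange(1996, 2021)
        s = si.AnnualStatSeries(years, 100 + 14.0 * (years - 1996), np.ones(25, int), "mean")
        fit = si.fit_trend(s)
        assert fit.slope == pytest.approx(14.0, abs=1e-10)
        assert fit.p_value < 1e-12

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(2)
        years = np.arange(1996, 2021)
        vals = rng.normal(0, 50, 25)
        fit = si.fit_trend(si.AnnualStatSeries(years, vals, np.ones(25, int), "mean"))
        xc = years - years.mean()
        assert fit.slope == pytest.approx((xc * vals).sum() / (xc**2).sum(), abs=1e-10)

    def test_too_few_years_raises(self):
        s = si.AnnualStatSeries([2000, 2001], [1, 2], [1, 1], "mean")
        with pytest.raises(ValueError, match="3"):
            si.fit_trend(s)

    def test_permutation_null_p_values_uniform(self):
        """Slope p-values under permuted years pass a KS uniformity check."""
        rng = np.random.default_rng(4)
        years = np.arange(1996, 2021)
        vals = rng.normal(1000, 150, 25)
        ps = []
        for _ in range(500):
            fit = si.fit_trend(si.AnnualStatSeries(years, rng.permutation(vals), np.ones(25, int), "mean"))
            ps.append(fit.p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBootstrap:
    def test_zero_noise_line_gives_zero_width_ci(self):
        years = np.repeat(np.arange(1996, 2021), 10)
        d = 100 + 14.0 * (years - 1995)
        lo, hi, _ = si.bootstrap_ci(records_from(years, d), "mean", n_boot=200, seed=0)
        assert hi - lo < 1e-9
        assert lo == pytest.approx(14.0, abs=1e-9)

    def test_small_b_warns(self):
        years = np.repeat(np.arange(1996, 2021), 3)
        d = np.random.default_rng(0).normal(500, 100, years.size)
        with pytest.warns(UserWarning, match="small"):
            si.bootstrap_ci(records_from(years, d), "mean", n_boot=50, seed=0)

    def test_q05_bootstrap_runs_and_brackets_truth(self):
        world = build_world(WorldSpec(grid_shape=(400, 12), cell_km=10.0))
        spec = SpeciesSimSpec("te", 16.0, 800, 217.0, annual_n=30)
        df = gen_strandings(spec, world, seed=6).rename(columns={"true_distance_km": "poleward_distance_km"})
        lo, hi, _ = si.bootstrap_ci(df, "q05", n_boot=300, seed=1)
        assert lo < 16.0 < hi

    def test_mean_path_slope_vectorization_matches_linregress(self):
        rng = np.random.default_rng(9)
        x = np.arange(1996, 2021, dtype=float)
        y = rng.normal(0, 1, (6, 25))
        mask = rng.random((6, 25)) < 0.8
        mask[:, :3] = True
        slopes = si._masked_ols_slopes(x, y, mask)
        for i in range(6):
            assert slopes[i] == pytest.approx(
                stats.linregress(x[mask[i]], y[i][mask[i]]).slope, abs=1e-10
            )

    def test_coverage_across_generator_grid(self):
        """95% event-bootstrap CI covers the true slope at roughly nominal rate
        across sigma x n conditions of the synthetic drift model."""
        world = build_world(WorldSpec(grid_shape=(1000, 8), cell_km=10.0))
        for sigma, n, reps in [(200, 5, 100), (400, 25, 100), (600, 100, 100)]:
            spec = SpeciesSimSpec("cov", 10.0, 2000, float(sigma), annual_n=n)
            hits = 0
            for seed in range(reps):
                df = gen_strandings(spec, world, seed=seed).rename(
                    columns={"true_distance_km": "poleward_distance_km"})
                lo, hi, _ = si.bootstrap_ci(df, "mean", n_boot=1000, seed=seed + 10_000)
                hits += lo <= 10.0 <= hi
            # 100 outer replicates: allow ~3 MC SE around 0.95
            assert 0.88 <= hits / reps <= 1.0


class TestSidak:
    def test_identity_at_m1(self):
        assert si.sidak_adjust(0.05, 1) == pytest.approx(0.05)

    def test_known_value_m9(self):
        assert si.sidak_adjust(0.05, 9) == pytest.approx(0.005683, abs=1e-6)

    def test_strictly_decreasing_in_m(self):
        vals = [si.sidak_adjust(0.05, m) for m in range(1, 30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            si.sidak_adjust(0.0, 3)
        with pytest.raises(ValueError):
            si.sidak_adjust(0.05, 0)

    def test_familywise_error_controlled_under_null(self):
        """Across simulated families of 9 null trend tests, the share of
        families with any Sidak-significant member stays near alpha."""
        rng = np.random.default_rng(13)
        years = np.arange(1996, 2021)
        a_adj = si.sidak_adjust(0.05, 9)
        xc = years - years.mean()
        sxx = (xc**2).sum()
        flagged = 0
        for _ in range(1000):
            y = rng.normal(0, 1, (9, 25))
            slope = y @ xc / sxx
            resid = y - y.mean(1, keepdims=True) - slope[:, None] * xc
            se = np.sqrt((resid**2).sum(1) / 23 / sxx)
            p = 2 * stats.t.sf(np.abs(slope / se), 23)
            flagged += (p < a_adj).any()
        assert flagged / 1000 <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 1000)


class TestComposition:
    def _records(self, rng, cool_frac_by_year):
        rows = []
        for t, f in enumerate(cool_frac_by_year):
            n = 200
            n_cool = int(round(n * f))
            rows.append(pd.DataFrame({
                "species_id": ["harbor_porpoise"] * n_cool + ["common_dolphin"] * (n - n_cool),
                "year": 1996 + t,
                "region": "NEUS",
            }))
        return pd.concat(rows, ignore_index=True)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(1)
        recs = self._records(rng, np.linspace(0.8, 0.2, 25))
        comp = si.composition_series(recs, default_registry(), region="NEUS")
        assert np.allclose(comp.proportions.sum(axis=1), 1.0)

    def test_linear_cool_decline_slope_recovered(self):
        recs = self._records(None, np.linspace(0.8, 0.2, 25))
        comp = si.composition_series(recs, default_registry(), region="NEUS")
        assert comp.vs_year["cool"].slope == pytest.approx(-0.025, abs=0.001)
        assert comp.vs_year["warm"].slope == pytest.approx(0.025, abs=0.001)

    def test_unmapped_species_raises_listing_them(self):
        recs = pd.DataFrame({"species_id": ["mystery_whale"], "year": [2000], "region": ["NEUS"]})
        with pytest.raises(ValueError, match="mystery_whale"):
            si.composition_series(recs, default_registry(), region="NEUS")

    def test_anomaly_regression_uses_shared_years(self):
        recs = self._records(None, np.linspace(0.8, 0.2, 25))
        anom = pd.Series(np.linspace(-0.5, 0.5, 25), index=np.arange(1996, 2021))
        comp = si.composition_series(recs, default_registry(), region="NEUS", anomaly=anom)
        # proportions linear in year and anomaly linear in year => exact link
        assert comp.vs_anomaly["cool"].slope == pytest.approx(-0.6, abs=0.02)


class TestSpeciesProportion:
    def test_single_species_proportion_one_slope_zero(self):
        recs = pd.DataFrame({"species_id": "only", "year": np.repeat(np.arange(2000, 2010), 5), "region": "NEUS"})
        res = si.species_proportion_trend(recs, "only")
        assert np.allclose(res.proportions, 1.0)
        assert res.vs_year.slope == pytest.approx(0.0, abs=1e-12)

    def test_two_species_swap_gives_equal_opposite_slopes(self):
        rows = []
        for t in range(25):
            n_a = 10 + 2 * t
            n_b = 60 - 2 * t
            rows.append(pd.DataFrame({"species_id": ["a"] * n_a + ["b"] * n_b, "year": 2000 + t}))
        recs = pd.concat(rows, ignore_index=True)
        ra = si.species_proportion_trend(recs, "a")
        rb = si.species_proportion_trend(recs, "b")
        assert ra.vs_year.slope == pytest.approx(-rb.vs_year.slope, abs=1e-12)

    def test_null_mixing_adjusted_significance_rate(self):
        """Binomially mixed null communities: rate of Sidak-significant
        proportion trends is near the adjusted alpha."""
        rng = np.random.default_rng(21)
        a_adj = si.sidak_adjust(0.05, 9)
        years = np.arange(1996, 2021)
        hits = 0
        n_sim = 800
        for _ in range(n_sim):
            counts = rng.binomial(80, 0.3, 25)
            props = counts / 80
            fit = si.ols_fit(years, props)
            hits += fit.p_value < a_adj
        rate = hits / n_sim
        assert rate <= a_adj + 3 * np.sqrt(a_adj * (1 - a_adj) / n_sim) + 0.005


class TestConvergence:
    def _series(self, years, vals, kind):
        return si.AnnualStatSeries(years, vals, np.ones(len(years), int), kind)

    def test_identical_series_zero_gap(self):
        years = np.arange(2000, 2010)
        v = np.linspace(100, 500, 10)
        res = si.convergence_check(self._series(years, v, "mean"), self._series(years, v, "q05"))
        assert np.allclose(res.gap_km, 0.0)
        assert res.converged

    def test_faster_trailing_edge_shrinks_gap(self):
        years = np.arange(1996, 2021)
        center = 2000 + 10.0 * (years - 1996)
        trailing = 1000 + 40.0 * (years - 1996)
        res = si.convergence_check(self._series(years, center, "mean"),
                                   self._series(years, trailing, "q05"), threshold_km=100)
        assert (np.diff(res.gap_km) < 0).all()

    def test_disjoint_years_raise(self):
        with pytest.raises(ValueError, match="share no years"):
            si.convergence_check(self._series([2000], [1.0], "mean"),
                                 self._series([2001], [1.0], "q05"))

    def test_gap_nonnegative_from_same_records(self):
        rng = np.random.default_rng(3)
        years = np.repeat(np.arange(1996, 2021), 20)
        recs = records_from(years, rng.normal(800, 300, years.size))
        c = si.annual_statistic(recs, "mean")
        t = si.annual_statistic(recs, "q05")
        res = si.convergence_check(c, t, threshold_km=0.0)
        assert (res.gap_km >= 0).all()


def test_censoring_fraction():
    recs = records_from([2000] * 10, np.linspace(50, 1000, 10))
    assert si.censoring_fraction(recs, domain_max_km=1000.0) == pytest.approx(0.1)
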