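import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from admixclock.tract_dating import (
    bootstrap_mode_ci,
    distribution_mode,
    fit_lambda,
    fit_lambda_vs_r,
    make_recombination_categories,
    mean_tract_length,
    method1_window_times,
    time_from_mean_length,
    time_from_slope,
    ExponentialFit,
    SlopeFit,
)
from admixclock.tract_io import AncestryTract, WindowRecord

from conftest import make_windows


class TestClockInversion:
    def test_unit_product_gives_two_generations(self):
        assert time_from_mean_length(1e8, 1e-8, 0.0) == pytest.approx(2.0)

    def test_published_western_date_round_trips(self):
        # mean length implied by t = 469.83 at the western admixture fraction
        lbar = 1.0 / (0.69 * 6.84e-8 * 468.83)
        t = time_from_mean_length(lbar, 6.84e-8, 0.31)
        assert t == pytest.approx(469.83, abs=1e-9)

    @given(
        st.floats(1.001, 50_000),
        st.floats(0.0, 0.99),
        st.floats(-9.5, -6.5),
    )
    def test_round_trip_is_identity(self, t, f, log10_r):
        r = 10.0 ** log10_r
        lbar = mean_tract_length(t, r, f)
        assert time_from_mean_length(lbar, r, f) == pytest.approx(t, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            time_from_mean_length(0.0, 1e-8, 0.1)
        with pytest.raises(ValueError):
            time_from_mean_length(1e5, 0.0, 0.1)
        with pytest.raises(ValueError):
            time_from_mean_length(1e5, 1e-8, 1.0)


class TestMethod1:
    def test_hand_computed_window_time(self):
        w = WindowRecord("chr1", 0, 100_000, 1.0, 1e-8)
        w.assigned_tracts = [
            AncestryTract("h1", "chr1", 0, 60_000),
            AncestryTract("h2", "chr1", 0, 140_000),
        ]
        [est] = method1_window_times([w], f=0.0)
        assert est.mean_length == pytest.approx(100_000)
        assert est.t_generations == pytest.approx(1_001.0)

    def test_doubling_r_halves_elapsed_time(self):
        tracts = [AncestryTract("h1", "chr1", 0, 80_000)]
        w1 = WindowRecord("chr1", 0, 100_000, 1.0, 1e-8)
        w2 = WindowRecord("chr1", 100_000, 200_000, 1.0, 2e-8)
        w1.assigned_tracts = list(tracts)
        w2.assigned_tracts = list(tracts)
        e1, e2 = method1_window_times([w1, w2], f=0.2)
        assert (e1.t_generations - 1) == pytest.approx(2 * (e2.t_generations - 1))

    def test_zero_r_window_excluded_with_warning(self, caplog):
        w = WindowRecord("chr1", 0, 100_000, 1.0, 0.0)
        w.assigned_tracts = [AncestryTract("h1", "chr1", 0, 60_000)]
        with caplog.at_level("WARNING"):
            assert method1_window_times([w], f=0.0) == []
        assert "r = 0" in caplog.text


class TestDistributionMode:
    def test_degenerate_distribution_returns_the_constant(self):
        assert distribution_mode([7.5] * 10) == 7.5

    def test_bimodal_sample_picks_the_taller_peak(self, rng):
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(5, 1, 150)])
        assert abs(distribution_mode(x)) < 0.6

    def test_known_unimodal_density_mode_recovered(self, rng):
        x = rng.normal(10.0, 2.0, 5_000)
        assert distribution_mode(x) == pytest.approx(10.0, abs=0.4)

    def test_matches_exact_gaussian_kde(self, rng):
        # the binned density is an approximation; cross-check its mode
        # against scipy's exact KDE evaluated on the same grid
        x = np.sort(rng.gamma(4.0, 25.0, 400))
        grid = np.linspace(x.min(), x.max(), 4096)
        kde = stats.gaussian_kde(x, bw_method="silverman")
        exact_mode = grid[np.argmax(kde(grid))]
        step = grid[1] - grid[0]
        assert abs(distribution_mode(x) - exact_mode) <= 3 * step

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            distribution_mode([1.0])


class TestBootstrapModeCI:
    def test_constant_data_collapses(self):
        lo, hi = bootstrap_mode_ci([3.0] * 20, n_reps=50, seed=0)
        assert lo == hi == 3.0

    def test_same_seed_reproduces_interval(self, rng):
        x = rng.normal(100, 10, 150)
        assert bootstrap_mode_ci(x, 200, seed=42) == bootstrap_mode_ci(x, 200, seed=42)

    def test_max_rule_uses_resampled_maximum(self, rng):
        x = rng.normal(100, 10, 150)
        lo, hi = bootstrap_mode_ci(x, 200, seed=0, mode_rule="max")
        assert hi <= x.max() and lo > np.median(x)

    def test_nominal_coverage_of_the_analytic_mode(self):
        # normal data: the density peak is the mean; the 95% bootstrap CI
        # should cover it in most outer replications
        covered = 0
        for i in range(25):
            data = np.random.default_rng(100 + i).normal(100, 10, 200)
            lo, hi = bootstrap_mode_ci(data, n_reps=300, seed=i)
            covered += lo <= 100 <= hi
        assert covered >= 19


class TestRecombinationCategories:
    def test_published_window_count_splits_evenly(self):
        windows = make_windows([1e-9 * (i + 1) for i in range(11)], n_per_rate=209)
        cats = make_recombination_categories(windows, 11)
        assert [c.n_windows for c in cats] == [209] * 11

    def test_small_even_split_is_ordered_by_rate(self, rng):
        rates = rng.permutation(np.linspace(1e-9, 3e-8, 22))
        windows = make_windows(rates, n_per_rate=1)
        cats = make_recombination_categories(windows, 11)
        assert [c.n_windows for c in cats] == [2] * 11
        assert all(cats[i].mean_r < cats[i + 1].mean_r for i in range(10))

    def test_remainder_goes_to_lowest_rate_categories(self, rng):
        rates = rng.permutation(np.linspace(1e-9, 3e-8, 25))
        cats = make_recombination_categories(make_windows(rates, 1), 11)
        assert [c.n_windows for c in cats] == [3, 3, 3, 2, 2, 2, 2, 2, 2, 2, 2]

    def test_category_mean_bounded_by_members(self, rng):
        rates = rng.uniform(1e-9, 5e-8, 40)
        for cat in make_recombination_categories(make_windows(rates, 1), 7):
            member_r = [w.r_morgans_per_bp for w in cat.windows]
            assert min(member_r) <= cat.mean_r <= max(member_r)

    def test_fewer_windows_than_categories_is_an_error(self):
        with pytest.raises(ValueError):
            make_recombination_categories(make_windows([1e-8], 5), 11)


def _point_mass_tracts(values, counts):
    tracts = []
    for k, (v, c) in enumerate(zip(values, counts)):
        for i in range(c):
            tracts.append(AncestryTract(f"h{k}_{i}", "chr1", 0, int(v)))
    return tracts


class TestFitLambda:
    def test_exact_geometric_counts_recover_rate_exactly(self):
        # 10 equally spaced point masses with geometrically decaying counts:
        # log(count) is exactly affine in the bin midpoint, so the fitted
        # rate equals ln(2) / bin_width to floating-point accuracy
        d, a = 100_000, 20_000
        values = [a + k * d for k in range(10)]
        counts = [5 * 2 ** (9 - k) for k in range(10)]
        fit = fit_lambda(_point_mass_tracts(values, counts), n_bins=10)
        width = 9 * d / 10
        assert fit.usable
        assert fit.lam == pytest.approx(np.log(2) / width, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n_tracts == sum(counts)

    def test_exponential_sample_agrees_with_inverse_mean_oracle(self, rng):
        lengths = np.maximum(1, rng.exponential(500_000, 10_000)).astype(int)
        tracts = [
            AncestryTract(f"h{i}", "chr1", 0, int(v)) for i, v in enumerate(lengths)
        ]
        fit = fit_lambda(tracts)
        lam_ml = 1.0 / lengths.mean()  # maximum-likelihood oracle
        assert lam_ml == pytest.approx(2e-6, rel=0.05)
        assert fit.lam == pytest.approx(lam_ml, rel=0.12)

    def test_too_few_usable_bins_marks_fit_unusable(self):
        # only one bin reaches the five-tract floor
        fit = fit_lambda(_point_mass_tracts([10_000, 500_000], [6, 3]), n_bins=20)
        assert not fit.usable
        assert np.isnan(fit.lam)
        # degenerate all-equal lengths are likewise unusable
        assert not fit_lambda(_point_mass_tracts([50_000], [20]), n_bins=20).usable

    def test_reports_table_contract_fields(self, rng):
        lengths = np.maximum(1, rng.exponential(300_000, 2_000)).astype(int)
        tracts = [
            AncestryTract(f"h{i}", "chr1", 0, int(v)) for i, v in enumerate(lengths)
        ]
        fit = fit_lambda(tracts, mean_r=2.06e-9, n_windows=209)
        for field in ("mean_r", "n_windows", "n_tracts", "lam", "se_lambda",
                      "r_squared", "p_value"):
            assert np.isfinite(getattr(fit, field))


class TestSlopeRegression:
    def _fits(self, rates, lams):
        return [
            ExponentialFit(
                mean_r=r, n_windows=10, n_tracts=100, lam=l, se_lambda=1e-7,
                r_squared=0.9, p_value=1e-4, usable=True,
            )
            for r, l in zip(rates, lams)
        ]

    def test_exact_line_through_origin(self):
        rates = np.linspace(1e-9, 3e-8, 11)
        fit = fit_lambda_vs_r(self._fits(rates, 690.0 * rates), f=0.31)
        assert fit.slope_a == pytest.approx(690.0, rel=1e-9)
        assert fit.t_generations == pytest.approx(1_001.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_published_slope_to_time_conversions(self):
        assert time_from_slope(323.49, 0.31) == pytest.approx(469.83, abs=0.005)
        assert time_from_slope(1_100.2, 0.13) == pytest.approx(1_265.60, abs=0.005)

    def test_unusable_category_fits_are_dropped(self):
        rates = np.linspace(1e-9, 1e-8, 5)
        fits = self._fits(rates, 500.0 * rates)
        fits[0] = ExponentialFit(
            mean_r=rates[0], n_windows=10, n_tracts=3, lam=float("nan"),
            se_lambda=float("nan"), r_squared=float("nan"),
            p_value=float("nan"), usable=False,
        )
        fit = fit_lambda_vs_r(fits, f=0.2)
        assert fit.slope_a == pytest.approx(500.0, rel=1e-6)

    def test_all_unusable_is_an_error(self):
        bad = ExponentialFit(
            mean_r=1e-8, n_windows=1, n_tracts=0, lam=float("nan"),
            se_lambda=float("nan"), r_squared=float("nan"),
            p_value=float("nan"), usable=False,
        )
        with pytest.raises(ValueError):
            fit_lambda_vs_r([bad, bad], f=0.1)

    def test_slope_fit_enforces_time_consistency(self):
        with pytest.raises(ValueError):
            SlopeFit(
                slope_a=100.0, se_a=1.0, r_squared=0.9, p_value=1e-3,
                f=0.31, t_generations=999.0, ci_95=(1.0, 2.0),
            )

    def test_ci_propagates_through_slope_se(self):
        rates = np.linspace(1e-9, 3e-8, 6)
        rng = np.random.default_rng(3)
        lams = 400.0 * rates * (1 + rng.normal(0, 0.05, 6))
        fit = fit_lambda_vs_r(self._fits(rates, lams), f=0.25)
        lo, hi = fit.ci_95
        assert lo == pytest.approx(time_from_slope(fit.slope_a - 1.96 * fit.se_a, 0.25))
        assert hi == pytest.approx(time_from_slope(fit.slope_a + 1.96 * fit.se_a, 0.25))
        assert lo < fit.t_generations < hi
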