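"""Entropy staircases, sectioning, and per-sample perplexity tuning."""

import numpy as np
import pytest

from qsne import (
    EntropyCurve,
    HierarchicalSpec,
    affinities_from_solution,
    build_affinities,
    entropy_curves,
    hierarchical_gaussian,
    locate_insensitive_optimum,
    row_entropy_at_bandwidth,
    tune_per_sample,
)
from qsne.autoperplexity import scan_report
from qsne.exceptions import DegenerateDataError, PerplexityRangeError


def count_plateaus(curve, frac=0.05, min_run=3):
    """Runs of the median sensitivity below frac of its max, each >= min_run."""
    s = np.median(np.abs(curve.sensitivity), axis=0)
    low = s < frac * s.max()
    count, run = 0, 0
    for flag in low:
        run = run + 1 if flag else 0
        if run == min_run:
            count += 1
    return count


class TestEntropyCurves:
    def test_hierarchical_staircase_has_three_plateaus(self, hierarchical_full):
        """The 5x5 nested benchmark shows plateaus for its three scales.

        The scan grid must span everything from the per-sample noise scale
        to saturation, so it is widened beyond the median-distance default.
        """
        data, _ = hierarchical_full
        curve = entropy_curves(data.values, sigma_grid_size=96, sigma_range=(5e-4, 5e3))
        assert count_plateaus(curve) >= 3

    @pytest.mark.parametrize("seed", [1, 2])
    def test_staircase_across_seeds(self, seed):
        data, _ = hierarchical_gaussian(HierarchicalSpec(seed=seed))
        curve = entropy_curves(data.values, sigma_grid_size=96, sigma_range=(5e-4, 5e3))
        assert count_plateaus(curve) >= 3

    def test_single_gaussian_single_transition(self):
        """One isotropic cluster: a single sensitivity bump, no interior plateau."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 5))
        curve = entropy_curves(X)
        s = np.median(np.abs(curve.sensitivity), axis=0)
        high = np.flatnonzero(s > 0.5 * s.max())
        # the above-half-max region is one contiguous run
        assert np.all(np.diff(high) == 1)

    def test_entropy_saturates_at_large_sigma(self, rng):
        X = rng.normal(size=(50, 3))
        curve = entropy_curves(X)
        assert np.all(curve.H[:, -1] >= 0.99 * np.log(49))

    def test_monotone_rows(self, rng):
        X = rng.normal(size=(40, 4))
        curve = entropy_curves(X)
        assert np.all(np.diff(curve.H, axis=1) >= -1e-8)

    def test_degenerate_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            entropy_curves(np.zeros((10, 3)))

    def test_grid_size_validated(self, rng):
        with pytest.raises(PerplexityRangeError):
            entropy_curves(rng.normal(size=(20, 2)), sigma_grid_size=8)

    def test_scan_report_columns(self, rng):
        df = scan_report(entropy_curves(rng.normal(size=(30, 3))))
        assert {"sigma", "H_median", "aggregate_sensitivity"} <= set(df.columns)
        assert len(df) == 64


def _synthetic_curve(m, sens_fn, grid=None):
    """Build an EntropyCurve whose sensitivity follows sens_fn(log sigma)."""
    if grid is None:
        grid = np.exp(np.linspace(np.log(1e-3), np.log(1e3), 256))
    lg = np.log(grid)
    sens = sens_fn(lg)
    H = np.concatenate([[0.0], np.cumsum(0.5 * (sens[1:] + sens[:-1]) * np.diff(lg))])
    H = np.clip(H, 0.0, np.log(m - 1))
    return EntropyCurve(sigma_grid=grid, H=H[None, :], sensitivity=sens[None, :])


class TestLocateInsensitiveOptimum:
    def test_flat_curve_returns_geometric_midpoint(self):
        curve = _synthetic_curve(1001, lambda lg: np.full(lg.size, 0.7))
        pivot = locate_insensitive_optimum(curve, (10.0, 90.0))
        assert pivot == pytest.approx(np.sqrt(10.0 * 90.0), rel=1e-9)

    def test_v_shaped_minimum_found(self):
        """Sensitivity V-shaped in log sigma; its minimum maps to pi = 50."""
        m = 1001
        lg_star = None
        # first find where a plain integration reaches H = log(50)
        base = _synthetic_curve(m, lambda lg: np.full(lg.size, 0.8))
        lg_star = float(base.log_sigma_at_perplexity(50.0)[0])
        curve = _synthetic_curve(m, lambda lg: 0.8 + 0.0 * lg)
        curve = EntropyCurve(
            sigma_grid=curve.sigma_grid,
            H=curve.H,
            sensitivity=(0.1 + np.abs(np.log(curve.sigma_grid) - lg_star))[None, :],
        )
        pivot = locate_insensitive_optimum(curve, (10.0, 500.0))
        assert pivot == pytest.approx(50.0, rel=0.05)

    def test_range_validated(self, hierarchical_small):
        data, _ = hierarchical_small
        curve = entropy_curves(data.values)
        with pytest.raises(PerplexityRangeError):
            locate_insensitive_optimum(curve, (0.5, 50.0))
        with pytest.raises(PerplexityRangeError):
            locate_insensitive_optimum(curve, (50.0, 10.0))

    def test_hierarchical_pivot_at_subcluster_scale(self, hierarchical_full):
        """On the nested benchmark the mid-scale optimum sits at the subcluster
        size (40 samples per subcluster -> exp(H) ~ 39)."""
        data, _ = hierarchical_full
        curve = entropy_curves(data.values)
        pivot = locate_insensitive_optimum(curve, (10.0, 150.0))
        assert 30.0 <= pivot <= 50.0


class TestTunePerSample:
    def test_degenerate_window_returns_pivot(self, hierarchical_small):
        data, _ = hierarchical_small
        sol = tune_per_sample(data.values, 20.0, (1.0, 1.0))
        np.testing.assert_allclose(sol.pi_star, 20.0, rtol=1e-4)

    def test_single_gaussian_low_dispersion(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(250, 5))
        sol = tune_per_sample(X, 30.0, (0.5, 2.0))
        iqr = np.subtract(*np.percentile(sol.pi_star, [75, 25]))
        assert iqr / 30.0 < 1.5  # well under the window width

    def test_unbalanced_mixture_bimodal(self):
        """Clusters of different sizes pull per-sample optima to different
        perplexities: small clusters toward their size, large toward theirs."""
        rng = np.random.default_rng(11)
        blocks, sizes = [], []
        for c in range(8):
            size = 30 if c % 2 == 0 else 90
            center = rng.normal(scale=5.0, size=3)
            blocks.append(center + rng.normal(scale=0.2, size=(size, 3)))
            sizes.append(size)
        X = np.vstack(blocks)
        labels = np.repeat(np.arange(8), sizes)
        sol = tune_per_sample(X, 50.0, (0.5, 2.0))
        small = sol.pi_star[np.isin(labels, [0, 2, 4, 6])]
        large = sol.pi_star[np.isin(labels, [1, 3, 5, 7])]
        # two separated modes near the cluster sizes
        assert np.median(small) < 40.0
        assert np.median(large) > 70.0

    def test_never_leaves_window(self, hierarchical_small):
        data, _ = hierarchical_small
        pivot = 30.0
        sol = tune_per_sample(data.values, pivot, (0.5, 2.0))
        assert np.all(sol.pi_star >= 0.5 * pivot * (1 - 1e-3))
        assert np.all(sol.pi_star <= 2.0 * pivot * (1 + 1e-3))

    def test_empty_window_rejected(self, hierarchical_small):
        data, _ = hierarchical_small
        with pytest.raises(PerplexityRangeError):
            tune_per_sample(data.values, 20.0, (2.0, 0.5))

    def test_scale_equivariance(self):
        """Scaling X scales sigma* proportionally but leaves pi* unchanged."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(120, 4))
        sol1 = tune_per_sample(X, 15.0, (0.5, 2.0))
        sol3 = tune_per_sample(3.0 * X, 15.0, (0.5, 2.0))
        np.testing.assert_allclose(sol3.sigma_star, 3.0 * sol1.sigma_star, rtol=0.01)
        np.testing.assert_allclose(sol3.pi_star, sol1.pi_star, rtol=0.01)


class TestAffinitiesFromSolution:
    def test_fixed_global_matches_fixed_pipeline(self, hierarchical_small):
        data, _ = hierarchical_small
        sol = tune_per_sample(data.values, 25.0, (1.0, 1.0))
        model_sol = affinities_from_solution(data.values, sol)
        model_fixed = build_affinities(data.values, 25.0)
        np.testing.assert_allclose(model_sol.joint, model_fixed.joint, atol=1e-12)

    def test_invariants_and_entropy_recompute(self, hierarchical_small):
        data, _ = hierarchical_small
        sol = tune_per_sample(data.values, 30.0, (0.5, 2.0))
        model = affinities_from_solution(data.values, sol)
        np.testing.assert_allclose(model.cond_rows.sum(axis=1), 1.0, atol=1e-9)
        assert model.joint.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(model.joint, model.joint.T, atol=1e-15)
        # H(P_i*) equals a direct per-row entropy recomputation
        from qsne import pairwise_sq_distances

        D2 = pairwise_sq_distances(data.values)
        for i in range(0, data.n_samples, 25):
            row = np.delete(D2[i], i)
            H, _ = row_entropy_at_bandwidth(row, sol.sigma_star[i])
            assert model.entropy[i] == pytest.approx(H, abs=1e-10)
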