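"""Three-step outlier detection: batch-corrected effects, robust bulk with
bootstrap deflation, elliptical region, per-gene bootstrap test, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unknome import (
    GeneEffect,
    OutlierRegion,
    ScreenConfig,
    ScreenTable,
    adjust_bh,
    deflate_scatter,
    fit_gene_effects,
    gen_screen,
    outlier_region,
    robust_center,
    robust_scatter,
    run_screen,
    test_outlier as outlier_p_value,
    transform_effects,
)


def table_from_rows(rows, value_cols=("v1",)):
    return ScreenTable(pd.DataFrame(rows), axis_labels=tuple(value_cols))


def bh_step_up_oracle(p):
    """Literal BH step-up: q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_i, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestFitGeneEffects:
    def test_single_batch_estimates_are_gene_means(self):
        rows = [
            {"gene": g, "batch": "b1", "replicate": f"r{r}", "v1": v}
            for g, vals in [("gA", [1.0, 2.0, 3.0]), ("gB", [10.0, 12.0, 14.0])]
            for r, v in enumerate(vals)
        ]
        effects = fit_gene_effects(table_from_rows(rows), ScreenConfig(seed=0))
        by_gene = {e.gene_id: e for e in effects}
        assert by_gene["gA"].estimate[0] == pytest.approx(2.0)
        assert by_gene["gB"].estimate[0] == pytest.approx(12.0)
        assert by_gene["gA"].n_replicates == 3

    def test_matches_hand_solved_two_by_two_least_squares(self):
        # y = mu_g + beta_b (beta_{b1}=0); fully crossed, one obs per cell:
        # beta = ((3-1)+(8-2))/2 = 4, mu_A = mean(1, 3-4) = 0, mu_B = mean(2, 8-4) = 3
        rows = [
            {"gene": "gA", "batch": "b1", "replicate": "r0", "v1": 1.0},
            {"gene": "gA", "batch": "b2", "replicate": "r0", "v1": 3.0},
            {"gene": "gB", "batch": "b1", "replicate": "r0", "v1": 2.0},
            {"gene": "gB", "batch": "b2", "replicate": "r0", "v1": 8.0},
        ]
        effects = fit_gene_effects(table_from_rows(rows), ScreenConfig(seed=0))
        by_gene = {e.gene_id: e for e in effects}
        assert by_gene["gA"].estimate[0] == pytest.approx(0.0)
        assert by_gene["gB"].estimate[0] == pytest.approx(3.0)

    def test_batch_corrected_estimates_cover_truth(self):
        # known additive batch offsets; reference-batch truth = mu + offset_0
        table, truth = gen_screen(
            J=500, d=1, contamination_frac=0.0, n_batches=2, batch_sd=5.0,
            reps_per_gene=4, noise_sd=1.0, seed=17,
        )
        effects = fit_gene_effects(table, ScreenConfig(seed=0))
        mu_ref = truth.mu[:, 0] + truth.batch_offsets[0, 0]
        by_gene = {e.gene_id: e for e in effects}
        hits = 0
        for j, g in enumerate(truth.gene_ids):
            e = by_gene[g]
            se = np.sqrt(e.covariance[0, 0])
            hits += abs(e.estimate[0] - mu_ref[j]) <= 2 * se
        assert hits / len(truth.gene_ids) >= 0.95

    def test_single_gene_batch_is_unidentifiable(self):
        rows = [
            {"gene": "gA", "batch": "b1", "replicate": "r0", "v1": 1.0},
            {"gene": "gB", "batch": "b1", "replicate": "r0", "v1": 2.0},
            {"gene": "gA", "batch": "b2", "replicate": "r1", "v1": 3.0},
        ]
        with pytest.raises(ValueError, match="b2"):
            fit_gene_effects(table_from_rows(rows), ScreenConfig(seed=0))


class TestTransformEffects:
    def effect(self, est, var):
        return GeneEffect("g", np.atleast_1d(est), np.atleast_2d(var))

    def test_identity_leaves_effects_unchanged(self):
        eff = self.effect(2.0, 0.3)
        out = transform_effects([eff], "identity")[0]
        assert out.estimate[0] == 2.0 and out.covariance[0, 0] == 0.3

    def test_log_delta_method_at_one(self):
        out = transform_effects([self.effect(1.0, 0.5)], "log")[0]
        assert out.estimate[0] == pytest.approx(0.0)
        assert out.covariance[0, 0] == pytest.approx(0.5)  # slope 1 at x=1

    def test_logit_delta_method_at_half(self):
        # d/dp logit(p) = 1/(p(1-p)) = 4 at p=0.5, so variance scales by 16
        out = transform_effects([self.effect(0.5, 0.01)], "logit")[0]
        assert out.estimate[0] == pytest.approx(0.0)
        assert out.covariance[0, 0] == pytest.approx(0.16)

    def test_log_of_non_positive_estimate_names_gene(self):
        with pytest.raises(ValueError, match="g"):
            transform_effects([self.effect(-1.0, 0.1)], "log")


class TestRobustBulk:
    def test_center_of_symmetric_data_is_zero(self):
        X = np.array([[-1.0], [0.0], [1.0], [-2.0], [2.0]])
        assert robust_center(X)[0] == 0.0

    def test_center_ignores_contamination(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (500, 2))
        X[:100] = 10.0  # 20% contamination
        assert np.all(np.abs(robust_center(X)) < 0.2)

    def test_center_permutation_invariant_and_small_sample_error(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 2))
        perm = rng.permutation(50)
        assert np.array_equal(robust_center(X), robust_center(X[perm]))
        with pytest.raises(ValueError):
            robust_center(X[:4])

    def test_scatter_consistent_on_clean_normal(self):
        rng = np.random.default_rng(5)
        X = rng.multivariate_normal([0, 0], np.eye(2), 2000)
        S = robust_scatter(X)
        assert np.all(np.abs(np.diag(S) - 1.0) < 0.15)
        assert abs(S[0, 1]) < 0.15

    def test_scatter_resists_20pct_contamination(self):
        rng = np.random.default_rng(6)
        X = rng.multivariate_normal([0, 0], np.eye(2), 2000)
        X[:400] = [10.0, 10.0]
        S = robust_scatter(X)
        assert np.all(np.abs(np.diag(S) - 1.0) < 0.25)
        classical = np.cov(X.T)
        assert np.all(np.diag(classical) > 5.0)  # classical covariance explodes

    def test_scatter_agrees_with_minimum_covariance_determinant(self):
        rng = np.random.default_rng(7)
        X = rng.multivariate_normal([0, 0], [[2.0, 0.5], [0.5, 1.0]], 1000)
        X[:150] += 20.0
        S_gk = robust_scatter(X, method="gk")
        S_mcd = robust_scatter(X, method="mcd")
        assert np.allclose(S_gk, S_mcd, rtol=0.25, atol=0.1)

    def test_scatter_scale_equivariance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(300, 2))
        assert np.allclose(robust_scatter(2 * X), 4 * robust_scatter(X), rtol=1e-9)

    def test_identical_points_are_singular(self):
        with pytest.raises(ValueError):
            robust_scatter(np.ones((50, 2)))


class TestDeflation:
    def test_zero_sampling_noise_leaves_scatter_unchanged(self):
        raw = np.array([[2.0, 0.3], [0.3, 1.0]])
        out = deflate_scatter(raw, np.zeros((50, 2, 2)), B=100, seed=0)
        assert np.array_equal(out, raw)

    def test_recovers_between_gene_variance(self):
        # law of total variance: raw ~ tau^2 + sigma^2 = 5, deflated ~ tau^2 = 3
        rng = np.random.default_rng(9)
        J = 1000
        mu = rng.normal(0, np.sqrt(3.0), (J, 1))
        muhat = mu + rng.normal(0, np.sqrt(2.0), (J, 1))
        raw = robust_scatter(muhat)
        deflated = deflate_scatter(raw, np.full((J, 1, 1), 2.0), B=300, seed=10)
        assert 2.4 <= deflated[0, 0] <= 3.6

    def test_overshoot_clipped_to_zero_with_warning(self):
        raw = np.array([[0.5]])
        covs = np.full((200, 1, 1), 5.0)  # sampling noise dwarfs raw scatter
        with pytest.warns(RuntimeWarning, match="clipped"):
            out = deflate_scatter(raw, covs, B=100, seed=11)
        assert out[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_deflation_never_inflates(self):
        rng = np.random.default_rng(12)
        muhat = rng.normal(size=(300, 2))
        raw = robust_scatter(muhat)
        covs = np.tile(0.2 * np.eye(2), (300, 1, 1))
        deflated = deflate_scatter(raw, covs, B=200, seed=13)
        assert np.linalg.eigvalsh(raw - deflated).min() >= -1e-10


class TestOutlierRegion:
    def test_one_dimensional_boundary_is_z_interval(self):
        region = outlier_region(np.zeros(1), np.eye(1), alpha=0.05)
        assert region.radius == pytest.approx(1.95996, abs=1e-4)

    def test_two_dimensional_chi_squared_radius(self):
        region = outlier_region(np.zeros(2), np.eye(2), alpha=0.05)
        assert region.radius**2 == pytest.approx(5.9915, abs=1e-3)

    def test_monte_carlo_coverage_matches_alpha(self):
        alpha = 0.05
        cov = np.array([[2.0, 0.7], [0.7, 1.0]])
        region = outlier_region(np.array([1.0, -1.0]), cov, alpha)
        rng = np.random.default_rng(14)
        draws = rng.multivariate_normal(region.center, cov, 100_000)
        outside = np.mean(region.mahalanobis(draws) > region.radius)
        se = np.sqrt(alpha * (1 - alpha) / 100_000)
        assert abs(outside - alpha) <= 3 * se

    def test_singular_scatter_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            outlier_region(np.zeros(2), np.zeros((2, 2)), 0.05)


class TestTestOutlier:
    REGION = OutlierRegion(np.zeros(2), np.eye(2), alpha=0.05)

    def effect(self, est, var=1e-2):
        return GeneEffect("g", np.asarray(est, dtype=float), var * np.eye(2))

    def test_estimate_at_center_gives_p_one(self):
        assert outlier_p_value(self.effect([0.0, 0.0]), self.REGION, B=100, seed=0) == 1.0

    def test_far_outlier_with_tiny_noise_is_significant(self):
        est = [self.REGION.radius + 10.0, 0.0]
        p = outlier_p_value(self.effect(est, var=1e-6), self.REGION, B=2000, seed=1)
        assert p < 0.001

    def test_p_non_increasing_moving_radially_outward(self):
        direction = np.array([1.0, 1.0]) / np.sqrt(2)
        ps = [
            outlier_p_value(
                self.effect(self.REGION.radius * t * direction, var=0.5),
                self.REGION, B=500, seed=21,
            )
            for t in (1.05, 1.5, 2.5, 4.0)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_calibration_on_boundary_null_is_conservative(self):
        # true effect exactly on the boundary: p should be stochastically
        # at least uniform (valid, conservative test)
        rng = np.random.default_rng(22)
        truth = np.array([self.REGION.radius, 0.0])
        sigma = 0.25 * np.eye(2)
        reps = 1000
        ps = np.empty(reps)
        for i in range(reps):
            est = rng.multivariate_normal(truth, sigma)
            ps[i] = outlier_p_value(
                GeneEffect("g", est, sigma), self.REGION, B=200, seed=1000 + i
            )
        for t in (0.01, 0.05, 0.1, 0.2):
            se = np.sqrt(t * (1 - t) / reps)
            assert np.mean(ps <= t) <= t + 3 * se

    def test_dimension_mismatch_rejected(self):
        effect = GeneEffect("g", np.zeros(1), np.eye(1))
        with pytest.raises(ValueError, match="dimension"):
            outlier_p_value(effect, self.REGION, B=100, seed=0)


class TestAdjustBH:
    def test_hand_computed_example(self):
        q = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.42])[0] == pytest.approx(0.42)

    def test_all_ones_stay_one(self):
        assert np.all(adjust_bh([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=100)
    def test_matches_brute_force_step_up(self, p):
        q = adjust_bh(p)
        assert np.allclose(q, bh_step_up_oracle(p), atol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12) and np.all(q <= 1.0)


class TestRunScreen:
    def test_null_screen_controls_false_flags(self):
        table, _ = gen_screen(J=200, d=2, contamination_frac=0.0, seed=30)
        result = run_screen(table, ScreenConfig(seed=31))
        flagged = sum(r.outlier for r in result.results)
        se = np.sqrt(0.05 * 0.95 / 200)
        assert flagged / 200 <= 0.05 + 2 * se

    def test_planted_outliers_recovered(self):
        table, truth = gen_screen(
            J=200, d=2, contamination_frac=0.05,
            displacement=[8 / np.sqrt(2)] * 2, seed=32,
        )
        result = run_screen(table, ScreenConfig(seed=33))
        flagged = {r.gene_id for r in result.results if r.outlier}
        assert len(flagged & truth.outlier_genes) >= 9
        assert len(flagged - truth.outlier_genes) <= 2

    def test_one_dimensional_screen_also_works(self):
        table, truth = gen_screen(
            J=100, d=1, contamination_frac=0.05, displacement=8.0, seed=34,
        )
        result = run_screen(table, ScreenConfig(seed=35))
        flagged = {r.gene_id for r in result.results if r.outlier}
        assert len(flagged & truth.outlier_genes) >= 4
        assert len(flagged - truth.outlier_genes) <= 2

    def test_rerun_with_same_seed_is_identical(self):
        table, _ = gen_screen(J=50, d=2, seed=36)
        a = run_screen(table, ScreenConfig(seed=37))
        b = run_screen(table, ScreenConfig(seed=37))
        assert a.results == b.results
        assert np.array_equal(a.bulk.deflated_scatter, b.bulk.deflated_scatter)

    def test_translation_equivariance(self):
        table, _ = gen_screen(J=60, d=2, contamination_frac=0.05, seed=38)
        shifted = ScreenTable(
            table.data.assign(
                value1=table.data["value1"] + 100.0,
                value2=table.data["value2"] - 50.0,
            ),
            axis_labels=table.axis_labels,
        )
        a = run_screen(table, ScreenConfig(seed=39))
        b = run_screen(shifted, ScreenConfig(seed=39))
        assert np.allclose(b.bulk.center - a.bulk.center, [100.0, -50.0], atol=1e-6)
        assert [r.gene_id for r in a.results if r.outlier] == [
            r.gene_id for r in b.results if r.outlier
        ]
        assert np.allclose(
            [r.p_value for r in a.results], [r.p_value for r in b.results], atol=1e-12
        )

    def test_deflation_inequality_holds_on_every_run(self):
        table, _ = gen_screen(J=80, d=2, seed=40)
        result = run_screen(table, ScreenConfig(seed=41))
        diff = result.bulk.raw_scatter - result.bulk.deflated_scatter
        assert np.linalg.eigvalsh(diff).min() >= -1e-10

    def test_results_sorted_by_q_then_gene(self):
        table, _ = gen_screen(J=50, d=2, contamination_frac=0.1, seed=42)
        result = run_screen(table, ScreenConfig(seed=43))
        keys = [(r.q_value, r.gene_id) for r in result.results]
        assert keys == sorted(keys)

    def test_controls_reported_but_excluded_from_bulk(self):
        table, _ = gen_screen(J=50, d=2, contamination_frac=0.0, seed=44)
        config = ScreenConfig(seed=45, control_genes=("gene0000", "gene0001"))
        result = run_screen(table, config)
        assert sum(r.is_control for r in result.results) == 2
        assert len(result.results) == 50
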