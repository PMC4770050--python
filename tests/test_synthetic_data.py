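"""Unit tests for ability sampling, pool generation, response simulation,
category recoding and the disattenuated-correlation estimators."""

from __future__ import annotations

import numpy as np
import pytest

import bifax as bx
from _oracles import cronbach_alpha_reference


class TestSampleThetas:
    def test_moments_and_orthogonality(self):
        thetas = bx.sample_thetas(10_000, 2021)
        assert thetas.shape == (10_000, 3)
        assert np.abs(thetas.mean(axis=0)).max() < 0.04
        assert np.abs(thetas.std(axis=0) - 1.0).max() < 0.04
        corr = np.corrcoef(thetas.T)
        assert np.abs(corr[np.triu_indices(3, 1)]).max() < 0.04

    def test_deterministic(self):
        np.testing.assert_array_equal(bx.sample_thetas(50, 9),
                                      bx.sample_thetas(50, 9))

    def test_positive_n_required(self):
        with pytest.raises(ValueError):
            bx.sample_thetas(0, 1)


class TestGenerateItemPool:
    def test_hits_target_correlation(self, pool08):
        rho = bx.implied_disattenuated_correlation(pool08, seed=1234)
        assert abs(rho - 0.80) <= 0.01

    def test_hits_high_target(self):
        pool = bx.generate_item_pool(
            bx.GeneratorConfig(target_rho=0.96, seed=2, n_mc=30))
        rho = bx.implied_disattenuated_correlation(pool, seed=1234)
        assert abs(rho - 0.96) <= 0.01

    def test_target_one_gives_zero_specific_loadings(self):
        pool = bx.generate_item_pool(bx.GeneratorConfig(target_rho=1.0, seed=3,
                                                        n_mc=10))
        assert all(it.a_mc == 0.0 for it in pool.mc_items)
        assert all(it.a_cr == 0.0 for it in pool.cr_items)

    def test_lower_target_needs_larger_specific_loadings(self):
        low = bx.generate_item_pool(
            bx.GeneratorConfig(target_rho=0.78, seed=4, n_mc=25))
        high = bx.generate_item_pool(
            bx.GeneratorConfig(target_rho=0.95, seed=4, n_mc=25))
        mean_spec = lambda p: np.mean([abs(it.a_mc) for it in p.mc_items])
        assert mean_spec(low) > mean_spec(high)
        # same seed implies identical base draws: general loadings match
        np.testing.assert_allclose([it.a_g for it in low.mc_items],
                                   [it.a_g for it in high.mc_items])

    def test_layout_and_validation(self, pool08):
        assert pool08.n_mc == 55 and pool08.n_cr == 3
        assert pool08.n_categories == 5
        with pytest.raises(ValueError, match="target_rho"):
            bx.GeneratorConfig(target_rho=1.2)
        with pytest.raises(ValueError, match="target_rho"):
            bx.GeneratorConfig(target_rho=0.0)


class TestSimulateResponses:
    def test_frequencies_match_probabilities(self, pool08):
        theta = bx.ThetaTriple(0.4, -0.3, 0.6)
        n = 20_000
        tiled = np.tile(theta.as_array(), (n, 1))
        sim = bx.simulate_responses(pool08, tiled, 77)
        for j, item in enumerate(pool08.mc_items):
            p = bx.prob_mc_bifactor(item, theta)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(sim.mc_values[:, j].mean() - p) <= 4.5 * se
        for j, item in enumerate(pool08.cr_items):
            for c in range(5):
                p = bx.prob_cr_bifactor(item, theta, c)
                se = np.sqrt(p * (1 - p) / n)
                freq = (sim.cr_values[:, j] == c).mean()
                assert abs(freq - p) <= 4.5 * se

    def test_unidimensional_simulation(self):
        items = bx.UnidimItemSet(
            (bx.UnidimMCItem(a=1.5, b=0.0, g=0.2),),
            (bx.UnidimCRItem(a=1.2, thresholds=(-0.5, 0.5, 1.5, 2.5)),),
        )
        theta = np.zeros(30_000)
        sim = bx.simulate_responses(items, theta, 3)
        p = bx.prob_mc_unidim(items.mc_items[0], 0.0)
        assert abs(sim.mc_values.mean() - p) < 4.5 * np.sqrt(p * (1 - p) / 30_000)

    def test_shape_errors(self, pool08):
        with pytest.raises(ValueError, match=r"\(n, 3\)"):
            bx.simulate_responses(pool08, np.zeros(10), 1)
        with pytest.raises(TypeError, match="ItemPool or UnidimItemSet"):
            bx.simulate_responses(["not items"], np.zeros((5, 3)), 1)

    def test_deterministic(self, pool08):
        thetas = bx.sample_thetas(40, 8)
        a = bx.simulate_responses(pool08, thetas, 55)
        b = bx.simulate_responses(pool08, thetas, 55)
        np.testing.assert_array_equal(a.values, b.values)


class TestResponseMatrix:
    def test_validation(self):
        labels = np.array(["MC", "CR"])
        with pytest.raises(ValueError, match="MC responses"):
            bx.ResponseMatrix(np.array([[2, 1]]), labels)
        with pytest.raises(ValueError, match="CR responses"):
            bx.ResponseMatrix(np.array([[1, 5]]), labels, n_categories=5)
        with pytest.raises(ValueError, match="integers"):
            bx.ResponseMatrix(np.array([[0.5, 1.0]]), labels)
        with pytest.raises(ValueError, match="format label"):
            bx.ResponseMatrix(np.array([[1, 1]]), np.array(["MC"]))

    def test_auto_item_ids(self):
        rm = bx.ResponseMatrix(np.array([[1, 0, 3]]),
                               np.array(["MC", "MC", "CR"]), n_categories=5)
        assert rm.item_ids == ("MC001", "MC002", "CR001")

    def test_csv_round_trip(self, tmp_path):
        rm = bx.ResponseMatrix(np.array([[1, 0, 3], [0, 1, 4]]),
                               np.array(["MC", "MC", "CR"]), n_categories=5)
        path = tmp_path / "resp.csv"
        bx.write_response_csv(path, rm)
        back = bx.read_response_csv(path, n_categories=5)
        np.testing.assert_array_equal(back.values, rm.values)
        np.testing.assert_array_equal(back.format_labels, rm.format_labels)
        assert back.item_ids == rm.item_ids


class TestRecodeCategories:
    @staticmethod
    def _matrix(cr_column, n_categories):
        values = np.column_stack([np.zeros(len(cr_column), dtype=int), cr_column])
        return bx.ResponseMatrix(values, np.array(["MC", "CR"]),
                                 n_categories=n_categories)

    def test_identity_when_already_at_target(self):
        rm = self._matrix(np.array([0, 1, 2, 3, 4] * 4), 5)
        out = bx.recode_categories(rm, 5)
        np.testing.assert_array_equal(out.values, rm.values)

    def test_uniform_ten_to_five_pairs(self):
        raw = np.repeat(np.arange(10), 6)  # perfectly uniform 10-point scale
        out = bx.recode_categories(self._matrix(raw, 10), 5)
        np.testing.assert_array_equal(out.cr_values[:, 0], raw // 2)
        assert out.n_categories == 5

    def test_monotone_and_surjective(self):
        rng = np.random.default_rng(17)
        raw = rng.integers(0, 9, 500)
        out = bx.recode_categories(self._matrix(raw, 9), 4)
        recoded = out.cr_values[:, 0]
        assert set(np.unique(recoded)) == {0, 1, 2, 3}
        # mapping is a non-decreasing function of the raw category
        for c in range(9):
            mask = raw == c
            if mask.any():
                assert len(np.unique(recoded[mask])) == 1
        reps = np.array([recoded[raw == c][0] for c in range(9) if (raw == c).any()])
        assert np.all(np.diff(reps) >= 0)
        assert np.all(np.diff(reps) <= 1)

    def test_too_few_occupied_categories(self):
        raw = np.array([0, 0, 7, 7, 7, 0])  # only two occupied categories
        with pytest.raises(ValueError, match="occupied"):
            bx.recode_categories(self._matrix(raw, 8), 5)

    def test_cannot_expand(self):
        rm = self._matrix(np.array([0, 1, 2, 0, 1, 2]), 3)
        with pytest.raises(ValueError, match="expand"):
            bx.recode_categories(rm, 5)


class TestDisattenuatedCorrelation:
    def test_cronbach_alpha_against_reference(self):
        rng = np.random.default_rng(23)
        common = rng.normal(0, 1, (200, 1))
        scores = np.round(common + rng.normal(0, 1, (200, 6)))
        assert bx.cronbach_alpha(scores) == pytest.approx(
            cronbach_alpha_reference(scores), abs=1e-10)

    def test_cronbach_alpha_hand_example(self):
        # four persons, two items; variances computed by hand (ddof = 1):
        # var(item1) = var(item2) = 5/3 over {0,1,2,3} and {1,0,3,2};
        # totals {1,1,5,5} have variance 16/3, alpha = 2 * (1 - (10/3)/(16/3))
        scores = np.array([[0, 1], [1, 0], [2, 3], [3, 2]], dtype=float)
        assert bx.cronbach_alpha(scores) == pytest.approx(0.75, abs=1e-12)

    def test_alpha_needs_two_items(self):
        with pytest.raises(ValueError, match="two items"):
            bx.cronbach_alpha(np.ones((10, 1)))

    def test_observed_tracks_implied(self, pool08):
        thetas = bx.sample_thetas(20_000, 31)
        responses = bx.simulate_responses(pool08, thetas, 32)
        observed = bx.observed_disattenuated_correlation(responses)
        implied = bx.implied_disattenuated_correlation(pool08, seed=33)
        assert abs(observed - implied) < 0.03

    def test_degenerate_inputs_rejected(self):
        values = np.ones((10, 4), dtype=int)
        rm = bx.ResponseMatrix(values, np.array(["MC", "MC", "CR", "CR"]),
                               n_categories=5)
        with pytest.raises(ValueError, match="zero-variance"):
            bx.observed_disattenuated_correlation(rm)
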