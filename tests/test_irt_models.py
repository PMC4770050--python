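"""Unit tests for the item response models and the item-parameter CSV format."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.special import erf

import bifax as bx
from bifax.irt_models import (
    cr_probs_bifactor,
    cr_probs_unidim,
    mc_probs_bifactor,
    mc_probs_unidim,
)

ORIGIN = bx.ThetaTriple(0.0, 0.0, 0.0)


class TestScalarProbabilities:
    def test_mc_bifactor_fixed_point(self):
        # Phi(0) = 0.5, so P = g + (1 - g)/2 = 0.6 at g = 0.2
        item = bx.BifactorMCItem(a_g=1.0, a_mc=0.5, d=0.0, g=0.2)
        assert bx.prob_mc_bifactor(item, ORIGIN) == pytest.approx(0.6, abs=1e-12)

    def test_mc_unidim_fixed_points(self):
        assert bx.prob_mc_unidim(bx.UnidimMCItem(a=1.0, b=0.0, g=0.0), 0.0) \
            == pytest.approx(0.5, abs=1e-12)
        assert bx.prob_mc_unidim(bx.UnidimMCItem(a=1.3, b=0.0, g=0.25), 0.0) \
            == pytest.approx(0.625, abs=1e-12)

    def test_normal_ogive_matches_erf(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            item = bx.BifactorMCItem(a_g=rng.uniform(0.2, 2.5),
                                     a_mc=rng.uniform(0.0, 2.5),
                                     d=rng.normal(0, 2), g=rng.uniform(0, 0.5))
            theta = bx.ThetaTriple(*rng.normal(0, 2, 3))
            z = item.a_g * theta.theta_g + item.a_mc * theta.theta_mc - item.d
            expected = item.g + (1 - item.g) * 0.5 * (1 + erf(z / math.sqrt(2)))
            assert bx.prob_mc_bifactor(item, theta) == pytest.approx(
                expected, abs=1e-10)

    def test_logistic_has_no_scaling_constant(self):
        # P = 1 / (1 + e^{-a(theta-b)}) exactly: no D = 1.7 factor anywhere
        item = bx.UnidimMCItem(a=1.0, b=0.0, g=0.0)
        assert bx.prob_mc_unidim(item, 2.0) == pytest.approx(
            1.0 / (1.0 + math.exp(-2.0)), abs=1e-12)

    def test_cr_bifactor_category_probabilities(self):
        item = bx.BifactorCRItem(a_g=1.2, a_cr=0.7, d=-0.5, offsets=(0.8, 1.6, 2.4))
        theta = bx.ThetaTriple(0.3, 0.0, -0.2)
        p = [bx.prob_cr_bifactor(item, theta, c) for c in range(5)]
        assert all(v >= 0 for v in p)
        assert sum(p) == pytest.approx(1.0, abs=1e-12)
        # cumulative P(y >= c) must decrease in c
        upper = np.cumsum(p[::-1])[::-1]
        assert np.all(np.diff(upper) < 0)

    def test_cr_unidim_category_probabilities(self):
        item = bx.UnidimCRItem(a=1.5, thresholds=(-1.0, 0.0, 1.0, 2.0))
        p = [bx.prob_cr_unidim(item, 0.4, c) for c in range(5)]
        assert sum(p) == pytest.approx(1.0, abs=1e-12)
        assert all(v > 0 for v in p)

    def test_bifactor_reduces_to_unidimensional_structure(self):
        # with a zero specific loading, theta_mc is irrelevant
        item = bx.BifactorMCItem(a_g=1.4, a_mc=0.0, d=0.3, g=0.1)
        p1 = bx.prob_mc_bifactor(item, bx.ThetaTriple(0.7, -2.0, 1.0))
        p2 = bx.prob_mc_bifactor(item, bx.ThetaTriple(0.7, 3.0, -1.0))
        assert p1 == pytest.approx(p2, abs=1e-14)

    def test_extreme_abilities_stay_in_unit_interval(self):
        item = bx.BifactorCRItem(a_g=2.0, a_cr=2.0, d=0.0, offsets=(1.0, 2.0, 3.0))
        for t in (-50.0, 50.0):
            theta = bx.ThetaTriple(t, 0.0, t)
            p = [bx.prob_cr_bifactor(item, theta, c) for c in range(5)]
            assert all(0.0 <= v <= 1.0 for v in p)
            assert sum(p) == pytest.approx(1.0, abs=1e-12)

    def test_category_out_of_range_raises(self):
        item = bx.BifactorCRItem(a_g=1.0, a_cr=1.0, d=0.0, offsets=(1.0,))
        with pytest.raises(ValueError, match="category"):
            bx.prob_cr_bifactor(item, ORIGIN, 3)


class TestValidation:
    def test_guessing_bounds(self):
        with pytest.raises(ValueError, match="asymptote"):
            bx.BifactorMCItem(a_g=1.0, a_mc=1.0, d=0.0, g=1.0)
        with pytest.raises(ValueError, match="asymptote"):
            bx.UnidimMCItem(a=1.0, b=0.0, g=-0.1)

    def test_offsets_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            bx.BifactorCRItem(a_g=1.0, a_cr=1.0, d=0.0, offsets=(1.0, 1.0))
        with pytest.raises(ValueError, match="increasing"):
            bx.BifactorCRItem(a_g=1.0, a_cr=1.0, d=0.0, offsets=(-0.5, 1.0))

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            bx.UnidimCRItem(a=1.0, thresholds=(0.5, 0.5))

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError):
            bx.BifactorMCItem(a_g=float("nan"), a_mc=1.0, d=0.0, g=0.1)
        with pytest.raises(ValueError):
            bx.ThetaTriple(0.0, float("inf"), 0.0)

    def test_boundaries_property(self):
        item = bx.BifactorCRItem(a_g=1.0, a_cr=1.0, d=-0.4, offsets=(0.9, 1.7))
        assert item.n_categories == 4
        np.testing.assert_allclose(item.boundaries, [-0.4, 0.5, 1.3])


class TestVectorisedAgreement:
    def test_bifactor_blocks_match_scalar(self, pool08):
        thetas = bx.sample_thetas(20, 42)
        p_mc = mc_probs_bifactor(pool08.mc_items, thetas)
        p_cr = cr_probs_bifactor(pool08.cr_items, thetas)
        for i in (0, 7, 19):
            triple = bx.ThetaTriple(*thetas[i])
            for j, item in enumerate(pool08.mc_items):
                assert p_mc[i, j] == pytest.approx(
                    bx.prob_mc_bifactor(item, triple), abs=1e-12)
            for j, item in enumerate(pool08.cr_items):
                for c in range(5):
                    assert p_cr[i, j, c] == pytest.approx(
                        bx.prob_cr_bifactor(item, triple, c), abs=1e-12)

    def test_unidim_blocks_match_scalar(self):
        mc = [bx.UnidimMCItem(a=1.2, b=-0.3, g=0.15),
              bx.UnidimMCItem(a=0.8, b=1.1, g=0.25)]
        cr = [bx.UnidimCRItem(a=1.4, thresholds=(-1.0, 0.2, 1.5, 2.2))]
        theta = np.array([-1.3, 0.0, 0.9])
        p_mc = mc_probs_unidim(mc, theta)
        p_cr = cr_probs_unidim(cr, theta)
        for i, t in enumerate(theta):
            for j, item in enumerate(mc):
                assert p_mc[i, j] == pytest.approx(
                    bx.prob_mc_unidim(item, t), abs=1e-12)
            for c in range(5):
                assert p_cr[i, 0, c] == pytest.approx(
                    bx.prob_cr_unidim(cr[0], t, c), abs=1e-12)


class TestItemCsv:
    def test_bifactor_round_trip(self, pool08, tmp_path):
        path = tmp_path / "items.csv"
        bx.write_item_csv(path, pool08.mc_items, pool08.cr_items, "bifactor")
        mc, cr, model, ids = bx.read_item_csv(path)
        assert model == "bifactor"
        assert len(ids) == 58
        for orig, back in zip(pool08.mc_items, mc):
            for name in ("a_g", "a_mc", "d", "g"):
                assert getattr(back, name) == pytest.approx(
                    getattr(orig, name), rel=1e-11)
        for orig, back in zip(pool08.cr_items, cr):
            for name in ("a_g", "a_cr", "d"):
                assert getattr(back, name) == pytest.approx(
                    getattr(orig, name), rel=1e-11)
            np.testing.assert_allclose(back.offsets, orig.offsets, rtol=1e-11)

    def test_unidim_round_trip(self, tmp_path):
        mc = [bx.UnidimMCItem(a=1.23456789012, b=-0.5, g=0.2)]
        cr = [bx.UnidimCRItem(a=0.9, thresholds=(-1.1, 0.0, 0.8, 2.0))]
        path = tmp_path / "items.csv"
        bx.write_item_csv(path, mc, cr, "unidim")
        mc2, cr2, model, _ = bx.read_item_csv(path)
        assert model == "unidim"
        assert mc2[0].a == pytest.approx(mc[0].a, rel=1e-11)
        np.testing.assert_allclose(cr2[0].thresholds, cr[0].thresholds,
                                   rtol=1e-11)

    def test_invalid_model_label(self, tmp_path):
        with pytest.raises(ValueError, match="model"):
            bx.write_item_csv(tmp_path / "x.csv", [], [], "rasch")

    def test_schema_violations_raise(self, tmp_path):
        path = tmp_path / "bad.csv"
        header = "item_id,format,model,a_g,a_spec,d,g,o2,o3,o4\n"
        cases = [
            ("MC001,XX,bifactor,1,1,0,0.2,,,\n", "format"),
            ("MC001,MC,bifactor,1,1,,0.2,,,\n", "required"),
            ("CR001,CR,bifactor,1,1,0,0.2,0.5,1.0,1.5\n", "blank"),
            ("MC001,MC,unidim,1,1,0,0.2,,,\n", "a_spec"),
        ]
        for row, match in cases:
            path.write_text(header + row)
            with pytest.raises(ValueError, match=match):
                bx.read_item_csv(path)

    def test_wrong_columns_raise(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,format,model,a_g,a_spec,d,g\nMC001,MC,unidim,1,,0,0.2\n")
        with pytest.raises(ValueError, match="columns"):
            bx.read_item_csv(path)

    def test_mixed_model_families_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "item_id,format,model,a_g,a_spec,d,g\n"
            "MC001,MC,unidim,1,,0,0.2\nMC002,MC,bifactor,1,1,0,0.2\n")
        with pytest.raises(ValueError, match="single model"):
            bx.read_item_csv(path)
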