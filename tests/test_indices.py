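"""Quality-index algebra and random-forest weight estimation."""

import numpy as np
import pandas as pd
import pytest

import eai_risk as er


def _grids(*cell_scores, shape=(2, 2)):
    return [er.Grid(np.full(shape, s)) for s in cell_scores]


def _index(ir):
    return ir.grid.values


class TestGeometricMean:
    def test_equal_inputs_identity(self):
        out = er.geometric_mean_index(_grids(*[10.0] * 6), "CQI")
        np.testing.assert_allclose(_index(out), 10.0)

    def test_six_factor_example_matches_direct_arithmetic(self):
        scores = (3.4, 8.0, 6.0, 6.0, 6.0, 5.0)
        expected = np.prod(scores) ** (1 / 6)  # independent arithmetic
        out = er.geometric_mean_index(_grids(*scores), "CQI")
        np.testing.assert_allclose(_index(out), expected)

    def test_five_factor_example_matches_direct_arithmetic(self):
        scores = (2.5, 2.5, 1.7, 2.0, 2.0)
        expected = np.prod(scores) ** (1 / 5)
        out = er.geometric_mean_index(_grids(*scores), "SQI")
        np.testing.assert_allclose(_index(out), expected)

    def test_mask_union(self):
        g1, g2 = _grids(4.0, 9.0)
        g1.nodata_mask[0, 0] = True
        g2.nodata_mask[1, 1] = True
        out = er.geometric_mean_index([g1, g2], "X")
        assert out.grid.nodata_mask.sum() == 2

    def test_nonpositive_score_rejected(self):
        g1, g2 = _grids(4.0, 0.0)
        with pytest.raises(ValueError, match="non-positive"):
            er.geometric_mean_index([g1, g2], "X")

    def test_misaligned_rejected(self):
        g1 = er.Grid(np.full((2, 2), 4.0))
        g2 = er.Grid(np.full((3, 3), 4.0))
        with pytest.raises(er.GridError):
            er.geometric_mean_index([g1, g2], "X")


class TestComputeIndices:
    def _stack(self, assignments, shape=(2, 2)):
        return er.FactorStack({k: er.Grid(np.full(shape, float(v)))
                               for k, v in assignments.items()})

    TOP = {"Pr": 900, "T": 15, "Di": 0.9, "Al": 1000, "Par": 3900,
           "At": 7000, "Sd": 120, "St": 0.9, "Sei": 6, "Som": 10,
           "Sm": 0.2, "Vc": 200, "Vr": 0.5, "Vrr": 4, "NPP": 1500, "A": 4}

    def test_all_top_classes_give_index_ten(self, tables):
        stack = self._stack(self.TOP)
        for fn in (er.compute_cqi, er.compute_sqi, er.compute_vqi):
            np.testing.assert_allclose(_index(fn(stack, tables)), 10.0)

    def test_sqi_bottom_classes_match_arithmetic_oracle(self, tables):
        # raw values in the lowest class of each soil table
        stack = self._stack({"Sd": 5, "St": 0.2, "Sei": 1, "Som": 0.5,
                             "Sm": 0.04})
        expected = (2.5 * 2.5 * 1.7 * 2.0 * 2.0) ** (1 / 5)
        np.testing.assert_allclose(_index(er.compute_sqi(stack, tables)),
                                   expected)

    def test_factor_order_is_irrelevant(self, tables):
        items = list(self.TOP.items())
        a = er.compute_cqi(self._stack(dict(items)), tables)
        b = er.compute_cqi(self._stack(dict(reversed(items))), tables)
        np.testing.assert_array_equal(_index(a), _index(b))

    def test_missing_factor_named_in_error(self, tables):
        stack = self._stack({k: v for k, v in self.TOP.items()
                             if k != "Par"})
        with pytest.raises(er.GridError, match="Par"):
            er.compute_cqi(stack, tables)


class TestEAI:
    def test_convex_combination_identity(self):
        five = er.IndexRaster("CQI", er.Grid(np.full((2, 2), 5.0)))
        out = er.compute_eai(five, five, five)
        np.testing.assert_allclose(_index(out), 5.0)

    def test_default_weights_arithmetic(self):
        cqi = er.IndexRaster("CQI", er.Grid(np.full((2, 2), 10.0)))
        sqi = er.IndexRaster("SQI", er.Grid(np.full((2, 2), 5.0)))
        vqi = er.IndexRaster("VQI", er.Grid(np.full((2, 2), 5.0)))
        out = er.compute_eai(cqi, sqi, vqi)
        np.testing.assert_allclose(_index(out), 0.6 * 10 + 0.2 * 5 + 0.2 * 5)

    def test_degenerate_weights_recover_cqi(self):
        rng = np.random.default_rng(0)
        cqi = er.IndexRaster("CQI", er.Grid(rng.uniform(1, 10, (4, 4))))
        sqi = er.IndexRaster("SQI", er.Grid(rng.uniform(1, 10, (4, 4))))
        vqi = er.IndexRaster("VQI", er.Grid(rng.uniform(1, 10, (4, 4))))
        out = er.compute_eai(cqi, sqi, vqi, er.IndexWeights(1.0, 0.0, 0.0))
        np.testing.assert_array_equal(_index(out), cqi.grid.values)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            er.IndexWeights(0.6, 0.2, 0.3)
        with pytest.raises(ValueError, match="non-negative"):
            er.IndexWeights(1.2, -0.1, -0.1)


@pytest.fixture(scope="module")
def samples(small_scene):
    return er.generate_weight_training_samples(small_scene, 1500, seed=4)


class TestEstimateWeights:

    def test_same_seed_identical_weights(self, samples):
        w1, g1 = er.estimate_weights(samples, n_trees=150, seed=9)
        w2, g2 = er.estimate_weights(samples, n_trees=150, seed=9)
        assert w1 == w2 and g1 == g2

    def test_cqi_thresholded_labels_concentrate_weight_on_cqi(self):
        # labels a deterministic function of CQI alone
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            cqi = rng.uniform(1, 10, 800)
            df = pd.DataFrame({
                "CQI": cqi, "SQI": rng.uniform(1, 10, 800),
                "VQI": rng.uniform(1, 10, 800),
                "reference_label": np.where(cqi > 5.5, "hi", "lo"),
            })
            w, _ = er.estimate_weights(df, n_trees=300, seed=seed)
            hits += (w.w_cqi > w.w_sqi) and (w.w_cqi > w.w_vqi)
        assert hits >= 5

    def test_random_labels_score_at_chance(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "CQI": rng.uniform(1, 10, 500), "SQI": rng.uniform(1, 10, 500),
            "VQI": rng.uniform(1, 10, 500),
            "reference_label": rng.choice(["a", "b"], 500),
        })
        _, goodness = er.estimate_weights(df, n_trees=400, seed=0)
        assert abs(goodness - 0.5) < 3 * np.sqrt(0.25 / 500)

    def test_single_class_labels_rejected(self):
        df = pd.DataFrame({"CQI": np.linspace(1, 9, 200),
                           "SQI": np.linspace(1, 9, 200),
                           "VQI": np.linspace(1, 9, 200),
                           "reference_label": ["x"] * 200})
        with pytest.raises(ValueError, match="single class"):
            er.estimate_weights(df)

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"CQI": [1.0] * 50, "SQI": [1.0] * 50,
                           "VQI": [1.0] * 50,
                           "reference_label": ["a", "b"] * 25})
        with pytest.raises(ValueError, match="100"):
            er.estimate_weights(df)


class TestAlgebraProperties:
    """Randomised invariants of the index algebra (seeded draws)."""

    def test_bounds_monotonicity_convexity(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 7))
            grids = [er.Grid(rng.uniform(1.25, 10, (3, 3)))
                     for _ in range(n)]
            gm = _index(er.geometric_mean_index(grids, "X"))
            stackv = np.stack([g.values for g in grids])
            assert (gm >= stackv.min(axis=0) - 1e-12).all()
            assert (gm <= stackv.max(axis=0) + 1e-12).all()
            # raising one input never lowers the index
            j = int(rng.integers(n))
            bumped = [g.copy() for g in grids]
            bumped[j] = er.Grid(np.minimum(bumped[j].values * 1.3, 10.0))
            gm2 = _index(er.geometric_mean_index(bumped, "X"))
            assert (gm2 >= gm - 1e-12).all()
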