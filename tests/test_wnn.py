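import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from omifuse.preprocess import CohortBundle
from omifuse.simulate import simulate_cohort, simulate_uninformative_layer, \
    LayerSpec, SimulationSpec
from omifuse.wnn import (PredictionSimilarity, bandwidth, build_knn,
                         cohort_weights, compute_prediction_similarities,
                         cross_prediction, omics_weights,
                         prediction_similarity, within_prediction)

from conftest import make_layer
from oracles import knn_brute, mean_prediction_brute, sigma_brute, theta_brute


class TestBuildKnn:
    def test_1d_enumeration(self):
        g = build_knn(make_layer([[0.0], [1.0], [10.0]]), k=1)
        assert g.neighbors[0, 0] == 1
        assert g.neighbors[1, 0] == 0
        assert g.neighbors[2, 0] == 1

    def test_k_equals_n_minus_1_lists_everyone(self, random_layer):
        g = build_knn(random_layer, k=9)
        for i in range(10):
            assert set(g.neighbors[i]) == set(range(10)) - {i}

    def test_duplicated_profiles_tie_break_by_index(self):
        g = build_knn(make_layer(np.zeros((4, 3))), k=2)
        np.testing.assert_array_equal(g.neighbors[0], [1, 2])
        np.testing.assert_array_equal(g.neighbors[3], [0, 1])

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=(12, 3))
        g = build_knn(make_layer(x), k=4)
        assert g.neighbors.tolist() == knn_brute(x, 4)

    def test_k_clamped_with_warning(self, random_layer, caplog):
        g = build_knn(random_layer, k=50)
        assert g.k == 9

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            build_knn(make_layer([[1.0, 2.0]]), k=1)


class TestPredictions:
    def test_k1_prediction_is_the_neighbor(self):
        layer = make_layer([[0.0], [1.0], [10.0]])
        g = build_knn(layer, k=1)
        pred = within_prediction(layer, g)
        np.testing.assert_allclose(pred[:, 0], [1.0, 0.0, 1.0])

    def test_identical_patients_predict_themselves(self):
        layer = make_layer(np.tile([2.0, 3.0], (5, 1)))
        pred = within_prediction(layer, build_knn(layer, k=2))
        np.testing.assert_allclose(pred, layer.values)

    def test_within_matches_brute_force(self, rng):
        x = rng.normal(size=(4, 3))
        layer = make_layer(x)
        g = build_knn(layer, k=2)
        np.testing.assert_allclose(within_prediction(layer, g),
                                   mean_prediction_brute(x, g.neighbors.tolist()),
                                   atol=1e-12)

    def test_cross_with_own_graph_equals_within(self, random_layer):
        g = build_knn(random_layer, k=3)
        np.testing.assert_array_equal(cross_prediction(random_layer, g),
                                      within_prediction(random_layer, g))

    def test_cross_matches_brute_force(self, rng):
        a = make_layer(rng.normal(size=(6, 4)), name="a")
        b = make_layer(rng.normal(size=(6, 3)), name="b")
        gb = build_knn(b, k=2)
        np.testing.assert_allclose(
            cross_prediction(a, gb),
            mean_prediction_brute(a.values, gb.neighbors.tolist()),
            atol=1e-12,
        )

    def test_ordering_mismatch_rejected(self, rng):
        a = make_layer(rng.normal(size=(4, 2)))
        b = make_layer(rng.normal(size=(4, 2)), patients=list("WXYZ"))
        with pytest.raises(ValueError):
            cross_prediction(a, build_knn(b, k=1))


class TestBandwidth:
    def test_arithmetic_mean_of_neighbor_distances(self):
        layer = make_layer([[0.0], [1.0], [3.0]])
        g = build_knn(layer, k=2)
        # patient 0: distances {1, 3} -> sigma = 2
        assert bandwidth(g)[0] == pytest.approx(2.0)

    def test_degenerate_data_floored(self):
        g = build_knn(make_layer(np.zeros((3, 2))), k=1)
        assert np.all(bandwidth(g) > 0)

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=(7, 3))
        g = build_knn(make_layer(x), k=3)
        np.testing.assert_allclose(bandwidth(g),
                                   sigma_brute(x, g.neighbors.tolist()), atol=1e-12)


class TestPredictionSimilarity:
    def test_perfect_prediction(self):
        obs = np.array([[1.0, 2.0]])
        assert prediction_similarity(obs, obs, 1.0)[0] == 1.0

    def test_unit_residual(self):
        obs = np.array([[0.0]])
        pred = np.array([[2.0]])
        assert prediction_similarity(obs, pred, 2.0)[0] == pytest.approx(math.exp(-1))

    def test_half_residual(self):
        obs = np.array([[0.0, 0.0]])
        pred = np.array([[2.0, 0.0]])
        assert prediction_similarity(obs, pred, 4.0)[0] == pytest.approx(
            math.exp(-0.5), abs=1e-12)

    def test_squared_variant(self):
        obs, pred = np.array([[0.0]]), np.array([[2.0]])
        assert prediction_similarity(obs, pred, 2.0, squared=True)[0] == \
            pytest.approx(math.exp(-2.0))

    def test_theta_matches_brute_force(self, rng):
        obs = rng.normal(size=(5, 4))
        pred = rng.normal(size=(5, 4))
        sigma = rng.uniform(0.5, 2.0, size=5)
        np.testing.assert_allclose(prediction_similarity(obs, pred, sigma),
                                   theta_brute(obs, pred, sigma), atol=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            prediction_similarity(np.zeros((1, 2)), np.zeros((1, 2)), 0.0)


def _sim(theta_within, theta_cross, omics=("r", "m"), patients=("P1",)):
    T, n = len(omics), len(patients)
    tw = np.asarray(theta_within, dtype=float).reshape(T, n)
    tc = np.asarray(theta_cross, dtype=float).reshape(T, T, n)
    for t in range(T):
        tc[t, t] = tw[t]
    return PredictionSimilarity(patients=list(patients), omics=list(omics),
                                theta_within=tw, theta_cross=tc,
                                sigma=np.ones((T, n)))


class TestOmicsWeights:
    def test_softmax_symmetry(self):
        sim = _sim([0.8, 0.8], [[0.8, 0.3], [0.3, 0.8]])
        w = omics_weights(sim).w
        np.testing.assert_allclose(w, 0.5)

    def test_worked_two_omics_example(self):
        # theta_rr=1, theta_rm=0.5, theta_mm=0.5, theta_mr=1 and negligible
        # epsilon give s_r = 2, s_m = 0.5, w_r = e^2/(e^2 + e^0.5)
        sim = _sim([1.0, 0.5], [[1.0, 0.5], [1.0, 0.5]])
        w = omics_weights(sim, epsilon=0.0).w
        expected = math.exp(2) / (math.exp(2) + math.exp(0.5))
        assert w[0, 0] == pytest.approx(expected, abs=1e-12)
        assert w[0, 1] == pytest.approx(1 - expected, abs=1e-12)

    def test_identical_layers_give_half(self, random_layer):
        twin = make_layer(random_layer.values.copy(), name="twin",
                          normalized=True)
        bundle = CohortBundle(layers=[random_layer, twin])
        w = cohort_weights(bundle, k=3).w
        np.testing.assert_allclose(w, 0.5, atol=1e-9)

    def test_single_omics_trivial(self, random_layer):
        sims = compute_prediction_similarities([random_layer], k=3)
        np.testing.assert_array_equal(omics_weights(sims).w, 1.0)

    def test_swap_symmetry(self, rng):
        a = make_layer(rng.normal(size=(12, 5)), name="a", normalized=True)
        b = make_layer(rng.normal(size=(12, 4)), name="b", normalized=True)
        w_ab = cohort_weights(CohortBundle(layers=[a, b]), k=4).w
        w_ba = cohort_weights(CohortBundle(layers=[b, a]), k=4).w
        np.testing.assert_allclose(w_ab, w_ba[:, ::-1], atol=1e-12)

    def test_non_finite_theta_named(self):
        sim = _sim([1.0, np.nan], [[1.0, 0.5], [1.0, np.nan]])
        with pytest.raises(ValueError, match="P1"):
            omics_weights(sim)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(hnp.arrays(np.float64, (3, 3, 5),
                      elements=st.floats(0.05, 1.0)))
    def test_rows_always_sum_to_one(self, tc):
        # theta in [0.05, 1] keeps the ratios below the overflow clip, so
        # no weight saturates to exactly 0 or 1 in float64
        tw = np.stack([tc[t, t] for t in range(3)])
        sim = PredictionSimilarity(patients=[f"P{i}" for i in range(5)],
                                   omics=["a", "b", "c"], theta_within=tw,
                                   theta_cross=tc, sigma=np.ones((3, 5)))
        w = omics_weights(sim).w
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(w > 0) and np.all(w < 1)

    def test_informative_layer_dominates_noise(self):
        bundle, labels, _ = simulate_cohort(SimulationSpec(
            n_patients=60,
            layers=[LayerSpec(name="signal", n_features=100),
                    LayerSpec(name="noise", n_features=100, signal_strength=0.0)],
            seed=11,
        ))
        w = cohort_weights(bundle, k=10).to_frame()
        assert w["signal"].median() > 0.5

    def test_self_consistent_neighborhoods_give_uniform_weights(self, random_layer):
        # identical layers => cross neighborhoods coincide with within ones
        twin = make_layer(random_layer.values.copy(), name="twin", normalized=True)
        sims = compute_prediction_similarities([random_layer, twin], k=3)
        s_ratio = sims.theta_within / (sims.theta_cross[0, 1] + 1e-8)
        np.testing.assert_allclose(s_ratio, 1.0, atol=1e-6)
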