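"""The l1-relaxed identification program and response prediction."""

import json

import numpy as np
import pytest

from pulsedyn.atoms import AtomDictionary, PoleGrid, build_pole_grid, scaling_factor
from pulsedyn.errors import ParameterError
from pulsedyn.identify import IdentifiedModel, identify_model, impulse_response, predict

from conftest import make_dataset


def single_pole_oracle(grid, N_l, epsilon):
    """Closed form for one smoking minute with u = 0: best single-pole cost.

    Only y(0) matters, and y(0) = sum_p alpha_p C^N_p.  Putting all mass on
    a real pole p costs (1 + eps)/alpha_p; a conjugate pair reaches the same
    real value with two coefficients of half the modulus, each charged its
    bound, so its cost is also (1 + eps)/alpha_p.  The optimum enumerates
    alpha over poles.
    """
    return min(
        (1.0 + epsilon) / scaling_factor(p, N_l) for p in grid.poles
    )


class TestIdentifyModel:
    def test_single_smoking_minute_matches_enumeration_oracle(
        self, tiny_grid, single_smoking_minute
    ):
        eps = 1e-5
        model = identify_model(single_smoking_minute, tiny_grid, epsilon=eps)
        expected = single_pole_oracle(tiny_grid, single_smoking_minute.N_l, eps)
        assert model.solver_status == "optimal"
        assert model.objective == pytest.approx(expected, abs=1e-6)
        assert model.objective == pytest.approx(1.0 + eps, abs=1e-6)
        # all mass on the origin pole (alpha is maximal there)
        assert model.support == (0,)
        assert model.natural_coeffs[1][0].real == pytest.approx(1.0 + eps, abs=1e-6)

    def test_all_nonsmoking_gives_zero_model(self, tiny_grid):
        data = make_dataset([([0.5, 0.3], [0, 0])])
        model = identify_model(data, tiny_grid)
        assert model.objective == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(model.input_coeffs, 0.0)
        assert model.support == ()

    def test_training_labels_reproduced(self, small_training_set):
        grid = build_pole_grid(4, 4, r_max=0.9)
        model = identify_model(small_training_set, grid)
        assert model.solver_status == "optimal"
        for ch in small_training_set.chunks:
            dec = predict(model, chunk_id=ch.chunk_id)
            assert np.array_equal(dec.smoking_pred, ch.s)

    def test_homogeneity_of_threshold(self, small_training_set):
        grid = build_pole_grid(3, 4, r_max=0.9)
        base = identify_model(small_training_set, grid, threshold=1.0)
        scaled = identify_model(small_training_set, grid, threshold=2.5)
        assert scaled.objective == pytest.approx(2.5 * base.objective, rel=1e-6)

    def test_objective_monotone_in_grid(self, single_smoking_minute):
        small = PoleGrid(poles=np.array([0.0 + 0.0j]))
        big = PoleGrid(poles=np.array([0.0 + 0.0j, 0.5 + 0.0j, 0.8 + 0.0j]))
        obj_small = identify_model(single_smoking_minute, small).objective
        obj_big = identify_model(single_smoking_minute, big).objective
        assert obj_big <= obj_small + 1e-8

    def test_invalid_epsilon_rejected(self, tiny_grid, single_smoking_minute):
        with pytest.raises(ParameterError):
            identify_model(single_smoking_minute, tiny_grid, epsilon=0.0)

    def test_complex_support_coefficients_are_conjugate_symmetric(self, mixed_grid):
        # a pattern needing oscillatory dynamics: smoking follows stress
        # with alternating gaps
        u = np.array([0.9, 0.0, 0.9, 0.0, 0.9, 0.0, 0.0, 0.0])
        s = np.array([1, 0, 1, 0, 1, 0, 0, 0])
        model = identify_model(make_dataset([(u, s)]), mixed_grid)
        pairing = model.grid.conjugate_pairing
        for i, j in pairing.items():
            assert model.input_coeffs[i] == pytest.approx(
                np.conj(model.input_coeffs[j]), abs=1e-8
            )
            for coeffs in model.natural_coeffs.values():
                assert coeffs[i] == pytest.approx(np.conj(coeffs[j]), abs=1e-8)


class TestPredict:
    def test_zero_model_predicts_no_smoking(self, tiny_grid):
        model = IdentifiedModel.zero(tiny_grid, N_l=5.0)
        dec = predict(model, u=np.array([0.9, 1.0, 0.3]))
        assert np.allclose(dec.y_system, 0.0)
        assert not dec.smoking_pred.any()

    def test_origin_pole_scales_input(self):
        grid = PoleGrid(poles=np.array([0.0 + 0.0j]))
        model = IdentifiedModel.zero(grid, N_l=3.0)
        model.input_coeffs = np.array([2.0 + 0.0j])
        dec = predict(model, u=np.array([1.0, 0.0]))
        assert np.allclose(dec.y_system, [2.0, 0.0])
        assert list(dec.smoking_pred) == [1, 0]

    def test_threshold_is_inclusive(self):
        grid = PoleGrid(poles=np.array([0.0 + 0.0j]))
        model = IdentifiedModel.zero(grid, N_l=3.0)
        model.input_coeffs = np.array([1.0 + 0.0j])
        dec = predict(model, u=np.array([1.0]))
        assert dec.y_system[0] == pytest.approx(1.0)
        assert dec.smoking_pred[0] == 1  # y == threshold counts as smoking

    def test_decomposition_sums(self, small_training_set):
        grid = build_pole_grid(4, 4, r_max=0.9)
        model = identify_model(small_training_set, grid)
        dec = predict(model, chunk_id=1)
        assert np.allclose(dec.y_system, dec.y_cause + dec.y_intrinsic, atol=1e-12)

    def test_unknown_chunk_raises(self, small_training_set, tiny_grid):
        model = identify_model(small_training_set, tiny_grid)
        with pytest.raises(KeyError):
            predict(model, chunk_id=99)


def test_impulse_response_is_real_for_conjugate_coefficients(mixed_grid):
    model = IdentifiedModel.zero(mixed_grid, N_l=8.0)
    C = 0.7 - 0.3j
    model.input_coeffs = np.array([0.5, -0.2, C, np.conj(C)], dtype=complex)
    h = impulse_response(model, 50)
    assert h.dtype == float
    # cross-check one lag by hand
    p = mixed_grid.poles[2]
    a = model.dictionary.alpha
    expected_h3 = (
        0.5 * a[0] * 0.0
        + (-0.2) * a[1] * 0.4**3
        + 2 * (C * a[2] * p**3).real
    )
    assert h[3] == pytest.approx(expected_h3, abs=1e-12)


def test_model_json_roundtrip(small_training_set):
    grid = build_pole_grid(3, 3, r_max=0.9)
    model = identify_model(small_training_set, grid)
    clone = IdentifiedModel.from_json(model.to_json())
    assert np.allclose(clone.input_coeffs, model.input_coeffs)
    assert clone.objective == pytest.approx(model.objective)
    assert clone.support == model.support
    assert clone.dictionary.N_l == pytest.approx(model.dictionary.N_l)
    for cid, arr in model.natural_coeffs.items():
        assert np.allclose(clone.natural_coeffs[cid], arr)
    # a clone predicts identically on explicit input
    u = np.array([0.5, 0.9, 0.1, 0.0])
    assert np.allclose(
        predict(clone, u=u).y_system, predict(model, u=u).y_system
    )
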