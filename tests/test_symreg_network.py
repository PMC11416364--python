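import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pksymreg._exceptions import FormatError, StructuralError
from pksymreg.pk_model import PARAM_NAMES
from pksymreg.symreg_network import (
    EPS_DIV,
    EPS_POW,
    ArchitectureConfig,
    NormalizationSpec,
    SymRegLayer,
    SymRegNetworkBank,
    bank_forward,
    bank_forward_many,
    base_expr_g1,
    base_expr_g2,
    base_expr_g3,
    init_bank,
    layer_forward,
    net_backward,
    net_forward,
    normalize,
)


class TestNormalization:
    def test_age_max(self):
        phi = normalize({"age": 88, "weight": 70, "bmi": 25,
                         "gender": "M", "site": "A"})
        assert phi[0] == pytest.approx(1.0)

    def test_age_half(self):
        phi = normalize({"age": 44, "weight": 70, "bmi": 25,
                         "gender": "M", "site": "A"})
        assert phi[0] == pytest.approx(0.5)

    def test_categorical_signs(self):
        m = normalize({"age": 10, "weight": 70, "bmi": 25,
                       "gender": "M", "site": "V"})
        f = normalize({"age": 10, "weight": 70, "bmi": 25,
                       "gender": "F", "site": "A"})
        assert (m[3], m[4]) == (0.5, -0.5)
        assert (f[3], f[4]) == (-0.5, 0.5)

    def test_unknown_label_rejected(self):
        with pytest.raises(FormatError):
            normalize({"age": 10, "weight": 70, "bmi": 25,
                       "gender": "X", "site": "A"})

    def test_out_of_range_warns_not_fails(self):
        with pytest.warns(UserWarning):
            phi = normalize({"age": 100, "weight": 70, "bmi": 25,
                             "gender": "M", "site": "A"})
        assert phi[0] > 1.0

    def test_in_range_continuous_in_unit_interval(self, rng):
        for _ in range(20):
            phi = normalize({
                "age": rng.uniform(0, 88), "weight": rng.uniform(0.68, 160),
                "bmi": rng.uniform(6.2, 52.8), "gender": "F", "site": "V",
            })
            assert np.all(phi[:3] >= 0) and np.all(phi[:3] <= 1)

    def test_spec_validation(self):
        with pytest.raises(FormatError):
            NormalizationSpec(age_max=-1)


class TestBaseExpressions:
    def test_g1_power(self):
        np.testing.assert_allclose(
            base_expr_g1(np.array([7.0, 2.0, 3.0, -2.0, 3.0])), [7, 6, 8]
        )

    def test_g1_zero_exponent(self):
        np.testing.assert_allclose(
            base_expr_g1(np.array([0.0, 0.0, 5.0, 1.0, 0.0])), [0, 0, 1]
        )

    def test_g1_guard_finite(self):
        out = base_expr_g1(np.array([0.0, 0.0, 0.0, 0.0, -1.0]))
        assert np.isfinite(out[2])
        assert out[2] == pytest.approx(1.0 / EPS_POW)

    def test_g2_unit_denominator(self):
        np.testing.assert_allclose(
            base_expr_g2(np.array([1.0, 2.0, 3.0, 4.0, 0.0])), [1, 6, 4]
        )

    def test_g2_ratio(self):
        np.testing.assert_allclose(
            base_expr_g2(np.array([0.0, 0.0, 0.0, 5.0, 4.0])), [0, 0, 1]
        )

    def test_g2_guard_bounded(self):
        out = base_expr_g2(np.array([0.0, 0.0, 0.0, 3.0, -1.0]))
        assert np.isfinite(out[2])
        assert abs(out[2]) <= 3.0 / EPS_DIV

    def test_g3(self):
        assert base_expr_g3(-0.3) == pytest.approx(0.3)
        assert base_expr_g3(0.0) == 0.0

    @given(st.lists(st.floats(min_value=-3, max_value=3), min_size=5,
                    max_size=5))
    def test_guards_inactive_on_well_scaled_inputs(self, zs):
        z = np.array(zs)
        if abs(z[3]) > EPS_POW:
            # == up to one ulp: numpy's pow may differ from libm's by 1 ulp
            assert base_expr_g1(z)[2] == pytest.approx(
                abs(z[3]) ** z[4], rel=5e-16, abs=0
            )
        if abs(z[4] + 1.0) > EPS_DIV:
            assert base_expr_g2(z)[2] == z[3] / (z[4] + 1.0)


class TestLayerForward:
    def test_zero_layer_g1(self):
        layer = SymRegLayer(
            W=np.zeros((5, 5)), b=np.zeros(5),
            W_mask=np.ones((5, 5)), b_mask=np.ones(5), base_expr="g1",
        )
        np.testing.assert_allclose(
            layer_forward(layer, np.zeros(5)), [0.0, 0.0, 1.0]
        )

    def test_identity_wiring_passes_through(self):
        W = np.zeros((5, 5))
        W[0, 0] = 1.0
        layer = SymRegLayer(W=W, b=np.zeros(5), W_mask=np.ones((5, 5)),
                            b_mask=np.ones(5), base_expr="g1")
        out = layer_forward(layer, np.array([0.7, 0.1, 0.2, 0.3, 0.4]))
        assert out[0] == pytest.approx(0.7)

    def test_matches_hand_computation(self, rng):
        W = rng.normal(size=(5, 5))
        b = rng.normal(size=5)
        layer = SymRegLayer(W=W, b=b, W_mask=np.ones((5, 5)),
                            b_mask=np.ones(5), base_expr="g2")
        x = rng.normal(size=5)
        z = W @ x + b
        expected = [z[0], z[1] * z[2], z[3] / (z[4] + 1.0)]
        np.testing.assert_allclose(layer_forward(layer, x), expected,
                                   rtol=1e-12)

    def test_dimension_mismatch(self):
        layer = SymRegLayer(W=np.zeros((5, 5)), b=np.zeros(5),
                            W_mask=np.ones((5, 5)), b_mask=np.ones(5),
                            base_expr="g1")
        with pytest.raises(StructuralError):
            layer_forward(layer, np.zeros(3))

    def test_masked_entries_contribute_zero(self, rng):
        W = rng.normal(size=(5, 5))
        mask = (rng.uniform(size=(5, 5)) > 0.5).astype(np.uint8)
        layer = SymRegLayer(W=W.copy(), b=rng.normal(size=5),
                            W_mask=mask, b_mask=np.ones(5), base_expr="g1")
        x = rng.normal(size=5)
        explicit = SymRegLayer(W=W * mask, b=layer.b.copy(),
                               W_mask=np.ones((5, 5)), b_mask=np.ones(5),
                               base_expr="g1")
        np.testing.assert_allclose(layer_forward(layer, x),
                                   layer_forward(explicit, x), rtol=1e-14)


class TestBank:
    def test_init_is_deterministic(self):
        g1 = init_bank(1).get_gamma()
        g2 = init_bank(1).get_gamma()
        np.testing.assert_array_equal(g1, g2)

    def test_different_seeds_differ(self):
        assert not np.array_equal(init_bank(1).get_gamma(),
                                  init_bank(2).get_gamma())

    def test_dense_parameter_count(self):
        bank = init_bank(0)
        for net in bank.networks.values():
            assert net.n_unmasked() == 54
        assert bank.get_gamma().size == 54 * 6

    def test_forward_positive(self, rng):
        for seed in range(20):
            bank = init_bank(seed)
            phi = rng.uniform(-0.5, 1.0, size=5)
            p = bank_forward(bank, phi)
            assert all(getattr(p, n) > 0 for n in PARAM_NAMES)

    def test_all_zero_weights_give_abs_bias(self):
        bank = init_bank(3)
        for net in bank.networks.values():
            for l in net.layers:
                l.W[:] = 0.0
                l.b[:] = 0.0
            net.layers[2].b[0] = -0.25
        theta = bank_forward_many(bank, np.zeros((1, 5)))[0]
        np.testing.assert_allclose(theta, 0.25)

    def test_gamma_round_trip(self, rng):
        bank = init_bank(4)
        gamma = rng.normal(size=bank.get_gamma().size)
        bank.set_gamma(gamma)
        np.testing.assert_array_equal(bank.get_gamma(), gamma)

    def test_set_gamma_wrong_length(self):
        bank = init_bank(0)
        with pytest.raises(StructuralError):
            bank.set_gamma(np.zeros(5))

    def test_json_round_trip_bit_exact(self):
        bank = init_bank(11)
        bank.networks["k10"].layers[0].W_mask[:, 2] = 0
        bank.networks["k10"].layers[0].apply_masks()
        restored = SymRegNetworkBank.from_json(bank.to_json())
        assert restored.seed == bank.seed
        for name in PARAM_NAMES:
            for a, b in zip(bank.networks[name].layers,
                            restored.networks[name].layers):
                np.testing.assert_array_equal(a.W, b.W)
                np.testing.assert_array_equal(a.b, b.b)
                np.testing.assert_array_equal(a.W_mask, b.W_mask)
                np.testing.assert_array_equal(a.b_mask, b.b_mask)

    def test_masking_equals_zeroing(self, rng):
        bank = init_bank(5)
        phi = rng.uniform(0, 1, size=(4, 5))
        net = bank.networks["k12"]
        # zero a weight by value
        zeroed = bank.copy()
        zeroed.networks["k12"].layers[1].W[2, 1] = 0.0
        # vs mask it out
        masked = bank.copy()
        masked.networks["k12"].layers[1].W_mask[2, 1] = 0
        masked.networks["k12"].layers[1].apply_masks()
        np.testing.assert_allclose(
            net_forward(zeroed.networks["k12"], phi)[0],
            net_forward(masked.networks["k12"], phi)[0],
            rtol=1e-14,
        )

    def test_custom_architecture_width(self):
        bank = init_bank(0, ArchitectureConfig(n_phi=4))
        assert bank.networks["k10"].layers[0].W.shape == (5, 4)


class TestBackprop:
    def test_gradient_matches_finite_differences(self, rng):
        bank = init_bank(6)
        net = bank.networks["k21"]
        phi = rng.uniform(0, 1, size=(8, 5))
        seed_vec = rng.normal(size=8)
        _, cache = net_forward(net, phi)
        grads, dphi = net_backward(net, cache, seed_vec)

        def value():
            return float(seed_vec @ net_forward(net, phi)[0])

        for li, l in enumerate(net.layers):
            for arr, g in ((l.W, grads[li][0]), (l.b, grads[li][1])):
                flat = arr.reshape(-1)
                gflat = np.asarray(g).reshape(-1)
                for k in range(flat.size):
                    h = 1e-6 * (1 + abs(flat[k]))
                    old = flat[k]
                    flat[k] = old + h
                    vp = value()
                    flat[k] = old - h
                    vm = value()
                    flat[k] = old
                    fd = (vp - vm) / (2 * h)
                    assert gflat[k] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_input_gradient_matches_finite_differences(self, rng):
        bank = init_bank(7)
        net = bank.networks["V1"]
        phi = rng.uniform(0, 1, size=(3, 5))
        seed_vec = np.ones(3)
        _, cache = net_forward(net, phi)
        _, dphi = net_backward(net, cache, seed_vec)
        for i in range(3):
            for k in range(5):
                h = 1e-6
                pp, pm = phi.copy(), phi.copy()
                pp[i, k] += h
                pm[i, k] -= h
                fd = (net_forward(net, pp)[0][i] - net_forward(net, pm)[0][i]) / (2 * h)
                assert dphi[i, k] == pytest.approx(fd, rel=1e-4, abs=1e-7)
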