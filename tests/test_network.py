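"""Architecture construction, parameter/shape audit, and the NumPy realization."""

import numpy as np
import pytest

from wearstate.network import (
    ModelSpec,
    audit_table,
    build_model,
    count_parameters,
    forward_shapes,
    kernel_shape,
)
from wearstate.nn import MultichannelCNN


class TestKernelRule:
    @pytest.mark.parametrize("x, k", [(4, 2), (3, 2), (15, 8), (2, 1), (5, 3), (16, 8)])
    def test_half_width_rounded_up(self, x, k):
        assert kernel_shape(x) == (k, 1)

    def test_too_narrow_channel_rejected(self):
        with pytest.raises(ValueError):
            kernel_shape(1)


class TestBuildAndAudit:
    def test_published_parameter_counts(self):
        counts = count_parameters(build_model())
        conv1 = {ch: counts["branches"][ch][1] for ch in counts["branches"]}
        conv2 = {ch: counts["branches"][ch][2] for ch in counts["branches"]}
        dense1 = {ch: counts["branches"][ch][5] for ch in counts["branches"]}
        dense2 = {ch: counts["branches"][ch][7] for ch in counts["branches"]}
        assert conv1 == {"ECG": 384, "EMG": 384, "RESP": 384, "BVP": 384, "ACCL": 1152}
        assert conv2 == {"ECG": 16448, "EMG": 16448, "RESP": 16448,
                         "BVP": 16448, "ACCL": 65600}
        assert dense1 == {"ECG": 8256, "EMG": 4160, "RESP": 4160,
                          "BVP": 4160, "ACCL": 4160}
        assert set(dense2.values()) == {2080}
        assert counts["trunk"] == [0, 5152, 165]

    def test_published_output_dimensions(self):
        shapes = forward_shapes(build_model())
        assert shapes["branches"]["ECG"][:3] == [(4, 1), (3, 128), (2, 64)]
        assert shapes["branches"]["EMG"][:3] == [(3, 1), (2, 128), (1, 64)]
        assert shapes["branches"]["ACCL"][:3] == [(15, 1), (8, 128), (1, 64)]
        assert shapes["branches"]["ECG"][3] == 128  # flatten
        assert shapes["branches"]["ACCL"][3] == 64
        assert shapes["trunk"] == [160, 32, 5]

    def test_single_channel_variant(self):
        spec = build_model({"X": 4})
        shapes = forward_shapes(spec)
        assert shapes["trunk"] == [32, 32, 5]

    def test_degenerate_channel_rejected(self):
        # the adaptive rule keeps both valid convolutions positive for any
        # x >= 2, so the only degenerate inputs are sub-2-feature channels
        with pytest.raises(ValueError):
            build_model({"X": 1})
        with pytest.raises(ValueError):
            build_model({})

    def test_audit_table_mirrors_counts(self):
        spec = build_model()
        table = audit_table(spec)
        assert int(table["n_parameters"].sum()) == count_parameters(spec)["total"]
        accl_conv1 = table[(table.channel == "ACCL") & (table.layer == 2)]
        assert accl_conv1["n_parameters"].item() == 1152
        assert accl_conv1["kernel"].item() == "(8, 1)"

    def test_json_round_trip(self, tmp_path):
        spec = build_model(dropout_rate=0.4)
        path = tmp_path / "spec.json"
        spec.to_json(path)
        back = ModelSpec.from_json(path)
        assert back == spec


class TestNumpyRealization:
    @pytest.fixture()
    def small_net(self):
        spec = build_model({"A": 4, "B": 3}, conv1_filters=8, conv2_filters=4,
                           dropout_rate=0.0)
        return MultichannelCNN(spec, seed=0)

    def _inputs(self, rng, n=6):
        return {"A": rng.standard_normal((n, 4)), "B": rng.standard_normal((n, 3))}

    def test_parameter_total_matches_audit(self):
        spec = build_model()
        net = MultichannelCNN(spec, seed=0)
        assert net.n_parameters == count_parameters(spec)["total"]

    def test_softmax_rows_sum_to_one(self, small_net):
        probs = small_net.predict_proba(self._inputs(np.random.default_rng(1), 32))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_channel_isolation(self, small_net):
        """Perturbing one channel's input leaves the other branch's
        pre-concatenation activations bit-identical."""
        rng = np.random.default_rng(2)
        xs = self._inputs(rng)
        base = small_net.branch_outputs(xs)
        xs_perturbed = {"A": xs["A"] + 10.0, "B": xs["B"]}
        pert = small_net.branch_outputs(xs_perturbed)
        np.testing.assert_array_equal(base["B"], pert["B"])
        assert not np.array_equal(base["A"], pert["A"])

    def test_gradients_match_finite_differences(self, small_net):
        """Analytic backprop agrees with central finite differences."""
        rng = np.random.default_rng(3)
        xs = self._inputs(rng)
        y = np.zeros((6, 5))
        y[np.arange(6), rng.integers(0, 5, 6)] = 1.0

        def loss():
            probs, _ = small_net.forward(xs, train=False)
            p = np.clip((y * probs).sum(axis=1), 1e-12, 1.0)
            return -np.mean(np.log(p))

        probs, cache = small_net.forward(xs, train=False)
        grads = small_net.backward(cache, y)
        eps = 1e-6
        for name in ("A/conv1/W", "A/conv2/b", "B/dense1/W", "trunk/out/W",
                     "trunk/dense/b"):
            P = small_net.params[name]
            flat_idx = rng.choice(P.size, size=min(5, P.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, P.shape)
                orig = P[idx]
                P[idx] = orig + eps
                up = loss()
                P[idx] = orig - eps
                down = loss()
                P[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[name][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)

    def test_save_load_round_trip(self, small_net, tmp_path):
        xs = self._inputs(np.random.default_rng(4))
        before = small_net.predict_proba(xs)
        small_net.save(tmp_path / "model.npz")
        back = MultichannelCNN.load(tmp_path / "model.npz")
        np.testing.assert_array_equal(back.predict_proba(xs), before)
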