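"""Architecture builders: shapes, parameter counts, loss values, checkpoints."""

import numpy as np
import pytest

from ecgsqa.model import (
    BaselineSpec,
    StageSpec,
    SubnetworkSpec,
    build_baseline,
    build_subnetwork,
    count_trainable_parameters,
    cross_entropy_loss,
    load_model,
    save_model,
)

#: Narrow variant used where full-width forward passes would be wasteful.
TINY_CNN1 = StageSpec(channels=(4, 8, 8), pool_sizes=((4, 2), (4, 2), (4, 4)),
                      tail_channels=4)
TINY_CNN2 = StageSpec(channels=(4, 8, 8), pool_sizes=((1, 4), (1, 4), (1, 4)),
                      tail_channels=4)


def closed_form_count(spec) -> int:
    """Independent parameter-count oracle: hand-summed layer arithmetic."""

    def trunk(stage, k):
        total, cin = 0, 1
        for depth, ch in zip(stage.block_counts, stage.channels):
            for _ in range(depth):
                total += k * cin * ch + ch  # conv kernel + bias
                total += 2 * ch  # batch-norm scale + shift
                cin = ch
        total += cin * stage.tail_channels + stage.tail_channels  # 1x1 conv
        return total

    def trunk_out(stage, hw):
        h, w = hw
        for ph, pw in stage.pool_sizes:
            h, w = h // ph, w // pw
        return h * w * stage.tail_channels

    if isinstance(spec, BaselineSpec):
        total = trunk(spec.cnn, 3)
        feats = trunk_out(spec.cnn, (1, 512))
        total += feats * spec.hidden_units + spec.hidden_units
        total += spec.hidden_units * spec.n_classes + spec.n_classes
        return total
    total = trunk(spec.cnn1, 9) + trunk(spec.cnn2, 3)
    feats = trunk_out(spec.cnn1, (257, 63)) + trunk_out(spec.cnn2, (1, 512))
    total += feats * spec.hidden_units + spec.hidden_units
    total += spec.hidden_units * spec.n_classes + spec.n_classes
    return total


class TestShapes:
    def test_default_subnetwork_feature_sizes(self):
        net = build_subnetwork(SubnetworkSpec(n_classes=3), seed=0)
        # 257 -> 64 -> 16 -> 4 and 63 -> 31 -> 15 -> 3 under floor pooling
        assert net.feature_sizes == (4 * 3 * 32, 1 * 8 * 32) == (384, 256)

    def test_forward_probabilities(self, rng):
        net = build_subnetwork(
            SubnetworkSpec(n_classes=3, cnn1=TINY_CNN1, cnn2=TINY_CNN2,
                           hidden_units=16), seed=0)
        spec_x = rng.standard_normal((4, 257, 63, 1)).astype(np.float32)
        sig_x = rng.standard_normal((4, 1, 512, 1)).astype(np.float32)
        p = net.forward(spec_x, sig_x)
        assert p.shape == (4, 3)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_baseline_forward(self, rng):
        net = build_baseline(BaselineSpec(cnn=TINY_CNN2, hidden_units=16), seed=0)
        p = net.forward(rng.standard_normal((3, 1, 512, 1)).astype(np.float32))
        assert p.shape == (3, 5)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_forward_is_deterministic(self, rng):
        net = build_subnetwork(
            SubnetworkSpec(n_classes=2, cnn1=TINY_CNN1, cnn2=TINY_CNN2,
                           hidden_units=16), seed=1)
        spec_x = rng.standard_normal((2, 257, 63, 1)).astype(np.float32)
        sig_x = rng.standard_normal((2, 1, 512, 1)).astype(np.float32)
        a = net.forward(spec_x, sig_x, training=False).copy()
        b = net.forward(spec_x, sig_x, training=False).copy()
        np.testing.assert_array_equal(a, b)

    def test_seeded_initialization_reproducible(self):
        a = build_baseline(seed=7)
        b = build_baseline(seed=7)
        for la, lb in zip(a.layers(), b.layers()):
            for k in la.params:
                np.testing.assert_array_equal(la.params[k], lb.params[k])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SubnetworkSpec(n_classes=5)
        with pytest.raises(ValueError):
            StageSpec(block_counts=(0, 2, 5))


class TestParameterCounts:
    def test_baseline_is_0_28_million(self):
        n = count_trainable_parameters(build_baseline(seed=0))
        assert round(n / 1e6, 2) == 0.28

    def test_cascade_is_3_2_million(self):
        total = count_trainable_parameters(
            build_subnetwork(SubnetworkSpec(n_classes=3), seed=0))
        total += 2 * count_trainable_parameters(
            build_subnetwork(SubnetworkSpec(n_classes=2), seed=0))
        assert round(total / 1e6, 1) == 3.2

    @pytest.mark.parametrize("spec", [
        BaselineSpec(),
        BaselineSpec(cnn=TINY_CNN2, hidden_units=16),
        SubnetworkSpec(n_classes=3),
        SubnetworkSpec(n_classes=2),
        SubnetworkSpec(n_classes=2, cnn1=TINY_CNN1, cnn2=TINY_CNN2, hidden_units=16),
        SubnetworkSpec(n_classes=3,
                       cnn1=StageSpec(block_counts=(2, 3, 1),
                                      pool_sizes=((4, 2), (4, 2), (4, 4))),
                       cnn2=StageSpec(block_counts=(2, 3, 1))),
    ])
    def test_count_matches_closed_form(self, spec):
        build = build_baseline if isinstance(spec, BaselineSpec) else build_subnetwork
        assert count_trainable_parameters(build(spec, 0)) == closed_form_count(spec)

    def test_lone_dense_layer(self, rng):
        from ecgsqa.nn import Dense

        assert Dense(10, 5, rng).n_parameters() == 55


class TestCrossEntropyLoss:
    def test_perfect_prediction_is_zero(self):
        assert cross_entropy_loss((1.0, 0.0, 0.0), (1.0, 0.0, 0.0)) <= 1e-9

    def test_uniform_three_class_value(self):
        # -[log(1/3) + 2 log(2/3)] evaluated directly
        expected = -(np.log(1 / 3) + 2 * np.log(2 / 3))
        got = cross_entropy_loss((1 / 3, 1 / 3, 1 / 3), (1.0, 0.0, 0.0))
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(1.9095, abs=1e-4)

    def test_permutation_symmetry(self, rng):
        p = rng.dirichlet(np.ones(4))
        y = np.eye(4)[2]
        perm = rng.permutation(4)
        assert cross_entropy_loss(p, y) == pytest.approx(
            cross_entropy_loss(p[perm], y[perm]), rel=1e-12)

    def test_categorical_form_available(self):
        got = cross_entropy_loss((1 / 3, 1 / 3, 1 / 3), (1.0, 0.0, 0.0),
                                 form="categorical")
        assert got == pytest.approx(np.log(3.0), abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss((0.5, 0.5), (1.0, 0.0, 0.0))


class TestCheckpointRoundTrip:
    def test_save_load_preserves_outputs(self, tmp_path, rng):
        spec = SubnetworkSpec(n_classes=2, cnn1=TINY_CNN1, cnn2=TINY_CNN2,
                              hidden_units=8)
        net = build_subnetwork(spec, seed=3)
        spec_x = rng.standard_normal((2, 257, 63, 1)).astype(np.float32)
        sig_x = rng.standard_normal((2, 1, 512, 1)).astype(np.float32)
        before = net.forward(spec_x, sig_x).copy()
        save_model(net, tmp_path / "net.h5")
        loaded = load_model(tmp_path / "net.h5")
        after = loaded.forward(spec_x, sig_x)
        np.testing.assert_allclose(after, before, atol=1e-7)

    def test_tampered_sidecar_rejected(self, tmp_path):
        net = build_baseline(BaselineSpec(cnn=TINY_CNN2, hidden_units=8), seed=0)
        save_model(net, tmp_path / "net.h5")
        sidecar = tmp_path / "net.h5.json"
        sidecar.write_text(sidecar.read_text().replace('"hash"', '"hash_x"', 1)
                           if '"hash"' in sidecar.read_text() else "{}")
        with pytest.raises((ValueError, KeyError)):
            load_model(tmp_path / "net.h5")
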