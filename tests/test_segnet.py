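"""Tests of the FRRN building blocks, assembly and training loop."""

import numpy as np
import pytest

from segpick import ClassMask, ThreeChannelImage
from segpick.nnops import weighted_cross_entropy
from segpick.segnet import (
    FRRN,
    FRRNConfig,
    FRRU,
    ResidualUnit,
    TrainConfig,
    build_frrn,
    load_model,
    predict,
    save_model,
    train,
)

MINI = FRRNConfig(n_classes=4, n_pooling_stages=2, n_unpooling_stages=2, base_channels=4)


def _zero(unit_layers):
    for layer in unit_layers:
        for p in layer.params():
            p.value[...] = 0.0


class TestResidualUnit:
    def test_zero_residual_is_identity(self, rng):
        ru = ResidualUnit(4, rng)
        _zero([ru.conv2, ru.bn2])
        ru.bn2.gamma.value[...] = 0.0
        x = rng.normal(size=(1, 4, 8, 8))
        assert np.allclose(ru.forward(x, training=True), x, atol=1e-12)

    def test_shape_preserved(self, rng):
        ru = ResidualUnit(6, rng)
        x = rng.normal(size=(2, 6, 16, 12))
        assert ru.forward(x, training=True).shape == x.shape

    def test_jacobian_has_identity_component(self, rng):
        # numeric differentiation on a 1x4x4 map: the unit's Jacobian
        # diagonal must equal 1 + the diagonal of the residual branch F,
        # with F evaluated independently through the raw layer stack
        ru = ResidualUnit(1, rng)

        def residual_branch(v):
            h = ru.relu.forward(ru.bn1.forward(ru.conv1.forward(v), False))
            return ru.bn2.forward(ru.conv2.forward(h), False)

        x = rng.normal(size=(1, 1, 4, 4))
        eps = 1e-6
        x2 = x.copy()
        x2[0, 0, 2, 2] += eps
        diag_unit = (ru.forward(x2, False) - ru.forward(x, False))[0, 0, 2, 2] / eps
        diag_f = (residual_branch(x2) - residual_branch(x))[0, 0, 2, 2] / eps
        assert diag_unit == pytest.approx(1.0 + diag_f, abs=1e-4)


class TestFRRU:
    def test_zero_pooling_reduces_to_ru(self, rng):
        # the limit statement: with H == 0 (and the projection zeroed) the
        # FRRU acts on the residual stream exactly like an RU with zero
        # residual, i.e. the identity
        frru = FRRU(4, 6, 8, scale=2, rng=rng)
        _zero([frru.conv1, frru.bn1, frru.conv2, frru.bn2, frru.proj])
        y = rng.normal(size=(1, 4, 16, 16))
        z = rng.normal(size=(1, 6, 8, 8))
        y2, z2 = frru.forward(y, z, training=True)
        ru = ResidualUnit(4, rng)
        _zero([ru.conv1, ru.bn1, ru.conv2, ru.bn2])
        assert np.allclose(y2, ru.forward(y, training=True), atol=1e-6)
        assert np.allclose(z2, 0.0, atol=1e-6)

    def test_zero_projection_leaves_y_unchanged(self, rng):
        frru = FRRU(4, 6, 8, scale=2, rng=rng)
        _zero([frru.proj])
        y = rng.normal(size=(1, 4, 16, 16))
        z = rng.normal(size=(1, 6, 8, 8))
        y2, _ = frru.forward(y, z, training=True)
        assert np.array_equal(y2, y)

    def test_stream_shapes(self, rng):
        frru = FRRU(3, 5, 7, scale=2, rng=rng)
        y = rng.normal(size=(1, 3, 64, 64))
        z = rng.normal(size=(1, 5, 32, 32))
        y2, z2 = frru.forward(y, z, training=True)
        assert y2.shape == (1, 3, 64, 64)
        assert z2.shape == (1, 7, 32, 32)

    def test_incompatible_scales_rejected(self, rng):
        frru = FRRU(3, 5, 7, scale=2, rng=rng)
        with pytest.raises(ValueError):
            frru.forward(rng.normal(size=(1, 3, 64, 64)),
                         rng.normal(size=(1, 5, 16, 16)), training=True)


class TestBuildFrrn:
    def test_output_shape_and_normalization(self):
        model = build_frrn(FRRNConfig(n_pooling_stages=5, n_unpooling_stages=4,
                                      base_channels=8), seed=0)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 3, 128, 128))
        prob = model.predict_proba(x)
        assert prob.shape == (1, 4, 128, 128)
        assert np.allclose(prob.sum(axis=1), 1.0, atol=1e-5)
        assert prob.min() >= 0.0

    def test_indivisible_input_rejected(self):
        model = build_frrn(MINI, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 3, 48, 50)), training=False)

    def test_mini_model_parameter_count(self):
        model = build_frrn(MINI, seed=0)
        assert model.n_parameters < 100_000

    def test_gradients_match_finite_differences(self, rng):
        model = FRRN(MINI, seed=0)
        x = rng.normal(size=(1, 3, 8, 8))
        t = rng.integers(0, 4, (1, 8, 8))
        w = np.ones(4)

        def loss():
            return weighted_cross_entropy(model.forward(x, training=True), t, w)

        _, dlog = loss()
        for p in model.params():
            p.zero_grad()
        model.backward(dlog)
        checked = 0
        for p in model.params()[::7]:
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            eps = 1e-6
            old = p.value[idx]
            p.value[idx] = old + eps
            l1, _ = loss()
            p.value[idx] = old - eps
            l2, _ = loss()
            p.value[idx] = old
            num = (l1 - l2) / (2 * eps)
            ana = p.grad[idx]
            assert abs(num - ana) <= 1e-4 * max(abs(num), abs(ana), 1.0)
            checked += 1
        assert checked >= 5


def _one_pair(seed=11):
    import segpick as sp

    mg, mask, _ = sp.make_micrograph(
        sp.SceneSpec(image_size=(64, 64), n_particles=5, particle_radius_px=6, seed=seed)
    )
    return sp.compose_three_channel(mg), mask


class TestTrain:
    def test_checkpoint_selection_argmax_earliest_tie(self):
        pairs = [_one_pair(1), _one_pair(2)]
        scores = iter([0.2, 0.9, 0.5, 0.9])
        snapshots = []

        def stub(model, val_pairs):
            snapshots.append(model.state_dict())
            return next(scores), {1: 0.0}

        model = build_frrn(MINI, seed=0)
        model, records = train(
            model, pairs, TrainConfig(epochs=4, seed=0, crop_size=64),
            val_metric_fn=stub,
        )
        assert [r.mean_f1 for r in records] == [0.2, 0.9, 0.5, 0.9]
        best = snapshots[1]  # first epoch attaining the max
        for k, v in model.state_dict().items():
            assert np.array_equal(v, best[k])

    def test_same_seed_same_split_and_first_loss(self):
        pairs = [_one_pair(s) for s in range(4)]
        losses = []
        for _ in range(2):
            model = build_frrn(MINI, seed=3)
            _, records = train(model, pairs, TrainConfig(epochs=1, seed=7, crop_size=64))
            losses.append(records[0].train_loss)
        assert losses[0] == losses[1]

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            train(build_frrn(MINI, seed=0), [], TrainConfig(epochs=1, seed=0))

    def test_single_class_masks_warn(self):
        img, _ = _one_pair(1)
        flat = ClassMask(np.zeros(img.shape, dtype=np.uint8))
        with pytest.warns(UserWarning):
            train(build_frrn(MINI, seed=0), [(img, flat)],
                  TrainConfig(epochs=1, seed=0, crop_size=64))


class TestPredict:
    def test_padding_restores_dims(self):
        model = build_frrn(MINI, seed=0)
        img = ThreeChannelImage(np.zeros((50, 46, 3), dtype=np.uint8))
        prob = predict(model, img)
        assert prob.shape == (50, 46, 4)
        assert np.allclose(prob.sum(axis=2), 1.0, atol=1e-5)

    def test_tiled_inference_matches_single_pass_closely(self):
        model = build_frrn(MINI, seed=1)
        rng = np.random.default_rng(0)
        img = ThreeChannelImage(rng.integers(0, 255, (64, 64, 3)).astype(np.uint8))
        whole = predict(model, img)
        tiled = predict(model, img, tile=48, overlap=16)
        # probabilities agree away from tile seams
        assert np.abs(whole - tiled).mean() < 0.2


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        model = build_frrn(MINI, seed=5)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 3, 16, 16))
        before = model.predict_proba(x)
        save_model(model, tmp_path / "m.ckpt.npz")
        back = load_model(tmp_path / "m.ckpt.npz")
        assert np.allclose(back.predict_proba(x), before, atol=1e-12)
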