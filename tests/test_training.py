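"""Loss functions, optimization step coverage, determinism, ablation modes."""

import numpy as np
import pytest

from aepseg.datatypes import SyntheticSpec
from aepseg.networks import NetworkConfig
from aepseg.synthetic import generate_dataset, split_kfold
from aepseg.training import (
    JointModel,
    LossBreakdown,
    TrainConfig,
    ce_loss,
    predict,
    total_loss,
    train,
)
from aepseg.nn.optim import Adam


def tiny_train_cfg(**kw):
    net = kw.pop("network", None) or NetworkConfig(
        num_classes=3, base_channels=4, dropout_rate=0.2
    )
    defaults = dict(network=net, batch_size=4, epochs=2, seed=0)
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestCeLoss:
    def test_uniform_logits_give_log_c(self, rng):
        logits = np.zeros((3, 8, 8))
        target = rng.integers(0, 3, (8, 8))
        assert ce_loss(logits, target) == pytest.approx(np.log(3), rel=1e-9)

    def test_perfect_prediction_limit(self):
        logits = np.zeros((2, 4, 4))
        logits[0] = 100.0
        target = np.zeros((4, 4), dtype=np.int64)
        assert ce_loss(logits, target) < 1e-9

    def test_two_class_scalar_closed_form(self):
        logits = np.array([[[2.0]], [[0.0]]])
        target = np.zeros((1, 1), dtype=np.int64)
        assert ce_loss(logits, target) == pytest.approx(np.log(1 + np.exp(-2)), rel=1e-9)

    def test_label_overflow_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 2\)"):
            ce_loss(np.zeros((2, 4, 4)), np.full((4, 4), 2))


class TestTotalLoss:
    def test_term_count_for_three_classes(self, rng):
        c, maps = 3, {}
        target = rng.integers(0, c, (8, 8))
        first = rng.normal(0, 1, (c, 8, 8))
        fused = rng.normal(0, 1, (c, 8, 8))
        translated = [rng.normal(0, 1, (c, 8, 8)) for _ in range(3)]
        bd = total_loss(first, fused, translated, target)
        assert len(bd.ce_n3) == 3  # 1 + 1 + 3 = 5 CE terms in total
        assert bd.total == pytest.approx(bd.ce_n1 + bd.ce_n2 + sum(bd.ce_n3))

    def test_perfect_heads_drive_total_to_zero(self):
        target = np.zeros((4, 4), dtype=np.int64)
        perfect = np.zeros((2, 4, 4))
        perfect[0] = 50.0
        bd = total_loss(perfect, perfect, [perfect, perfect], target)
        assert bd.total < 1e-9

    def test_matches_independent_term_sums(self, rng):
        target = rng.integers(0, 3, (8, 8))
        first = rng.normal(0, 1, (3, 8, 8))
        fused = rng.normal(0, 1, (3, 8, 8))
        translated = [rng.normal(0, 1, (3, 8, 8)) for _ in range(3)]
        bd = total_loss(first, fused, translated, target)
        expected = (
            ce_loss(first, target)
            + ce_loss(fused, target)
            + sum(ce_loss(t, target) for t in translated)
        )
        assert bd.total == pytest.approx(expected, rel=1e-6)

    def test_missing_fused_head_rejected_unless_awel_off(self, rng):
        target = rng.integers(0, 2, (4, 4))
        first = rng.normal(0, 1, (2, 4, 4))
        with pytest.raises(ValueError, match="fused"):
            total_loss(first, None, [first], target, awel_mode="automated")
        bd = total_loss(first, None, [first], target, awel_mode="off")
        assert bd.ce_n2 == 0.0

    def test_breakdown_invariant_enforced(self):
        with pytest.raises(ValueError, match="total"):
            LossBreakdown(ce_n1=1.0, ce_n2=1.0, ce_n3=[1.0], total=5.0)


class TestGradientCoverage:
    def test_one_adam_step_updates_every_component(self, rng):
        """After one optimization step on a nonzero-loss batch, parameters
        change in the first-network trunk, both output convolutions, the
        second network, and the AWEL weights (automated mode)."""
        cfg = tiny_train_cfg()
        model = JointModel(cfg, 1, 2)
        x = rng.random((2, 1, 16, 16)).astype(np.float32)
        y = rng.integers(0, 3, (2, 16, 16))
        groups = {
            "first_trunk": list(model.first.trunk.parameters()),
            "first_out_filters": list(model.first.out_conv_filters.parameters()),
            "first_out_logits": list(model.first.out_conv_logits.parameters()),
            "second": list(model.second.parameters()),
            "awel": [model.awel.w],
        }
        before = {k: [p.data.copy() for p in ps] for k, ps in groups.items()}
        opt = Adam(model.parameters(), lr=cfg.learning_rate, betas=cfg.adam_betas)
        opt.zero_grad()
        bd = model.forward_backward(x, y)
        assert bd.total > 0
        opt.step()
        for name, ps in groups.items():
            delta = sum(
                float(np.abs(p.data - b).sum()) for p, b in zip(ps, before[name])
            )
            assert delta > 0, f"no parameter movement in {name}"


@pytest.fixture(scope="module")
def trained_tiny(small_dataset_3c_module=None):
    spec = SyntheticSpec(num_classes=3, image_size=(32, 32), cell_count_range=(2, 3), seed=21)
    ds = generate_dataset(spec, n=8)
    folds = split_kfold(8, 4, seed=5)
    cfg = tiny_train_cfg(epochs=2)
    bundles, histories = train(ds, folds, cfg, folds_to_run=[0])
    return ds, folds, cfg, bundles, histories


class TestTrain:
    def test_seed_determinism(self, trained_tiny):
        ds, folds, cfg, bundles, histories = trained_tiny
        bundles2, histories2 = train(ds, folds, cfg, folds_to_run=[0])
        assert histories == histories2
        for p, q in zip(bundles[0].first.parameters(), bundles2[0].first.parameters()):
            assert np.array_equal(p.data, q.data)
        r1 = predict(bundles[0], ds[0][0])
        r2 = predict(bundles2[0], ds[0][0])
        assert np.array_equal(r1.mask.labels, r2.mask.labels)

    def test_fixed_weights_stay_at_one(self, trained_tiny):
        ds, folds, cfg, _, _ = trained_tiny
        from dataclasses import replace

        cfg_fixed = replace(cfg, awel_mode="fixed", epochs=1)
        bundles, _ = train(ds, folds, cfg_fixed, folds_to_run=[0])
        np.testing.assert_array_equal(bundles[0].awel.w.data, 1.0)

    def test_history_schema_and_breakdown(self, trained_tiny):
        _, _, _, _, histories = trained_tiny
        row = histories[0][0]
        assert set(row) == {"epoch", "ce_n1", "ce_n2", "ce_n3_mean", "total", "val_miou"}
        assert row["total"] >= 0

    def test_class_mismatch_rejected_before_training(self, small_dataset_2c):
        folds = split_kfold(8, 4, seed=0)
        cfg = tiny_train_cfg()  # 3-class network vs 2-class data
        with pytest.raises(ValueError, match="classes"):
            train(small_dataset_2c, folds, cfg, folds_to_run=[0])


class TestPredict:
    def test_intermediate_artifact_counts(self, trained_tiny):
        ds, _, _, bundles, _ = trained_tiny
        result = predict(bundles[0], ds[0][0])
        assert result.filters.num_filters == 3
        assert result.translated.images.shape[0] == 3
        assert result.stack.shape[0] == 4
        assert result.mask.labels.shape == ds[0][0].shape

    def test_awel_off_predicts_from_second_network_only(self, trained_tiny):
        ds, folds, cfg, _, _ = trained_tiny
        from dataclasses import replace

        cfg_off = replace(cfg, awel_mode="off", epochs=1)
        bundles, _ = train(ds, folds, cfg_off, folds_to_run=[0])
        result = predict(bundles[0], ds[0][0])
        expected = np.argmax(result.logits_translated.mean(axis=0), axis=0)
        assert np.array_equal(result.mask.labels, expected)

    def test_constant_head_pipeline_walkthrough(self):
        """Hand-built bundle with constant outputs: the final mask follows a
        step-by-step manual composition of the pipeline."""
        cfg = tiny_train_cfg(epochs=1)
        model = JointModel(cfg, 1, 2)
        # force the first network's output convs to constants: filters head
        # emits -1 (filters -> 0.5), logits head emits class-0 dominance
        fc = model.first.out_conv_filters
        fc.weight.data[...] = 0.0
        fc.bias.data[...] = -1.0
        lc = model.first.out_conv_logits
        lc.weight.data[...] = 0.0
        lc.bias.data[...] = np.array([3.0, 0.0, 0.0], dtype=lc.bias.data.dtype)
        sc = model.second.out_conv
        sc.weight.data[...] = 0.0
        sc.bias.data[...] = np.array([0.0, 2.0, 0.0], dtype=sc.bias.data.dtype)
        model.awel.w.data[...] = np.array([1.0, 1.0, 1.0, 1.0], dtype=np.float32)
        x = np.full((1, 1, 16, 16), 0.25, dtype=np.float32)
        out = model.infer(x)
        # manual walk: filters = sigmoid(relu(-1)) = 0.5; translated = 0.75;
        # stack = first(3,0,0) + 3 x second(0,2,0); fused = (3,6,0) -> class 1
        np.testing.assert_allclose(out["filters"], 0.5)
        np.testing.assert_allclose(out["translated"], 0.75)
        np.testing.assert_allclose(out["fused"][0, 0], 3.0, atol=1e-5)
        np.testing.assert_allclose(out["fused"][0, 1], 6.0, atol=1e-5)
        assert (out["mask"] == 1).all()
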