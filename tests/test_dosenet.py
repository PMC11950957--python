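"""Dose-model architecture, training mechanics and ensembling."""

import numpy as np
import pytest

from phandose.dosenet import (
    NetConfig,
    TrainConfig,
    cross_validate,
    ensemble_predict,
    make_folds,
    train_fold,
)
from phandose.nn import build_unet, mse_loss


def _expected_param_count(b: int, d: int) -> int:
    """Layer-by-layer arithmetic walk over the architecture."""
    ch = [b * 2**l for l in range(d + 1)]
    total = 9 * 7 * b + b  # stem conv
    for c in ch[:-1]:
        total += 18 * c * c + 2 * c + 4 * c  # encoder residual block (+2 BNs)
        total += 8 * c * c + 2 * c  # 2x2 stride-2 down conv c -> 2c
        total += 18 * c * c + c  # upconv 2c -> c after upsampling
        total += 18 * c * c + c  # fuse conv 2c -> c after skip concat
        total += 18 * c * c + 2 * c + 4 * c  # decoder residual block
    C = ch[-1]
    total += 18 * C * C + 2 * C + 4 * C  # bottleneck residual block
    total += b + 1  # 1x1 head
    return total


class TestArchitecture:
    def test_input_output_geometry(self):
        model = build_unet(NetConfig(base_features=4, depth=2), seed=0)
        x = np.random.default_rng(0).random((2, 7, 128, 128)).astype(np.float32)
        y = model.predict(x)
        assert y.shape == (2, 1, 128, 128)

    def test_indivisible_spatial_size_rejected(self):
        model = build_unet(NetConfig(base_features=4, depth=2), seed=0)
        x = np.zeros((1, 7, 30, 30), dtype=np.float32)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(x)

    def test_wrong_channel_count_rejected(self):
        model = build_unet(NetConfig(base_features=4, depth=2), seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 3, 16, 16), dtype=np.float32))

    def test_inference_is_deterministic(self, rng):
        model = build_unet(NetConfig(base_features=4, depth=2, dropout=0.1), seed=7)
        x = rng.random((3, 7, 32, 32)).astype(np.float32)
        assert np.array_equal(model.predict(x), model.predict(x))

    @pytest.mark.parametrize("base,depth", [(4, 1), (4, 2), (8, 2), (6, 3)])
    def test_parameter_count_arithmetic(self, base, depth):
        model = build_unet(NetConfig(base_features=base, depth=depth), seed=0)
        assert model.num_params() == _expected_param_count(base, depth)

    def test_same_seed_same_weights(self, rng):
        a = build_unet(NetConfig(base_features=4, depth=2), seed=11)
        b = build_unet(NetConfig(base_features=4, depth=2), seed=11)
        x = rng.random((2, 7, 16, 16)).astype(np.float32)
        assert np.array_equal(a.predict(x), b.predict(x))


class TestFolds:
    def test_partition_is_disjoint_exhaustive_balanced(self):
        ids = [f"s{i}" for i in range(60)]
        folds = make_folds(ids, 5, seed=3)
        assert all(len(f) == 12 for f in folds)
        flat = [i for f in folds for i in f]
        assert sorted(flat) == sorted(ids)

    def test_leave_one_out_degenerate(self):
        folds = make_folds([f"s{i}" for i in range(5)], 5, seed=0)
        assert sorted(len(f) for f in folds) == [1, 1, 1, 1, 1]

    def test_cohort_smaller_than_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], 5, seed=0)

    def test_seeded_reproducibility(self):
        ids = [f"s{i}" for i in range(20)]
        assert make_folds(ids, 5, 9) == make_folds(ids, 5, 9)
        assert make_folds(ids, 5, 9) != make_folds(ids, 5, 10)


def _tiny_dataset(rng, n_samples=5, n_slices=2, size=16):
    stacks, targets = {}, {}
    for i in range(n_samples):
        sid = f"s{i}"
        stacks[sid] = rng.random((n_slices, 7, size, size)).astype(np.float32)
        targets[sid] = rng.random((n_slices, size, size)).astype(np.float32) * 0.5
    return stacks, targets


class TestTraining:
    def test_loss_decreases_and_history_recorded(self, rng):
        stacks, targets = _tiny_dataset(rng)
        net = NetConfig(base_features=4, depth=2)
        tcfg = TrainConfig(epochs=5, batch_size=4, seed=0)
        _, hist = train_fold(stacks, targets, ["s0", "s1", "s2", "s3"], ["s4"], net, tcfg)
        assert len(hist["train_mse"]) == len(hist["val_mse"]) == 5
        assert hist["train_mse"][-1] < hist["train_mse"][0]

    def test_overfit_five_identical_slices(self, rng):
        # memorisation oracle: with adequate capacity, a repeated mask-like
        # slice with a smooth dose-like target is driven to near-zero MSE
        from scipy.ndimage import gaussian_filter

        ch = (rng.random((7, 16, 16)) < 0.3).astype(np.float32)
        x = np.repeat(ch[None], 5, axis=0)
        t = gaussian_filter(rng.random((16, 16)), sigma=2.0)
        t = ((t - t.min()) / (t.max() - t.min()) * 0.8).astype(np.float32)
        y = np.repeat(t[None], 5, axis=0)
        net = NetConfig(base_features=16, depth=2, dropout=0.0)
        tcfg = TrainConfig(epochs=200, batch_size=1, seed=1)
        _, hist = train_fold({"s": x}, {"s": y}, ["s"], [], net, tcfg)
        assert min(hist["train_mse"]) < 1e-4

    def test_seeded_history_reproducible(self, rng):
        stacks, targets = _tiny_dataset(rng, n_samples=3)
        net = NetConfig(base_features=4, depth=1)
        tcfg = TrainConfig(epochs=3, batch_size=4, seed=5)
        _, h1 = train_fold(stacks, targets, ["s0", "s1"], ["s2"], net, tcfg)
        _, h2 = train_fold(stacks, targets, ["s0", "s1"], ["s2"], net, tcfg)
        assert h1["train_mse"] == h2["train_mse"]
        assert h1["val_mse"] == h2["val_mse"]

    def test_empty_fold_rejected(self, rng):
        stacks, targets = _tiny_dataset(rng, n_samples=2)
        with pytest.raises(ValueError, match="empty"):
            train_fold(stacks, targets, [], ["s0"], NetConfig(base_features=4, depth=1),
                       TrainConfig(epochs=1))


class TestCrossValidate:
    def test_leave_one_out_runs_and_partitions(self, rng):
        stacks, targets = _tiny_dataset(rng, n_samples=5)
        net = NetConfig(base_features=4, depth=1)
        tcfg = TrainConfig(epochs=1, batch_size=4, folds=5, seed=2)
        models, summary = cross_validate(stacks, targets, net, tcfg)
        assert len(models) == 5
        val_ids = [i for m in summary["folds"] for i in m["val_ids"]]
        assert sorted(val_ids) == sorted(stacks)
        assert np.isfinite(summary["val_mse_mean"])

    def test_cohort_smaller_than_folds(self, rng):
        stacks, targets = _tiny_dataset(rng, n_samples=3)
        with pytest.raises(ValueError):
            cross_validate(stacks, targets, NetConfig(base_features=4, depth=1),
                           TrainConfig(epochs=1, folds=5))


class TestEnsemble:
    def test_single_model_identity(self, rng):
        model = build_unet(NetConfig(base_features=4, depth=1), seed=0)
        stack = rng.random((3, 7, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(ensemble_predict([model], stack),
                                      model.predict(stack)[:, 0])

    def test_constant_members_average(self, rng):
        consts = [0.2, 0.5, 0.8]
        models = []
        for c in consts:
            m = build_unet(NetConfig(base_features=4, depth=1), seed=0)
            for p in m.params():
                p.value[...] = 0.0
            m.head.b.value[...] = c  # zeroed conv weights leave only the head bias
            models.append(m)
        stack = rng.random((2, 7, 16, 16)).astype(np.float32)
        pred = ensemble_predict(models, stack)
        assert np.allclose(pred, np.mean(consts), atol=1e-6)

    def test_mismatched_architectures_rejected(self, rng):
        a = build_unet(NetConfig(base_features=4, depth=1), seed=0)
        b = build_unet(NetConfig(base_features=8, depth=1), seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            ensemble_predict([a, b], rng.random((1, 7, 16, 16)).astype(np.float32))

    def test_ensemble_mse_not_worse_than_worst_member(self, rng):
        # convexity of squared error in the prediction
        x = rng.random((4, 7, 16, 16)).astype(np.float32)
        y = rng.random((4, 1, 16, 16)).astype(np.float32)
        models = [build_unet(NetConfig(base_features=4, depth=1), seed=s) for s in (1, 2, 3)]
        member_mse = [mse_loss(m.predict(x), y)[0] for m in models]
        ens = ensemble_predict(models, x)[:, None]
        ens_mse = mse_loss(ens, y)[0]
        assert ens_mse <= max(member_mse) + 1e-9
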