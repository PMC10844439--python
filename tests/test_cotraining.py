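"""Co-training engine: disagreement masks, sharpening, generator selection,
the hand-worked single step, gradient isolation, schedule, and the loop."""

import numpy as np
import pytest

from sdnet.autodiff import SGD, Tensor
from sdnet.backbones import binarize, build_backbone
from sdnet.cotraining import (
    TrainConfig,
    difference_mask,
    learning_rate,
    select_generator,
    sharpen,
    train,
    train_step,
)
from sdnet.errors import ConfigurationError, ShapeError, TrainingError
from sdnet.phantoms import PhantomSpec, generate_split
from sdnet.volume_io import GroundTruthMask, Volume

from .conftest import random_binary_mask, random_probability_map
from . import oracles


class TestDifferenceMask:
    def test_identical_predictions_give_empty_mask(self, prob_map_factory):
        p = prob_map_factory()
        assert difference_mask(p, p).is_empty

    def test_total_disagreement_gives_full_mask(self):
        ones = np.stack([np.zeros((3, 3, 3)), np.ones((3, 3, 3))])
        zeros = np.stack([np.ones((3, 3, 3)), np.zeros((3, 3, 3))])
        assert difference_mask(ones, zeros).data.all()

    def test_matches_xor_loop(self, rng):
        p1 = random_probability_map(rng, (4, 4, 4))
        p2 = random_probability_map(rng, (4, 4, 4))
        got = difference_mask(p1, p2).data
        expected = np.array(oracles.xor_loop(binarize(p1), binarize(p2)))
        np.testing.assert_array_equal(got, expected)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ShapeError):
            difference_mask(
                random_probability_map(rng, (4, 4, 4)), random_probability_map(rng, (2, 2, 2))
            )


class TestSharpen:
    def test_half_is_fixed_point(self):
        for T in (0.1, 0.5, 1.0, 3.0):
            assert sharpen(np.array([0.5]), T)[0] == pytest.approx(0.5)

    def test_known_value(self):
        # p=0.6, T=0.5: 0.36/(0.36+0.16)
        assert sharpen(np.array([0.6]), 0.5)[0] == pytest.approx(0.36 / 0.52, rel=1e-12)

    def test_temperature_one_is_identity(self, rng):
        p = rng.uniform(size=(4, 4, 4))
        np.testing.assert_array_equal(sharpen(p, 1.0), p)

    def test_small_temperature_approaches_hard_threshold(self, rng):
        p = rng.uniform(size=(100,))
        s = sharpen(p, 0.01)
        np.testing.assert_allclose(s[p > 0.55], 1.0, atol=1e-6)
        np.testing.assert_allclose(s[p < 0.45], 0.0, atol=1e-6)

    def test_endpoints_exact(self):
        np.testing.assert_array_equal(sharpen(np.array([0.0, 1.0]), 0.5), [0.0, 1.0])

    def test_matches_scalar_oracle(self, rng):
        p = rng.uniform(size=(20,))
        for T in (0.25, 0.5, 2.0):
            expected = [oracles.sharpen_scalar(float(v), T) for v in p]
            np.testing.assert_allclose(sharpen(p, T), expected, rtol=1e-10)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ConfigurationError):
            sharpen(np.array([0.5]), 0.0)

    def test_output_stays_in_unit_interval(self, rng):
        s = sharpen(rng.uniform(size=(500,)), 0.3)
        assert s.min() >= 0.0 and s.max() <= 1.0


class TestSelectGenerator:
    @pytest.mark.parametrize(
        "lv,lr,expected", [(0.20, 0.30, "vnet"), (0.30, 0.20, "resvnet"), (0.25, 0.25, "vnet")]
    )
    def test_smaller_dice_loss_generates(self, lv, lr, expected):
        assert select_generator(lv, lr) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(FloatingPointError):
            select_generator(float("nan"), 0.2)


class TestLearningRate:
    def test_schedule_values(self):
        cfg = TrainConfig()
        assert learning_rate(0, cfg) == pytest.approx(0.01)
        assert learning_rate(199, cfg) == pytest.approx(0.01)
        assert learning_rate(200, cfg) == pytest.approx(0.001)
        assert learning_rate(1199, cfg) == pytest.approx(0.01 * 10**-5)

    def test_piecewise_constant_nonincreasing_with_expected_drops(self):
        cfg = TrainConfig()
        lrs = [learning_rate(i, cfg) for i in range(cfg.total_iterations)]
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))
        drops = sum(1 for a, b in zip(lrs, lrs[1:]) if b < a)
        assert drops == cfg.total_iterations // cfg.lr_decay_every - 1
        assert all(lr > 0 for lr in lrs)


class FrozenModel:
    """A model with preset probability outputs, keyed by input fingerprint."""

    def __init__(self, outputs):
        self.outputs = outputs  # {fingerprint: fg array}

    def forward_probs(self, data):
        fg = self.outputs[round(float(np.asarray(data).flat[0]), 3)]
        return Tensor(np.stack([1.0 - fg, fg]))

    def parameters(self):
        return []


# hand-set toy probabilities on a 2x2x2 grid
TOY_TRUTH = np.zeros((2, 2, 2), np.uint8)
TOY_TRUTH[0, 0, 0] = TOY_TRUTH[0, 1, 1] = TOY_TRUTH[1, 0, 1] = 1
TOY_A = np.array([[[0.9, 0.2], [0.3, 0.8]], [[0.4, 0.7], [0.2, 0.6]]])  # vnet, labeled
TOY_B = np.array([[[0.8, 0.1], [0.6, 0.7]], [[0.1, 0.2], [0.4, 0.6]]])  # resvnet, labeled
TOY_C = np.array([[[0.6, 0.4], [0.3, 0.7]], [[0.2, 0.8], [0.5, 0.1]]])  # vnet, unlabeled
TOY_D = np.array([[[0.7, 0.3], [0.2, 0.9]], [[0.3, 0.6], [0.5, 0.2]]])  # resvnet, unlabeled


def _toy_setup():
    labeled_vol = Volume(np.full((2, 2, 2), 0.1))
    unlabeled_vol = Volume(np.full((2, 2, 2), 0.2))
    models = {
        "vnet": FrozenModel({0.1: TOY_A, 0.2: TOY_C}),
        "resvnet": FrozenModel({0.1: TOY_B, 0.2: TOY_D}),
    }
    labeled = [(labeled_vol, GroundTruthMask(TOY_TRUTH))]
    return models, labeled, [unlabeled_vol]


class TestHandWorkedStep:
    """One frozen co-training step reproduces scalar hand computation of
    the disagreement mask, all supervised components, generator choice,
    sharpened pseudo-labels and the unsupervised MSE."""

    def test_all_five_losses_match_hand_computation(self):
        models, labeled, unlabeled = _toy_setup()
        cfg = TrainConfig(sharpen_T=0.5)
        step = train_step(models, labeled, unlabeled, cfg, iteration=0)

        # binarized A/B disagree exactly at (0,1,0) and (1,0,1)
        assert step.dif_fraction == pytest.approx(2 / 8)

        v, r = step.bundles["vnet"], step.bundles["resvnet"]
        assert float(v.ce) == pytest.approx(0.3644071766, rel=1e-8)
        assert float(v.dice) == pytest.approx(0.3239432057, rel=1e-8)
        assert float(v.mse_dif) == pytest.approx(0.09, rel=1e-8)
        assert float(v.supervised_total) == pytest.approx(0.7783503824, rel=1e-8)
        assert float(r.ce) == pytest.approx(0.5929230658, rel=1e-8)
        assert float(r.dice) == pytest.approx(0.4769223432, rel=1e-8)
        assert float(r.mse_dif) == pytest.approx(0.5, rel=1e-8)
        assert float(r.supervised_total) == pytest.approx(1.5698454090, rel=1e-8)

        # vnet has the smaller labeled Dice loss, so it generates and the
        # residual twin incurs the pseudo-label MSE
        assert step.generator_id == "vnet"
        assert v.mse_pseudo is None
        assert float(r.mse_pseudo) == pytest.approx(0.0268762496, rel=1e-8)

    def test_matches_loop_oracles_recomputed(self):
        """Same step checked against the loop oracles end to end."""
        models, labeled, unlabeled = _toy_setup()
        step = train_step(models, labeled, unlabeled, TrainConfig(sharpen_T=0.5), 0)
        dif = np.array(oracles.xor_loop((TOY_A > 0.5).astype(int), (TOY_B > 0.5).astype(int)))
        pa = np.stack([1 - TOY_A, TOY_A])
        assert float(step.bundles["vnet"].ce) == pytest.approx(
            oracles.ce_loop(pa, TOY_TRUTH), rel=1e-9
        )
        assert float(step.bundles["vnet"].mse_dif) == pytest.approx(
            oracles.dif_mse_loop(pa, TOY_TRUTH, dif), rel=1e-9
        )
        pl = np.vectorize(lambda p: oracles.sharpen_scalar(p, 0.5))(TOY_C)
        pd = np.stack([1 - TOY_D, TOY_D])
        assert float(step.bundles["resvnet"].mse_pseudo) == pytest.approx(
            oracles.pseudo_mse_loop(pd, pl), rel=1e-9
        )


class TestTrainStepContracts:
    def test_empty_labeled_batch_rejected(self):
        models, _, unlabeled = _toy_setup()
        with pytest.raises(TrainingError):
            train_step(models, [], unlabeled, TrainConfig(), 0)

    def test_empty_unlabeled_reduces_to_supervised(self):
        models, labeled, _ = _toy_setup()
        step = train_step(models, labeled, [], TrainConfig(), 0)
        assert step.generator_id is None
        assert step.bundles["vnet"].mse_pseudo is None
        assert step.bundles["resvnet"].mse_pseudo is None

    def test_identical_twins_have_empty_dif_and_tie(self):
        fg = TOY_A
        models = {
            "vnet": FrozenModel({0.1: fg, 0.2: TOY_C}),
            "resvnet": FrozenModel({0.1: fg, 0.2: TOY_C}),
        }
        labeled = [(Volume(np.full((2, 2, 2), 0.1)), GroundTruthMask(TOY_TRUTH))]
        step = train_step(models, labeled, [Volume(np.full((2, 2, 2), 0.2))], TrainConfig(), 0)
        assert step.dif_fraction == 0.0
        assert float(step.bundles["vnet"].mse_dif) == 0.0
        assert step.generator_id == "vnet"  # tie rule


class TestGradientIsolation:
    def test_generator_update_unaffected_by_pseudo_label_loss(self):
        """The generator's parameters after a step are identical whether or
        not the other model's unsupervised loss was computed."""
        spec = PhantomSpec(grid_shape=(8, 8, 8), organ_axes=(3.0, 2.5, 2.0),
                           distractor_count=1, lobe_count=1)
        split = generate_split(1, 1, 0, spec, seed=4)
        labeled = [(Volume(split.labeled[0][0].data / 400.0), split.labeled[0][1])]
        unlabeled = [Volume(split.unlabeled[0].data / 400.0)]

        params = {}
        for unsup_weight in (0.0, 1.0):
            models = {
                "vnet": build_backbone("vnet", 2, 2, seed=10),
                "resvnet": build_backbone("resvnet", 2, 2, seed=11),
            }
            opts = {
                mid: SGD(models[mid].parameters(), lr=0.01, momentum=0.9, weight_decay=1e-4)
                for mid in models
            }
            cfg = TrainConfig(unsup_weight=unsup_weight, depth=2, width_scale=2)
            step = train_step(models, labeled, unlabeled, cfg, 0, opts)
            gen = step.generator_id or select_generator(
                float(step.bundles["vnet"].dice), float(step.bundles["resvnet"].dice)
            )
            params[unsup_weight] = (gen, [p.data.copy() for p in models[gen].parameters()])

        gen0, p0 = params[0.0]
        gen1, p1 = params[1.0]
        assert gen0 == gen1
        for a, b in zip(p0, p1):
            np.testing.assert_array_equal(a, b)


class TestTrainLoop:
    def _tiny_split(self, n_lab=1, n_unl=1, n_test=1, seed=3):
        spec = PhantomSpec(grid_shape=(8, 8, 8), organ_axes=(3.0, 2.5, 2.0),
                           distractor_count=1, lobe_count=1)
        return generate_split(n_lab, n_unl, n_test, spec, seed=seed)

    def _tiny_cfg(self, **kw):
        base = dict(total_iterations=3, width_scale=2, depth=2, checkpoint_every=0,
                    batch_labeled=1, batch_unlabeled=1, seed=0)
        base.update(kw)
        return TrainConfig(**base)

    def test_zero_iterations_returns_initialized_models(self):
        res = train(self._tiny_split(), self._tiny_cfg(total_iterations=0))
        assert len(res.log) == 0
        fresh = build_backbone("vnet", 2, 2, seed=res.models["vnet"].rng_seed)
        for a, b in zip(res.models["vnet"].parameters(), fresh.parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_empty_labeled_set_rejected(self):
        split = self._tiny_split(n_lab=0)
        with pytest.raises(TrainingError):
            train(split, self._tiny_cfg())

    def test_supervised_only_fallback_with_empty_unlabeled(self):
        split = self._tiny_split(n_unl=0)
        res = train(split, self._tiny_cfg(batch_unlabeled=0))
        assert (res.log["generator"] == "").all()
        assert (res.log["vnet_mse_pseudo"] == 0).all()

    def test_checkpoints_written_at_requested_cadence(self, tmp_path):
        cfg = self._tiny_cfg(total_iterations=4, checkpoint_every=2)
        res = train(self._tiny_split(), cfg, out_dir=tmp_path)
        names = sorted(p.name for p in res.checkpoints)
        assert names == ["checkpoint_000002.npz", "checkpoint_000004.npz"]
        assert (tmp_path / "training_log.csv").exists()

    def test_same_seed_reproduces_iteration_zero_losses(self):
        split = self._tiny_split()
        cfg = self._tiny_cfg(total_iterations=1)
        a = train(split, cfg).log.iloc[0]
        b = train(split, cfg).log.iloc[0]
        for col in ("vnet_ce", "vnet_dice", "resvnet_supervised_total"):
            assert a[col] == b[col]

    def test_log_contains_loss_components_and_lr(self):
        res = train(self._tiny_split(), self._tiny_cfg())
        for col in ("iteration", "lr", "generator", "vnet_ce", "vnet_dice",
                    "vnet_mse_dif", "vnet_mse_pseudo", "resvnet_supervised_total"):
            assert col in res.log.columns
        assert (res.log["lr"] == 0.01).all()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            {"total_iterations": -1},
            {"lr0": 0.0},
            {"lr_decay_every": 0},
            {"batch_labeled": 0},
            {"sharpen_T": -0.5},
            {"dif_loss": "huber"},
            {"hu_lo": 400.0, "hu_hi": 0.0},
        ],
    )
    def test_invalid_fields_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            TrainConfig.from_dict(bad)

    def test_unknown_field_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainConfig.from_dict({"learning_rate": 0.1})

    def test_round_trip(self):
        cfg = TrainConfig(total_iterations=10)
        assert TrainConfig.from_dict(cfg.to_dict()) == cfg
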