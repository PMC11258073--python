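"""Segmentation module: label rules, schedule, inference tiling, postprocessing."""

import numpy as np
import pytest
from scipy import ndimage

from noisekit import (LabelMask, PhantomSpec, TrainingConfig, Volume, dice,
                      generate_phantom, postprocess, preprocess_labels,
                      sliding_window_infer)
from noisekit.errors import TrainingDiverged
from noisekit.nn.losses import IGNORE_LABEL
from noisekit.segnet import PlateauScheduler, TrainedModel, train



# ---------------------------------------------------------------------------
# Label preprocessing
# ---------------------------------------------------------------------------

class TestPreprocessLabels:
    def _tube_mask(self):
        """Aorta block plus an LM tube extending 40 voxels (= 40 mm at 1 mm)."""
        labels = np.zeros((9, 9, 60), np.int64)
        labels[2:7, 2:7, 0:8] = 1          # aorta block
        labels[3:6, 3:6, 8:48] = 2         # LM tube, 40 mm long
        return LabelMask(labels, (1.0, 1.0, 1.0))

    def test_distal_artery_ignored_proximal_kept(self):
        mask = self._tube_mask()
        out = preprocess_labels(mask, aorta_distance_cutoff=20.0)
        # independent oracle: distance from each LM voxel to the nearest
        # aorta voxel, by explicit coordinate arithmetic
        aorta_idx = np.argwhere(mask.labels == 1)
        lm_idx = np.argwhere(mask.labels == 2)
        d = np.sqrt(((lm_idx[:, None, :] - aorta_idx[None, :, :]) ** 2)
                    .sum(-1)).min(1)
        far = lm_idx[d > 20.0]
        near = lm_idx[d <= 20.0]
        assert np.all(out.labels[tuple(far.T)] == IGNORE_LABEL)
        # near voxels keep LM unless they sit on the tube's boundary shell
        interior = out.labels[tuple(near.T)]
        assert set(np.unique(interior)) <= {2, IGNORE_LABEL}
        assert (interior == 2).any()

    def test_thin_structure_fully_ignored(self):
        labels = np.zeros((5, 9, 9), np.int64)
        labels[2, 2:7, 2:7] = 1            # one-voxel-thin aorta plate
        out = preprocess_labels(LabelMask(labels, (1, 1, 1)), np.inf)
        assert np.all(out.labels[labels == 1] == IGNORE_LABEL)

    def test_infinite_cutoff_only_shells(self):
        mask = self._tube_mask()
        out = preprocess_labels(mask, np.inf)
        aorta = mask.labels == 1
        interior = aorta & ndimage.binary_erosion(aorta)
        assert np.all(out.labels[interior] == 1)
        shell = aorta & ~ndimage.binary_erosion(aorta)
        assert np.all(out.labels[shell] == IGNORE_LABEL)
        # distal LM voxels survive when the distance rule is disabled
        assert (out.labels[mask.labels == 2] == 2).any()

    def test_no_aorta_is_an_error(self):
        labels = np.zeros((4, 4, 4), np.int64)
        labels[1, 1, 1] = 2
        with pytest.raises(ValueError):
            preprocess_labels(LabelMask(labels, (1, 1, 1)))


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------

class TestPlateauScheduler:
    def test_flat_loss_halves_lr_at_epoch_six(self):
        sched = PlateauScheduler(1e-4, 0.5, lr_patience=5, stop_patience=10)
        lrs = [sched.update(1.0)[0] for _ in range(6)]
        assert lrs[4] == 1e-4          # through epoch 5 the LR is unchanged
        assert lrs[5] == 5e-5          # halved at epoch 6

    def test_flat_loss_stops_after_ten_stale_epochs(self):
        sched = PlateauScheduler(1e-4)
        stops = [sched.update(1.0)[1] for _ in range(11)]
        assert not any(stops[:10])
        assert stops[10]

    def test_strict_decrease_resets_patience(self):
        sched = PlateauScheduler(1e-4)
        for loss in [1.0, 1.0, 1.0, 1.0, 0.9]:   # improvement at epoch 5
            lr, stop = sched.update(loss)
        assert lr == 1e-4 and not stop and sched.streak == 0
        # equal-to-best is NOT an improvement
        sched.update(0.9)
        assert sched.streak == 1


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

class _StubNet:
    """Emits constant logits favouring the aorta class."""

    n_classes = 4

    def forward(self, x, train=False):
        out = np.zeros((x.shape[0], 4) + x.shape[2:], np.float32)
        out[:, 1] = 5.0
        return out


def _stub_model(patch=(8, 16, 16)):
    cfg = TrainingConfig.toy(patch_size=patch)
    return TrainedModel(net=_StubNet(), config=cfg)


class TestSlidingWindowInfer:
    def test_constant_model_gives_all_aorta_full_shape(self, small_phantom):
        out = sliding_window_infer(_stub_model(), small_phantom.volume)
        assert out.shape == small_phantom.volume.shape
        assert np.all(out.labels == 1)

    def test_overlap_invariance_for_constant_logits(self, small_phantom):
        m = _stub_model()
        a = sliding_window_infer(m, small_phantom.volume, overlap=0.5)
        b = sliding_window_infer(m, small_phantom.volume, overlap=0.0)
        assert np.array_equal(a.labels, b.labels)

    def test_volume_smaller_than_patch_is_padded_and_cropped(self):
        vol = Volume(np.zeros((3, 5, 5), np.float32), (1, 1, 1))
        out = sliding_window_infer(_stub_model(patch=(8, 16, 16)), vol)
        assert out.shape == (3, 5, 5)

    def test_single_window_equals_direct_forward(self, rng):
        from noisekit.segnet import _normalize
        from noisekit.nn import UNet3D
        net = UNet3D(levels=2, base_width=4, seed=5)
        cfg = TrainingConfig.toy(patch_size=(8, 16, 16))
        model = TrainedModel(net=net, config=cfg)
        vol = Volume(rng.normal(300, 50, (8, 16, 16)).astype(np.float32), (1, 1, 1))
        out = sliding_window_infer(model, vol)
        direct = np.argmax(net.forward(_normalize(vol.values)[None, None])[0], axis=0)
        assert np.array_equal(out.labels, direct)


# ---------------------------------------------------------------------------
# Postprocessing and Dice
# ---------------------------------------------------------------------------

class TestPostprocess:
    def test_small_component_removed(self):
        labels = np.zeros((10, 10, 20), np.int64)
        labels[2:7, 2:7, 2:7] = 1              # ~1000 voxels
        labels[1:2, 1:2, 12:19] = 1            # 7 voxels, disconnected
        out = postprocess(LabelMask(labels, (1, 1, 1)))
        assert out.labels[1, 1, 15] == 0
        assert out.labels[4, 4, 4] == 1

    def test_sealed_cavity_filled(self):
        labels = np.zeros((8, 8, 8), np.int64)
        labels[1:7, 1:7, 1:7] = 1
        labels[3:5, 3:5, 3:5] = 0              # internal cavity
        out = postprocess(LabelMask(labels, (1, 1, 1)))
        assert np.all(out.labels[3:5, 3:5, 3:5] == 1)

    def test_idempotent(self, small_phantom):
        once = postprocess(small_phantom.labels)
        twice = postprocess(once)
        assert np.array_equal(once.labels, twice.labels)

    def test_equal_size_tiebreak_lexicographic(self):
        labels = np.zeros((4, 4, 12), np.int64)
        labels[1, 1, 8:10] = 1                 # later in (z, y, x) order
        labels[1, 2, 0:2] = 1                  # smaller y -> earlier
        out = postprocess(LabelMask(labels, (1, 1, 1)))
        # brute-force oracle: enumerate components and their minimum indices
        lab, n = ndimage.label(labels == 1, structure=np.ones((3, 3, 3)))
        mins = {c: tuple(np.argwhere(lab == c).min(0)) for c in range(1, n + 1)}
        keep = min(mins, key=mins.get)
        assert np.array_equal(out.labels == 1, lab == keep)

    def test_empty_class_stays_empty(self):
        labels = np.zeros((4, 4, 4), np.int64)
        labels[1:3, 1:3, 1:3] = 1
        out = postprocess(LabelMask(labels, (1, 1, 1)))
        assert not (out.labels == 2).any() and not (out.labels == 3).any()


class TestDice:
    @pytest.mark.parametrize("na,nb,ni,expected", [
        (100, 100, 100, 1.0),   # identical
        (100, 100, 0, 0.0),     # disjoint
        (100, 100, 50, 0.5),    # half overlap
    ])
    def test_closed_form(self, na, nb, ni, expected):
        a = np.zeros((1, 1, 300), np.int64)
        b = np.zeros((1, 1, 300), np.int64)
        a[0, 0, :na] = 1
        b[0, 0, na - ni:na - ni + nb] = 1
        got = dice(LabelMask(a, (1, 1, 1)), LabelMask(b, (1, 1, 1)), "aorta")
        assert got == pytest.approx(expected)

    def test_both_empty_is_one(self):
        z = LabelMask(np.zeros((2, 2, 2), np.int64), (1, 1, 1))
        assert dice(z, z, "lm") == 1.0

    def test_shape_mismatch_errors(self):
        a = LabelMask(np.zeros((2, 2, 2), np.int64), (1, 1, 1))
        b = LabelMask(np.zeros((2, 2, 3), np.int64), (1, 1, 1))
        with pytest.raises(ValueError):
            dice(a, b)


# ---------------------------------------------------------------------------
# Training (ultra-toy: seconds, not minutes)
# ---------------------------------------------------------------------------

def _tiny_config(seed=0, **kw):
    base = dict(iterations_per_epoch=4, hardmine_every_epochs=2,
                patch_size=(8, 16, 16), batch_size=1, levels=2, base_width=4,
                max_epochs=2, infer_overlap=0.0, seed=seed)
    base.update(kw)
    return TrainingConfig.toy(**base)


def _tiny_phantoms(n, seed0=50):
    spec = dict(shape=(16, 32, 64), aorta_radius=7.0, lm_radius=1.5,
                lm_length=10.0, rca_length=10.0, noise_sd=30.0)
    return [generate_phantom(PhantomSpec(**spec, seed=seed0 + i))
            for i in range(n)]


class TestTraining:
    def test_two_runs_identical_logs(self):
        phs = _tiny_phantoms(3)
        m1 = train(phs[:2], phs[2:], _tiny_config(seed=4))
        m2 = train(phs[:2], phs[2:], _tiny_config(seed=4))
        assert m1.training_log == m2.training_log

    def test_log_structure_and_lr_column(self):
        phs = _tiny_phantoms(3)
        model = train(phs[:2], phs[2:], _tiny_config())
        assert len(model.training_log) == 2
        for row in model.training_log:
            assert {"epoch", "train_loss", "val_loss", "val_dice_aorta",
                    "lr"} <= set(row)
        assert 0.0 <= model.best_val_dice["aorta"] <= 1.0

    def test_checkpoint_roundtrip(self, tmp_path):
        phs = _tiny_phantoms(3)
        model = train(phs[:2], phs[2:], _tiny_config())
        model.save(tmp_path / "ckpt")
        back = TrainedModel.load(tmp_path / "ckpt")
        assert back.best_val_dice == model.best_val_dice
        x = np.random.default_rng(0).normal(size=(1, 1, 8, 16, 16)).astype(np.float32)
        assert np.array_equal(back.net.forward(x), model.net.forward(x))

    def test_empty_or_overlapping_splits_rejected(self):
        phs = _tiny_phantoms(2)
        with pytest.raises(ValueError):
            train([], phs, _tiny_config())
        with pytest.raises(ValueError):
            train(phs, phs, _tiny_config())

    def test_nonfinite_loss_aborts_with_diagnostic(self):
        phs = _tiny_phantoms(3)
        phs[0].volume.values[:] = np.nan   # every patch from it poisons the loss
        with pytest.raises(TrainingDiverged):
            train(phs[:2], phs[2:], _tiny_config(iterations_per_epoch=50))
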