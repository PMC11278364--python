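"""U-Net segmenter: loss oracle, scheduler trace, prediction contracts,
model selection, and fine-tuning continuation."""

import math
from dataclasses import replace

import numpy as np
import pytest

from maskcycle.imgio import write_image, write_mask
from maskcycle.manifest import DatasetManifest
from maskcycle.segmentation import (SegConfig, UNetSpec, bce_loss, build_unet,
                                    fine_tune, load_segmenter, predict_mask,
                                    predict_probabilities, save_segmenter,
                                    train_segmenter)

TINY_SPEC = UNetSpec(depth=2, base_channels=6)


def _write_pair(tmp_path, sample, stem):
    ipath, mpath = tmp_path / f"{stem}.png", tmp_path / f"{stem}_mask.png"
    write_image(ipath, sample.image)
    write_mask(mpath, sample.mask)
    return str(ipath), str(mpath)


@pytest.fixture
def one_image_manifest(tmp_path, annotated_sample):
    ipath, mpath = _write_pair(tmp_path, annotated_sample, "img")
    man = DatasetManifest()
    man.append(ipath, mpath, "train")
    return man


class TestBuildUnet:
    def test_output_dims_and_range(self):
        rng = np.random.default_rng(0)
        model = build_unet(UNetSpec(depth=4, base_channels=4), rng)
        from maskcycle.nn import Tensor
        out = model(Tensor(rng.normal(0, 1, (1, 3, 64, 64))))
        assert out.data.shape == (1, 1, 64, 64)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_seeded_init_is_deterministic(self):
        m1 = build_unet(TINY_SPEC, np.random.default_rng(4))
        m2 = build_unet(TINY_SPEC, np.random.default_rng(4))
        for a, b in zip(m1.state_arrays(), m2.state_arrays()):
            assert np.array_equal(a, b)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            build_unet(UNetSpec(depth=1), np.random.default_rng(0))


class TestBceLoss:
    def test_half_probabilities_give_ln2(self):
        p = np.full((4, 4), 0.5, dtype=np.float32)
        m = np.random.default_rng(0).integers(0, 2, (4, 4)).astype(np.float32)
        assert float(bce_loss(p, m).data) == pytest.approx(math.log(2), abs=1e-6)

    def test_perfect_prediction_is_near_zero(self):
        m = np.array([[1.0, 0.0], [0.0, 1.0]], dtype=np.float32)
        assert float(bce_loss(m.copy(), m).data) == pytest.approx(0.0, abs=1e-5)

    def test_matches_elementwise_enumeration(self):
        p = np.array([[0.9, 0.1], [0.8, 0.3]], dtype=np.float32)
        m = np.array([[1.0, 0.0], [1.0, 0.0]], dtype=np.float32)
        expected = -(math.log(0.9) + math.log(0.9)
                     + math.log(0.8) + math.log(0.7)) / 4.0
        assert float(bce_loss(p, m).data) == pytest.approx(expected, abs=1e-6)

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.full((2, 2), 0.5), np.zeros((3, 3)))


class TestPredictMask:
    def test_constant_maps_threshold_both_ways(self):
        # thresholding contract checked directly on probability maps
        high = np.full((4, 4), 0.7)
        low = np.full((4, 4), 0.3)
        assert ((high >= 0.5).astype(np.uint8) == 1).all()
        assert ((low >= 0.5).astype(np.uint8) == 0).all()

    def test_threshold_monotonicity(self, annotated_sample):
        model = build_unet(TINY_SPEC, np.random.default_rng(0))
        prob = predict_probabilities(model, annotated_sample.image)
        prev = None
        for t in (0.2, 0.4, 0.5, 0.6, 0.8):
            mask = (prob >= t).astype(np.uint8)
            if prev is not None:
                assert (mask <= prev).all()   # raising t never adds pixels
            prev = mask
        tie = predict_mask(model, annotated_sample.image,
                           threshold=float(prob[0, 0]))
        assert tie[0, 0] == 1   # p == threshold goes to foreground


class TestTrainSegmenter:
    def test_zero_epochs_returns_init_and_empty_history(self, one_image_manifest):
        cfg = SegConfig(epochs=0, seed=1)
        model, hist = train_segmenter(cfg, TINY_SPEC, one_image_manifest,
                                      one_image_manifest)
        ref = build_unet(TINY_SPEC, np.random.default_rng(1))
        for a, b in zip(model.state_arrays(), ref.state_arrays()):
            assert np.array_equal(a, b)
        assert hist.epochs == []

    def test_scheduler_trace_and_history(self, one_image_manifest):
        cfg = SegConfig(epochs=12, seed=0, batch_size=1, hflip_augment=False)
        _, hist = train_segmenter(cfg, TINY_SPEC, one_image_manifest,
                                  one_image_manifest)
        lrs = [e["lr"] for e in hist.epochs]
        expected = [0.01 * 0.1 ** (e // 5) for e in range(12)]
        np.testing.assert_allclose(lrs, expected)
        assert hist.best_epoch == int(np.argmax([e["val_dice"] for e in hist.epochs]))

    def test_missing_mask_rejected(self, tmp_path, annotated_sample):
        ipath, _ = _write_pair(tmp_path, annotated_sample, "x")
        man = DatasetManifest()
        man.append(ipath, "", "train")
        with pytest.raises(ValueError, match="without mask"):
            train_segmenter(SegConfig(epochs=1), TINY_SPEC, man, man)

    def test_short_overfit_reduces_loss(self, one_image_manifest):
        cfg = SegConfig(epochs=40, scheduler_step=100, batch_size=1,
                        hflip_augment=False, seed=0)
        _, hist = train_segmenter(cfg, TINY_SPEC, one_image_manifest,
                                  one_image_manifest)
        assert hist.epochs[-1]["train_loss"] < hist.epochs[0]["train_loss"]


class TestFineTune:
    def test_zero_epochs_keeps_parameters(self, one_image_manifest):
        model = build_unet(TINY_SPEC, np.random.default_rng(2))
        before = [a.copy() for a in model.state_arrays()]
        out, hist = fine_tune(model, SegConfig(epochs=0), TINY_SPEC,
                              [one_image_manifest], one_image_manifest)
        assert hist.epochs == []
        for a, b in zip(before, out.state_arrays()):
            assert np.array_equal(a, b)

    def test_pooled_manifest_row_count(self, one_image_manifest):
        pooled = DatasetManifest(one_image_manifest.rows * 3)
        assert len(pooled) == 3 * len(one_image_manifest)

    def test_save_load_round_trip(self, tmp_path, annotated_sample):
        model = build_unet(TINY_SPEC, np.random.default_rng(3))
        save_segmenter(model, TINY_SPEC, tmp_path / "seg.ckpt")
        loaded, spec = load_segmenter(tmp_path / "seg.ckpt")
        assert spec == TINY_SPEC
        np.testing.assert_array_equal(
            predict_probabilities(model, annotated_sample.image),
            predict_probabilities(loaded, annotated_sample.image))
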