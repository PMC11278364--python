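"""Mask-preserving CycleGAN: loss oracles, arity contracts, training
mechanics, and the mask-invariance guarantee of dataset translation."""

import hashlib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

from maskcycle.cutpaste import SynthesisConfig, extract_cutouts, synthesize_dataset
from maskcycle.cyclegan import (GanConfig, adversarial_loss, build_gan_dataset,
                                cycle_loss_r, cycle_loss_s, init_gan,
                                load_checkpoint, mask_from_channel, recreate_s,
                                save_checkpoint, to_domain_r, to_domain_s,
                                train_gan, training_step, translate_sample)
from maskcycle.fixtures import AnnotatedSample, generate_fixture_corpus
from maskcycle.imgio import read_image, read_mask

TINY = GanConfig(epochs=1, crop_size=64, base_channels=6, n_res_blocks=1,
                 disc_layers=2, seed=0, replay_buffer_size=4)


def _tiny_state():
    return init_gan(TINY)


def _random_batches(rng, h=32, w=32):
    xs = rng.uniform(-1, 1, (1, 4, h, w)).astype(np.float32)
    xs[:, 3] = np.sign(xs[:, 3]) + (xs[:, 3] == 0)   # valid binary mask channel
    yr = rng.uniform(-1, 1, (1, 3, h, w)).astype(np.float32)
    return xs, yr


class TestLossOracles:
    def test_adversarial_loss_trivial_values(self):
        ones = np.ones((1, 1, 2, 2), dtype=np.float32)
        assert float(adversarial_loss(ones, True).data) == pytest.approx(0.0)
        assert float(adversarial_loss(np.zeros_like(ones), True).data) == pytest.approx(1.0)

    def test_adversarial_loss_matches_elementwise_enumeration(self):
        scores = np.array([[0.3, -0.2], [1.4, 0.9]], dtype=np.float32)
        expected = np.mean([(s - 1.0) ** 2 for s in scores.flatten()])
        assert float(adversarial_loss(scores, True).data) == pytest.approx(expected, abs=1e-6)
        expected_fake = np.mean([s ** 2 for s in scores.flatten()])
        assert float(adversarial_loss(scores, False).data) == pytest.approx(expected_fake, abs=1e-6)

    def test_adversarial_loss_rejects_nonfinite(self):
        with pytest.raises(FloatingPointError):
            adversarial_loss(np.array([np.nan]), True)

    def test_cycle_losses_identity_and_constant_offset(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(-1, 1, (4, 4, 4)).astype(np.float32)
        assert float(cycle_loss_s(s, s).data) == pytest.approx(0.0)
        c = 0.25
        assert float(cycle_loss_s(s, s + c).data) == pytest.approx(c, abs=1e-6)
        r = rng.uniform(-1, 1, (3, 4, 4)).astype(np.float32)
        assert float(cycle_loss_r(r, r + c).data) == pytest.approx(c, abs=1e-6)

    def test_cycle_loss_matches_elementwise_enumeration(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(-1, 1, (4, 4, 4)).astype(np.float32)
        b = rng.uniform(-1, 1, (4, 4, 4)).astype(np.float32)
        expected = sum(abs(float(x) - float(y))
                       for x, y in zip(a.flatten(), b.flatten())) / a.size
        assert float(cycle_loss_s(a, b).data) == pytest.approx(expected, abs=1e-6)

    def test_cycle_loss_dim_mismatch_rejected(self):
        a = np.zeros((4, 4, 4), dtype=np.float32)
        with pytest.raises(ValueError):
            cycle_loss_s(a, np.zeros((4, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError):
            cycle_loss_r(a, a)   # 4 channels into the 3-channel loss


class TestDomainConversion:
    def test_round_trip_and_mask_channel_extremes(self, annotated_sample):
        s = to_domain_s(annotated_sample.image, annotated_sample.mask)
        assert s.shape == (4, 64, 64)
        assert s.min() >= -1.0 and s.max() <= 1.0
        assert set(np.unique(s[3])) <= {-1.0, 1.0}
        r = to_domain_r(annotated_sample.image)
        assert r.shape == (3, 64, 64)

    def test_mask_binarization_threshold_and_tie_rule(self):
        channel = np.array([[0.7, -0.7], [0.0, -0.0]], dtype=np.float32)
        out = mask_from_channel(channel)
        # 0.7 -> fg, -0.7 -> bg, exact zero (tie) -> fg by convention
        assert out.tolist() == [[1, 0], [1, 1]]
        assert mask_from_channel(np.full((2, 2), 0.7)).all()


class TestTrainingMechanics:
    def test_step_losses_finite_and_nonnegative(self):
        state = _tiny_state()
        xs, yr = _random_batches(np.random.default_rng(0))
        _, losses = training_step(state, xs, yr, np.random.default_rng(1))
        assert all(np.isfinite(v) and v >= 0 for v in losses.values())
        assert len(state.history) == 1

    def test_zero_learning_rate_freezes_parameters(self):
        state = init_gan(replace(TINY, learning_rate=1e-12))
        state.opt_g.lr = 0.0
        state.opt_d.lr = 0.0
        before = [p.data.copy() for p in state.g_s2r.parameters()]
        xs, yr = _random_batches(np.random.default_rng(0))
        training_step(state, xs, yr, np.random.default_rng(1))
        after = [p.data for p in state.g_s2r.parameters()]
        assert all(np.array_equal(a, b) for a, b in zip(before, after))

    def test_channel_arity_mismatch_rejected(self):
        state = _tiny_state()
        xs, yr = _random_batches(np.random.default_rng(0))
        with pytest.raises(ValueError, match="channels"):
            training_step(state, yr, yr, np.random.default_rng(1))

    def test_identical_runs_yield_identical_loss_sequences(self):
        seqs = []
        for _ in range(2):
            state = _tiny_state()
            rng = np.random.default_rng(5)
            data_rng = np.random.default_rng(6)
            losses = []
            for _ in range(3):
                xs, yr = _random_batches(data_rng)
                _, l = training_step(state, xs, yr, rng)
                losses.append(l)
            seqs.append(losses)
        assert seqs[0] == seqs[1]


@pytest.fixture(scope="module")
def tiny_corpus(tmp_path_factory):
    from maskcycle.fixtures import DomainShift, FixtureConfig
    root = tmp_path_factory.mktemp("gan_corpus")
    cfg = FixtureConfig(seed=7, image_height=64, image_width=64,
                        blobs_per_frame=(3, 8), blob_axes=(4.0, 10.0),
                        texture_scale=12.0, n_background_frames=3,
                        n_real_frames=5, n_test_frames=2)
    manifests = generate_fixture_corpus(cfg, root / "fx")
    src = manifests["source"].rows[0]
    cuts = extract_cutouts(
        AnnotatedSample(read_image(src.image_path), read_mask(src.mask_path)),
        min_area=8)
    synth = synthesize_dataset(
        SynthesisConfig(n_images=6, heads_per_image=(3, 6), seed=3,
                        train_fraction=1.0, min_area=8),
        cuts, manifests["backgrounds"], root / "synth")
    return manifests, synth


class TestTrainGan:
    def test_zero_epochs_returns_initialized_state(self, tiny_corpus):
        manifests, synth = tiny_corpus
        state = train_gan(replace(TINY, epochs=0), synth, manifests["real"])
        assert state.epoch == 0 and state.history == []

    def test_unmasked_s_row_rejected(self, tiny_corpus):
        manifests, _ = tiny_corpus
        with pytest.raises(ValueError, match="without mask"):
            train_gan(TINY, manifests["real"], manifests["real"])

    def test_checkpoint_per_epoch_and_reload(self, tiny_corpus, tmp_path):
        manifests, synth = tiny_corpus
        cfg = replace(TINY, epochs=2)
        state = train_gan(cfg, synth, manifests["real"], checkpoint_dir=tmp_path)
        ckpts = sorted(tmp_path.glob("gan_epoch*.ckpt"))
        assert len(ckpts) == 2
        reloaded = load_checkpoint(ckpts[-1])
        xs = to_domain_s(read_image(synth.rows[0].image_path),
                         read_mask(synth.rows[0].mask_path))
        np.testing.assert_array_equal(translate_sample(state, xs),
                                      translate_sample(reloaded, xs))


class TestInference:
    def test_translate_dims_range_and_determinism(self, annotated_sample):
        state = _tiny_state()
        xs = to_domain_s(annotated_sample.image, annotated_sample.mask)
        out1 = translate_sample(state, xs)
        out2 = translate_sample(state, xs)
        assert out1.shape == (3, 64, 64)
        assert out1.min() >= -1.0 and out1.max() <= 1.0
        np.testing.assert_array_equal(out1, out2)

    def test_recreate_has_four_channels_and_binarizes(self):
        state = _tiny_state()
        yr = np.random.default_rng(0).uniform(-1, 1, (3, 32, 32)).astype(np.float32)
        out = recreate_s(state, yr, binarize_mask=True)
        assert out.shape == (4, 32, 32)
        assert set(np.unique(out[3])) <= {-1.0, 1.0}

    def test_double_cycle_conserves_arity(self):
        state = _tiny_state()
        xs, yr = _random_batches(np.random.default_rng(2))
        assert translate_sample(state, xs).shape[1] == 3
        assert recreate_s(state, translate_sample(state, xs)).shape[1] == 4
        assert recreate_s(state, yr).shape[1] == 4
        assert translate_sample(state, recreate_s(state, yr)).shape[1] == 3


class TestBuildGanDataset:
    def test_masks_copied_bitwise_rows_and_splits_preserved(self, tiny_corpus, tmp_path):
        _, synth = tiny_corpus
        state = _tiny_state()
        out = build_gan_dataset(state, synth, tmp_path / "gan")
        assert len(out) == len(synth)
        for a, b in zip(synth, out):
            assert a.split == b.split
            ha = hashlib.sha256(Path(a.mask_path).read_bytes()).hexdigest()
            hb = hashlib.sha256(Path(b.mask_path).read_bytes()).hexdigest()
            assert ha == hb
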