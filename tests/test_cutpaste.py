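"""Cut-and-paste synthesis: extraction, placement sampling, compositing."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from maskcycle.cutpaste import (Cutout, PasteInstance, SynthesisConfig,
                                bilinear_sample, extract_cutouts, render_paste,
                                sample_instances, synthesize_dataset)
from maskcycle.fixtures import AnnotatedSample, generate_fixture_corpus
from maskcycle.imgio import read_mask
from oracles import coverage_oracle


def _sample(mask):
    mask = np.asarray(mask, dtype=np.uint8)
    img = np.zeros(mask.shape + (3,), dtype=np.uint8)
    img[mask > 0] = (200, 150, 50)
    return AnnotatedSample(img, mask)


class TestExtractCutouts:
    def test_single_solid_square(self):
        mask = np.zeros((12, 12), dtype=np.uint8)
        mask[3:8, 4:9] = 1
        cuts = extract_cutouts(_sample(mask), min_area=1)
        assert len(cuts) == 1
        assert cuts[0].alpha.sum() == 25
        assert cuts[0].alpha.shape == (5, 5)

    def test_all_zero_mask(self):
        cuts = extract_cutouts(_sample(np.zeros((8, 8))), min_area=1)
        assert cuts == []

    def test_diagonal_touch_is_one_component(self):
        """8-connectivity joins diagonal neighbours; 4-connectivity would not."""
        from skimage.measure import label
        mask = np.zeros((6, 6), dtype=np.uint8)
        mask[2, 2] = mask[3, 3] = 1
        assert label(mask, connectivity=1).max() == 2  # oracle: 4-conn splits
        assert label(mask, connectivity=2).max() == 1  # oracle: 8-conn joins
        cuts = extract_cutouts(_sample(mask), min_area=1)
        assert len(cuts) == 1
        assert cuts[0].alpha.sum() == 2

    def test_min_area_filter(self):
        mask = np.zeros((12, 12), dtype=np.uint8)
        mask[1:5, 1:5] = 1    # area 16
        mask[8, 8] = 1        # area 1
        cuts = extract_cutouts(_sample(mask), min_area=4)
        assert len(cuts) == 1

    def test_nonbinary_or_mismatched_inputs_rejected(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="binary"):
            AnnotatedSample(img, np.full((4, 4), 2, dtype=np.uint8))
        with pytest.raises(ValueError, match="dims differ"):
            AnnotatedSample(img, np.zeros((5, 5), dtype=np.uint8))


class TestSampleInstances:
    CFG = SynthesisConfig(n_images=1, heads_per_image=(3, 3),
                          scale_range=(1.0, 1.0), rotation_range=(0.0, 0.0))

    def test_point_range_counts_and_values(self):
        inst = sample_instances(self.CFG, 4, (32, 32), np.random.default_rng(0))
        assert len(inst) == 3
        assert all(i.scale == 1.0 and i.rotation == 0.0 for i in inst)

    def test_zero_cutouts_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            inst = sample_instances(self.CFG, 0, (32, 32), np.random.default_rng(0))
        assert inst == []

    def test_seeded_determinism(self):
        cfg = SynthesisConfig(n_images=1, heads_per_image=(2, 6))
        a = sample_instances(cfg, 5, (64, 64), np.random.default_rng(11))
        b = sample_instances(cfg, 5, (64, 64), np.random.default_rng(11))
        assert a == b


def _square_cutout(side=5):
    patch = np.full((side, side, 3), 180, dtype=np.uint8)
    return Cutout(patch, np.ones((side, side), dtype=np.uint8))


class TestRenderPaste:
    def test_zero_instances_is_identity(self):
        bg = np.random.default_rng(0).integers(0, 255, (16, 16, 3)).astype(np.uint8)
        out = render_paste(bg, [_square_cutout()], [])
        assert np.array_equal(out.image, bg)
        assert out.mask.sum() == 0

    def test_identity_paste_popcount(self):
        bg = np.zeros((20, 20, 3), dtype=np.uint8)
        cut = _square_cutout(5)
        out = render_paste(bg, [cut], [PasteInstance(0, (10.0, 10.0))])
        assert out.mask.sum() == cut.alpha.sum() == 25

    def test_fully_offframe_instance_contributes_nothing(self):
        bg = np.zeros((20, 20, 3), dtype=np.uint8)
        out = render_paste(bg, [_square_cutout(5)],
                           [PasteInstance(0, (100.0, 100.0))])
        assert out.mask.sum() == 0

    def test_overlapping_pastes_match_coverage_oracle(self):
        bg = np.zeros((24, 24, 3), dtype=np.uint8)
        cuts = [_square_cutout(5)]
        instances = [
            PasteInstance(0, (10.0, 10.0), scale=1.3, rotation=25.0),
            PasteInstance(0, (12.0, 12.0), scale=0.9, rotation=-40.0),
        ]
        out = render_paste(bg, cuts, instances)
        oracle = coverage_oracle((24, 24), cuts, instances)
        assert np.array_equal(out.mask, oracle)

    def test_extraction_render_round_trip(self, annotated_sample):
        """Pasting a cutout back at its source position restores its footprint."""
        cuts = extract_cutouts(annotated_sample, min_area=8)
        assert cuts
        cut = cuts[0]
        h, w = cut.alpha.shape
        center = (cut.origin[0] + (h - 1) / 2.0, cut.origin[1] + (w - 1) / 2.0)
        out = render_paste(np.zeros_like(annotated_sample.image), [cut],
                           [PasteInstance(0, center)])
        expected = np.zeros_like(annotated_sample.mask)
        expected[cut.origin[0]:cut.origin[0] + h,
                 cut.origin[1]:cut.origin[1] + w] = cut.alpha
        assert np.array_equal(out.mask, expected)


class TestSynthesizeDataset:
    def test_counts_splits_binary_masks_and_determinism(self, small_config, tmp_path):
        manifests = generate_fixture_corpus(small_config, tmp_path / "fx")
        cfg = SynthesisConfig(n_images=10, heads_per_image=(2, 4), seed=5,
                              train_fraction=0.9, min_area=8)
        cuts = [_square_cutout(6)]
        m1 = synthesize_dataset(cfg, cuts, manifests["backgrounds"], tmp_path / "s1")
        assert len(m1) == 10
        assert sum(r.split == "train" for r in m1) == 9
        assert sum(r.split == "val" for r in m1) == 1
        for row in m1:
            mask = read_mask(row.mask_path)   # read_mask validates {0,255}
            assert set(np.unique(mask)) <= {0, 1}
        m2 = synthesize_dataset(cfg, cuts, manifests["backgrounds"], tmp_path / "s2")
        for r1, r2 in zip(m1, m2):
            assert (hashlib.sha256(Path(r1.image_path).read_bytes()).digest()
                    == hashlib.sha256(Path(r2.image_path).read_bytes()).digest())

    def test_empty_cutout_list_errors(self, small_config, tmp_path):
        manifests = generate_fixture_corpus(small_config, tmp_path / "fx")
        with pytest.raises(ValueError, match="empty cutout"):
            synthesize_dataset(SynthesisConfig(n_images=2), [],
                               manifests["backgrounds"], tmp_path / "s")
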