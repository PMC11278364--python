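"""A self-contained desk-scale run of the full pipeline.

Reproduces the study design end to end on procedural fixtures at small
resolution: synthesize the annotated composite dataset, train the
mask-preserving translation model, translate the composites, train
segmenters on the raw (model A) and translated (model B) data, fine-tune
with pseudo-labels (model C), and evaluate everything on held-out
real-domain frames.  Problem sizes are chosen so the whole study runs in
minutes on one CPU core; they scale the study design down, not the method.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .cutpaste import SynthesisConfig, extract_cutouts, synthesize_dataset
from .cyclegan import GanConfig, build_gan_dataset, train_gan
from .fixtures import AnnotatedSample, FixtureConfig, generate_fixture_corpus
from .imgio import read_image, read_mask
from .metrics import delta_table, evaluate_model, ratio_table
from .pseudolabel import SelectionCriterion, generate_candidates, select_candidates
from .segmentation import (SegConfig, UNetSpec, build_unet, fine_tune,
                           train_segmenter)


@dataclass(frozen=True)
class DeskStudyConfig:
    """Problem sizes for the desk-scale pipeline run."""
    seed: int = 0
    image_size: int = 64
    n_backgrounds: int = 6
    n_real: int = 24
    n_test: int = 8
    n_synthetic: int = 120
    train_fraction: float = 0.85
    gan_epochs: int = 6
    seg_epochs: int = 10
    finetune_epochs: int = 4
    pseudolabel_k: int = 8
    gan_base_channels: int = 12
    gan_res_blocks: int = 2
    unet_depth: int = 2
    unet_base_channels: int = 8

    def fixture_config(self) -> FixtureConfig:
        return FixtureConfig(
            seed=self.seed, image_height=self.image_size,
            image_width=self.image_size, blobs_per_frame=(3, 8),
            blob_axes=(4.0, 10.0), texture_scale=12.0,
            n_background_frames=self.n_backgrounds,
            n_real_frames=self.n_real, n_test_frames=self.n_test)


def run_desk_study(config: DeskStudyConfig, work_dir) -> dict:
    """Run the full pipeline; returns reports for models A, B and C.

    Every stage derives its seed from ``config.seed`` so the study is a
    pure function of its configuration.
    """
    work_dir = Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # 1. fixture corpus: annotated source, backgrounds, real pool, test set
    manifests = generate_fixture_corpus(config.fixture_config(),
                                        work_dir / "fixtures")
    src = manifests["source"].rows[0]
    source = AnnotatedSample(read_image(src.image_path), read_mask(src.mask_path))

    # 2. cut-and-paste composites with exact masks
    cutouts = extract_cutouts(source, min_area=8)
    synth_cfg = SynthesisConfig(
        n_images=config.n_synthetic, heads_per_image=(3, 8),
        scale_range=(0.8, 1.2), seed=seed + 1,
        train_fraction=config.train_fraction, min_area=8)
    synth = synthesize_dataset(synth_cfg, cutouts, manifests["backgrounds"],
                               work_dir / "synth")

    # 3. mask-preserving translation toward the real domain
    gan_cfg = GanConfig(
        epochs=config.gan_epochs, crop_size=config.image_size,
        base_channels=config.gan_base_channels,
        n_res_blocks=config.gan_res_blocks, disc_layers=2,
        seed=seed + 2, replay_buffer_size=20)
    gan_state = train_gan(gan_cfg, synth.subset("train"), manifests["real"])
    translated = build_gan_dataset(gan_state, synth, work_dir / "gan")

    # 4. segmenters: A on raw composites, B on translated composites
    seg_cfg = SegConfig(epochs=config.seg_epochs, seed=seed + 3,
                        batch_size=2, scheduler_step=5)
    spec = UNetSpec(depth=config.unet_depth,
                    base_channels=config.unet_base_channels)
    model_a, hist_a = train_segmenter(seg_cfg, spec, synth.subset("train"),
                                      synth.subset("val"))
    model_b, hist_b = train_segmenter(seg_cfg, spec, translated.subset("train"),
                                      translated.subset("val"))

    # 5. pseudo-label the unlabeled real pool with model B, fine-tune to C
    candidates = generate_candidates(model_b, manifests["real"])
    pseudo = select_candidates(
        candidates, SelectionCriterion("top_k", k=config.pseudolabel_k),
        work_dir / "pseudo", gallery=False)
    ft_cfg = replace(seg_cfg, epochs=config.finetune_epochs, seed=seed + 4)
    # fine-tune a copy so model B itself stays evaluable
    model_b_copy = build_unet(spec, np.random.default_rng(0))
    model_b_copy.load_state_arrays(model_b.state_arrays())
    model_c, hist_c = fine_tune(model_b_copy, ft_cfg, spec,
                                [translated.subset("train"), pseudo],
                                translated.subset("val"))

    # 6. evaluate all three on the held-out real-domain test frames
    test = manifests["test"]
    reports = {
        "A": evaluate_model(model_a, test, model_id="A", dataset_id="fixture_test"),
        "B": evaluate_model(model_b, test, model_id="B", dataset_id="fixture_test"),
        "C": evaluate_model(model_c, test, model_id="C", dataset_id="fixture_test"),
    }
    deltas = delta_table([reports["A"]], [reports["B"]])
    ratios = ratio_table([reports["A"]], [reports["C"]])
    return {
        "manifests": manifests, "synthetic": synth, "translated": translated,
        "pseudo": pseudo, "models": {"A": model_a, "B": model_b, "C": model_c},
        "histories": {"A": hist_a, "B": hist_b, "C": hist_c},
        "reports": reports, "deltas": deltas, "ratios": ratios,
        "gan_state": gan_state,
    }
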