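"""Pseudo-label generation and selection for domain-adaptive fine-tuning.

A segmenter trained on translated data predicts masks for an unlabeled
pool of real images.  Each prediction receives a confidence score — the
average of the mean probability over predicted-foreground pixels and the
mean complement over predicted-background pixels — standing in for the
human judgement that a good pseudo-label covers the wheat heads and
nothing else.  The highest-scoring predictions (or those above a
threshold) become a small labeled dataset for fine-tuning; a thumbnail
gallery of every candidate is emitted so a human can still review or veto
the automated choice.
"""

from __future__ import annotations

import base64
import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .imgio import read_image, write_mask
from .manifest import DatasetManifest
from .segmentation import predict_probabilities


@dataclass
class PseudoCandidate:
    image_ref: str
    probability_map: np.ndarray   # H×W in [0,1]
    predicted_mask: np.ndarray    # H×W in {0,1}
    quality_score: float = float("nan")


@dataclass(frozen=True)
class SelectionCriterion:
    """Exactly one of top_k / score_threshold / manual review list."""
    mode: str                      # "top_k" | "score_threshold" | "manual_review_list"
    k: int | None = None
    threshold: float | None = None
    accepted_refs: tuple[str, ...] | None = None

    def validate(self) -> None:
        modes = {"top_k": self.k, "score_threshold": self.threshold,
                 "manual_review_list": self.accepted_refs}
        if self.mode not in modes:
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if modes[self.mode] is None:
            raise ValueError(f"mode {self.mode!r} needs its parameter set")


def score_prediction(probability_map: np.ndarray,
                     predicted_mask: np.ndarray) -> float:
    """Confidence proxy in [0,1].

    ½·(mean p over predicted foreground + mean (1−p) over predicted
    background); an empty region contributes 0 for its term, so a
    prediction with only one class present cannot exceed 0.5.
    """
    p = np.asarray(probability_map, dtype=np.float64)
    m = np.asarray(predicted_mask).astype(bool)
    if p.shape != m.shape:
        raise ValueError(f"map {p.shape} and mask {m.shape} dims differ")
    fg = float(p[m].mean()) if m.any() else 0.0
    bg = float((1.0 - p[~m]).mean()) if (~m).any() else 0.0
    return 0.5 * (fg + bg)


def generate_candidates(model, pool: DatasetManifest,
                        threshold: float = 0.5) -> list[PseudoCandidate]:
    """Predict and score every pool row, preserving manifest order."""
    candidates = []
    for row in pool:
        try:
            image = read_image(row.image_path)
        except OSError as exc:
            raise OSError(f"cannot read pool image {row.image_path}: {exc}") from exc
        prob = predict_probabilities(model, image)
        mask = (prob >= threshold).astype(np.uint8)
        candidates.append(PseudoCandidate(
            image_ref=row.image_path, probability_map=prob,
            predicted_mask=mask,
            quality_score=score_prediction(prob, mask)))
    return candidates


def _thumb_base64(image: np.ndarray, mask: np.ndarray, size: int = 96) -> str:
    """Side-by-side image/mask thumbnail as a base64 PNG for the gallery."""
    im = Image.fromarray(image).resize((size, size))
    mk = Image.fromarray((mask * 255).astype(np.uint8)).convert("RGB").resize((size, size))
    combo = Image.new("RGB", (2 * size, size))
    combo.paste(im, (0, 0))
    combo.paste(mk, (size, 0))
    buf = io.BytesIO()
    combo.save(buf, format="PNG")
    return base64.b64encode(buf.getvalue()).decode("ascii")


def write_gallery(candidates: list[PseudoCandidate], selected_refs: set[str],
                  path) -> None:
    """Static HTML contact sheet of all candidates with scores."""
    rows = []
    for c in sorted(candidates, key=lambda c: -c.quality_score):
        tag = "selected" if c.image_ref in selected_refs else "rejected"
        b64 = _thumb_base64(read_image(c.image_ref), c.predicted_mask)
        rows.append(
            f'<div class="{tag}"><img src="data:image/png;base64,{b64}"/>'
            f"<p>{Path(c.image_ref).name} — score {c.quality_score:.3f} ({tag})</p></div>")
    html = ("<html><head><style>div{display:inline-block;margin:4px;padding:4px}"
            ".selected{border:3px solid green}.rejected{border:3px solid #999}"
            "</style></head><body><h1>Pseudo-label candidates</h1>"
            + "\n".join(rows) + "</body></html>")
    Path(path).write_text(html)


def select_candidates(candidates: list[PseudoCandidate],
                      criterion: SelectionCriterion, out_dir,
                      gallery: bool = True) -> DatasetManifest:
    """Write the selected image+predicted-mask pairs as a labeled manifest.

    Selection is deterministic: candidates are ranked by score with ties
    broken lexicographically by image path.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    criterion.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ranked = sorted(candidates, key=lambda c: (-c.quality_score, c.image_ref))
    if criterion.mode == "top_k":
        if criterion.k > len(candidates):
            raise ValueError(f"k={criterion.k} exceeds pool size {len(candidates)}")
        chosen = ranked[:criterion.k]
    elif criterion.mode == "score_threshold":
        chosen = [c for c in ranked if c.quality_score >= criterion.threshold]
        if not chosen:
            warnings.warn("score threshold selected no candidates")
    else:
        accepted = set(criterion.accepted_refs)
        chosen = [c for c in ranked if c.image_ref in accepted]
    manifest = DatasetManifest()
    for c in chosen:
        mpath = out_dir / (Path(c.image_ref).stem + "_pseudomask.png")
        write_mask(mpath, c.predicted_mask)
        manifest.append(c.image_ref, mpath, "train")
    manifest.to_csv(out_dir / "manifest.csv")
    if gallery:
        write_gallery(candidates, {c.image_ref for c in chosen},
                      out_dir / "gallery.html")
    return manifest
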