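"""Dice/IoU metrics, per-dataset evaluation, and comparison tables.

Dice = 2|A∩B| / (|A|+|B|), IoU (Jaccard) = |A∩B| / |A∪B| over predicted
and true foreground pixel sets; two empty masks score 1.0 under both (the
prediction is vacuously perfect).  Dataset scores are unweighted per-image
(macro) means.  Comparison tables report percentage-point deltas between a
later and an earlier model and IoU ratios between a final and a baseline
model, computed on stored (unrounded) precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imgio import read_image, read_mask, require_binary
from .manifest import DatasetManifest


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = require_binary(pred, "pred")
    truth = require_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"mask dims differ: {pred.shape} vs {truth.shape}")
    return pred.astype(bool), truth.astype(bool)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    p, t = _check_pair(pred, truth)
    total = int(p.sum()) + int(t.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((p & t).sum()) / total


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    p, t = _check_pair(pred, truth)
    union = int((p | t).sum())
    if union == 0:
        return 1.0
    return int((p & t).sum()) / union


@dataclass
class MetricsReport:
    """Per-(model, dataset) evaluation: macro-mean Dice and IoU."""
    model_id: str
    dataset_id: str
    per_image: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_images(self) -> int:
        return len(self.per_image)

    @property
    def mean_dice(self) -> float:
        return float(np.mean([d for d, _ in self.per_image]))

    @property
    def mean_iou(self) -> float:
        return float(np.mean([i for _, i in self.per_image]))

    @classmethod
    def from_means(cls, model_id: str, dataset_id: str,
                   mean_dice: float, mean_iou: float) -> "MetricsReport":
        """A single-entry report carrying externally reported mean scores."""
        return cls(model_id, dataset_id, [(float(mean_dice), float(mean_iou))])


def evaluate_model(model, test: DatasetManifest, threshold: float = 0.5,
                   model_id: str = "model", dataset_id: str = "test"
                   ) -> MetricsReport:
    """Per-image Dice/IoU of a segmenter over a labeled manifest."""
    from .segmentation import predict_mask   # local import avoids a cycle
    report = MetricsReport(model_id, dataset_id)
    for row in test:
        if not row.has_mask:
            raise ValueError(f"test row without mask: {row.image_path}")
        pred = predict_mask(model, read_image(row.image_path), threshold)
        truth = read_mask(row.mask_path)
        report.per_image.append((dice(pred, truth), iou(pred, truth)))
    return report


def _by_dataset(reports: list[MetricsReport]) -> dict[str, MetricsReport]:
    out = {}
    for r in reports:
        if r.dataset_id in out:
            raise ValueError(f"duplicate dataset_id {r.dataset_id!r}")
        out[r.dataset_id] = r
    return out


def delta_table(earlier: list[MetricsReport], later: list[MetricsReport]
                ) -> pd.DataFrame:
    """Percentage-point changes, later minus earlier, per dataset.

    Columns: dataset_id, dice_delta_pct, iou_delta_pct (unrounded;
    display rounding is render_report's job).
    """
    e, l = _by_dataset(earlier), _by_dataset(later)
    if set(e) != set(l):
        raise ValueError(f"dataset ids differ: {sorted(e)} vs {sorted(l)}")
    rows = [{"dataset_id": ds,
             "dice_delta_pct": 100.0 * (l[ds].mean_dice - e[ds].mean_dice),
             "iou_delta_pct": 100.0 * (l[ds].mean_iou - e[ds].mean_iou)}
            for ds in e]
    return pd.DataFrame(rows)


def ratio_table(baseline: list[MetricsReport], final: list[MetricsReport]
                ) -> pd.DataFrame:
    """IoU of the final model divided by IoU of the baseline, per dataset."""
    b, f = _by_dataset(baseline), _by_dataset(final)
    if set(b) != set(f):
        raise ValueError(f"dataset ids differ: {sorted(b)} vs {sorted(f)}")
    rows = []
    for ds in b:
        if b[ds].mean_iou == 0:
            raise ZeroDivisionError(f"baseline IoU is zero on {ds}")
        rows.append({"dataset_id": ds,
                     "iou_ratio": f[ds].mean_iou / b[ds].mean_iou})
    return pd.DataFrame(rows)


def render_report(reports: list[MetricsReport], out_prefix,
                  deltas: pd.DataFrame | None = None,
                  ratios: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write the results table as CSV and markdown.

    The CSV has columns model_id,dataset_id,mean_dice,mean_iou,n_images;
    the markdown table has one row per model and Dice/IoU columns per
    dataset (metrics shown to 3 decimals, deltas to 1, ratios to 3).
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame([
        {"model_id": r.model_id, "dataset_id": r.dataset_id,
         "mean_dice": r.mean_dice, "mean_iou": r.mean_iou,
         "n_images": r.n_images} for r in reports])
    csv_path = out_prefix.with_suffix(".csv")
    frame.to_csv(csv_path, index=False)

    models = list(dict.fromkeys(frame.model_id))
    datasets = list(dict.fromkeys(frame.dataset_id))
    lines = ["| Model | " + " | ".join(f"{d} Dice | {d} IoU" for d in datasets) + " |",
             "|" + "---|" * (1 + 2 * len(datasets))]
    for m in models:
        cells = []
        for d in datasets:
            sel = frame[(frame.model_id == m) & (frame.dataset_id == d)]
            if len(sel):
                cells += [f"{sel.mean_dice.iloc[0]:.3f}", f"{sel.mean_iou.iloc[0]:.3f}"]
            else:
                cells += ["-", "-"]
        lines.append("| " + m + " | " + " | ".join(cells) + " |")
    if deltas is not None and len(deltas):
        lines += ["", "Deltas (percentage points, later − earlier):", ""]
        for r in deltas.itertuples(index=False):
            lines.append(f"- {r.dataset_id}: Dice {r.dice_delta_pct:+.1f}, "
                         f"IoU {r.iou_delta_pct:+.1f}")
    if ratios is not None and len(ratios):
        lines += ["", "IoU ratios (final / baseline):", ""]
        for r in ratios.itertuples(index=False):
            lines.append(f"- {r.dataset_id}: {r.iou_ratio:.3f}")
    md_path = out_prefix.with_suffix(".md")
    md_path.write_text("\n".join(lines) + "\n")
    return {"csv": csv_path, "markdown": md_path}
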