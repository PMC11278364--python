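"""Dataset manifests: ordered CSV lists of (image_path, mask_path, split).

The manifest is the hand-off format between every pipeline stage.  A row
with an empty ``mask_path`` is an unlabeled image (the real-domain pool);
``split`` is free-form text, conventionally ``train``/``val``/``test``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

COLUMNS = ["image_path", "mask_path", "split"]


@dataclass
class ManifestRow:
    image_path: str
    mask_path: str = ""
    split: str = "train"

    @property
    def has_mask(self) -> bool:
        return bool(self.mask_path)


@dataclass
class DatasetManifest:
    rows: list[ManifestRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def append(self, image_path, mask_path="", split="train") -> None:
        self.rows.append(ManifestRow(str(image_path), str(mask_path), str(split)))

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest([r for r in self.rows if r.split == split])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.image_path, r.mask_path, r.split) for r in self.rows],
            columns=COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DatasetManifest":
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        rows = [ManifestRow(str(r.image_path),
                            "" if pd.isna(r.mask_path) else str(r.mask_path),
                            str(r.split))
                for r in df.itertuples(index=False)]
        return cls(rows)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False,
                                          dtype=str, na_values=[]))

    def validate_files_exist(self) -> None:
        for r in self.rows:
            if not Path(r.image_path).exists():
                raise FileNotFoundError(r.image_path)
            if r.mask_path and not Path(r.mask_path).exists():
                raise FileNotFoundError(r.mask_path)
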