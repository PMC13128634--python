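"""Seeded 2D cue masks.

Cues are the only manual input of the extraction pipeline: binary masks of
the target plant in 1-5 operator-selected views, stored with metadata
{image_id, view_index, mask_id, bbox}.  Masks are produced upstream (e.g.
by box-prompted zero-shot segmentation); here they are plain inputs.

On disk each cue is an 8-bit 0/255 PNG plus a JSON sidecar with the
metadata; a directory of such pairs forms a CueSet.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class CueEntry:
    image_id: str
    view_index: int
    mask_id: int
    bbox: tuple[float, float, float, float]  # (x0, y0, x1, y1) pixels
    mask: np.ndarray                          # (H, W) bool

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        x0, y0, x1, y1 = self.bbox
        h, w = self.mask.shape
        if not (0 <= x0 <= x1 <= w and 0 <= y0 <= y1 <= h):
            raise ValueError(f"bbox {self.bbox} outside {w}x{h} image")


@dataclass
class CueSet:
    entries: list[CueEntry]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("CueSet must contain at least one entry")

    @property
    def view_indices(self) -> list[int]:
        return sorted({e.view_index for e in self.entries})

    def combined_mask(self, view_index: int) -> np.ndarray | None:
        """OR-union of all masks for one view (fragments of one target)."""
        masks = [e.mask for e in self.entries if e.view_index == view_index]
        if not masks:
            return None
        out = masks[0].copy()
        for m in masks[1:]:
            out |= m
        return out

    def validate_against(self, views) -> None:
        by_index = {v.view_index: v for v in views}
        for e in self.entries:
            if e.view_index not in by_index:
                raise ValueError(f"cue references unknown view {e.view_index}")
            w, h = by_index[e.view_index].image_size
            if e.mask.shape != (h, w):
                raise ValueError(
                    f"mask shape {e.mask.shape} != view {e.view_index} size {(h, w)}")


def bbox_of_mask(mask: np.ndarray) -> tuple[float, float, float, float]:
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        return (0.0, 0.0, 0.0, 0.0)
    return (float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1))


def write_cues(directory, cues: CueSet) -> None:
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for e in cues.entries:
        stem = f"cue_v{e.view_index:03d}_m{e.mask_id:02d}"
        iio.imwrite(directory / f"{stem}.png", (e.mask.astype(np.uint8) * 255))
        with open(directory / f"{stem}.json", "w") as fh:
            json.dump({"image_id": e.image_id, "view_index": e.view_index,
                       "mask_id": e.mask_id, "bbox": list(e.bbox)}, fh)


def read_cues(directory) -> CueSet:
    import imageio.v3 as iio

    directory = Path(directory)
    entries = []
    for sidecar in sorted(directory.glob("*.json")):
        with open(sidecar) as fh:
            meta = json.load(fh)
        mask = iio.imread(sidecar.with_suffix(".png")) > 127
        if mask.ndim == 3:
            mask = mask[..., 0]
        entries.append(CueEntry(meta["image_id"], int(meta["view_index"]),
                                int(meta["mask_id"]), tuple(meta["bbox"]), mask))
    return CueSet(entries)
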