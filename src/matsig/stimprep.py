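"""Stimulus preparation: square context boxes around painting segments.

Each stimulus shown to raters is a square crop ("context box") around the
segment: side = round(1.25 x the larger bounding-box dimension), centred on
the segment's bounding box.  Where the box overflows the painting, the
overflow is filled with the mean RGB of the painting pixels inside the
clipped box, so the crop keeps a 1:1 aspect ratio.

Coordinates are 0-based with half-open boxes [r0, r1) x [c0, c1); rounding is
round-half-up.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

MARGIN_FACTOR = 1.25


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class BoxGeometry:
    """Square box in painting coordinates; may extend past the image bounds."""

    r0: int
    r1: int
    c0: int
    c1: int

    @property
    def side(self) -> int:
        return self.r1 - self.r0

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class SegmentMask:
    """Binary segment mask aligned to its painting."""

    mask: np.ndarray           # 2-D bool
    material: str | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("mask has no positive pixels")

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(r0, r1, c0, c1), half-open, of the segment's positive pixels."""
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


@dataclass
class ContextStimulus:
    """Rendered square crop plus its geometry and fill colour."""

    image: np.ndarray          # side x side x 3, uint8
    box: BoxGeometry
    fill_color: tuple[int, int, int]
    mask_crop: np.ndarray      # side x side bool, segment in crop coordinates


def context_box(mask: SegmentMask) -> BoxGeometry:
    """Square context box: side = round(1.25 x max(width, height)), centred on
    the segment's bounding-box centre.  The box may exceed the painting."""
    r0, r1, c0, c1 = mask.bounding_box()
    h, w = r1 - r0, c1 - c0
    side = _round_half_up(MARGIN_FACTOR * max(h, w))
    cr = (r0 + r1) / 2.0
    cc = (c0 + c1) / 2.0
    br0 = _round_half_up(cr - side / 2.0)
    bc0 = _round_half_up(cc - side / 2.0)
    return BoxGeometry(br0, br0 + side, bc0, bc0 + side)


def render_stimulus(painting: np.ndarray, mask: SegmentMask,
                    box: BoxGeometry | None = None) -> ContextStimulus:
    """Render the square stimulus crop for a segment.

    Pixels of the box that lie inside the painting are copied; overflow pixels
    are filled with the per-channel mean RGB over painting ∩ box.
    """
    painting = np.asarray(painting)
    if painting.ndim == 2:
        painting = np.stack([painting] * 3, axis=-1)
    if painting.shape[:2] != mask.mask.shape:
        raise ValueError("painting and mask dimensions differ")
    if box is None:
        box = context_box(mask)
    H, W = painting.shape[:2]
    ir0, ir1 = max(box.r0, 0), min(box.r1, H)
    ic0, ic1 = max(box.c0, 0), min(box.c1, W)
    if ir0 >= ir1 or ic0 >= ic1:
        raise ValueError("context box does not intersect the painting")

    inside = painting[ir0:ir1, ic0:ic1].astype(np.float64)
    fill = inside.reshape(-1, inside.shape[-1]).mean(axis=0)
    fill_u8 = tuple(int(_round_half_up(v)) for v in fill)

    crop = np.empty((box.side, box.side, 3), dtype=np.uint8)
    crop[...] = np.array(fill_u8, dtype=np.uint8)
    # paste the painting part into crop coordinates
    dr0, dc0 = ir0 - box.r0, ic0 - box.c0
    crop[dr0:dr0 + (ir1 - ir0), dc0:dc0 + (ic1 - ic0)] = painting[ir0:ir1, ic0:ic1]

    mask_crop = np.zeros((box.side, box.side), dtype=bool)
    mask_crop[dr0:dr0 + (ir1 - ir0), dc0:dc0 + (ic1 - ic0)] = mask.mask[ir0:ir1, ic0:ic1]
    return ContextStimulus(image=crop, box=box, fill_color=fill_u8, mask_crop=mask_crop)


def overflow_area(box: BoxGeometry, image_shape: tuple[int, int]) -> int:
    """Number of box pixels falling outside an image of the given (H, W)."""
    H, W = image_shape
    ov_h = max(box.r0, 0), min(box.r1, H)
    ov_w = max(box.c0, 0), min(box.c1, W)
    overlap = max(0, ov_h[1] - ov_h[0]) * max(0, ov_w[1] - ov_w[0])
    return box.side * box.side - overlap
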