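"""Center / Pizhang region-of-interest partition of a segmented block.

The block is located by the minimum (axis-aligned) bounding rectangle of
the foreground mask.  A fixed-size rectangle centered on the bounding
rectangle's center is the *center ROI* — nominally 200x500 px (width x
height) for the layer-1 task and 120x500 px for layer-2, defined at the
native 6000x4000 capture resolution and scaled linearly to the working
resolution.  Foreground outside the center rectangle is the *Pizhang ROI*
(the raw starchy rim whose thickness is a grading cue).

Coordinates are 0-based, row-major, half-open.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

NATIVE_SIZE = (4000, 6000)  # (H, W) of the capture rig

# nominal (height, width) of the center rectangle at native resolution
CENTER_NOMINAL = {"L1": (500, 200), "L2": (500, 120)}


class Layer(str, enum.Enum):
    """Classification layer: L1 = {P,F} vs S, L2 = P vs F."""

    L1 = "L1"
    L2 = "L2"


def _as_layer(layer) -> Layer:
    if isinstance(layer, Layer):
        return layer
    return Layer(str(layer))


class Rect(NamedTuple):
    """Axis-aligned rectangle: 0-based, half-open [row0, row0+height) etc."""

    row0: int
    col0: int
    height: int
    width: int

    @property
    def area(self) -> int:
        return self.height * self.width

    @property
    def center(self) -> tuple[float, float]:
        return (self.row0 + self.height / 2.0, self.col0 + self.width / 2.0)

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.height),
                slice(self.col0, self.col0 + self.width))


@dataclass
class RoiPartition:
    bounding_rect: Rect
    center_rect: Rect
    center_mask: np.ndarray    # bool, foreground inside the center rectangle
    pizhang_mask: np.ndarray   # bool, foreground outside it
    layer: Layer
    pizhang_empty: bool = False


def min_bounding_rect(mask: np.ndarray) -> Rect:
    """Smallest axis-aligned rectangle containing all foreground pixels."""
    mask = np.asarray(mask, dtype=bool)
    rows = np.any(mask, axis=1)
    if not rows.any():
        raise ValueError("mask is empty; cannot compute a bounding rectangle")
    cols = np.any(mask, axis=0)
    r = np.flatnonzero(rows)
    c = np.flatnonzero(cols)
    return Rect(int(r[0]), int(c[0]), int(r[-1] - r[0] + 1), int(c[-1] - c[0] + 1))


def default_scale(shape: tuple[int, int]) -> float:
    """Working-resolution / native-resolution scale for an image shape."""
    return min(shape[0] / NATIVE_SIZE[0], shape[1] / NATIVE_SIZE[1])


def _round_even(x: float) -> int:
    return max(2 * int(round(x / 2.0)), 0)


def extract_center_roi(mask: np.ndarray, layer, scale: float | None = None) -> Rect:
    """Center rectangle for the given layer, scaled and clipped to the block.

    The nominal rectangle (200x500 or 120x500, width x height, at native
    resolution) is multiplied by ``scale``, rounded to the nearest even
    integer per dimension, centered at the bounding rectangle's center, and
    clipped to the bounding rectangle.
    """
    layer = _as_layer(layer)
    mask = np.asarray(mask, dtype=bool)
    if scale is None:
        scale = default_scale(mask.shape)
    if scale <= 0:
        raise ValueError("scale must be positive")
    bounding = min_bounding_rect(mask)
    nom_h, nom_w = CENTER_NOMINAL[layer.value]
    ch = _round_even(nom_h * scale)
    cw = _round_even(nom_w * scale)
    if ch == 0 or cw == 0:
        raise ValueError(f"scale {scale} makes the center rectangle degenerate")
    cr, cc = bounding.center
    r0 = int(round(cr - ch / 2.0))
    c0 = int(round(cc - cw / 2.0))
    # clip to the bounding rectangle
    r0 = max(r0, bounding.row0)
    c0 = max(c0, bounding.col0)
    r1 = min(r0 + ch, bounding.row0 + bounding.height)
    c1 = min(c0 + cw, bounding.col0 + bounding.width)
    if r1 <= r0 or c1 <= c0:
        raise ValueError("clipped center rectangle is degenerate")
    return Rect(r0, c0, r1 - r0, c1 - c0)


def partition(mask: np.ndarray, layer, scale: float | None = None) -> RoiPartition:
    """Split foreground into center and Pizhang masks (disjoint, exhaustive)."""
    layer = _as_layer(layer)
    mask = np.asarray(mask, dtype=bool)
    bounding = min_bounding_rect(mask)
    center_rect = extract_center_roi(mask, layer, scale)
    in_rect = np.zeros_like(mask)
    in_rect[center_rect.slices()] = True
    center_mask = mask & in_rect
    pizhang_mask = mask & ~in_rect
    return RoiPartition(
        bounding_rect=bounding,
        center_rect=center_rect,
        center_mask=center_mask,
        pizhang_mask=pizhang_mask,
        layer=layer,
        pizhang_empty=not bool(pizhang_mask.any()),
    )
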