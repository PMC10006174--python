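"""Back-projection of pixel class labels onto the tissue raster.

Each classified pixel is painted with its class color at its original
(row, column) position — no resampling, so the 1 px = 1 µm acquisition
raster is preserved. The renderer displays at most 9 classes with unique
colors; background pixels show either a flat background color or a
grayscale base channel (percentile-clipped, min-max scaled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gating import MAX_RENDERED_CLASSES, PixelClusterLabeling
from .preprocess import percentile_threshold


class PaletteCapacityError(ValueError):
    """More classes than the palette can display."""


@dataclass(frozen=True)
class Palette:
    """Ordered class colors (≤ 9) plus a background color, all distinct."""

    colors: tuple[tuple[int, int, int], ...]
    background: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if len(self.colors) > MAX_RENDERED_CLASSES:
            raise ValueError(
                f"palette holds at most {MAX_RENDERED_CLASSES} class colors"
            )
        all_colors = (*self.colors, self.background)
        if len(set(all_colors)) != len(all_colors):
            raise ValueError("palette colors (incl. background) must be distinct")

    def __len__(self) -> int:
        return len(self.colors)


# Nine maximally-distinct qualitative colors, fixed so figures reproduce
# across runs; background is black.
DEFAULT_PALETTE = Palette(
    colors=(
        (230, 25, 75),    # red
        (60, 180, 75),    # green
        (0, 130, 200),    # blue
        (255, 225, 25),   # yellow
        (245, 130, 48),   # orange
        (145, 30, 180),   # purple
        (70, 240, 240),   # cyan
        (240, 50, 230),   # magenta
        (255, 255, 255),  # white
    )
)


def backproject(
    labeling: PixelClusterLabeling,
    palette: Palette = DEFAULT_PALETTE,
    base: np.ndarray | None = None,
    base_percentile: float = 98.0,
) -> np.ndarray:
    """Paint class labels as an H×W×3 byte overlay at original resolution.

    Named classes (excluding "unassigned") are colored in ascending label
    order; background (and unassigned) pixels show the grayscale ``base``
    channel when given, else the palette's background color. Raises
    :class:`PaletteCapacityError` beyond the palette capacity — merge or
    drop classes to get at or under 9.
    """
    rendered = labeling.rendered_class_names()
    if len(rendered) > len(palette):
        raise PaletteCapacityError(
            f"{len(rendered)} classes exceed the {len(palette)}-color palette; "
            "merge or drop classes to display at most "
            f"{len(palette)} cell types"
        )
    h, w = labeling.label_map.shape
    out = np.empty((h, w, 3), dtype=np.uint8)
    if base is not None:
        base = np.asarray(base, dtype=np.float64)
        if base.shape != (h, w):
            raise ValueError(
                f"base channel shape {base.shape} != label map shape {(h, w)}"
            )
        _, clipped = percentile_threshold(base, base_percentile)
        lo, hi = clipped.min(), clipped.max()
        gray = (
            np.zeros((h, w), dtype=np.uint8)
            if hi <= lo
            else np.round((clipped - lo) / (hi - lo) * 255).astype(np.uint8)
        )
        out[:] = gray[:, :, None]
    else:
        out[:] = np.array(palette.background, dtype=np.uint8)

    for i, label in enumerate(sorted(rendered)):
        out[labeling.label_map == label] = palette.colors[i]
    return out


def invert_overlay(
    overlay: np.ndarray, labeling: PixelClusterLabeling, palette: Palette
) -> np.ndarray:
    """Map overlay colors back to class labels (inverse of backproject).

    Only meaningful for overlays rendered without a base channel.
    """
    rendered = sorted(labeling.rendered_class_names())
    out = np.zeros(overlay.shape[:2], dtype=np.int32)
    for i, label in enumerate(rendered):
        match = np.all(overlay == np.array(palette.colors[i], np.uint8), axis=2)
        out[match] = label
    return out
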