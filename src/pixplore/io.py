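"""Raster and table I/O for multiplexed tissue images.

Imaging mass cytometry (IMC) acquisitions arrive as multichannel TIFFs —
one intensity plane per metal-tagged antibody — accompanied by a marker
panel table mapping channel order to marker names. Regions of interest
(ROIs) for quantification are exchanged as integer label-mask TIFFs plus a
small text table tagging each label with a name and a group (e.g. "LF" for
lymphoid follicle vs "non-LF" control areas).

Conventions: pixel coordinates are 0-based, origin top-left, (row, column)
order; 1 pixel corresponds to 1 µm unless overridden.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile


class FormatError(ValueError):
    """Raised when a file's structure does not match what was declared."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerPanel:
    """Ordered binding of image channels to metal tags and marker names.

    Parameters
    ----------
    entries
        Sequence of ``(channel_index, metal_tag, marker_name)`` with
        0-based, contiguous, unique channel indices and unique marker names.
    """

    entries: tuple[tuple[int, str, str], ...]

    def __post_init__(self) -> None:
        idx = [e[0] for e in self.entries]
        if sorted(idx) != list(range(len(idx))):
            raise ValueError(
                f"channel indices must be unique and contiguous from 0, got {idx}"
            )
        names = [e[2] for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError(f"marker names must be unique, got {names}")
        object.__setattr__(
            self, "entries", tuple(sorted(self.entries, key=lambda e: e[0]))
        )

    @classmethod
    def from_markers(cls, markers: Sequence[str]) -> "MarkerPanel":
        """Panel with synthetic metal tags, one channel per marker in order."""
        return cls(tuple((i, f"M{i}", m) for i, m in enumerate(markers)))

    @property
    def marker_names(self) -> list[str]:
        return [e[2] for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def index_of(self, marker: str) -> int:
        for i, _, name in self.entries:
            if name == marker:
                return i
        raise KeyError(f"marker {marker!r} not in panel {self.marker_names}")


@dataclass
class ChannelStack:
    """C×H×W non-negative intensity raster bound to a marker panel.

    ``pixel_size`` is the physical edge length of one pixel in µm; IMC
    acquires at 1 µm.
    """

    data: np.ndarray
    panel: MarkerPanel
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected C×H×W data, got shape {self.data.shape}")
        c, h, w = self.data.shape
        if c != len(self.panel):
            raise ValueError(
                f"channel count {c} does not match panel length {len(self.panel)}"
            )
        if h < 1 or w < 1:
            raise ValueError("image must have at least one pixel")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def channel(self, marker: str) -> np.ndarray:
        """H×W view of one marker's intensity plane."""
        return self.data[self.panel.index_of(marker)]


@dataclass
class Roi:
    name: str
    mask: np.ndarray
    group: str


@dataclass
class RoiSet:
    """Named, group-tagged boolean region masks over one image raster."""

    regions: list[Roi] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError(f"ROI names must be unique, got {names}")
        shapes = {r.mask.shape for r in self.regions}
        if len(shapes) > 1:
            raise ValueError(f"ROI masks disagree on image dimensions: {shapes}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def by_group(self, group: str) -> list[Roi]:
        return [r for r in self.regions if r.group == group]

    def get(self, name: str) -> Roi:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"no ROI named {name!r}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_panel(path: str | Path) -> MarkerPanel:
    """Read a panel table (CSV/TSV: channel_index, metal_tag, marker_name)."""
    path = Path(path)
    entries = []
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or "marker_name" not in reader.fieldnames:
            raise FormatError(
                f"{path}: expected columns channel_index, metal_tag, marker_name"
            )
        for row in reader:
            entries.append(
                (int(row["channel_index"]), row["metal_tag"], row["marker_name"])
            )
    return MarkerPanel(tuple(entries))


def write_panel(path: str | Path, panel: MarkerPanel) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["channel_index", "metal_tag", "marker_name"])
        w.writerows(panel.entries)


def read_multichannel_tiff(path: str | Path, panel: MarkerPanel) -> ChannelStack:
    """Read a multi-page or interleaved multichannel TIFF as a ChannelStack.

    Accepts both plane-per-page stacks and a single page with a leading
    channel axis. Integer pixel data are promoted to float64; channel order
    follows the panel.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"{path} is not a readable TIFF: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected 2-D or 3-D TIFF, got shape {arr.shape}")
    # Heuristic for H×W×C pages written by generic tools: channel axis last
    # and small. Plane-per-page exports are already C×H×W.
    if arr.shape[0] != len(panel) and arr.shape[2] == len(panel):
        arr = np.moveaxis(arr, 2, 0)
    if arr.shape[0] != len(panel):
        raise FormatError(
            f"{path}: file has {arr.shape[0]} channels but panel declares "
            f"{len(panel)}"
        )
    return ChannelStack(arr.astype(np.float64), panel)


def write_multichannel_tiff(path: str | Path, stack: ChannelStack) -> None:
    """Write plane-per-page float32 TIFF (lossless for IMC count ranges)."""
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")


def read_group_table(path: str | Path) -> dict[int, tuple[str, str]]:
    """Read a label→(name, group) table (CSV/TSV: label, name, group)."""
    table: dict[int, tuple[str, str]] = {}
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        for row in csv.DictReader(fh, delimiter=delim):
            table[int(row["label"])] = (row["name"], row["group"])
    return table


def write_group_table(path: str | Path, table: dict[int, tuple[str, str]]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "name", "group"])
        for label, (name, group) in sorted(table.items()):
            w.writerow([label, name, group])


def read_roi_mask(
    path: str | Path, group_table: dict[int, tuple[str, str]]
) -> RoiSet:
    """Turn an integer label-mask TIFF into a RoiSet.

    Every nonzero label in the image must appear in ``group_table``
    (label → (name, group)); one disjoint boolean region per label.
    """
    labels = np.asarray(tifffile.imread(Path(path)))
    if labels.ndim != 2:
        raise FormatError(f"{path}: ROI mask must be a single-plane label image")
    if not np.issubdtype(labels.dtype, np.integer):
        raise FormatError(f"{path}: ROI mask must be integer-typed, got {labels.dtype}")
    present = [int(v) for v in np.unique(labels) if v != 0]
    missing = [v for v in present if v not in group_table]
    if missing:
        raise FormatError(
            f"{path}: labels {missing} present in mask but absent from group table"
        )
    regions = [
        Roi(name=group_table[v][0], mask=(labels == v), group=group_table[v][1])
        for v in present
    ]
    return RoiSet(regions)


def write_roi_mask(
    path: str | Path, roi_set: RoiSet, shape: tuple[int, int] | None = None
) -> None:
    """Write a RoiSet as a label-mask TIFF (labels 1..n in region order)."""
    if shape is None:
        if not roi_set.regions:
            raise ValueError("cannot infer image shape from an empty RoiSet")
        shape = roi_set.regions[0].mask.shape
    labels = np.zeros(shape, dtype=np.uint16)
    for i, roi in enumerate(roi_set, start=1):
        labels[roi.mask] = i
    tifffile.imwrite(path, labels)


def write_overlay(path: str | Path, rgb_image: np.ndarray) -> None:
    """Write an H×W×3 byte raster losslessly (PNG or uncompressed TIFF)."""
    import imageio.v3 as iio

    rgb_image = np.asarray(rgb_image)
    if rgb_image.ndim != 3 or rgb_image.shape[2] != 3:
        raise ValueError(f"expected H×W×3 raster, got shape {rgb_image.shape}")
    rgb_image = rgb_image.astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, rgb_image, photometric="rgb")
    else:
        iio.imwrite(path, rgb_image, extension=path.suffix or ".png")


def read_overlay(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(Path(path)))[..., :3]
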