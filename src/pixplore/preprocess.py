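"""Intensity normalization and pixel-table construction.

Raw IMC counts are heavy-tailed; the standard cytometry variance
stabilizer is the inverse hyperbolic sine with a cofactor, asinh(x / c),
applied here with c = 5 by default. Before the transform each channel is
clipped at a maximum-signal threshold, the 98th percentile of all pixels
in the ROI (linear-interpolation order-statistic convention), which tames
hot pixels without rescaling the bulk of the signal.

``flatten`` turns a ChannelStack into the N×M pixels-by-markers matrix the
embedding stages consume, keeping (row, column) coordinates so any result
can be scattered back onto the tissue raster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import ChannelStack

DEFAULT_COFACTOR = 5.0
DEFAULT_PERCENTILE = 98.0


@dataclass
class PixelTable:
    """Pixels × markers matrix of transformed intensities.

    ``coords`` holds 0-based (row, column) pixel coordinates aligned
    row-wise with ``values`` so tables are invertible back to the raster.
    """

    values: np.ndarray
    coords: np.ndarray
    marker_names: list[str]
    source_roi: str | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.int64))
        if self.values.shape[0] != self.coords.shape[0]:
            raise ValueError("values and coords disagree on pixel count")
        if self.coords.shape[1] != 2:
            raise ValueError("coords must be (row, column) pairs")
        if self.values.shape[1] != len(self.marker_names):
            raise ValueError("marker_names length must match value columns")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    def column(self, marker: str) -> np.ndarray:
        return self.values[:, self.marker_names.index(marker)]

    def subset(self, row_indices: np.ndarray) -> "PixelTable":
        return PixelTable(
            values=self.values[row_indices],
            coords=self.coords[row_indices],
            marker_names=list(self.marker_names),
            source_roi=self.source_roi,
        )

    def scatter(self, shape: tuple[int, int], marker: str) -> np.ndarray:
        """Paint one marker column back onto an H×W raster (zeros elsewhere)."""
        out = np.zeros(shape)
        out[self.coords[:, 0], self.coords[:, 1]] = self.column(marker)
        return out


def save_table(path, table: PixelTable, config_hash: str = "") -> None:
    """Persist a PixelTable to a .npz container (with provenance hash)."""
    np.savez_compressed(
        path,
        format=np.array("pixplore-table-1"),
        config_hash=np.array(config_hash),
        values=table.values,
        coords=table.coords,
        marker_names=np.array(table.marker_names),
        source_roi=np.array(table.source_roi or ""),
    )


def load_table(path) -> tuple[PixelTable, str]:
    """Load a PixelTable; returns (table, config_hash)."""
    with np.load(path, allow_pickle=False) as z:
        if str(z["format"]) != "pixplore-table-1":
            raise ValueError(f"unsupported table container: {z['format']}")
        table = PixelTable(
            values=z["values"],
            coords=z["coords"],
            marker_names=[str(m) for m in z["marker_names"]],
            source_roi=str(z["source_roi"]) or None,
        )
        return table, str(z["config_hash"])


def arcsinh_transform(values, cofactor: float = DEFAULT_COFACTOR) -> np.ndarray:
    """Elementwise asinh(value / cofactor).

    Strictly monotone, maps 0 to 0, and approaches the identity as the
    cofactor grows; the default cofactor of 5 matches common practice for
    mass-cytometry counts.
    """
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return np.arcsinh(np.asarray(values, dtype=np.float64) / cofactor)


def percentile_threshold(
    channel: np.ndarray, q: float = DEFAULT_PERCENTILE
) -> tuple[float, np.ndarray]:
    """Clip a channel at its q-th percentile (maximum-signal threshold).

    The threshold is the linearly interpolated order statistic over all
    pixels of the channel; the returned channel is ``min(channel,
    threshold)``. Idempotent: clipping a clipped channel is a no-op.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.size == 0:
        raise ValueError("channel must be non-empty")
    if not 0.0 < q <= 100.0:
        raise ValueError(f"percentile must be in (0, 100], got {q}")
    threshold = float(np.percentile(channel, q, method="linear"))
    return threshold, np.minimum(channel, threshold)


def flatten(
    stack: ChannelStack,
    markers: Sequence[str] | None = None,
    mask: np.ndarray | None = None,
    cofactor: float = DEFAULT_COFACTOR,
    percentile: float | None = DEFAULT_PERCENTILE,
    source_roi: str | None = None,
) -> PixelTable:
    """Flatten selected channels/pixels into a transformed PixelTable.

    Per channel, raw counts are first clipped at the ``percentile``
    threshold computed over the masked pixels (pass ``None`` to skip
    clipping), then arcsinh-transformed. Rows follow row-major raster
    order over the selected pixels.
    """
    if markers is None:
        markers = stack.panel.marker_names
    unknown = [m for m in markers if m not in stack.panel.marker_names]
    if unknown:
        raise ValueError(f"unknown marker name(s): {unknown}")

    _, h, w = stack.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (h, w):
            raise ValueError(
                f"mask shape {mask.shape} does not match image shape {(h, w)}"
            )

    rows, cols = np.nonzero(mask)  # row-major order
    columns = []
    for m in markers:
        raw = stack.channel(m)[rows, cols]
        if percentile is not None and raw.size:
            _, raw = percentile_threshold(raw, percentile)
        columns.append(arcsinh_transform(raw, cofactor))
    values = (
        np.column_stack(columns) if columns else np.empty((rows.size, 0))
    )
    return PixelTable(
        values=values,
        coords=np.column_stack([rows, cols]),
        marker_names=list(markers),
        source_roi=source_roi,
    )
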