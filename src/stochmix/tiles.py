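"""Segmentation-free coarse-grained image quantification.

Large optical fields of confluent cells are partitioned into square tiles
(default ~50 μm, sized to hold a few cells each); each tile becomes an
effective "pixel" carrying the mean fluorescence of its real pixels.  The
only segmentation-like step is the exclusion of large lacunae — cell-free
regions — identified by thresholding a reference channel's tile means.
Local cell density is read out as the fraction of cell-covered area inside
a sliding square window (default area 10^4 μm²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .simulate import ImageField

__all__ = [
    "TileGrid",
    "DensityMap",
    "make_tiles",
    "lacunae_mask",
    "cell_density",
    "EmptyFieldError",
]

DEFAULT_TILE_UM = 50.0
DEFAULT_DENSITY_AREA_UM2 = 1.0e4


class EmptyFieldError(ValueError):
    """Raised when lacunae exclusion invalidates every tile."""


@dataclass
class TileGrid:
    """Coarse-grained image: per-tile channel means plus bookkeeping.

    ``means`` has shape ``(n_channels, n_rows, n_cols)``; ``pixel_count``
    and the boolean ``valid`` / ``partial`` masks are per tile.  Tile
    ``(0, 0)`` covers the top-left corner of the image; edge tiles may be
    partial (averaged over the pixels they do have).
    """

    tile_size: float
    tile_px: int
    pixel_size: float
    channels: list[str]
    means: np.ndarray
    pixel_count: np.ndarray
    valid: np.ndarray
    partial: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_rows(self) -> int:
        return self.means.shape[1]

    @property
    def n_cols(self) -> int:
        return self.means.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """Tile means of one channel; invalid tiles are NaN."""
        m = self.means[self.channels.index(name)].copy()
        m[~self.valid] = np.nan
        return m

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: row, col, valid, pixels, <channel>_mean."""
        rr, cc = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        out = pd.DataFrame(
            {
                "row": rr.ravel(),
                "col": cc.ravel(),
                "valid": self.valid.ravel(),
                "pixels": self.pixel_count.ravel(),
            }
        )
        for k, ch in enumerate(self.channels):
            col = self.means[k].ravel().copy()
            col[~self.valid.ravel()] = np.nan
            out[f"{ch}_mean"] = col
        return out


@dataclass
class DensityMap:
    """Fraction of cell-covered area per square window, values in [0, 1]."""

    square_size: float
    fraction_covered: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fraction_covered)
        if f.size and (f.min() < 0 or f.max() > 1):
            raise ValueError("covered fractions must lie in [0, 1]")
        self.fraction_covered = f


def _block_sums(a: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-block sums and pixel counts with partial edge blocks retained."""
    rows, cols = a.shape
    r_edges = np.arange(0, rows, size)
    c_edges = np.arange(0, cols, size)
    sums = np.add.reduceat(np.add.reduceat(a, r_edges, axis=0), c_edges, axis=1)
    rc = np.diff(np.append(r_edges, rows))
    cc = np.diff(np.append(c_edges, cols))
    counts = np.outer(rc, cc)
    return sums, counts


def make_tiles(image: ImageField, tile_size: float = DEFAULT_TILE_UM) -> TileGrid:
    """Partition the image into square tiles and average each channel.

    ``tile_size`` is in micrometres and is converted to whole pixels by
    flooring; a tile larger than the image degrades to a single tile with a
    warning.  Every pixel belongs to exactly one tile; edge tiles may hold
    fewer pixels and are flagged ``partial``.
    """
    tile_px = int(tile_size / image.pixel_size)
    if tile_px < 1:
        raise ValueError("tile_size must be at least one pixel")
    rows, cols = image.shape
    if tile_px > max(rows, cols):
        warnings.warn("tile larger than image; using a single tile", stacklevel=2)
        tile_px = max(rows, cols)
    sums = []
    counts = None
    for k in range(image.data.shape[0]):
        s, counts = _block_sums(image.data[k].astype(np.float64), tile_px)
        sums.append(s)
    means = np.stack(sums) / counts
    full = tile_px * tile_px
    partial = counts < full
    return TileGrid(
        tile_size=tile_px * image.pixel_size,
        tile_px=tile_px,
        pixel_size=image.pixel_size,
        channels=list(image.channels),
        means=means,
        pixel_count=counts,
        valid=np.ones_like(counts, dtype=bool),
        partial=partial,
    )


def lacunae_mask(
    tiles: TileGrid | ImageField,
    reference_channel: str,
    method: str = "quantile",
    threshold: float = 0.05,
    tile_size: float = DEFAULT_TILE_UM,
) -> TileGrid:
    """Invalidate cell-free tiles by thresholding a reference channel.

    Accepts either a :class:`TileGrid` or a raw :class:`ImageField`
    (tiled at ``tile_size`` first).

    Methods: ``"absolute"`` (tiles with mean < ``threshold`` a.u. are
    lacunae), ``"quantile"`` (threshold at the given quantile of the
    tile-mean distribution), ``"otsu"`` (automatic bimodal split; the
    ``threshold`` argument is ignored).  Re-application with the same
    parameters is idempotent.  Returns a new grid; raises
    :class:`EmptyFieldError` if nothing survives.
    """
    if isinstance(tiles, ImageField):
        tiles = make_tiles(tiles, tile_size)
    ref = tiles.means[tiles.channels.index(reference_channel)]
    if method == "absolute":
        cut = threshold
    elif method == "quantile":
        cut = float(np.quantile(ref[tiles.valid], threshold))
    elif method == "otsu":
        vals = ref[tiles.valid]
        cut = float(threshold_otsu(vals)) if np.ptp(vals) > 0 else -np.inf
    else:
        raise ValueError(f"unknown lacunae method {method!r}")
    new_valid = tiles.valid & (ref >= cut)
    if not new_valid.any():
        raise EmptyFieldError("lacunae exclusion removed every tile")
    return TileGrid(
        tile_size=tiles.tile_size,
        tile_px=tiles.tile_px,
        pixel_size=tiles.pixel_size,
        channels=tiles.channels,
        means=tiles.means,
        pixel_count=tiles.pixel_count,
        valid=new_valid,
        partial=tiles.partial,
    )


def cell_density(
    occupancy: np.ndarray,
    pixel_size: float,
    square_area: float = DEFAULT_DENSITY_AREA_UM2,
) -> DensityMap:
    """Fraction of cell-covered area per square window.

    ``occupancy`` is a boolean pixel raster (from bright-field thresholding,
    external segmentation, or the simulator's ground truth); the window is a
    square of area ``square_area`` μm² (default 10^4 μm², i.e. 100×100 μm),
    tiled without overlap.
    """
    occ = np.asarray(occupancy, dtype=bool)
    side_um = float(np.sqrt(square_area))
    side_px = int(side_um / pixel_size)
    if side_px < 1:
        raise ValueError("density window smaller than one pixel")
    sums, counts = _block_sums(occ.astype(np.float64), side_px)
    return DensityMap(square_size=side_um, fraction_covered=sums / counts)
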