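"""Deterministic tiling of large frames and patch grids with exact inverses.

A raw UAV frame (3000x4000 px in the motivating acquisition) is first cut
into non-overlapping ``tile_size`` x ``tile_size`` subimages (default 1000,
so a 3000x4000 frame yields a 3x4 grid); remainder pixels past the last
full tile are dropped.  Each subimage is then decomposed into a grid of
``patch_size`` x ``patch_size`` classification patches (default 128).

1000 is not a multiple of 128, so the patch grid supports two edge modes:

``"flush"`` (default)
    the final row/column of patches is shifted inward so its far edge lies
    on the image border; neighbouring patches may then overlap by up to
    ``patch_size - 1`` pixels, and the union of patches covers every pixel.

``"drop"``
    the remainder strip is simply not covered.

All grids enumerate row-major from the top-left; ``map_to_source``
translates patch/tile-local boxes back into source-frame coordinates so
that crop-then-map is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

from .geometry import Box

__all__ = [
    "TileGrid",
    "PatchGrid",
    "tile_image",
    "patch_grid",
    "map_to_source",
    "extract_positive_patches",
    "extract_negative_patches",
]


@dataclass(frozen=True)
class TileGrid:
    """Non-overlapping decomposition of a source frame into square tiles."""

    source_width: int
    source_height: int
    tile_size: int
    tiles: tuple[tuple[int, int, int, int], ...]  # (row, col, origin_x, origin_y)

    @property
    def n_rows(self) -> int:
        return self.source_height // self.tile_size

    @property
    def n_cols(self) -> int:
        return self.source_width // self.tile_size

    def __len__(self) -> int:
        return len(self.tiles)

    def origin(self, tile_index: int) -> tuple[int, int]:
        _, _, ox, oy = self.tiles[tile_index]
        return ox, oy

    def tile_box(self, tile_index: int) -> Box:
        ox, oy = self.origin(tile_index)
        return Box(ox, oy, ox + self.tile_size, oy + self.tile_size)


@dataclass(frozen=True)
class PatchGrid(TileGrid):
    """Patch decomposition of a subimage; see module docstring for edge modes."""

    edge_mode: str = "flush"


def _axis_offsets(extent: int, size: int, edge_mode: str) -> list[int]:
    offsets = list(range(0, extent - size + 1, size))
    if edge_mode == "flush" and offsets[-1] + size < extent:
        offsets.append(extent - size)
    return offsets


def tile_image(
    image: np.ndarray, tile_size: int = 1000
) -> tuple[TileGrid, list[np.ndarray]]:
    """Cut ``image`` into non-overlapping square tiles, row-major.

    Returns the grid plus a list of tile pixel arrays (copies).  Remainder
    rows/columns that do not fill a whole tile are dropped.
    """
    h, w = image.shape[:2]
    if h < tile_size or w < tile_size:
        raise ValueError(f"image {h}x{w} smaller than tile_size {tile_size}")
    tiles = []
    subimages = []
    for r in range(h // tile_size):
        for c in range(w // tile_size):
            ox, oy = c * tile_size, r * tile_size
            tiles.append((r, c, ox, oy))
            subimages.append(image[oy : oy + tile_size, ox : ox + tile_size].copy())
    return TileGrid(w, h, tile_size, tuple(tiles)), subimages


def patch_grid(
    subimage_shape: tuple[int, ...] | np.ndarray,
    patch_size: int = 128,
    edge_mode: str = "flush",
) -> PatchGrid:
    """Build the patch grid of a subimage (pass the array or its shape)."""
    if isinstance(subimage_shape, np.ndarray):
        subimage_shape = subimage_shape.shape
    h, w = int(subimage_shape[0]), int(subimage_shape[1])
    if h < patch_size or w < patch_size:
        raise ValueError(f"subimage {h}x{w} smaller than patch_size {patch_size}")
    if edge_mode not in ("flush", "drop"):
        raise ValueError(f"edge_mode must be 'flush' or 'drop', got {edge_mode!r}")
    ys = _axis_offsets(h, patch_size, edge_mode)
    xs = _axis_offsets(w, patch_size, edge_mode)
    tiles = tuple(
        (r, c, ox, oy) for r, oy in enumerate(ys) for c, ox in enumerate(xs)
    )
    return PatchGrid(w, h, patch_size, tiles, edge_mode)


def iter_patches(
    image: np.ndarray, grid: PatchGrid
) -> Iterator[tuple[int, Box, np.ndarray]]:
    """Yield ``(index, box, pixels)`` for every patch of ``grid`` in order."""
    s = grid.tile_size
    for i, (_, _, ox, oy) in enumerate(grid.tiles):
        yield i, Box(ox, oy, ox + s, oy + s), image[oy : oy + s, ox : ox + s]


def map_to_source(grid: TileGrid, local_box: Box, tile_index: int) -> Box:
    """Translate a tile-local box into source-frame coordinates."""
    s = grid.tile_size
    if not (
        0 <= local_box.xmin
        and local_box.xmax <= s
        and 0 <= local_box.ymin
        and local_box.ymax <= s
    ):
        raise ValueError(f"local box {local_box} exceeds tile bounds 0..{s}")
    ox, oy = grid.origin(tile_index)
    return local_box.translate(ox, oy)


def _centered_window(lo: float, hi: float, size: int, extent: int) -> int:
    """Start of a size-wide window centered on [lo, hi), clamped in-bounds."""
    start = int(round((lo + hi) / 2.0)) - size // 2
    return max(0, min(start, extent - size))


def extract_positive_patches(
    subimage: np.ndarray,
    annotations: Sequence[Box],
    patch_size: int = 128,
) -> list[tuple[Box, np.ndarray]]:
    """One patch per annotated box, centered on the box center.

    Windows that would overflow the subimage are translated (never shrunk)
    back inside, so every returned patch is exactly
    ``patch_size x patch_size``.
    """
    h, w = subimage.shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError(f"subimage {h}x{w} smaller than patch_size {patch_size}")
    out = []
    for box in annotations:
        if not (0 <= box.xmin and box.xmax <= w and 0 <= box.ymin and box.ymax <= h):
            raise ValueError(f"annotation {box} outside subimage {h}x{w}")
        x0 = _centered_window(box.xmin, box.xmax, patch_size, w)
        y0 = _centered_window(box.ymin, box.ymax, patch_size, h)
        pbox = Box(x0, y0, x0 + patch_size, y0 + patch_size)
        out.append((pbox, subimage[y0 : y0 + patch_size, x0 : x0 + patch_size].copy()))
    return out


def extract_negative_patches(
    image: np.ndarray,
    n: int,
    patch_size: int = 128,
    seed: int = 0,
    annotations: Sequence[Box] = (),
) -> list[tuple[Box, np.ndarray]]:
    """Sample ``n`` background patches at seeded-uniform positions.

    Refuses to run on an annotated image: background ("no tassel") patches
    may only come from frames known to contain no tassels at all, which
    keeps the negative class label pure.
    """
    if len(annotations) > 0:
        raise ValueError(
            "extract_negative_patches requires a tassel-free image; "
            f"got {len(annotations)} annotations"
        )
    h, w = image.shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError(f"image {h}x{w} smaller than patch_size {patch_size}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        x0 = int(rng.integers(0, w - patch_size + 1))
        y0 = int(rng.integers(0, h - patch_size + 1))
        pbox = Box(x0, y0, x0 + patch_size, y0 + patch_size)
        out.append((pbox, image[y0 : y0 + patch_size, x0 : x0 + patch_size].copy()))
    return out
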