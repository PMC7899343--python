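"""Tile an orthomosaic into fixed-size subject images and place animals on tiles.

A whole-island orthomosaic is cut into square tiles (default 700 x 700 px),
each of which becomes one classification subject shown to volunteers. Tiles
containing no island content are flagged blank and excluded from counting.
Every ground-truth animal is owned by exactly one tile: the tile whose
half-open pixel bounds contain the animal's *head* coordinate, mirroring the
instruction given to volunteers to mark an animal only where its head is
visible (this is what prevents double counting across adjacent tiles).

Coordinates are 0-based; tile bounds are half-open intervals
``[x0, x1) x [y0, y1)`` so that the tiles of one mosaic partition the pixel
domain exactly.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_TILE_SIZE = 700

__all__ = [
    "DEFAULT_TILE_SIZE",
    "MosaicSpec",
    "Tile",
    "AnimalInstance",
    "tile_mosaic",
    "filter_blank_tiles",
    "assign_animals_to_tiles",
    "animals_by_tile",
    "manifest_frame",
]


@dataclass(frozen=True)
class MosaicSpec:
    """Pixel domain of one flight's orthomosaic.

    Parameters
    ----------
    width, height : int
        Mosaic dimensions in pixels; both must be >= 1.
    flight_id : str
        Opaque label identifying the drone flight.
    content_mask : numpy.ndarray, optional
        Boolean array of shape ``(height, width)``; True where the pixel
        shows island content, False for background (open water / white
        space). Required for blank-tile filtering in synthetic mode.
    """

    width: int
    height: int
    flight_id: str = "flight"
    content_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(
                f"mosaic dimensions must be positive, got {self.width}x{self.height}"
            )
        if self.content_mask is not None:
            mask = np.asarray(self.content_mask, dtype=bool)
            if mask.shape != (self.height, self.width):
                raise ValueError(
                    "content_mask shape "
                    f"{mask.shape} does not match (height, width)="
                    f"{(self.height, self.width)}"
                )
            object.__setattr__(self, "content_mask", mask)


@dataclass(frozen=True)
class Tile:
    """One classification subject: a rectangular crop of the mosaic."""

    tile_id: str
    x0: int
    y0: int
    x1: int
    y1: int
    flight_id: str = "flight"
    is_blank: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.x0 < self.x1 and 0 <= self.y0 < self.y1):
            raise ValueError(f"invalid tile bounds {self!r}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass(frozen=True)
class AnimalInstance:
    """One true animal, located by its head pixel on the mosaic."""

    animal_id: str
    species: str
    head_x: float
    head_y: float
    flight_id: str = "flight"


def tile_mosaic(mosaic: MosaicSpec, tile_size: int = DEFAULT_TILE_SIZE) -> list[Tile]:
    """Partition the mosaic pixel domain into a row-major grid of tiles.

    Interior tiles are ``tile_size x tile_size``; tiles on the right and
    bottom edges carry the remainder and are kept (not padded or dropped).
    Every pixel of the mosaic lies in exactly one returned tile.
    """
    if tile_size < 1:
        raise ValueError(f"tile_size must be >= 1, got {tile_size}")
    n_cols = math.ceil(mosaic.width / tile_size)
    n_rows = math.ceil(mosaic.height / tile_size)
    tiles: list[Tile] = []
    for r in range(n_rows):
        y0 = r * tile_size
        y1 = min(y0 + tile_size, mosaic.height)
        for c in range(n_cols):
            x0 = c * tile_size
            x1 = min(x0 + tile_size, mosaic.width)
            tiles.append(
                Tile(
                    tile_id=f"{mosaic.flight_id}-r{r:03d}c{c:03d}",
                    x0=x0,
                    y0=y0,
                    x1=x1,
                    y1=y1,
                    flight_id=mosaic.flight_id,
                )
            )
    return tiles


def filter_blank_tiles(
    tiles: Sequence[Tile],
    mosaic: MosaicSpec | None = None,
    min_content_fraction: float = 0.001,
    content_scores: Mapping[str, float] | None = None,
) -> list[Tile]:
    """Flag tiles whose content fraction falls below a threshold as blank.

    The content fraction comes either from the mosaic's ``content_mask``
    (synthetic mode) or from a precomputed per-tile ``content_scores``
    mapping (real mode, e.g. derived from file sizes or pixel variance).
    Blank tiles are retained in the returned list — downstream stages skip
    them but the manifest records them.
    """
    if content_scores is None and (mosaic is None or mosaic.content_mask is None):
        raise ValueError(
            "blank filtering needs a mosaic content_mask or per-tile content_scores"
        )
    out: list[Tile] = []
    for t in tiles:
        if content_scores is not None:
            frac = float(content_scores[t.tile_id])
        else:
            sub = mosaic.content_mask[t.y0 : t.y1, t.x0 : t.x1]
            frac = float(sub.mean()) if sub.size else 0.0
        out.append(replace(t, is_blank=frac < min_content_fraction))
    return out


def assign_animals_to_tiles(
    animals: Iterable[AnimalInstance], tiles: Sequence[Tile]
) -> dict[str, dict[str, int]]:
    """Count animals per tile and species; the head pixel decides ownership.

    Returns ``{tile_id: {species: count}}`` covering every tile (zero counts
    are implicit: absent species keys mean zero). Raises if any animal's head
    lies outside every tile, which cannot happen when ``tiles`` is the full
    partition of the mosaic the animals were generated on.
    """
    index = _TileIndex(tiles)
    counts: dict[str, dict[str, int]] = {t.tile_id: {} for t in tiles}
    for a in animals:
        tile = index.locate(a.head_x, a.head_y)
        if tile is None:
            raise ValueError(
                f"animal {a.animal_id} at ({a.head_x}, {a.head_y}) "
                "lies outside the tiled domain"
            )
        per = counts[tile.tile_id]
        per[a.species] = per.get(a.species, 0) + 1
    return counts


def animals_by_tile(
    animals: Iterable[AnimalInstance], tiles: Sequence[Tile]
) -> dict[str, list[AnimalInstance]]:
    """Group animals by owning tile (head-pixel rule), keeping full records."""
    index = _TileIndex(tiles)
    groups: dict[str, list[AnimalInstance]] = defaultdict(list)
    for a in animals:
        tile = index.locate(a.head_x, a.head_y)
        if tile is None:
            raise ValueError(
                f"animal {a.animal_id} at ({a.head_x}, {a.head_y}) "
                "lies outside the tiled domain"
            )
        groups[tile.tile_id].append(a)
    return dict(groups)


def manifest_frame(tiles: Sequence[Tile]) -> pd.DataFrame:
    """Tabulate tiles as the manifest CSV schema."""
    return pd.DataFrame(
        {
            "flight_id": [t.flight_id for t in tiles],
            "tile_id": [t.tile_id for t in tiles],
            "x0": [t.x0 for t in tiles],
            "y0": [t.y0 for t in tiles],
            "x1": [t.x1 for t in tiles],
            "y1": [t.y1 for t in tiles],
            "is_blank": [t.is_blank for t in tiles],
        }
    )


class _TileIndex:
    """O(1) point-to-tile lookup for a regular grid, linear scan otherwise."""

    def __init__(self, tiles: Sequence[Tile]):
        self.tiles = list(tiles)
        self._grid = self._try_grid()

    def _try_grid(self):
        if not self.tiles:
            return None
        xs = sorted({t.x0 for t in self.tiles})
        ys = sorted({t.y0 for t in self.tiles})
        lookup = {(t.x0, t.y0): t for t in self.tiles}
        if len(lookup) != len(self.tiles):
            return None
        return xs, ys, lookup

    def locate(self, x: float, y: float) -> Tile | None:
        if self._grid is not None:
            xs, ys, lookup = self._grid
            cx = xs[np.searchsorted(xs, x, side="right") - 1] if x >= xs[0] else None
            cy = ys[np.searchsorted(ys, y, side="right") - 1] if y >= ys[0] else None
            if cx is not None and cy is not None:
                tile = lookup.get((cx, cy))
                if tile is not None and tile.contains(x, y):
                    return tile
            return None
        for t in self.tiles:
            if t.contains(x, y):
                return t
        return None
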