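"""TIFF stack I/O with JSON sidecar metadata, plus tile stitching.

Stacks are stored as multipage TIFF (one page per spectral channel or time
bin) alongside a ``<name>.json`` sidecar recording the acquisition
geometry, seed, and any ground-truth parameters; label maps are
single-page integer TIFF.  Write → read round-trips counts bit-exactly
and metadata field-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "write_stack",
    "read_stack",
    "write_label_map",
    "read_label_map",
    "stitch_tiles",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path, stack: np.ndarray, metadata: dict) -> None:
    """Write an (H, W, K) stack as a K-page TIFF plus a JSON sidecar."""
    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (H, W, K)")
    metadata = dict(metadata)
    metadata["n_pages"] = int(stack.shape[2])
    tifffile.imwrite(path, np.moveaxis(stack, 2, 0), photometric="minisblack")
    _sidecar(path).write_text(json.dumps(metadata, indent=2, sort_keys=True))


def read_stack(path) -> tuple[np.ndarray, dict]:
    """Read a stack written by :func:`write_stack`; validates page count."""
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    metadata = json.loads(sidecar.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != metadata.get("n_pages"):
        raise ValueError(
            f"{path} has {pages.shape[0]} pages but metadata declares "
            f"{metadata.get('n_pages')}")
    return np.moveaxis(pages, 0, 2), metadata


def write_label_map(path, labels: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(labels, dtype=np.int32))


def read_label_map(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def _ramp_weights(n: int, overlap_px: int) -> np.ndarray:
    """1-D blending weights: linear feather over the overlap width at both
    ends, flat in the interior.  Normalizing by the accumulated weight in
    the mosaic makes the blend exact for constant tiles."""
    w = np.ones(n)
    if overlap_px > 0:
        ramp = (np.arange(overlap_px) + 1.0) / (overlap_px + 1.0)
        w[:overlap_px] = ramp
        w[-overlap_px:] = ramp[::-1]
    return w


def stitch_tiles(tiles, overlap_fraction: float = 0.2) -> np.ndarray:
    """Stitch a 2-D grid of tiles into a mosaic with linear feathering.

    ``tiles`` is a sequence of rows of equally shaped arrays, laid out on
    a regular grid where adjacent tiles overlap by ``overlap_fraction`` of
    the tile size.  The mosaic step is ``round(size * (1 - overlap))`` per
    axis and overlap zones are linearly blended, so a grid of identical
    constant tiles stitches to a constant mosaic.
    """
    if not 0 <= overlap_fraction < 0.5:
        raise ValueError("overlap_fraction must be in [0, 0.5)")
    grid = [list(row) for row in tiles]
    ny, nx = len(grid), len(grid[0])
    if any(len(row) != nx for row in grid):
        raise ValueError("tile grid must be rectangular")
    shape0 = np.asarray(grid[0][0]).shape
    for row in grid:
        for t in row:
            if np.asarray(t).shape != shape0:
                raise ValueError("all tiles must share a shape")
    th, tw = shape0[:2]
    oy, ox = int(round(th * overlap_fraction)), int(round(tw * overlap_fraction))
    sy, sx = th - oy, tw - ox
    out_shape = (sy * (ny - 1) + th, sx * (nx - 1) + tw) + shape0[2:]
    acc = np.zeros(out_shape, dtype=float)
    wacc = np.zeros(out_shape[:2], dtype=float)
    wy = _ramp_weights(th, oy)
    wx = _ramp_weights(tw, ox)
    weight = np.outer(wy, wx)
    for iy, row in enumerate(grid):
        for ix, tile in enumerate(row):
            tile = np.asarray(tile, dtype=float)
            y0, x0 = iy * sy, ix * sx
            w = weight if tile.ndim == 2 else weight[..., None]
            acc[y0:y0 + th, x0:x0 + tw] += tile * w
            wacc[y0:y0 + th, x0:x0 + tw] += weight
    wsafe = np.where(wacc > 0, wacc, 1.0)
    return acc / (wsafe if acc.ndim == 2 else wsafe[..., None])
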