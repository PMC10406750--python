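"""Region systems for whole-breast texture analysis.

Two region definitions are supported:

* a lattice of distinct (non-overlapping) square blocks tiling the cropped
  breast image, retaining only blocks sufficiently covered by the breast
  mask — features computed per block are later summarised across blocks;
* the largest axis-aligned square fully inscribed in the breast mask, used
  as a single large region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LatticeGrid", "InscribedSquare", "lattice_blocks", "largest_inscribed_square"]

DEFAULT_BLOCK_SIZE = 214
DEFAULT_COVERAGE_MIN = 0.9


@dataclass
class LatticeGrid:
    """Retained distinct-block origins on a regular grid anchored at (0, 0)."""

    block_size: int
    origins: list[tuple[int, int]]
    coverage_min: float


@dataclass
class InscribedSquare:
    """Top-left corner (0-based) and side of the largest all-true square."""

    row: int
    col: int
    side: int


def lattice_blocks(
    mask: np.ndarray,
    block_size: int = DEFAULT_BLOCK_SIZE,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
) -> LatticeGrid:
    """Tile the mask with distinct blocks and retain well-covered ones.

    The grid starts at the crop origin and advances in steps of
    ``block_size``; tiles extending past the image are discarded (no
    padding). A tile is retained iff its fraction of mask-true pixels is at
    least ``coverage_min``. Origins are returned in row-major order. An
    empty grid is legal and handled downstream.
    """
    mask = np.asarray(mask, dtype=bool)
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    if not 0 < coverage_min <= 1:
        raise ValueError("coverage_min must be in (0, 1]")
    h, w = mask.shape
    area = block_size * block_size
    origins = []
    for r in range(0, h - block_size + 1, block_size):
        for c in range(0, w - block_size + 1, block_size):
            if mask[r : r + block_size, c : c + block_size].sum() / area >= coverage_min:
                origins.append((r, c))
    return LatticeGrid(block_size=block_size, origins=origins, coverage_min=coverage_min)


def largest_inscribed_square(mask: np.ndarray) -> InscribedSquare:
    """Find the largest axis-aligned square of mask-true pixels.

    Exact maximal-square search: the side length is found by monotone
    bisection (a square of side s fits somewhere iff one of side s-1 does),
    testing each candidate side with an integral-image all-true check. Ties
    in position are broken by smallest row, then smallest column.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask has no true pixels")
    h, w = mask.shape
    # integral image with zero padding: counts[i, j] = sum of mask[:i, :j]
    counts = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=counts[1:, 1:])

    def first_fit(s: int) -> tuple[int, int] | None:
        if s > min(h, w):
            return None
        win = (
            counts[s:, s:]
            - counts[:-s, s:]
            - counts[s:, :-s]
            + counts[:-s, :-s]
        )
        hits = np.argwhere(win == s * s)
        if hits.size == 0:
            return None
        return tuple(int(v) for v in hits[0])  # row-major argwhere -> tie-break

    lo, hi = 1, min(h, w)  # side 1 always fits (mask non-empty)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if first_fit(mid) is not None:
            lo = mid
        else:
            hi = mid - 1
    r, c = first_fit(lo)
    return InscribedSquare(row=r, col=c, side=lo)
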