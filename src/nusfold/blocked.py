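"""Blocked-wavefront engine: the GPU tiling decomposition run on CPU workers.

The upper triangle of the score matrix is partitioned into tiles:

* **triangles** adjacent to the main diagonal — one per row band of ``BS``
  rows, covering cells ``(i, j)`` with ``i <= j < (band+1)*BS - 1``;
* **squares** of size ``BS × BS`` whose column origin is offset one column to
  the *left* of the aligned grid (block ``(bi, bj)`` covers columns
  ``[bi*BS - 1, (bi+1)*BS - 1)``) — the offset makes the last column of each
  aligned diagonal band belong to the neighbouring square rather than the
  triangle;
* **edge rectangles** where the offset tiling runs past column ``n`` — for
  ``n`` a multiple of ``BS`` these are the ``BS × 1`` strips at the right end.

Tiles on one *block diagonal* ``d = bi - bj`` have no mutual dependencies, so
the grid is processed as a wavefront over block diagonals with a barrier
between consecutive diagonals; tiles of one diagonal may run concurrently.

Within a tile the split term ``max_k entry(i,k) + entry(k+1,j)`` decomposes
by the position of ``k`` relative to the tile (rows ``[r0, r1)``, columns
``[c0, c1)``):

* ``k in [r1-1, c0)`` — both operands live on earlier block diagonals.  This
  is a pure max-plus (tropical) inner product between a row strip of the
  tile's band and a column strip of the tile's columns, accumulated
  block-width by block-width (:func:`maxplus_combine`, the strip kernel).
* ``k in [i, r1-1)`` and ``k in [c0, j)`` — one operand lies inside the tile
  itself.  These fringe terms, together with the bond term
  ``entry(i+1, j-1) + bond(a_i, a_j)``, are resolved by an intra-tile sweep
  in anti-diagonal order (:func:`finish_block`).

Mirrored storage is maintained throughout, so every column strip is read as
a row from the lower triangle.  The result is entrywise identical to the
serial engines for every block size and worker count.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

from .model import DEFAULT_RULE, PairingRule, RnaSequence, ScoreMatrix


@dataclass(frozen=True)
class Block:
    """One tile of the upper-triangle partition.

    ``bi`` indexes block columns (increasing rightward), ``bj`` block rows
    (increasing downward); the main-diagonal tiles ``(i, i)`` are triangles.
    Rows covered are ``[row0, row1)``; for non-triangles the columns covered
    are ``[col0, col1)``, while a triangle covers ``(i, j)`` with
    ``row0 <= i <= j < col1`` (its ``col0`` equals ``row0``).
    """

    bi: int
    bj: int
    row0: int
    row1: int
    col0: int
    col1: int
    kind: str  # "triangle" | "square" | "edge"

    @property
    def diagonal(self) -> int:
        return self.bi - self.bj

    @property
    def height(self) -> int:
        return self.row1 - self.row0

    @property
    def width(self) -> int:
        return self.col1 - self.col0

    def cells(self) -> Iterator[Tuple[int, int]]:
        if self.kind == "triangle":
            for i in range(self.row0, self.row1):
                for j in range(i, self.col1):
                    yield i, j
        else:
            for i in range(self.row0, self.row1):
                for j in range(max(self.col0, i), self.col1):
                    yield i, j

    def cell_count(self) -> int:
        return sum(1 for _ in self.cells())


class BlockGrid:
    """The tiling of an ``n × n`` upper triangle into ``BS``-sized blocks."""

    def __init__(self, n: int, bs: int, blocks: List[Block]) -> None:
        self.n = n
        self.bs = bs
        self.blocks = blocks
        self.d_max = max(b.diagonal for b in blocks) + 1 if blocks else 0

    def diagonals(self) -> List[List[Block]]:
        """Blocks grouped by block diagonal, in wavefront order."""
        out: List[List[Block]] = [[] for _ in range(self.d_max)]
        for b in self.blocks:
            out[b.diagonal].append(b)
        return out

    def cell_count(self) -> int:
        return sum(b.cell_count() for b in self.blocks)

    def to_frame(self) -> pd.DataFrame:
        """Tabular debug dump of the tiling geometry."""
        rows = [
            {
                "block": f"({b.bi},{b.bj})",
                "kind": b.kind,
                "row0": b.row0,
                "col0": b.col0,
                "height": b.height,
                "width": b.width,
                "diagonal": b.diagonal,
                "cells": b.cell_count(),
            }
            for b in sorted(self.blocks, key=lambda b: (b.diagonal, b.bj))
        ]
        return pd.DataFrame(rows)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)

    def __repr__(self) -> str:
        return (f"BlockGrid(n={self.n}, bs={self.bs}, "
                f"blocks={len(self.blocks)}, d_max={self.d_max})")


def plan_grid(n: int, bs: int) -> BlockGrid:
    """Plan the tiling of an ``n × n`` upper triangle with block size ``bs``.

    Raises ``ValueError`` unless ``1 <= bs <= n``.  The returned grid covers
    every upper-triangle cell exactly once.
    """
    if bs < 1 or bs > n:
        raise ValueError(f"block size must satisfy 1 <= bs <= n, got bs={bs}, n={n}")
    blocks: List[Block] = []
    n_bands = -(-n // bs)  # ceil
    for bj in range(n_bands):
        r0, r1 = bj * bs, min((bj + 1) * bs, n)
        tri_end = (bj + 1) * bs - 1
        if tri_end >= n:
            tri_end = n
        blocks.append(Block(bj, bj, r0, r1, r0, tri_end, "triangle"))
        bi = bj + 1
        while bi * bs - 1 < n:
            c0 = bi * bs - 1
            c1 = min((bi + 1) * bs - 1, n)
            kind = ("square"
                    if (c1 - c0 == bs and r1 - r0 == bs) else "edge")
            blocks.append(Block(bi, bj, r0, r1, c0, c1, kind))
            bi += 1
    return BlockGrid(n, bs, blocks)


@dataclass
class StripPair:
    """Operand strips for one max-plus combination step.

    ``a`` is the row strip ``entry(rows, k-range)`` (shape ``h × K``); ``b``
    holds ``entry(k+1, cols)`` for the same k-range (shape ``K × w``), read
    row-wise from the mirrored lower triangle by the scheduler.
    """

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        if self.a.shape[1] != self.b.shape[0]:
            raise ValueError("strip k-ranges disagree")


def maxplus_combine(strip: StripPair, accumulator: np.ndarray) -> np.ndarray:
    """Fold one strip pair into the accumulator by max-plus inner product.

    ``accumulator[r, c] = max(accumulator[r, c],
    max_k strip.a[r, k] + strip.b[k, c])`` — the tropical-semiring analogue
    of a matrix-multiply update.  No bond term is involved.  The accumulator
    never decreases.
    """
    cand = (strip.a[:, :, None] + strip.b[None, :, :]).max(axis=1)
    np.maximum(accumulator, cand, out=accumulator)
    return accumulator


def _combine_strips(M: np.ndarray, block: Block, bs: int,
                    written: Optional[np.ndarray]) -> Optional[np.ndarray]:
    """Phase 1: accumulate all split terms whose operands lie on earlier
    block diagonals, one block-width of k at a time."""
    r0, r1, c0, c1 = block.row0, block.row1, block.col0, block.col1
    if block.kind == "triangle" or c0 <= r1 - 1:
        return None
    acc = np.zeros((r1 - r0, c1 - c0), dtype=np.int32)
    for k0 in range(r1 - 1, c0, bs):
        k1 = min(k0 + bs, c0)
        if written is not None:
            if not written[r0:r1, k0:k1].all():
                raise AssertionError("A-strip read before write")
            if not written[k0 + 1:k1 + 1, c0:c1].all():
                raise AssertionError("B-strip read before write")
        a = M[r0:r1, k0:k1]
        # column strip entry(k+1, cols) read as rows of the mirror
        b = M[c0:c1, k0 + 1:k1 + 1].T
        maxplus_combine(StripPair(a, b), acc)
    return acc


def finish_block(M: np.ndarray, block: Block, codes: np.ndarray,
                 table: np.ndarray, accumulator: Optional[np.ndarray],
                 written: Optional[np.ndarray] = None) -> None:
    """Phase 2: intra-tile sweep in anti-diagonal order.

    Each cell takes the max of its accumulator value, the bond term
    ``entry(i+1, j-1) + bond(a_i, a_j)`` and the fringe split terms whose
    operands lie inside this tile or on already-finished tiles.  After the
    sweep every cell of the tile equals the serial engine's value; results
    are written to both triangles (mirrored storage).
    """
    r0, r1, c0, c1 = block.row0, block.row1, block.col0, block.col1
    if block.kind == "triangle":
        c0 = r1 - 1  # no inter-tile split range exists for triangles
    for i, j in sorted(block.cells(), key=lambda c: c[1] - c[0]):
        if j - i < 2:
            if written is not None:
                written[i, j] = written[j, i] = True
            continue
        best = int(accumulator[i - block.row0, j - block.col0]) \
            if accumulator is not None else 0
        if written is not None and not (written[i + 1, j - 1]
                                        or j - 1 - (i + 1) < 2):
            raise AssertionError("bond operand read before write")
        t = int(M[i + 1, j - 1]) + int(table[codes[i], codes[j]])
        if t > best:
            best = t
        lo_end = min(r1 - 1, j)  # k in [i, lo_end): right operand intra-tile
        if lo_end > i:
            if written is not None:
                if not written[i, i:lo_end].all():
                    raise AssertionError("low-fringe A read before write")
                if not written[j, i + 1:lo_end + 1].all():
                    raise AssertionError("low-fringe B read before write")
            t = int((M[i, i:lo_end] + M[j, i + 1:lo_end + 1]).max())
            if t > best:
                best = t
        hi_start = max(c0, i)  # k in [hi_start, j): left operand intra-tile
        if j > hi_start:
            if written is not None:
                if not written[i, hi_start:j].all():
                    raise AssertionError("high-fringe A read before write")
                if not written[j, hi_start + 1:j + 1].all():
                    raise AssertionError("high-fringe B read before write")
            t = int((M[i, hi_start:j] + M[j, hi_start + 1:j + 1]).max())
            if t > best:
                best = t
        M[i, j] = M[j, i] = best
        if written is not None:
            written[i, j] = written[j, i] = True


def _compute_block(M: np.ndarray, block: Block, bs: int, codes: np.ndarray,
                   table: np.ndarray, written: Optional[np.ndarray]) -> None:
    acc = _combine_strips(M, block, bs, written)
    finish_block(M, block, codes, table, acc, written)


def fill_blocked(seq: RnaSequence, block_size: int = 32, workers: int = 1,
                 rule: Optional[PairingRule] = None, layout: str = "mirrored",
                 audit: bool = False) -> ScoreMatrix:
    """Fill the score table by the blocked wavefront schedule.

    ``block_size`` is clamped to ``n`` (a single-tile grid degenerates to one
    intra-tile sweep).  Blocks of one block diagonal may run on ``workers``
    threads; a barrier separates consecutive block diagonals, so the output
    is identical for any worker count and any block size.  With
    ``audit=True`` every read is checked against a write-epoch map and a
    scheduler bug raises ``AssertionError``.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    rule = rule or DEFAULT_RULE
    n = seq.n
    bs = min(block_size, n)
    grid = plan_grid(n, bs)
    M = np.zeros((n, n), dtype=np.int32)
    codes, table = seq.codes, rule.table
    written = None
    if audit:
        # cells of span < 2 are base cases, written at initialization
        written = np.zeros((n, n), dtype=bool)
        ii, jj = np.triu_indices(n)
        base = jj - ii < 2
        written[ii[base], jj[base]] = True
        written[jj[base], ii[base]] = True
    diagonals = grid.diagonals()
    if workers == 1:
        for blocks in diagonals:
            for b in blocks:
                _compute_block(M, b, bs, codes, table, written)
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            for blocks in diagonals:
                futures = [
                    pool.submit(_compute_block, M, b, bs, codes, table,
                                written)
                    for b in blocks
                ]
                for f in futures:  # barrier between block diagonals
                    f.result()
    if layout == "mirrored":
        return ScoreMatrix(n, layout="mirrored", data=M, filled=True)
    return ScoreMatrix.from_dense(M, layout=layout, filled=True)
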