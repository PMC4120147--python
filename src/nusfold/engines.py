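"""Reference dynamic-programming engines filling the score table.

Three serial engines compute identical upper triangles:

* ``original`` — the classical four-case recurrence: drop ``a_i``, drop
  ``a_j``, pair ``(a_i, a_j)`` onto the inner interval, or split the interval
  at an interior point ``i < k < j``.
* ``chang`` — the simplified two-term recurrence: pair term plus a split term
  with ``i <= k < j``.  Including ``k = i`` and ``k = j-1`` (where one operand
  is a zero-length interval) subsumes the two "drop" cases of the original
  recurrence, so only two terms remain.  Filled as a naive anti-diagonal
  sweep.
* ``mirrored`` — the same sweep, but every score is also written to the
  transposed lower-triangle cell; the split term then reads ``entry(j, k+1)``
  from the mirror instead of ``entry(k+1, j)``, turning a strided column walk
  into a contiguous row walk (cache-efficient variant).

All engines use the convention ``entry(i, i) = entry(i, i+1) = 0``: adjacent
bases never pair.  Scores are integers throughout; results are exact and
identical across engines, worker counts and block sizes.

:func:`fill_parallel` runs any serial engine with cells of one anti-diagonal
distributed over a thread pool.  Cells on one anti-diagonal depend only on
strictly shorter intervals (earlier diagonals), so with a barrier between
diagonals the output is bit-identical for any worker count.

The inner loops are JIT-compiled with numba; the kernels release the GIL so
thread-based diagonal parallelism can make real progress.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .model import (
    DEFAULT_RULE,
    PairingRule,
    RnaSequence,
    ScoreMatrix,
)

ENGINE_NAMES = ("original", "chang", "mirrored", "blocked")


@dataclass(frozen=True)
class EngineSpec:
    """Which engine to run and how.

    ``workers=1`` means serial execution; ``block_size`` only applies to the
    blocked engine; ``keep_matrix`` asks callers of the high-level API to
    retain the filled table in the result.
    """

    name: str = "chang"
    workers: int = 1
    keep_matrix: bool = True
    block_size: int = 32

    def __post_init__(self) -> None:
        if self.name not in ENGINE_NAMES:
            raise ValueError(f"unknown engine {self.name!r}; "
                             f"choose from {ENGINE_NAMES}")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


@njit(cache=True, nogil=True)
def _diag_original(M, codes, table, diag, lo, hi):  # pragma: no cover - jit
    # four-case recurrence, interior split only (i < k < j)
    for row in range(lo, hi):
        col = diag + row
        best = M[row + 1, col]
        if M[row, col - 1] > best:
            best = M[row, col - 1]
        t = M[row + 1, col - 1] + table[codes[row], codes[col]]
        if t > best:
            best = t
        for k in range(row + 1, col):
            t = M[row, k] + M[k + 1, col]
            if t > best:
                best = t
        M[row, col] = best


@njit(cache=True, nogil=True)
def _diag_chang(M, codes, table, diag, lo, hi):  # pragma: no cover - jit
    # two-term recurrence, split range k in [row, col)
    for row in range(lo, hi):
        col = diag + row
        best = M[row + 1, col - 1] + table[codes[row], codes[col]]
        for k in range(row, col):
            t = M[row, k] + M[k + 1, col]
            if t > best:
                best = t
        M[row, col] = best


@njit(cache=True, nogil=True)
def _diag_mirrored(M, codes, table, diag, lo, hi):  # pragma: no cover - jit
    # as _diag_chang, but the right split operand is read from the mirror
    # (row read) and every result is written to both triangles
    for row in range(lo, hi):
        col = diag + row
        best = M[row + 1, col - 1] + table[codes[row], codes[col]]
        for k in range(row, col):
            t = M[row, k] + M[col, k + 1]
            if t > best:
                best = t
        M[row, col] = best
        M[col, row] = best


_KERNELS = {
    "original": _diag_original,
    "chang": _diag_chang,
    "mirrored": _diag_mirrored,
}


def _fill_dense(seq: RnaSequence, rule: Optional[PairingRule],
                style: str, workers: int = 1) -> np.ndarray:
    rule = rule or DEFAULT_RULE
    n = seq.n
    M = np.zeros((n, n), dtype=np.int32)
    kernel = _KERNELS[style]
    codes, table = seq.codes, rule.table
    if workers <= 1:
        for diag in range(2, n):
            kernel(M, codes, table, diag, 0, n - diag)
        return M
    with ThreadPoolExecutor(max_workers=workers) as pool:
        for diag in range(2, n):
            width = n - diag
            if width < 2 * workers:
                kernel(M, codes, table, diag, 0, width)
                continue
            bounds = np.linspace(0, width, workers + 1).astype(np.int64)
            futures = [
                pool.submit(kernel, M, codes, table, diag,
                            int(bounds[w]), int(bounds[w + 1]))
                for w in range(workers)
            ]
            for f in futures:  # barrier between consecutive diagonals
                f.result()
    return M


def fill_original(seq: RnaSequence, rule: Optional[PairingRule] = None,
                  workers: int = 1) -> ScoreMatrix:
    """Fill the table with the classical four-case recurrence."""
    return ScoreMatrix.from_dense(
        _fill_dense(seq, rule, "original", workers), layout="full")


def fill_chang(seq: RnaSequence, rule: Optional[PairingRule] = None,
               workers: int = 1) -> ScoreMatrix:
    """Fill the table with the simplified two-term recurrence (naive sweep)."""
    return ScoreMatrix.from_dense(
        _fill_dense(seq, rule, "chang", workers), layout="full")


def fill_mirrored(seq: RnaSequence, rule: Optional[PairingRule] = None,
                  workers: int = 1) -> ScoreMatrix:
    """Cache-efficient sweep keeping a transposed copy in the lower triangle."""
    dense = _fill_dense(seq, rule, "mirrored", workers)
    return ScoreMatrix(seq.n, layout="mirrored", data=dense, filled=True)


def fill_parallel(seq: RnaSequence, spec: EngineSpec,
                  rule: Optional[PairingRule] = None) -> ScoreMatrix:
    """Run the engine named in ``spec`` with ``spec.workers`` threads.

    Parallelism is only across cells of one anti-diagonal (or, for the
    blocked engine, across blocks of one block diagonal); a barrier separates
    consecutive diagonals, so the output is identical for any worker count.
    """
    if spec.name == "blocked":
        from .blocked import fill_blocked
        return fill_blocked(seq, block_size=spec.block_size,
                            workers=spec.workers, rule=rule)
    fillers = {"original": fill_original, "chang": fill_chang,
               "mirrored": fill_mirrored}
    return fillers[spec.name](seq, rule=rule, workers=spec.workers)


def fold_score(matrix: ScoreMatrix) -> int:
    """Maximum number of bonded pairs for the whole sequence: ``entry(0, n-1)``."""
    if not matrix.filled:
        raise ValueError("score matrix has not been filled")
    return matrix.entry(0, matrix.n - 1)
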