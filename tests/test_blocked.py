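"""Blocked wavefront engine: tiling geometry, max-plus strip kernel,
schedule safety and equivalence with the serial engines."""

import numpy as np
import pytest

from nusfold.blocked import (
    StripPair,
    fill_blocked,
    finish_block,
    maxplus_combine,
    plan_grid,
)
from nusfold.engines import fill_chang, fold_score
from nusfold.model import DEFAULT_RULE, normalize_sequence
from nusfold.oracle import random_sequences


class TestPlanGrid:
    def test_worked_example_20_by_4(self):
        grid = plan_grid(20, 4)
        assert grid.d_max == 6  # six wavefront iterations
        diag_blocks = [b for b in grid.blocks if b.bi == b.bj]
        assert len(diag_blocks) == 5
        assert all(b.kind == "triangle" for b in diag_blocks)
        edges = [b for b in grid.blocks if b.kind == "edge"]
        assert [(b.height, b.width) for b in edges] == [(4, 1)] * 5
        assert all(b.col0 == 19 for b in edges)

    def test_offset_square_origins(self):
        grid = plan_grid(20, 4)
        squares = [b for b in grid.blocks if b.kind == "square"]
        # column origin one left of the aligned grid: bi*BS - 1
        assert all(b.col0 == b.bi * 4 - 1 for b in squares)

    @pytest.mark.parametrize("n", [1, 2, 5, 9, 20, 33])
    def test_complete_non_overlapping_cover(self, n):
        for bs in range(1, n + 1):
            grid = plan_grid(n, bs)
            seen = set()
            for b in grid.blocks:
                for cell in b.cells():
                    assert cell not in seen, (n, bs, cell)
                    seen.add(cell)
            assert len(seen) == n * (n + 1) // 2

    def test_completeness_sweep(self):
        # exhaustive sweep of the cell-count identity
        for n in range(1, 65):
            for bs in range(1, n + 1):
                assert plan_grid(n, bs).cell_count() == n * (n + 1) // 2

    def test_single_block_limit(self):
        grid = plan_grid(10, 10)
        triangles = [b for b in grid.blocks if b.kind == "triangle"]
        assert len(triangles) == 1
        assert grid.d_max <= 2

    @pytest.mark.parametrize("n,bs", [(10, 0), (10, 11), (5, -1)])
    def test_invalid_block_size_rejected(self, n, bs):
        with pytest.raises(ValueError):
            plan_grid(n, bs)

    def test_tsv_dump_lists_every_block(self):
        grid = plan_grid(20, 4)
        lines = grid.to_tsv().strip().splitlines()
        assert len(lines) == len(grid.blocks) + 1  # header
        assert lines[0].split("\t") == [
            "block", "kind", "row0", "col0", "height", "width",
            "diagonal", "cells"]


class TestMaxplusCombine:
    def test_zero_strips_leave_accumulator_unchanged(self):
        acc = np.zeros((3, 3), dtype=np.int32)
        strip = StripPair(np.zeros((3, 4), np.int32), np.zeros((4, 3), np.int32))
        maxplus_combine(strip, acc)
        assert np.all(acc == 0)

    def test_single_cell_strip_is_one_split_term(self):
        # BS = 1: the combination reduces to one k-term a + b
        acc = np.full((1, 1), -1, dtype=np.int32)
        strip = StripPair(np.array([[2]], np.int32), np.array([[3]], np.int32))
        maxplus_combine(strip, acc)
        assert acc[0, 0] == 5

    def test_accumulator_never_decreases(self):
        rng = np.random.default_rng(0)
        acc = rng.integers(0, 5, (4, 4)).astype(np.int32)
        before = acc.copy()
        strip = StripPair(rng.integers(0, 3, (4, 6)).astype(np.int32),
                          rng.integers(0, 3, (6, 4)).astype(np.int32))
        maxplus_combine(strip, acc)
        assert np.all(acc >= before)

    def test_mismatched_k_ranges_rejected(self):
        with pytest.raises(ValueError):
            StripPair(np.zeros((2, 3), np.int32), np.zeros((4, 2), np.int32))

    def test_accumulator_dominated_by_final_entries(self, seq_hairpin):
        # partial max-plus results never exceed the final table values
        ref = fill_chang(seq_hairpin).upper()
        grid = plan_grid(seq_hairpin.n, 3)
        M = fill_blocked(seq_hairpin, block_size=3).data
        for b in grid.blocks:
            if b.kind == "triangle" or b.col0 <= b.row1 - 1:
                continue
            acc = np.zeros((b.height, b.width), np.int32)
            k0, k1 = b.row1 - 1, b.col0
            strip = StripPair(M[b.row0:b.row1, k0:k1],
                              M[b.col0:b.col1, k0 + 1:k1 + 1].T)
            maxplus_combine(strip, acc)
            for i in range(b.row0, b.row1):
                for j in range(max(b.col0, i), b.col1):
                    assert acc[i - b.row0, j - b.col0] <= ref[i, j]


class TestFinishBlock:
    def test_triangle_reproduces_serial_engine(self, seq_hairpin):
        ref = fill_chang(seq_hairpin).upper()
        grid = plan_grid(seq_hairpin.n, seq_hairpin.n)
        tri = [b for b in grid.blocks if b.kind == "triangle"][0]
        M = np.zeros((seq_hairpin.n,) * 2, np.int32)
        finish_block(M, tri, seq_hairpin.codes, DEFAULT_RULE.table, None)
        for i, j in tri.cells():
            assert M[i, j] == ref[i, j]


class TestFillBlocked:
    def test_single_block_degenerates_to_serial(self, seq_hairpin):
        out = fill_blocked(seq_hairpin, block_size=seq_hairpin.n)
        assert out.upper_equal(fill_chang(seq_hairpin))

    def test_cross_block_size_equality(self):
        (seq,) = random_sequences(1, [100], seed=23)
        ref = fill_chang(seq)
        for bs in (1, 7, 16, 32, 100):
            out = fill_blocked(seq, block_size=bs)
            assert ref.upper_equal(out), bs

    def test_worker_count_does_not_change_output(self):
        (seq,) = random_sequences(1, [200], seed=29)
        ref = fill_blocked(seq, block_size=32, workers=1)
        for workers in (2, 8):
            out = fill_blocked(seq, block_size=32, workers=workers)
            assert np.array_equal(ref.data, out.data)

    def test_block_size_larger_than_n_is_clamped(self, seq_hairpin):
        out = fill_blocked(seq_hairpin, block_size=32)
        assert fold_score(out) == 3

    def test_schedule_safety_audit(self):
        # every read must land on an earlier block diagonal or earlier
        # intra-block anti-diagonal; audit mode raises otherwise
        for n, bs in [(37, 5), (40, 8), (21, 4)]:
            (seq,) = random_sequences(1, [n], seed=n)
            out = fill_blocked(seq, block_size=bs, audit=True)
            assert out.upper_equal(fill_chang(seq))

    def test_packed_layout_output(self, seq_hairpin):
        packed = fill_blocked(seq_hairpin, block_size=4, layout="packed")
        assert packed.layout == "packed"
        assert packed.upper_equal(fill_chang(seq_hairpin))

    def test_mirrored_invariant_maintained(self):
        (seq,) = random_sequences(1, [50], seed=31)
        out = fill_blocked(seq, block_size=8)
        out.validate()  # includes the mirror check

    def test_invalid_parameters_rejected(self, seq_hairpin):
        with pytest.raises(ValueError):
            fill_blocked(seq_hairpin, block_size=0)
        with pytest.raises(ValueError):
            fill_blocked(seq_hairpin, workers=0)
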