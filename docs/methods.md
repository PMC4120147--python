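# Methods

## Model and assumptions

`nusfold` maximizes the number of bonded base pairs in a single RNA strand
under the nested-structure restriction: for any two pairs `(i, j)` and
`(k, l)` with `i < k`, either the second pair lies entirely inside the first
(`j > l`) or entirely after it (`k > j`). Pseudoknots, stacking energies,
loop penalties and suboptimal-structure enumeration are out of scope — the
score is a pure pair count, which keeps the DP exact over the integers and
lets four very different execution strategies be checked against each other
entrywise.

The bond function is configurable (`PairingRule`); the default awards 1 to
A·U, G·C and the G·U wobble and 0 to everything else. DNA input is accepted
by mapping T→U.

**Minimum pairing separation.** The base cases fix `C(i, i) = C(i, i+1) = 0`,
so paired bases always satisfy `j − i ≥ 2` (a hairpin loop of at least one
unpaired base). The classical formulation with base case `C(i, i−1) = 0`
would admit an adjacent pair through the bond term at `j = i + 1`; the two
conventions disagree on that edge, and we apply the stricter one uniformly
to *all* engines so that entrywise equivalence across engines is literally
true rather than true-up-to-an-edge-case. The structure type enforces the
same separation, so traceback output and matrix scores can never drift
apart.

**Split-term range.** The simplified recurrence's split
`max_{i ≤ k < j} C(i, k) + C(k+1, j)` includes `k = i` and `k = j − 1`;
with zero-diagonal base cases these reproduce the "drop `a_i`" / "drop
`a_j`" cases of the four-case recurrence, which is why two terms suffice.
The test suite asserts this subsumption at the level of individual terms on
random instances, not just on final values.

## Engines and numerical choices

Scores are `int32` throughout; there is no floating point anywhere in the
DP, so "equivalent" always means *bit-identical upper triangles*.

* `original` / `chang` — anti-diagonal sweeps of the four-case and two-term
  recurrences. Inner loops are numba-JIT-compiled, one kernel call per
  anti-diagonal.
* `mirrored` — identical arithmetic, but every score is also stored at the
  transposed position and the split term's right operand is read as
  `entry(j, k+1)` from the lower triangle: a contiguous row read instead of
  a strided column read. This is purely a memory-layout change; the tests
  assert the upper triangle is unchanged and the lower triangle is its
  transpose.
* Diagonal parallelism (`fill_parallel`) splits each anti-diagonal's cells
  over a thread pool (the JIT kernels release the GIL) with a barrier
  between diagonals. Cells of one diagonal depend only on strictly shorter
  intervals, so the contract is determinism — identical output for any
  worker count — rather than any particular schedule.

### Blocked wavefront engine

The blocked engine reproduces, on CPU workers, the tiling decomposition
used to map this DP onto massively parallel hardware:

* **Geometry.** Row bands of `BS` rows; a triangle per band covering
  `(i, j)` with `i ≤ j < (band+1)·BS − 1`; squares whose column origin is
  `bi·BS − 1` — offset one column *left* of the aligned grid — and edge
  rectangles where the offset tiling is clipped at column `n` (for `n` a
  multiple of `BS`, these are `BS×1` strips at the right end). The offset
  is what makes the strips available on earlier block diagonals cover
  exactly the dependency ranges of each tile; an aligned grid would leave a
  one-column gap. For `n = 20`, `BS = 4` the grid has 6 block diagonals.
  `BS = n` degenerates to one triangle plus one `n×1` rectangle, i.e. an
  almost purely intra-tile sweep.
* **Schedule.** Tiles are processed by block diagonal `d = bi − bj`; tiles
  within one diagonal have no mutual dependencies and may run concurrently;
  a barrier separates diagonals. The per-tile split range decomposes by the
  position of `k`: for `k ∈ [r1−1, c0)` both operands are final (earlier
  diagonals) and are combined by a max-plus inner product over strips one
  block-width of `k` at a time (`maxplus_combine`); the remaining `k` ranges
  and the bond term involve cells of the tile itself and are resolved by an
  intra-tile anti-diagonal sweep (`finish_block`). The fringe ranges were
  derived from the dependency analysis and are verified by entrywise
  equality with the serial engines over randomized `(sequence, BS, workers)`
  triples.
* **Strip kernel.** On the original hardware target this combination is a
  register-tiled, coalesced max-plus analogue of a matrix-multiply kernel;
  that choreography is a performance detail of the device, so here it is a
  dense numpy broadcast with the identical mathematical effect.
* **Audit mode.** `fill_blocked(..., audit=True)` tags every cell with a
  written flag and asserts, at each strip and fringe read, that the operand
  was produced on an earlier block diagonal or earlier intra-tile
  anti-diagonal — a direct check of schedule safety, exercised in the test
  suite.
* `block_size` is clamped to `n` so the default (32) works on short
  sequences; the grid planner itself rejects `BS > n`.

### Storage layouts

`full` keeps the upper triangle of an `n×n` array; `mirrored` additionally
maintains the transpose in the lower triangle (the cache-efficient and
blocked engines' native form); `packed` maps the upper triangle row-major
into a 1-D array, halving memory for long sequences at a small access cost.
Traceback reads only `entry(i, j)` with `i ≤ j`, so it is layout-blind.

## Traceback

Many co-optimal structures usually exist and the model itself does not
prefer one; the reported structure is fixed by a repository convention: at
each cell take the pairing case when it attains the maximum, otherwise the
smallest attaining split point. This makes output deterministic and
identical across engines, worker counts and layouts — the property the CLI
determinism test pins down at byte level. The walk is iterative (explicit
stack), linear in `n` plus the number of interval splits.

## Oracle and fixtures

The brute-force oracle enumerates every nested, bond-valid, separation-≥2
pair set by plain recursion ("first position unpaired, or paired with each
admissible partner, then recurse inside and outside"). Memoization is
deliberately disabled so the oracle shares no code path or asymptotics with
the DP it certifies; the default length cap of 16 keeps the exponential
search desk-scale. Fixture sequences are i.i.d. uniform over {A, C, G, U}
(`FixtureSpec` is fully deterministic in `(n, seed, composition)`). Uniform
random sequences exercise every code path of the DP — the table is filled
completely regardless of sequence content — but they are not biologically
realistic RNAs, and pair-count maximization is itself a simplified model;
passing tests certify algorithmic correctness and equivalence, not
predictive accuracy on real molecules.

## Problem sizes and defaults

Defaults: bond rule AU/GC/GU; block size 32 (a common tile size balancing
strip-kernel efficiency against wavefront width, and the value used by the
GPU implementations this engine mirrors); one worker; `full` layout on
serial engines, `mirrored` on the blocked engine; oracle cap 16. The test
suite evaluates 500 random sequences of length 3–14 against the oracle,
200 of length 3–64 plus 20 of length 200/500 for cross-engine equivalence
with block sizes {1, 7, 16, 32, n} and worker counts {1, 2, 8}, and checks
cubic scaling of the serial fill between n = 500 and n = 1000 (time ratio
expected in [4, 16], measured as best-of-several after JIT warm-up).

## Known limitations

* Pair-count maximization ignores thermodynamics; structures are "optimal"
  only in this combinatorial sense.
* Thread-based parallelism targets determinism and schedule fidelity, not
  speedups: outside the GIL-releasing JIT kernels, Python-level tile
  bookkeeping limits scaling.
* The packed layout is an output/storage option; engines compute on dense
  working arrays internally.
* No pseudoknots, no co-optimal enumeration, no partition function.
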