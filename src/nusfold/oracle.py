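"""Independent test machinery: brute-force folding and random fixtures.

:func:`brute_force_score` enumerates every nested, bond-valid set of pairs by
plain recursion — position ``i`` is left unpaired, or paired with each
admissible partner ``m`` followed by recursion on the inside and outside
intervals.  Memoization is deliberately absent so the oracle shares no code
path (and no asymptotics) with the dynamic-programming engines it checks;
the search is exponential, hence the length cap.

:func:`random_rna` draws i.i.d. residues from a fixed composition (uniform
by default, matching the uniform-random benchmark sequences the folding
engines are normally exercised on) with a fully deterministic seed contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model import DEFAULT_RULE, RNA_ALPHABET, PairingRule, RnaSequence

#: Default maximum length for the exhaustive search.
DEFAULT_CAP = 16

UNIFORM = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for one random RNA sequence.

    The same ``(n, seed, composition)`` always yields the same sequence.
    ``composition`` gives per-residue probabilities in A, C, G, U order.
    """

    n: int
    seed: int
    composition: Tuple[float, float, float, float] = UNIFORM

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError(
                "composition must be 4 non-negative probabilities summing to 1")


def random_rna(spec: FixtureSpec) -> RnaSequence:
    """Draw the sequence described by ``spec`` (deterministic in the spec)."""
    rng = np.random.default_rng(spec.seed)
    codes = rng.choice(4, size=spec.n, p=np.asarray(spec.composition))
    residues = "".join(RNA_ALPHABET[c] for c in codes)
    return RnaSequence(residues, id=f"random_n{spec.n}_s{spec.seed}")


def random_sequences(count: int, lengths: Sequence[int], seed: int,
                     composition: Tuple[float, ...] = UNIFORM,
                     ) -> List[RnaSequence]:
    """Deterministic batch of random sequences for tests and fixtures.

    ``lengths`` may hold one value per sequence or a pool to draw from
    uniformly.  Per-sequence seeds are spawned from ``seed`` so batches with
    different counts stay prefix-compatible.
    """
    rng = np.random.default_rng(seed)
    lengths = list(lengths)
    out = []
    for i in range(count):
        n = lengths[i] if len(lengths) == count else int(rng.choice(lengths))
        sub = int(rng.integers(0, 2**31 - 1))
        seq = random_rna(FixtureSpec(n=n, seed=sub, composition=composition))
        out.append(RnaSequence(seq.residues, id=f"random_{i + 1}"))
    return out


def brute_force_score(seq: RnaSequence, rule: Optional[PairingRule] = None,
                      cap: int = DEFAULT_CAP) -> int:
    """Maximum nested bond-valid pair count by exhaustive enumeration.

    Considers every set of pairs that is bond-valid, uses each index at most
    once, separates partners by at least two positions and nests without
    crossings.  Raises ``ValueError`` for sequences longer than ``cap``.
    """
    if seq.n > cap:
        raise ValueError(
            f"sequence length {seq.n} exceeds the oracle cap {cap}")
    table = (rule or DEFAULT_RULE).table
    codes = seq.codes

    def best(i: int, j: int) -> int:
        # maximum pairs within the closed interval [i, j]
        if j - i < 2:
            return 0
        score = best(i + 1, j)  # i unpaired
        ci = codes[i]
        for m in range(i + 2, j + 1):  # i paired with m
            if table[ci, codes[m]]:
                v = 1 + best(i + 1, m - 1) + best(m + 1, j)
                if v > score:
                    score = v
        return score

    return best(0, seq.n - 1)
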