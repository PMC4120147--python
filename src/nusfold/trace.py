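"""Traceback: recover one optimal secondary structure from a filled table.

The walk only ever reads the upper triangle via ``ScoreMatrix.entry``, so it
works identically on full, mirrored and packed layouts.  Because many
co-optimal structures usually exist, a fixed tie-break makes the output
deterministic and engine-independent:

1. if the pairing case ``entry(i+1, j-1) + bond(a_i, a_j)`` attains the cell
   value, take it (adding the pair when the bond is 1);
2. otherwise take the smallest split point ``k`` in ``[i, j)`` with
   ``entry(i, k) + entry(k+1, j)`` attaining the value.
"""

from __future__ import annotations

from typing import List, Optional, Tuple, Union

from .model import (
    DEFAULT_RULE,
    PairingRule,
    RnaSequence,
    ScoreMatrix,
    SecondaryStructure,
)


def traceback(matrix: ScoreMatrix, seq: RnaSequence,
              rule: Optional[PairingRule] = None) -> SecondaryStructure:
    """Reconstruct one optimal structure whose pair count equals the score."""
    if matrix.n != seq.n:
        raise ValueError(
            f"matrix dimension {matrix.n} != sequence length {seq.n}")
    if not matrix.filled:
        raise ValueError("score matrix has not been filled")
    rule = rule or DEFAULT_RULE
    table = rule.table
    codes = seq.codes
    pairs: List[Tuple[int, int]] = []
    stack: List[Tuple[int, int]] = [(0, seq.n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        v = matrix.entry(i, j)
        if v == 0:
            continue
        b = int(table[codes[i], codes[j]])
        if matrix.entry(i + 1, j - 1) + b == v:
            if b:
                pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        for k in range(i, j):
            left = matrix.entry(i, k) if k > i else 0
            if left + matrix.entry(k + 1, j) == v:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
        else:  # unreachable on a correctly filled table
            raise ValueError(f"no recurrence case attains entry({i}, {j})")
    return SecondaryStructure(pairs, seq)


def to_dotbracket(structure: SecondaryStructure) -> str:
    """Vienna dot-bracket string: ``(`` / ``)`` for paired bases, ``.`` else."""
    chars = ["."] * structure.sequence.n
    for i, j in structure.pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def parse_dotbracket(
    text: str, sequence: Optional[RnaSequence] = None,
) -> Union[SecondaryStructure, Tuple[Tuple[int, int], ...]]:
    """Parse a dot-bracket string into pairs.

    Returns a :class:`SecondaryStructure` when ``sequence`` is given
    (lengths must agree), otherwise the sorted tuple of 0-based pairs.
    """
    stack: List[int] = []
    pairs: List[Tuple[int, int]] = []
    for idx, c in enumerate(text):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {idx + 1}")
            pairs.append((stack.pop(), idx))
        elif c != ".":
            raise ValueError(f"invalid character {c!r} at position {idx + 1}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1] + 1}")
    if sequence is None:
        return tuple(sorted(pairs))
    if sequence.n != len(text):
        raise ValueError(
            f"structure length {len(text)} != sequence length {sequence.n}")
    return SecondaryStructure(pairs, sequence)
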