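"""Domain types shared by all folding engines.

The central objects are:

* :class:`RnaSequence` — a validated string over the RNA alphabet ``{A,C,G,U}``.
* :class:`PairingRule` — the 0/1 bond scoring function.  By default AU, GC and
  the GU wobble pair score 1 and everything else scores 0.
* :class:`ScoreMatrix` — the dynamic-programming table ``C`` where
  ``entry(i, j)`` (0-based, ``i <= j``) is the maximum number of bonded pairs
  in the subsequence ``a_i .. a_j``.  Three storage layouts are supported:
  ``full`` (upper triangle of an n×n array), ``mirrored`` (each score also
  written to the transposed cell so column reads become row reads) and
  ``packed`` (upper triangle flattened row-major into a 1-D array, halving
  memory).
* :class:`SecondaryStructure` — a nested (pseudoknot-free) set of base pairs.

Conventions applied uniformly across the package: indices are 0-based; the
matrix diagonals ``entry(i, i)`` and ``entry(i, i+1)`` are fixed at 0, so
paired bases are always separated by at least two positions (no adjacent
pairs, minimum hairpin loop of one unpaired base).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Tuple

import numpy as np

RNA_ALPHABET = "ACGU"
_CODE = {c: i for i, c in enumerate(RNA_ALPHABET)}

#: Pairs awarded a bond score of 1 by default: Watson–Crick plus the GU wobble.
DEFAULT_PAIRS: Tuple[str, ...] = ("AU", "GC", "GU")
#: Watson–Crick pairs only (no wobble).
WATSON_CRICK_PAIRS: Tuple[str, ...] = ("AU", "GC")

MATRIX_LAYOUTS = ("full", "mirrored", "packed")


class InvalidSequenceError(ValueError):
    """Input text cannot be normalized to a valid RNA sequence."""


class PairingRule:
    """Symmetric 0/1 scoring of nucleotide pairs.

    Parameters
    ----------
    pairs
        Iterable of two-character strings naming the residue pairs that score
        1 (order within a pair is irrelevant).  Defaults to AU, GC, GU.
    """

    def __init__(self, pairs: Iterable[str] = DEFAULT_PAIRS) -> None:
        table = np.zeros((4, 4), dtype=np.int32)
        canonical = set()
        for p in pairs:
            p = p.upper()
            if len(p) not in (1, 2) or any(c not in _CODE for c in p):
                raise ValueError(f"invalid residue pair {p!r}")
            a, b = (p[0], p[-1])
            table[_CODE[a], _CODE[b]] = 1
            table[_CODE[b], _CODE[a]] = 1
            canonical.add(frozenset((a, b)))
        self._pairs = frozenset(canonical)
        self.table = table
        self.table.setflags(write=False)

    @classmethod
    def watson_crick(cls) -> "PairingRule":
        return cls(WATSON_CRICK_PAIRS)

    @property
    def pairs(self) -> frozenset:
        return self._pairs

    def bond(self, a: str, b: str) -> int:
        """Return 1 if residues ``a`` and ``b`` form a scoring pair, else 0."""
        try:
            return int(self.table[_CODE[a.upper()], _CODE[b.upper()]])
        except KeyError as exc:
            raise InvalidSequenceError(f"invalid residue {exc.args[0]!r}") from None

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PairingRule) and self._pairs == other._pairs

    def __hash__(self) -> int:
        return hash(self._pairs)

    def __repr__(self) -> str:
        names = "+".join(sorted("".join(sorted(p)) for p in self._pairs))
        return f"PairingRule({names})"


DEFAULT_RULE = PairingRule()


def bond(a: str, b: str, rule: Optional[PairingRule] = None) -> int:
    """Bond score of a residue pair under ``rule`` (default AU/GC/GU → 1)."""
    return (rule or DEFAULT_RULE).bond(a, b)


class RnaSequence:
    """A validated RNA sequence over ``{A, C, G, U}``.

    Use :func:`normalize_sequence` (or :meth:`from_string`) to build one from
    arbitrary user text; the constructor itself requires already-normalized
    residues.
    """

    __slots__ = ("residues", "id", "codes")

    def __init__(self, residues: str, id: Optional[str] = None) -> None:
        if not residues:
            raise InvalidSequenceError("empty sequence")
        for pos, c in enumerate(residues, start=1):
            if c not in _CODE:
                raise InvalidSequenceError(
                    f"invalid residue {c!r} at position {pos}"
                )
        self.residues = residues
        self.id = id
        codes = np.fromiter((_CODE[c] for c in residues), dtype=np.int64,
                            count=len(residues))
        codes.setflags(write=False)
        self.codes = codes

    @classmethod
    def from_string(cls, raw: str, id: Optional[str] = None) -> "RnaSequence":
        return normalize_sequence(raw, id=id)

    @property
    def n(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        return self.residues[i]

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RnaSequence) and self.residues == other.residues

    def __hash__(self) -> int:
        return hash(self.residues)

    def __repr__(self) -> str:
        label = f" id={self.id!r}" if self.id else ""
        shown = self.residues if self.n <= 24 else self.residues[:21] + "..."
        return f"RnaSequence({shown!r}, n={self.n}{label})"


def normalize_sequence(raw: str, id: Optional[str] = None) -> RnaSequence:
    """Normalize raw text into an :class:`RnaSequence`.

    Uppercases, strips whitespace, maps DNA thymine ``T`` to ``U`` and rejects
    anything outside ``{A, C, G, U, T}`` (case-insensitive), reporting the
    1-based position of the first offending character.
    """
    if raw is None:
        raise InvalidSequenceError("empty sequence")
    cleaned = "".join(raw.split()).upper()
    if not cleaned:
        raise InvalidSequenceError("empty sequence")
    out = []
    for pos, c in enumerate(cleaned, start=1):
        if c == "T":
            c = "U"
        if c not in _CODE:
            where = f" in record {id!r}" if id else ""
            raise InvalidSequenceError(
                f"invalid residue {c!r} at position {pos}{where}"
            )
        out.append(c)
    return RnaSequence("".join(out), id=id)


def _packed_index(n: int, i: int, j: int) -> int:
    # row-major upper triangle including the diagonal
    return i * (2 * n - i - 1) // 2 + j


class ScoreMatrix:
    """The DP score table with an explicit storage layout.

    ``entry(i, j)`` for 0-based ``0 <= i <= j < n`` is the maximum bonded-pair
    count over subsequence ``a_i .. a_j`` (the classical 1-based table maps as
    ``M[i][j] = C(i+1, j+1)``).
    """

    def __init__(self, n: int, layout: str = "full",
                 data: Optional[np.ndarray] = None, filled: bool = False) -> None:
        if layout not in MATRIX_LAYOUTS:
            raise ValueError(f"unknown layout {layout!r}")
        if n < 1:
            raise ValueError("n must be >= 1")
        self.n = n
        self.layout = layout
        self.filled = filled
        if data is None:
            shape = (n * (n + 1) // 2,) if layout == "packed" else (n, n)
            data = np.zeros(shape, dtype=np.int32)
        else:
            expected = (n * (n + 1) // 2,) if layout == "packed" else (n, n)
            if data.shape != expected:
                raise ValueError(
                    f"data shape {data.shape} incompatible with layout "
                    f"{layout!r} at n={n}")
        self.data = data

    @classmethod
    def from_dense(cls, dense: np.ndarray, layout: str = "full",
                   filled: bool = True) -> "ScoreMatrix":
        """Wrap a dense n×n array whose upper triangle holds the scores."""
        n = dense.shape[0]
        upper = np.triu(dense)
        if layout == "full":
            data = upper
        elif layout == "mirrored":
            # entries are non-negative and the diagonal is its own mirror
            data = np.maximum(upper, upper.T)
        elif layout == "packed":
            data = upper[np.triu_indices(n)].astype(np.int32, copy=False)
        else:
            raise ValueError(f"unknown layout {layout!r}")
        return cls(n, layout, data=np.ascontiguousarray(data), filled=filled)

    def entry(self, i: int, j: int) -> int:
        """Score of subsequence ``a_i .. a_j`` (requires ``i <= j``)."""
        if not (0 <= i <= j < self.n):
            raise IndexError(f"entry({i}, {j}) outside upper triangle of n={self.n}")
        if self.layout == "packed":
            return int(self.data[_packed_index(self.n, i, j)])
        return int(self.data[i, j])

    def upper(self) -> np.ndarray:
        """Dense n×n int array: scores above/on the diagonal, zeros below."""
        if self.layout == "packed":
            out = np.zeros((self.n, self.n), dtype=np.int32)
            out[np.triu_indices(self.n)] = self.data
            return out
        return np.triu(self.data)

    def to_layout(self, layout: str) -> "ScoreMatrix":
        if layout == self.layout:
            return self
        return ScoreMatrix.from_dense(self.upper(), layout, filled=self.filled)

    def upper_equal(self, other: "ScoreMatrix") -> bool:
        """Entrywise equality of the upper triangles."""
        return self.n == other.n and bool(
            np.array_equal(self.upper(), other.upper()))

    def validate(self) -> None:
        """Assert the structural invariants of a filled score table.

        Checks the zero base diagonals, the pair-count upper bound
        ``entry(i,j) <= floor((j-i+1)/2)``, interval monotonicity in both
        arguments, and (for mirrored layout) lower-triangle consistency.
        Raises ``ValueError`` on the first violation.
        """
        n = self.n
        u = self.upper()
        if np.any(np.diagonal(u) != 0):
            raise ValueError("nonzero main diagonal")
        if n > 1 and np.any(np.diagonal(u, 1) != 0):
            raise ValueError("nonzero first superdiagonal")
        ii, jj = np.triu_indices(n)
        if np.any(u[ii, jj] < 0) or np.any(u[ii, jj] > (jj - ii + 1) // 2):
            raise ValueError("entry outside [0, floor((j-i+1)/2)]")
        # entry(i, j) >= entry(i+1, j) and entry(i, j) >= entry(i, j-1)
        sub = np.triu_indices(n, 1)
        if np.any(u[sub] - u[sub[0] + 1, sub[1]] < 0):
            raise ValueError("monotonicity violated in i")
        if np.any(u[sub] - u[sub[0], sub[1] - 1] < 0):
            raise ValueError("monotonicity violated in j")
        if self.layout == "mirrored":
            if not np.array_equal(np.tril(self.data).T, np.triu(self.data)):
                raise ValueError("mirror invariant violated")

    def __repr__(self) -> str:
        state = "filled" if self.filled else "unfilled"
        return f"ScoreMatrix(n={self.n}, layout={self.layout!r}, {state})"


class SecondaryStructure:
    """A nested set of 0-based base pairs ``(i, j)`` with ``i < j``.

    Construction enforces the geometric invariants: indices in range, each
    index in at most one pair, pairs separated by at least two positions and
    no two pairs crossing.  Bond validity under a :class:`PairingRule` is
    checked by :meth:`validate`, since the rule is contextual.
    """

    def __init__(self, pairs: Iterable[Tuple[int, int]],
                 sequence: RnaSequence) -> None:
        self.sequence = sequence
        n = sequence.n
        canon = sorted(tuple(p) for p in pairs)
        partner = np.full(n, -1, dtype=np.int64)
        for i, j in canon:
            if not (0 <= i < j < n):
                raise ValueError(f"pair ({i}, {j}) out of range for n={n}")
            if j - i < 2:
                raise ValueError(f"pair ({i}, {j}) violates separation >= 2")
            if partner[i] != -1 or partner[j] != -1:
                raise ValueError(f"index reused by pair ({i}, {j})")
            partner[i] = j
            partner[j] = i
        # nesting: a stack scan must close pairs in LIFO order
        stack: list[int] = []
        for idx in range(n):
            p = partner[idx]
            if p > idx:
                stack.append(idx)
            elif p >= 0:
                if not stack or stack[-1] != p:
                    raise ValueError(
                        f"crossing pairs involving ({p}, {idx})")
                stack.pop()
        self.pairs: Tuple[Tuple[int, int], ...] = tuple(canon)
        self._partner = partner
        self._partner.setflags(write=False)

    @property
    def score(self) -> int:
        """Number of base pairs (the quantity the DP maximizes)."""
        return len(self.pairs)

    def partner_array(self) -> np.ndarray:
        """Per-position partner index, -1 for unpaired positions."""
        return self._partner

    def validate(self, rule: Optional[PairingRule] = None) -> None:
        """Check every pair scores 1 under ``rule`` (default AU/GC/GU)."""
        rule = rule or DEFAULT_RULE
        seq = self.sequence.residues
        for i, j in self.pairs:
            if rule.bond(seq[i], seq[j]) != 1:
                raise ValueError(
                    f"pair ({i}, {j}) = {seq[i]}·{seq[j]} is not a scoring "
                    f"pair under {rule!r}")

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, SecondaryStructure)
                and self.pairs == other.pairs
                and self.sequence == other.sequence)

    def __repr__(self) -> str:
        return (f"SecondaryStructure(n={self.sequence.n}, "
                f"pairs={self.score})")


@dataclass
class FoldResult:
    """Outcome of folding one sequence with one engine."""

    score: int
    structure: SecondaryStructure
    engine: str
    matrix: Optional[ScoreMatrix] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.score != self.structure.score:
            raise ValueError(
                f"score {self.score} != structure pair count "
                f"{self.structure.score}")
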