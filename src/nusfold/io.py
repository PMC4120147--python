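"""File formats: FASTA input and structure/matrix writers.

FASTA parsing is delegated to Biopython; records are normalized (uppercase,
``T`` mapped to ``U``) on the way in.  Structure writers follow the field's
conventions: dot-bracket is 0-based-free plain text, CT and BPSEQ use
1-based positions with 0 marking an unpaired base.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Iterator, List, TextIO, Union

from Bio import SeqIO

from .model import InvalidSequenceError, RnaSequence, SecondaryStructure
from .model import ScoreMatrix, normalize_sequence

PathLike = Union[str, Path]


def read_fasta(source: Union[PathLike, TextIO]) -> Iterator[RnaSequence]:
    """Yield normalized :class:`RnaSequence` records from a FASTA file.

    Invalid residues raise :class:`InvalidSequenceError` naming the record
    and the offending position; a missing file raises ``FileNotFoundError``.
    """
    for record in SeqIO.parse(source, "fasta"):
        yield normalize_sequence(str(record.seq), id=record.id)


def write_fasta(seqs: Iterable[RnaSequence], handle: TextIO,
                width: int = 70) -> None:
    """Write sequences as FASTA with fixed line wrapping."""
    for idx, seq in enumerate(seqs, start=1):
        header = seq.id or f"seq_{idx}"
        handle.write(f">{header}\n")
        res = seq.residues
        for start in range(0, len(res), width):
            handle.write(res[start:start + width] + "\n")


def to_ct(structure: SecondaryStructure, title: str = "") -> str:
    """CT format: per 1-based position its base, neighbours and partner."""
    seq = structure.sequence
    partner = structure.partner_array()
    n = seq.n
    lines = [f"{n} {title or (seq.id or '')}".rstrip()]
    for i in range(n):
        nxt = i + 2 if i + 1 < n else 0
        mate = int(partner[i]) + 1 if partner[i] >= 0 else 0
        lines.append(f"{i + 1} {seq[i]} {i} {nxt} {mate} {i + 1}")
    return "\n".join(lines) + "\n"


def to_bpseq(structure: SecondaryStructure) -> str:
    """BPSEQ format: ``position base partner`` triples, 0 = unpaired."""
    seq = structure.sequence
    partner = structure.partner_array()
    lines = [
        f"{i + 1} {seq[i]} {int(partner[i]) + 1 if partner[i] >= 0 else 0}"
        for i in range(seq.n)
    ]
    return "\n".join(lines) + "\n"


def matrix_to_tsv(matrix: ScoreMatrix) -> str:
    """Tab-separated dump of the upper triangle; ``.`` below the diagonal.

    Only the upper triangle is ever shown, so the storage layout (full,
    mirrored or packed) never leaks into the output.
    """
    upper = matrix.upper()
    n = matrix.n
    lines = []
    for i in range(n):
        cells = ["." for _ in range(i)] + [
            str(int(upper[i, j])) for j in range(i, n)
        ]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
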