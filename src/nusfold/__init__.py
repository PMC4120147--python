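"""nusfold: base-pair-maximization RNA secondary-structure prediction.

Implements the Nussinov dynamic program with four provably equivalent
engines — the classical four-case recurrence, the simplified two-term
recurrence, a cache-efficient mirrored-storage sweep, and a blocked
wavefront engine that runs the GPU-style tiling decomposition on CPU
workers — plus traceback to dot-bracket, CT and BPSEQ formats.
"""

from __future__ import annotations

from typing import Optional

__version__ = "1.0.0"

from .model import (  # noqa: F401
    DEFAULT_RULE,
    FoldResult,
    InvalidSequenceError,
    PairingRule,
    RnaSequence,
    ScoreMatrix,
    SecondaryStructure,
    bond,
    normalize_sequence,
)
from .engines import (  # noqa: F401
    ENGINE_NAMES,
    EngineSpec,
    fill_chang,
    fill_mirrored,
    fill_original,
    fill_parallel,
    fold_score,
)
from .blocked import BlockGrid, fill_blocked, plan_grid  # noqa: F401
from .trace import parse_dotbracket, to_dotbracket, traceback  # noqa: F401
from .oracle import FixtureSpec, brute_force_score, random_rna  # noqa: F401


def fold(sequence, engine: str = "chang", block_size: int = 32,
         workers: int = 1, rule: Optional[PairingRule] = None,
         layout: Optional[str] = None, keep_matrix: bool = False,
         ) -> FoldResult:
    """Fold one sequence end to end: fill, score and trace back.

    ``sequence`` may be an :class:`RnaSequence` or raw text (normalized on
    the fly).  Returns a :class:`FoldResult`; the filled matrix is retained
    only when ``keep_matrix`` is true.
    """
    if not isinstance(sequence, RnaSequence):
        sequence = normalize_sequence(sequence)
    spec = EngineSpec(name=engine, workers=workers, block_size=block_size,
                      keep_matrix=keep_matrix)
    matrix = fill_parallel(sequence, spec, rule=rule)
    if layout is not None:
        matrix = matrix.to_layout(layout)
    structure = traceback(matrix, sequence, rule=rule)
    return FoldResult(
        score=fold_score(matrix),
        structure=structure,
        engine=engine,
        matrix=matrix if keep_matrix else None,
        metadata={"block_size": block_size, "workers": workers}
        if engine == "blocked" else {"workers": workers},
    )
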