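"""Global and local pairwise protein alignment with affine gaps.

Scoring is delegated to Biopython's ``PairwiseAligner``; this module fixes the
conventions used throughout the package: EMBOSS-style defaults (BLOSUM62,
gap open 10, gap extend 0.5, free end gaps for global mode), identity and
similarity percentages computed over the full alignment length, and a
deterministic choice among co-optimal tracebacks.

A gap of length L costs ``gap_open + gap_extend * (L - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from apctools.seqio import Alphabet, SequenceRecord

__all__ = [
    "AlignMode",
    "AlignmentParams",
    "AlignmentResult",
    "align_global",
    "align_local",
    "align_pair",
    "load_matrix",
]


class AlignMode(str, Enum):
    global_ = "global"
    local = "local"


@lru_cache(maxsize=8)
def load_matrix(name: str) -> substitution_matrices.Array:
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters shared by both alignment modes."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    mode: AlignMode = AlignMode.global_
    #: penalize terminal gaps in global mode (EMBOSS needle default: no)
    end_gap_penalty: bool = False

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        mat = load_matrix(self.matrix)
        arr = np.asarray(mat)
        if not np.allclose(arr, arr.T):
            raise ValueError(f"substitution matrix {self.matrix} not symmetric")


@dataclass(frozen=True)
class AlignmentResult:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = load_matrix(params.matrix)
    # Biopython charges open_gap_score for the first gap residue and
    # extend_gap_score for each subsequent one.
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    if params.mode is AlignMode.local:
        aligner.mode = "local"
    else:
        aligner.mode = "global"
        if not params.end_gap_penalty:
            if hasattr(aligner, "open_end_insertion_score"):
                aligner.open_end_insertion_score = 0.0
                aligner.extend_end_insertion_score = 0.0
                aligner.open_end_deletion_score = 0.0
                aligner.extend_end_deletion_score = 0.0
            else:  # Biopython < 1.86 attribute names
                aligner.target_end_open_gap_score = 0.0
                aligner.target_end_extend_gap_score = 0.0
                aligner.query_end_open_gap_score = 0.0
                aligner.query_end_extend_gap_score = 0.0
    return aligner


def _column_stats(aligned_a: str, aligned_b: str,
                  matrix: substitution_matrices.Array) -> tuple[int, int]:
    ident = simil = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb:
            ident += 1
        if matrix[ca, cb] > 0:
            simil += 1
    return ident, simil


def align_pair(a: SequenceRecord, b: SequenceRecord,
               params: AlignmentParams) -> AlignmentResult:
    """Align two protein records under ``params`` (dispatch on mode)."""
    for rec in (a, b):
        if rec.alphabet is not Alphabet.protein:
            raise ValueError(f"record {rec.id!r}: protein sequence required")
    aligner = _make_aligner(params)
    matrix = load_matrix(params.matrix)

    if params.mode is AlignMode.local:
        score = aligner.score(a.residues, b.residues)
        if score <= 0:
            return AlignmentResult(a.id, b.id, "", "", 0.0, 0.0, 0.0)

    alignment = aligner.align(a.residues, b.residues)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    ident, simil = _column_stats(aligned_a, aligned_b, matrix)
    length = len(aligned_a)
    return AlignmentResult(
        id_a=a.id,
        id_b=b.id,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        identity_pct=100.0 * ident / length if length else 0.0,
        similarity_pct=100.0 * simil / length if length else 0.0,
    )


def align_global(a: SequenceRecord, b: SequenceRecord,
                 params: AlignmentParams | None = None) -> AlignmentResult:
    """Needleman–Wunsch alignment (free end gaps unless configured)."""
    if params is None:
        params = AlignmentParams(mode=AlignMode.global_)
    if params.mode is not AlignMode.global_:
        raise ValueError("align_global requires mode='global'")
    return align_pair(a, b, params)


def align_local(a: SequenceRecord, b: SequenceRecord,
                params: AlignmentParams | None = None) -> AlignmentResult:
    """Smith–Waterman alignment; the empty alignment (score 0) is allowed."""
    if params is None:
        params = AlignmentParams(mode=AlignMode.local)
    if params.mode is not AlignMode.local:
        raise ValueError("align_local requires mode='local'")
    return align_pair(a, b, params)
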