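"""Global protein alignment and percent identity.

Pairwise comparisons throughout the duplication/synteny stage use
Needleman–Wunsch global alignment with BLOSUM62 and affine gaps
(open 10, extend 0.5), via Biopython's PairwiseAligner. Identity is
identical columns over total alignment columns including gap columns
(the EMBOSS-needle convention); dividing by the shorter sequence
length instead is available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class AlignmentResult:
    id_a: str
    id_b: str
    aligned_length: int  # alignment columns, gap columns included
    identical: int
    identity_pct: float
    score: float


@lru_cache(maxsize=None)
def _aligner(open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    aligner.mode = "global"
    return aligner


@lru_cache(maxsize=200_000)
def align_score(a: str, b: str, open_gap: float = 10.0, extend_gap: float = 0.5) -> float:
    """Alignment score only (no traceback); used for partner ranking.

    Cached: the all-vs-all anchor search evaluates each pair from
    both directions.
    """
    if b < a:  # score is symmetric
        a, b = b, a
    return float(_aligner(open_gap, extend_gap).score(a, b))


def global_align(
    a: str,
    b: str,
    id_a: str = "a",
    id_b: str = "b",
    open_gap: float = 10.0,
    extend_gap: float = 0.5,
    identity_denominator: str = "alignment",
) -> AlignmentResult:
    """Globally align two protein sequences and report percent identity.

    identity_denominator: "alignment" (all columns, default) or
    "shorter" (length of the shorter sequence).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner(open_gap, extend_gap)
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    identical = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    if identity_denominator == "alignment":
        denom = len(row_a)
    elif identity_denominator == "shorter":
        denom = min(len(a), len(b))
    else:
        raise ValueError(f"unknown identity denominator {identity_denominator!r}")
    return AlignmentResult(
        id_a, id_b, len(row_a), identical, 100.0 * identical / denom, float(aln.score)
    )
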