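"""Pairwise alignment identity, shared by curation and the rule-2 engine.

Identity here follows the BLAST convention: identical aligned positions
divided by the number of alignment columns (including gap columns). For the
sliding-window rule an alternative denominator — the fixed window length —
is selectable, since published descriptions of the 35%-in-80-aa criterion
leave the denominator unstated.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices


@lru_cache(maxsize=8)
def make_aligner(
    mode: str = "local",
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairwiseAligner:
    """Build a cached affine-gap protein aligner.

    Defaults are the classic protein-search settings: BLOSUM62 with gap
    open 11 / extend 1. ``mode`` is ``"local"`` (Smith-Waterman) or
    ``"global"`` (Needleman-Wunsch).
    """
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open)
    aligner.extend_gap_score = -(gap_extend)
    return aligner


@dataclass(frozen=True)
class IdentityResult:
    identity: float  # identical columns / denominator
    identities: int  # identical aligned columns
    length: int  # alignment columns (local: aligned region only)
    score: float


def alignment_identity(
    seq_a: str,
    seq_b: str,
    mode: str = "local",
    denominator: int | None = None,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> IdentityResult:
    """Best-alignment percent identity between two sequences.

    Takes the first optimal alignment (ties share the same score; identity
    of co-optimal alignments can differ marginally, which is why thresholds
    in this package are config-exposed rather than hair-splitting).
    ``denominator=None`` divides by the alignment length; an explicit integer
    (e.g. the window size) divides by that instead.
    """
    aligner = make_aligner(mode, matrix, gap_open, gap_extend)
    alignments = aligner.align(seq_a, seq_b)
    try:
        best = alignments[0]
    except IndexError:  # no alignment with positive score (local mode)
        return IdentityResult(0.0, 0, 0, 0.0)
    counts = best.counts()
    length = best.length
    if length == 0:
        return IdentityResult(0.0, 0, 0, float(best.score))
    denom = denominator if denominator is not None else length
    return IdentityResult(counts.identities / denom, counts.identities, length, float(best.score))
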