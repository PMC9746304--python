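"""Local pairwise protein alignment with Karlin–Altschul E-values.

Optimal Smith–Waterman alignment under affine gap costs, scored with
BLOSUM62 by default (gap of length g costs open + g*extend, i.e. the BLASTP
11/1 convention). The alignment engine is Biopython's C ``PairwiseAligner``;
the surrounding statistics (bit scores, E = K*m*n*exp(-lambda*S)) use the
standard gapped BLOSUM62 constants lambda=0.267, K=0.041.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringParams",
    "LocalAlignmentHit",
    "default_params",
    "local_align",
    "evalue_of",
    "bit_score_of",
]


@dataclass
class ScoringParams:
    """Substitution matrix, affine gap penalties and Karlin–Altschul constants.

    ``gap_open``/``gap_extend`` are positive costs; a gap of length g costs
    ``gap_open + g * gap_extend``. ``lam`` is in nats per raw-score unit.
    """

    matrix: substitution_matrices.Array
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive costs")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    def score(self, a: str, b: str) -> float:
        return self.matrix[a, b]


@lru_cache(maxsize=None)
def _blosum62_xworst() -> substitution_matrices.Array:
    m = substitution_matrices.load("BLOSUM62")
    worst = m.min()
    # conservative ambiguity handling: X (and B/Z/*) score as the matrix minimum
    for amb in "XBZ*":
        if amb in m.alphabet:
            for a in m.alphabet:
                m[amb, a] = worst
                m[a, amb] = worst
    return m


def default_params() -> ScoringParams:
    """BLOSUM62 with 11/1 affine gaps and standard gapped constants."""
    return ScoringParams(matrix=_blosum62_xworst())


@dataclass
class LocalAlignmentHit:
    """Best local alignment between a query and a subject sequence.

    ``percent_identity`` is over aligned columns of the hit region, counting
    gapped columns in the denominator. Spans are 1-based inclusive residue
    intervals. ``aligned_pairs`` lists (query_pos, subject_pos) with ``None``
    marking a gap on that side (positions 1-based).
    """

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    percent_identity: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    aligned_pairs: list[tuple[int | None, int | None]] = field(repr=False)

    @property
    def aligned_columns(self) -> int:
        return len(self.aligned_pairs)


def _make_aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = params.matrix
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def bit_score_of(raw_score: float, params: ScoringParams) -> float:
    return (params.lam * raw_score - math.log(params.K)) / math.log(2.0)


def evalue_of(
    raw_score: float, db_residues: int, query_len: int, params: ScoringParams
) -> float:
    """Karlin–Altschul expected hit count: E = K * m * n * exp(-lambda * S)."""
    return params.K * query_len * db_residues * math.exp(-params.lam * raw_score)


def local_align(
    query: str,
    subject: str,
    params: ScoringParams | None = None,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    db_residues: int | None = None,
) -> LocalAlignmentHit | None:
    """Optimal local alignment of two protein sequences, or ``None``.

    Returns ``None`` for empty input or when no positive-scoring local
    alignment exists. E-values are computed against ``db_residues`` (defaults
    to the subject length). The traceback is deterministic (the aligner's
    canonical first alignment).
    """
    if not query or not subject:
        return None
    if params is None:
        params = default_params()
    query = query.upper()
    subject = subject.upper()
    aligner = _make_aligner(params)
    score = aligner.score(query, subject)
    if score <= 0:
        return None
    aln = aligner.align(query, subject)[0]
    blocks = np.asarray(aln.aligned)  # shape (2, nblocks, 2)
    qblocks, sblocks = blocks[0], blocks[1]
    pairs: list[tuple[int | None, int | None]] = []
    identical = 0
    for bi, ((qs, qe), (ss, se)) in enumerate(zip(qblocks, sblocks)):
        if bi > 0:
            pq, ps = qblocks[bi - 1][1], sblocks[bi - 1][1]
            for q in range(pq, qs):  # gap in subject
                pairs.append((q + 1, None))
            for s in range(ps, ss):  # gap in query
                pairs.append((None, s + 1))
        for q, s in zip(range(qs, qe), range(ss, se)):
            pairs.append((q + 1, s + 1))
            if query[q] == subject[s]:
                identical += 1
    pident = 100.0 * identical / len(pairs) if pairs else 0.0
    n = db_residues if db_residues is not None else len(subject)
    return LocalAlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=int(round(score)),
        bit_score=bit_score_of(score, params),
        e_value=evalue_of(score, n, len(query), params),
        percent_identity=pident,
        query_span=(int(qblocks[0][0]) + 1, int(qblocks[-1][1])),
        subject_span=(int(sblocks[0][0]) + 1, int(sblocks[-1][1])),
        aligned_pairs=pairs,
    )
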