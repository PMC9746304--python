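"""Projection of a candidate sequence onto reference-MSA columns.

Globally aligns a candidate protein against the column profile of a
reference alignment without ever altering the reference columns (the
"keeplength" contract): every candidate residue is either assigned to a
reference column or marked as an insertion, and every reference column
either receives a candidate residue or is a gap. The resulting mapping
drives the overlap filter (fraction of gapped columns, fraction of
unassignable residues) and the catalytic-triad check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ..errors import DataError
from .pairwise import ScoringParams, default_params
from .phmm import AA_ORDER, _AA_INDEX

__all__ = ["ColumnMapping", "map_to_reference", "overlap_fractions", "INSERTION", "GAP"]

INSERTION = -1  # candidate residue not assignable to any reference column
GAP = -1  # reference column with no candidate residue

_GAP_CHARS = frozenset("-.")


@dataclass
class ColumnMapping:
    """Monotone assignment between candidate residues and reference columns.

    ``residue_to_column[i]`` is the 0-based reference column of candidate
    residue i, or :data:`INSERTION`. ``column_to_residue[c]`` is the 0-based
    candidate residue index in column c, or :data:`GAP`.
    """

    reference_column_count: int
    candidate: str
    residue_to_column: np.ndarray = field(repr=False)
    column_to_residue: np.ndarray = field(repr=False)

    def residue_at_column(self, column: int) -> str | None:
        """Candidate residue letter occupying a 0-based column, or None (gap)."""
        idx = int(self.column_to_residue[column])
        return None if idx == GAP else self.candidate[idx]


@njit(cache=True)
def _nw_affine_profile(S, gap_open_cost, gap_extend_cost):  # pragma: no cover - jit
    """Global affine-gap DP of candidate rows vs profile columns.

    ``S[i, j]`` scores candidate residue i against column j. A gap of length
    g costs gap_open_cost + (g-1)*gap_extend_cost (the opening move already
    includes one extension). Returns traceback pointers for the three states
    (M=diagonal, X=gap-in-profile/insertion, Y=gap-in-candidate/column gap)
    and the winning end state, preferring M, then Y, then X on ties.
    """
    L, C = S.shape
    NEG = -1e30
    M = np.full((L + 1, C + 1), NEG)
    X = np.full((L + 1, C + 1), NEG)
    Y = np.full((L + 1, C + 1), NEG)
    pM = np.zeros((L + 1, C + 1), dtype=np.int8)
    pX = np.zeros((L + 1, C + 1), dtype=np.int8)
    pY = np.zeros((L + 1, C + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, L + 1):
        X[i, 0] = -gap_open_cost - (i - 1) * gap_extend_cost
        pX[i, 0] = 1
    for j in range(1, C + 1):
        Y[0, j] = -gap_open_cost - (j - 1) * gap_extend_cost
        pY[0, j] = 2
    for i in range(1, L + 1):
        for j in range(1, C + 1):
            s = S[i - 1, j - 1]
            # M: consume residue i and column j
            bm, pb = M[i - 1, j - 1], 0
            if Y[i - 1, j - 1] > bm:
                bm, pb = Y[i - 1, j - 1], 2
            if X[i - 1, j - 1] > bm:
                bm, pb = X[i - 1, j - 1], 1
            M[i, j] = bm + s
            pM[i, j] = pb
            # X: consume residue i (insertion)
            open_x = M[i - 1, j] - gap_open_cost
            ext_x = X[i - 1, j] - gap_extend_cost
            if open_x >= ext_x:
                X[i, j] = open_x
                pX[i, j] = 0
            else:
                X[i, j] = ext_x
                pX[i, j] = 1
            # Y: consume column j (gap column)
            open_y = M[i, j - 1] - gap_open_cost
            ext_y = Y[i, j - 1] - gap_extend_cost
            if open_y >= ext_y:
                Y[i, j] = open_y
                pY[i, j] = 0
            else:
                Y[i, j] = ext_y
                pY[i, j] = 2
    end_state = 0
    best = M[L, C]
    if Y[L, C] > best:
        best, end_state = Y[L, C], 2
    if X[L, C] > best:
        best, end_state = X[L, C], 1
    return pM, pX, pY, end_state


def _profile_scores(
    msa_rows: list[str], candidate: str, params: ScoringParams
) -> np.ndarray:
    """(L, C) expected substitution scores of candidate residues vs columns."""
    width = len(msa_rows[0])
    freqs = np.zeros((width, 20))
    for row in msa_rows:
        for c, ch in enumerate(row):
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                freqs[c, idx] += 1.0
    occ = freqs.sum(axis=1, keepdims=True)
    occ[occ == 0] = 1.0
    freqs /= occ
    B = np.array(
        [[params.matrix[a, b] for b in AA_ORDER] for a in AA_ORDER], dtype=float
    )
    col_scores = freqs @ B.T  # (C, 20): expected score of residue r in column c
    worst = B.min()
    codes = np.array([_AA_INDEX.get(ch, -1) for ch in candidate.upper()])
    S = np.empty((len(candidate), width))
    known = codes >= 0
    S[known] = col_scores[:, codes[known]].T
    S[~known] = worst
    return S


def map_to_reference(
    msa: list[tuple[str, str]],
    candidate: str,
    params: ScoringParams | None = None,
) -> ColumnMapping:
    """Align a candidate to a reference MSA's columns without altering them.

    Global alignment of the candidate against the MSA column profile under
    the same affine gap costs as pairwise search. The reference column count
    is preserved exactly; candidate residues that cannot be assigned to a
    column are marked insertions.
    """
    if not candidate:
        raise DataError("cannot map an empty candidate")
    rows = [row.upper() for _, row in msa]
    if not rows:
        raise DataError("reference MSA is empty")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise DataError("ragged reference MSA")
    if params is None:
        params = default_params()
    S = _profile_scores(rows, candidate, params)
    open_cost = float(params.gap_open + params.gap_extend)
    ext_cost = float(params.gap_extend)
    pM, pX, pY, state = _nw_affine_profile(S, open_cost, ext_cost)
    L, C = len(candidate), width
    res_to_col = np.full(L, INSERTION, dtype=np.int64)
    col_to_res = np.full(C, GAP, dtype=np.int64)
    i, j = L, C
    while i > 0 or j > 0:
        if state == 0:  # M
            prev = pM[i, j]
            res_to_col[i - 1] = j - 1
            col_to_res[j - 1] = i - 1
            i, j, state = i - 1, j - 1, prev
        elif state == 1:  # X: insertion
            prev = pX[i, j]
            i, state = i - 1, prev
        else:  # Y: gap column
            prev = pY[i, j]
            j, state = j - 1, prev
    return ColumnMapping(
        reference_column_count=C,
        candidate=candidate.upper(),
        residue_to_column=res_to_col,
        column_to_residue=col_to_res,
    )


def overlap_fractions(mapping: ColumnMapping) -> tuple[float, float]:
    """(gap_fraction, unaligned_fraction) of a column mapping.

    gap_fraction = gapped reference columns / reference columns;
    unaligned_fraction = insertion residues / candidate length.
    """
    gaps = int((mapping.column_to_residue == GAP).sum())
    inserts = int((mapping.residue_to_column == INSERTION).sum())
    return (
        gaps / mapping.reference_column_count,
        inserts / len(mapping.candidate),
    )
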