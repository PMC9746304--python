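"""Profile hidden Markov models built from a reference alignment.

A simplified plan7-style profile: alignment columns with gap fraction < 0.5
become match states; residue counts get Laplace (+1) pseudocounts; match
emissions are stored as log-odds against the BLOSUM62 marginal background, so
insert states (background emitters) contribute zero and the forward
algorithm returns a log-odds score directly, reported in bits.

E-values come from a Gumbel (EVD) tail fitted by the method of moments to
forward scores of residue-shuffled copies of the query (seeded, hence
deterministic).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from ..errors import DataError

__all__ = [
    "AA_ORDER",
    "BACKGROUND",
    "ProfileHMM",
    "build_phmm",
    "forward_bits",
    "phmm_score",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

# BLOSUM62 marginal residue frequencies (Robinson–Robinson style background)
BACKGROUND = np.array(
    [
        0.074,  # A
        0.025,  # C
        0.054,  # D
        0.054,  # E
        0.047,  # F
        0.074,  # G
        0.026,  # H
        0.068,  # I
        0.058,  # K
        0.099,  # L
        0.025,  # M
        0.045,  # N
        0.039,  # P
        0.034,  # Q
        0.052,  # R
        0.057,  # S
        0.051,  # T
        0.073,  # V
        0.013,  # W
        0.032,  # Y
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()

_GAP_CHARS = frozenset("-.")
_M, _I, _D = 0, 1, 2
_EULER_GAMMA = 0.5772156649015329


@dataclass
class ProfileHMM:
    """Profile HMM over match/insert/delete states.

    ``match_logodds``: (K, 20) natural-log odds vs background for match
    states 1..K. ``log_trans``: (K+1, 3, 3) log transition probabilities from
    level-k states (M_k, I_k, D_k) to (M_{k+1}, I_k, D_{k+1}); level 0 is the
    begin state, 'to M' at level K is the end state. Invalid transitions are
    -inf.
    """

    n_match_states: int
    match_logodds: np.ndarray = field(repr=False)
    log_trans: np.ndarray = field(repr=False)
    source_msa_id: str = ""
    match_columns: tuple[int, ...] = ()

    def consensus(self) -> str:
        """Most probable residue per match state (under the emission odds)."""
        return "".join(AA_ORDER[i] for i in self.match_logodds.argmax(axis=1))

    # --- serialization (versioned text format) -------------------------------
    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write("micromine-phmm v1\n")
        buf.write(f"K {self.n_match_states}\n")
        buf.write(f"source {self.source_msa_id or '-'}\n")
        buf.write(f"alphabet {AA_ORDER}\n")
        buf.write("match_columns " + ",".join(map(str, self.match_columns)) + "\n")
        buf.write("match_logodds\n")
        for row in self.match_logodds:
            buf.write(" ".join(f"{v:.8f}" for v in row) + "\n")
        buf.write("log_trans\n")
        for k in range(self.n_match_states + 1):
            flat = self.log_trans[k].reshape(-1)
            buf.write(" ".join("-inf" if not np.isfinite(v) else f"{v:.8f}" for v in flat) + "\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "ProfileHMM":
        lines = text.strip().splitlines()
        if not lines or lines[0].strip() != "micromine-phmm v1":
            raise DataError("not a micromine-phmm v1 file")
        k = int(lines[1].split()[1])
        source = lines[2].split(maxsplit=1)[1]
        if lines[3].split()[1] != AA_ORDER:
            raise DataError("unexpected alphabet in model file")
        cols_field = lines[4].split(maxsplit=1)
        cols = tuple(int(c) for c in cols_field[1].split(",")) if len(cols_field) > 1 and cols_field[1] else ()
        assert lines[5].strip() == "match_logodds"
        emis = np.array([[float(v) for v in lines[6 + i].split()] for i in range(k)])
        assert lines[6 + k].strip() == "log_trans"
        trans = np.array(
            [[float(v) for v in lines[7 + k + i].split()] for i in range(k + 1)]
        ).reshape(k + 1, 3, 3)
        return cls(
            n_match_states=k,
            match_logodds=emis,
            log_trans=trans,
            source_msa_id="" if source == "-" else source,
            match_columns=cols,
        )


def _encode(seq: str) -> np.ndarray:
    """Residues to indices; unknown/ambiguous letters become -1 (neutral)."""
    return np.array([_AA_INDEX.get(ch, -1) for ch in seq.upper()], dtype=np.int64)


def build_phmm(
    msa: list[tuple[str, str]],
    background: np.ndarray | None = None,
    source_msa_id: str = "",
) -> ProfileHMM:
    """Build a profile HMM from an aligned protein FASTA (list of (name, row)).

    Columns with gap fraction < 0.5 are match states. Emission and transition
    probabilities use Laplace (+1) pseudocounts and are normalized before the
    emissions are converted to log-odds against ``background``.
    """
    if len(msa) < 2:
        raise DataError("profile construction needs at least 2 aligned sequences")
    rows = [row.upper() for _, row in msa]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise DataError("ragged alignment: aligned sequences differ in length")
    if background is None:
        background = BACKGROUND
    nseq = len(rows)
    gap_frac = [
        sum(1 for r in rows if r[c] in _GAP_CHARS) / nseq for c in range(width)
    ]
    match_cols = [c for c in range(width) if gap_frac[c] < 0.5]
    K = len(match_cols)
    if K == 0:
        raise DataError("alignment yields no match states")
    is_match = [False] * width
    for c in match_cols:
        is_match[c] = True
    col_to_state = {c: k + 1 for k, c in enumerate(match_cols)}

    emis_counts = np.ones((K, 20))  # Laplace
    trans_counts = np.ones((K + 1, 3, 3))
    # invalid cells get zero count so they normalize to probability 0
    trans_counts[K, :, _D] = 0.0  # no delete state beyond K
    trans_counts[0, _D, :] = 0.0  # no D_0
    trans_counts[0, _I, :] = 1.0  # I_0 (N-terminal inserts) is valid

    for r in rows:
        prev_state, prev_level = _M, 0  # begin
        for c in range(width):
            ch = r[c]
            gap = ch in _GAP_CHARS
            if is_match[c]:
                level = col_to_state[c]
                state = _D if gap else _M
                trans_counts[prev_level, prev_state, state] += 1
                if not gap and ch in _AA_INDEX:
                    emis_counts[level - 1, _AA_INDEX[ch]] += 1
                prev_state, prev_level = state, level
            elif not gap:
                trans_counts[prev_level, prev_state, _I] += 1
                prev_state = _I
        trans_counts[prev_level, prev_state, _M] += 1  # to end

    emis = emis_counts / emis_counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        tprob = trans_counts / trans_counts.sum(axis=2, keepdims=True)
        log_trans = np.where(tprob > 0, np.log(tprob), -np.inf)
        match_logodds = np.log(emis / background)
    return ProfileHMM(
        n_match_states=K,
        match_logodds=match_logodds,
        log_trans=log_trans,
        source_msa_id=source_msa_id,
        match_columns=tuple(match_cols),
    )


def _chain_deletes(a: np.ndarray, tdd: np.ndarray) -> np.ndarray:
    """Solve D_k = logaddexp(a_k, D_{k-1} + tdd_{k-1}) along the last axis.

    ``a`` has shape (..., K) holding entry contributions into each delete
    state; ``tdd`` has shape (K,) with tdd[k-1] the D_{k-1}->D_k log prob
    (first element unused).
    """
    S = np.concatenate([[0.0], np.cumsum(tdd[1:])])  # offsets, shape (K,)
    shifted = a - S
    with np.errstate(invalid="ignore"):
        acc = np.logaddexp.accumulate(shifted, axis=-1)
    return acc + S


def forward_bits(model: ProfileHMM, seqs: list[str]) -> np.ndarray:
    """Log-odds forward scores in bits for equal-length sequences (batched)."""
    if not seqs:
        return np.zeros(0)
    L = len(seqs[0])
    if L == 0:
        raise DataError("cannot score an empty sequence")
    if any(len(s) != L for s in seqs):
        raise DataError("batched sequences must share one length")
    K = model.n_match_states
    codes = np.stack([_encode(s) for s in seqs])  # (B, L)
    B = codes.shape[0]
    t = model.log_trans  # (K+1, 3, 3)
    # per-level transition vectors, aligned so index k refers to level k
    tMM, tMI, tMD = t[:, _M, _M], t[:, _M, _I], t[:, _M, _D]
    tIM, tII, tID = t[:, _I, _M], t[:, _I, _I], t[:, _I, _D]
    tDM, tDI, tDD = t[:, _D, _M], t[:, _D, _I], t[:, _D, _D]
    # emission log-odds with a neutral row for unknown residues (code -1)
    emis = np.vstack([model.match_logodds.T, np.zeros((1, K))])  # (21, K)

    NEG = -np.inf
    fM = np.full((B, K + 1), NEG)
    fI = np.full((B, K + 1), NEG)
    fM[:, 0] = 0.0  # begin
    # D_{k-1}->D_k steps; index 1 (from the nonexistent D_0) is masked to 0,
    # harmless because the D_0 value itself is always -inf
    tdd_step = np.concatenate([[0.0], tDD[:-1]])
    tdd_step[~np.isfinite(tdd_step)] = 0.0
    # delete chain reachable from begin before emitting anything
    a0 = np.full((B, K + 1), NEG)
    a0[:, 1] = tMD[0]
    fD = _chain_deletes(a0, tdd_step)
    fD[:, 0] = NEG

    for i in range(L):
        e = emis[codes[:, i]]  # (B, K)
        newM = np.full((B, K + 1), NEG)
        newI = np.full((B, K + 1), NEG)
        # M_k from level k-1 states
        fromM = fM[:, :-1] + tMM[:K]
        fromI = fI[:, :-1] + tIM[:K]
        fromD = fD[:, :-1] + tDM[:K]
        newM[:, 1:] = e + np.logaddexp(np.logaddexp(fromM, fromI), fromD)
        # I_k from level k states (insert emits at background: log-odds 0)
        newI = np.logaddexp(
            np.logaddexp(fM + tMI, fI + tII), fD + tDI
        )
        # D_k chain within this position
        a = np.full((B, K + 1), NEG)
        a[:, 1:] = np.logaddexp(newM[:, :-1] + tMD[:K], newI[:, :-1] + tID[:K])
        newD = _chain_deletes(a, tdd_step)
        newD[:, 0] = NEG
        fM, fI, fD = newM, newI, newD

    end = np.logaddexp(
        np.logaddexp(fM[:, K] + tMM[K], fI[:, K] + tIM[K]), fD[:, K] + tDM[K]
    )
    return end / math.log(2.0)


def _gumbel_fit(scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel fit; returns (mu, lambda_gumbel)."""
    sd = float(scores.std(ddof=1))
    if sd <= 0:
        return float(scores.mean()), np.inf
    lam = math.pi / (sd * math.sqrt(6.0))
    mu = float(scores.mean()) - _EULER_GAMMA / lam
    return mu, lam


def phmm_score(
    model: ProfileHMM,
    seq: str,
    calibration_n: int = 200,
    seed: int = 1234,
    db_size: int = 1,
) -> tuple[float, float]:
    """Forward log-odds score (bits) and a shuffle-calibrated E-value.

    The score does not depend on ``calibration_n``; only the E-value does.
    ``db_size`` scales the tail probability into an expected hit count over
    the database the query was drawn from.
    """
    if not seq:
        raise DataError("cannot score an empty sequence")
    bits = float(forward_bits(model, [seq])[0])
    rng = np.random.default_rng(seed)
    letters = np.array(list(seq.upper()))
    shuffles = ["".join(letters[rng.permutation(len(letters))]) for _ in range(calibration_n)]
    null_scores = forward_bits(model, shuffles)
    mu, lam = _gumbel_fit(null_scores)
    if not np.isfinite(lam):
        pval = 0.0 if bits > mu else 1.0
    else:
        x = lam * (bits - mu)
        # P(S >= s) = 1 - exp(-exp(-x)), computed stably
        pval = float(-np.expm1(-np.exp(-x)))
    return bits, db_size * pval
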