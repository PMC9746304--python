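"""Class II microcin precursor screening.

Two-stage homology detection over the per-sample nonredundant proteome:
an inclusive 30–150 aa length gate, a pairwise-alignment prescreen against
each verified precursor (best-of, E <= 1e-3 over the training database),
and profile-HMM confirmation (E <= 10). Survivors are reported per genomic
locus with percent identity measured over the prescreen hit region; hits at
100% identity are flagged "verified", all others "novel".

The double-glycine-type leader motif (last GG/GA in the N-terminal region)
is annotated for inspection but never used as a filter.
"""

from __future__ import annotations

from .config import PipelineConfig
from .errors import DataError
from .hits import ComponentHit, best_hit_per_contig, filter_by_length
from .homology.pairwise import LocalAlignmentHit, ScoringParams, default_params, local_align
from .homology.phmm import ProfileHMM, phmm_score
from .ingest import NonRedundantSet, ProteinRecord
from .training import TrainingSet

__all__ = ["screen_microcins", "prescreen_best", "leader_motif_position"]


def leader_motif_position(seq: str, n_terminal_fraction: float = 0.4) -> int | None:
    """1-based position of the second residue of the last GG/GA in the leader.

    The leader of a class II precursor ends in a double-glycine-type (GG or
    GA) cleavage site; the scan is restricted to the N-terminal part of the
    precursor (default 40%) so core-peptide glycines are not mistaken for a
    cleavage site. Returns None when no motif is present.
    """
    limit = max(2, int(len(seq) * n_terminal_fraction))
    region = seq[:limit].upper()
    for i in range(len(region) - 2, -1, -1):
        if region[i] == "G" and region[i + 1] in ("G", "A"):
            return i + 2
    return None


def prescreen_best(
    record: ProteinRecord,
    training: TrainingSet,
    params: ScoringParams,
    evalue_max: float,
) -> tuple[str, LocalAlignmentHit] | None:
    """Best pairwise hit of a protein against any training sequence.

    E-values are computed over the whole training database (sum of subject
    lengths), mirroring a search against a database of the verified
    sequences. Returns (subject_name, hit) or None when nothing reaches
    ``evalue_max``.
    """
    db_residues = training.total_residues
    best: tuple[str, LocalAlignmentHit] | None = None
    for name, subject in training.sequences:
        hit = local_align(
            record.sequence,
            subject,
            params,
            query_id=record.protein_id,
            subject_id=name,
            db_residues=db_residues,
        )
        if hit is None or hit.e_value > evalue_max:
            continue
        if best is None or (hit.raw_score, -hit.e_value) > (
            best[1].raw_score,
            -best[1].e_value,
        ):
            best = (name, hit)
    return best


def screen_microcins(
    nrset: NonRedundantSet,
    training: TrainingSet,
    model: ProfileHMM,
    config: PipelineConfig | None = None,
    params: ScoringParams | None = None,
) -> list[ComponentHit]:
    """Putative microcin precursor hits, one per genomic locus.

    Returns all surviving hits (not yet reduced per contig); apply
    :func:`micromine.hits.best_hit_per_contig` for reporting.
    """
    if training.component != "microcin":
        raise DataError(f"expected microcin training set, got {training.component}")
    if not training.sequences:
        raise DataError("empty microcin training set")
    if config is None:
        config = PipelineConfig()
    if params is None:
        params = default_params()
    gated = filter_by_length(nrset, *config.microcin_len)
    db_size = max(len(gated), 1)
    hits: list[ComponentHit] = []
    for record in gated:
        pre = prescreen_best(record, training, params, config.prescreen_evalue_max)
        if pre is None:
            continue
        subject_name, aln = pre
        bits, hmm_e = phmm_score(
            model,
            record.sequence,
            calibration_n=config.calibration_n,
            seed=config.calibration_seed,
            db_size=db_size,
        )
        if hmm_e > config.hmm_evalue_max:
            continue
        pident = aln.percent_identity
        flag = "verified" if abs(pident - 100.0) < 1e-9 else "novel"
        motif = leader_motif_position(record.sequence)
        for locus in record.loci:
            hits.append(
                ComponentHit(
                    component="microcin",
                    protein=record,
                    locus=locus,
                    best_subject=subject_name,
                    percent_identity=pident,
                    alignment=aln,
                    hmm_bits=bits,
                    hmm_evalue=hmm_e,
                    verified_flag=flag,
                    leader_motif_pos=motif,
                )
            )
    return hits
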