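"""Immunity-protein candidate identification.

Immunity proteins protect the producer from its own microcin. They are too
sequence-diverse for reliable homology detection, so candidates are proposed
by genomic context instead: the three protein-coding genes on each side of
the best microcin hit on a contig (six neighbors), kept if 30-250 aa long.
Transmembrane helices — typical of known immunity proteins — are annotated
with a Kyte-Doolittle hydropathy heuristic as supporting information only,
never as a filter. A homology-based search against known immunity proteins
is also run for the best-hits report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .errors import DataError
from .hits import ComponentHit, best_hit_per_contig, filter_by_length
from .homology.pairwise import ScoringParams, default_params
from .homology.phmm import ProfileHMM, phmm_score
from .ingest import GeneLocus, NonRedundantSet, ProteinRecord, protein_hash
from .microcins import prescreen_best
from .training import TrainingSet

__all__ = [
    "ImmunityCandidate",
    "neighbor_candidates",
    "filter_immunity",
    "predict_tm_helices",
    "homology_immunity_hit",
    "KYTE_DOOLITTLE",
]

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass
class ImmunityCandidate:
    """A gene-neighborhood immunity candidate for one microcin hit."""

    protein: ProteinRecord
    locus: GeneLocus
    microcin_protein_id: str
    offset: int  # signed gene-rank distance from the microcin gene, never 0
    length_aa: int
    tm_helix_count: int
    same_strand_as_microcin: bool


def neighbor_candidates(
    contig_genes: list[tuple[GeneLocus, str]],
    microcin_locus: GeneLocus,
    window: int = 3,
) -> list[tuple[int, GeneLocus, str]]:
    """Up to ``window`` genes on each side of the microcin gene, by gene rank.

    Distance is measured in gene ranks (gene_index), strand-agnostic; the
    microcin gene itself is excluded. Results are sorted by |offset| then
    sign (upstream first), and truncated at contig edges.
    """
    ordered = sorted(contig_genes, key=lambda t: t[0].gene_index)
    anchor = None
    for i, (locus, _) in enumerate(ordered):
        if (
            locus.contig_id == microcin_locus.contig_id
            and locus.start == microcin_locus.start
            and locus.end == microcin_locus.end
            and locus.strand == microcin_locus.strand
        ):
            anchor = i
            break
    if anchor is None:
        raise DataError(
            f"microcin locus {microcin_locus.contig_id}:{microcin_locus.start}-"
            f"{microcin_locus.end} not found among contig genes"
        )
    out: list[tuple[int, GeneLocus, str]] = []
    for offset in range(-window, window + 1):
        if offset == 0:
            continue
        j = anchor + offset
        if 0 <= j < len(ordered):
            locus, seq = ordered[j]
            out.append((offset, locus, seq))
    out.sort(key=lambda t: (abs(t[0]), t[0]))
    return out


def filter_immunity(
    candidates: list[tuple[int, GeneLocus, str]],
    microcin: ComponentHit | None = None,
    lo: int = 30,
    hi: int = 250,
    *,
    tm_window: int = 19,
    tm_threshold: float = 1.6,
) -> list[ImmunityCandidate]:
    """Inclusive length filter [lo, hi]; survivors get a TM-helix annotation."""
    microcin_id = microcin.protein.protein_id if microcin else ""
    microcin_strand = microcin.locus.strand if microcin else "+"
    out: list[ImmunityCandidate] = []
    for offset, locus, seq in candidates:
        if not lo <= len(seq) <= hi:
            continue
        out.append(
            ImmunityCandidate(
                protein=ProteinRecord(
                    protein_id=protein_hash(seq), sequence=seq, loci=(locus,)
                ),
                locus=locus,
                microcin_protein_id=microcin_id,
                offset=offset,
                length_aa=len(seq),
                tm_helix_count=predict_tm_helices(
                    seq, window=tm_window, threshold=tm_threshold
                ),
                same_strand_as_microcin=(locus.strand == microcin_strand),
            )
        )
    return out


def predict_tm_helices(seq: str, window: int = 19, threshold: float = 1.6) -> int:
    """Count putative transmembrane helices by mean hydropathy.

    Slides a ``window``-residue Kyte-Doolittle window; windows with mean
    hydropathy >= ``threshold`` qualify, and overlapping qualifying windows
    merge into a single helix. Annotation only — never a screening
    criterion. Sequences shorter than the window give 0.
    """
    if not seq:
        raise DataError("cannot annotate an empty sequence")
    if len(seq) < window:
        return 0
    values = np.array([KYTE_DOOLITTLE.get(ch, 0.0) for ch in seq.upper()])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    qualifying = np.flatnonzero(means >= threshold)
    if qualifying.size == 0:
        return 0
    # windows starting within `window` of each other share residues -> merge
    breaks = np.flatnonzero(np.diff(qualifying) >= window)
    return int(breaks.size + 1)


def homology_immunity_hit(
    nrset: NonRedundantSet,
    training: TrainingSet,
    model: ProfileHMM,
    config: PipelineConfig | None = None,
    params: ScoringParams | None = None,
) -> list[ComponentHit]:
    """Homology search against known immunity proteins; best hit per contig.

    Same two-stage machinery as the microcin screen but with the immunity
    length gate (30-250 aa) and no verified/novel flag. Feeds the best-hits
    report only.
    """
    if training.component != "immunity":
        raise DataError(f"expected immunity training set, got {training.component}")
    if config is None:
        config = PipelineConfig()
    if params is None:
        params = default_params()
    gated = filter_by_length(nrset, *config.immunity_len)
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
        for locus in record.loci:
            hits.append(
                ComponentHit(
                    component="immunity",
                    protein=record,
                    locus=locus,
                    best_subject=subject_name,
                    percent_identity=aln.percent_identity,
                    alignment=aln,
                    hmm_bits=bits,
                    hmm_evalue=hmm_e,
                )
            )
    return best_hit_per_contig(hits)
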