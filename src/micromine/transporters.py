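"""PCAT and MFP export-machinery screening.

Export of a class II microcin needs a peptidase-containing ABC transporter
(PCAT, which cleaves the double-glycine leader and pumps the core peptide)
bridged to TolC by a membrane fusion protein (MFP). Candidates pass an
inclusive size gate (600–800 aa for PCATs, 375–450 aa for MFPs) and a
pairwise homology search, then are projected onto the reference MSA: hits
leaving too many reference columns empty or too many of their own residues
unassigned are rejected. PCAT hits must additionally present the C39
peptidase catalytic triad (Cys/His/Asp) at the columns homologous to
positions 32/105/121 of the reference transporter row.
"""

from __future__ import annotations

from .config import PipelineConfig, TriadSpec
from .errors import DataError
from .hits import ComponentHit, best_hit_per_contig, filter_by_length
from .homology.pairwise import ScoringParams, default_params
from .homology.profile_map import ColumnMapping, map_to_reference, overlap_fractions
from .ingest import NonRedundantSet
from .microcins import prescreen_best
from .training import TrainingSet

__all__ = ["triad_columns", "check_triad", "passes_overlap", "screen_component"]

_GAP_CHARS = frozenset("-.")


def triad_columns(msa: list[tuple[str, str]], spec: TriadSpec) -> list[int]:
    """MSA columns (1-based) occupied by the reference row's triad residues.

    Counts ungapped residues along the named reference row; the residue at
    each specified position must match the expected amino acid, otherwise
    the reference data are corrupt.
    """
    row = None
    for name, seq in msa:
        if name == spec.reference_row:
            row = seq.upper()
            break
    if row is None:
        raise DataError(f"reference row {spec.reference_row!r} not found in MSA")
    wanted = {pos: aa for aa, pos in spec.residues}
    columns: dict[int, int] = {}
    residue_no = 0
    for col, ch in enumerate(row, start=1):
        if ch in _GAP_CHARS:
            continue
        residue_no += 1
        if residue_no in wanted:
            if ch != wanted[residue_no]:
                raise DataError(
                    f"reference row {spec.reference_row!r} has {ch} at position "
                    f"{residue_no}, expected {wanted[residue_no]}"
                )
            columns[residue_no] = col
    missing = [p for p in wanted if p not in columns]
    if missing:
        raise DataError(
            f"reference row {spec.reference_row!r} shorter than triad positions {missing}"
        )
    return [columns[pos] for _, pos in spec.residues]


def check_triad(
    mapping: ColumnMapping, columns: list[int], spec: TriadSpec
) -> bool:
    """True iff the candidate carries the exact triad residues at the columns.

    ``columns`` are 1-based MSA columns from :func:`triad_columns`. A gap at
    any triad column, or any substitution (even conservative, e.g. Asp→Glu),
    fails.
    """
    for (expected, _pos), col in zip(spec.residues, columns):
        residue = mapping.residue_at_column(col - 1)
        if residue != expected:
            return False
    return True


def passes_overlap(
    gap_fraction: float, unaligned_fraction: float, config: PipelineConfig
) -> bool:
    """Apply the reference-overlap retention rule.

    ``either_exceeds_rejects`` (default): reject when gap_fraction or
    unaligned_fraction exceeds its maximum. ``both_exceed_rejects``: reject
    only when both exceed.
    """
    gap_bad = gap_fraction > config.overlap_gap_max
    unaligned_bad = unaligned_fraction > config.overlap_unaligned_max
    if config.overlap_rule == "either_exceeds_rejects":
        return not (gap_bad or unaligned_bad)
    return not (gap_bad and unaligned_bad)


def screen_component(
    nrset: NonRedundantSet,
    training: TrainingSet,
    config: PipelineConfig | None = None,
    component: str = "PCAT",
    params: ScoringParams | None = None,
    *,
    triad_check: bool = True,
) -> list[ComponentHit]:
    """PCAT or MFP hits surviving size gate, homology, overlap (and triad).

    Returns the per-contig best hits (highest percent identity, documented
    tie-breaks). ``triad_check`` applies to PCAT only and exists so the
    filter's effect can be inspected.
    """
    if component not in ("PCAT", "MFP"):
        raise DataError(f"component must be PCAT or MFP, got {component!r}")
    if training.component != component:
        raise DataError(
            f"training set is for {training.component}, expected {component}"
        )
    if training.reference_msa is None:
        raise DataError(f"{component} screening requires a reference MSA")
    if config is None:
        config = PipelineConfig()
    if params is None:
        params = default_params()
    gate = config.pcat_len if component == "PCAT" else config.mfp_len
    gated = filter_by_length(nrset, *gate)
    columns = (
        triad_columns(training.reference_msa, config.triad)
        if component == "PCAT" and triad_check
        else None
    )
    hits: list[ComponentHit] = []
    for record in gated:
        pre = prescreen_best(record, training, params, config.prescreen_evalue_max)
        if pre is None:
            continue
        subject_name, aln = pre
        mapping = map_to_reference(training.reference_msa, record.sequence, params)
        gap_frac, unaligned_frac = overlap_fractions(mapping)
        if not passes_overlap(gap_frac, unaligned_frac, config):
            continue
        triad_ok: bool | None = None
        if columns is not None:
            triad_ok = check_triad(mapping, columns, config.triad)
            if not triad_ok:
                continue
        for locus in record.loci:
            hits.append(
                ComponentHit(
                    component=component,
                    protein=record,
                    locus=locus,
                    best_subject=subject_name,
                    percent_identity=aln.percent_identity,
                    alignment=aln,
                    gap_fraction=gap_frac,
                    unaligned_fraction=unaligned_frac,
                    triad_pass=triad_ok,
                )
            )
    return best_hit_per_contig(hits)
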