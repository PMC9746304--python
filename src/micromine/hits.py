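"""Screened component hits and per-contig best-hit selection."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DataError
from .homology.pairwise import LocalAlignmentHit
from .ingest import GeneLocus, NonRedundantSet, ProteinRecord

__all__ = ["ComponentHit", "best_hit_per_contig", "filter_by_length"]


@dataclass
class ComponentHit:
    """A screened hit for one system component at one genomic locus.

    ``verified_flag`` ("verified"/"novel") is set for microcin hits only:
    verified means 100% identity to a training sequence within the hit
    region. Overlap/triad fields are populated by the transporter screen.
    """

    component: str
    protein: ProteinRecord
    locus: GeneLocus
    best_subject: str
    percent_identity: float
    alignment: LocalAlignmentHit = field(repr=False)
    hmm_bits: float | None = None
    hmm_evalue: float | None = None
    verified_flag: str | None = None
    leader_motif_pos: int | None = None
    gap_fraction: float | None = None
    unaligned_fraction: float | None = None
    triad_pass: bool | None = None

    def __post_init__(self) -> None:
        if self.verified_flag is not None:
            is_exact = abs(self.percent_identity - 100.0) < 1e-9
            if (self.verified_flag == "verified") != is_exact:
                raise DataError(
                    "verified_flag inconsistent with percent identity "
                    f"({self.percent_identity})"
                )

    @property
    def sample_id(self) -> str:
        return self.locus.sample_id

    @property
    def contig_id(self) -> str:
        return self.locus.contig_id


def filter_by_length(nrset: NonRedundantSet, lo: int, hi: int) -> NonRedundantSet:
    """Keep records whose protein length is within [lo, hi], inclusive."""
    if lo > hi:
        raise DataError(f"empty length interval [{lo}, {hi}]")
    return NonRedundantSet(
        sample_id=nrset.sample_id,
        records=[r for r in nrset.records if lo <= r.length <= hi],
    )


def best_hit_per_contig(hits: list[ComponentHit]) -> list[ComponentHit]:
    """At most one hit per (sample, contig, component).

    Selection: highest percent identity, then lower prescreen E-value, then
    lower start coordinate. Idempotent; output order follows sorted keys.
    """
    best: dict[tuple[str, str, str], ComponentHit] = {}
    for hit in hits:
        key = (hit.sample_id, hit.contig_id, hit.component)
        cur = best.get(key)
        if cur is None or _rank(hit) < _rank(cur):
            best[key] = hit
    return [best[k] for k in sorted(best)]


def _rank(hit: ComponentHit) -> tuple[float, float, int]:
    return (-hit.percent_identity, hit.alignment.e_value, hit.locus.start)
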