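"""Hermetic synthetic benchmarks for the detection pipeline.

Generates a synthetic "verified" microcin system — a family of precursor
peptides with a double-glycine-type leader, cognate immunity proteins,
PCATs carrying the Cys/His/Asp catalytic triad, and MFPs — then plants
complete operons into random genomic background at a controlled amino-acid
identity, with decoy genes and optional contig fragmentation, emitting a
ground-truth manifest for precision/recall scoring.

Families are generated by substitution-only mutation of a random ancestor,
so each component family is fixed-length and its generative alignment is
the ungapped stack of members. Component lengths are drawn once per family
from the ranges characteristic of the real components: precursors 75-120
aa, immunity proteins 51-216 aa, PCATs 600-800 aa, MFPs 375-450 aa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .config import TriadSpec
from .errors import DataError
from .homology.phmm import AA_ORDER, BACKGROUND
from .ingest import Assembly
from .pipeline import BestHitsReport
from .training import TrainingBundle, TrainingSet

__all__ = [
    "SyntheticFamily",
    "PlantedGene",
    "TruthManifest",
    "make_family",
    "plant_genome",
    "evaluate_recovery",
    "back_translate",
]

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE11.forward_table.items()):
    _CODONS_BY_AA.setdefault(aa, []).append(codon)

# stops in the reading frame of the downstream gene, so spurious upstream
# in-frame starts cannot extend a planted ORF
_FRAME_GUARD = "TAATAGTGA"

TRIAD_POSITIONS = (32, 105, 121)  # 1-based, initiator Met = 1


@dataclass
class SyntheticFamily:
    """A synthetic verified microcin system: four component families."""

    seed: int
    microcins: list[tuple[str, str]]
    immunity: list[tuple[str, str]]
    pcats: list[tuple[str, str]]
    mfps: list[tuple[str, str]]
    triad_spec: TriadSpec = field(default_factory=TriadSpec)

    def members(self, component: str) -> list[tuple[str, str]]:
        return {
            "microcin": self.microcins,
            "immunity": self.immunity,
            "PCAT": self.pcats,
            "MFP": self.mfps,
        }[component]

    def to_training_bundle(self) -> TrainingBundle:
        """Training sets whose reference MSAs are the generative alignments."""
        return TrainingBundle(
            microcin=TrainingSet("microcin", self.microcins, self.microcins),
            immunity=TrainingSet("immunity", self.immunity, self.immunity),
            pcat=TrainingSet("PCAT", self.pcats, self.pcats),
            mfp=TrainingSet("MFP", self.mfps, self.mfps),
        )

    def pipeline_config(self, **overrides) -> "PipelineConfig":
        """A PipelineConfig whose triad spec points at this family's reference row."""
        from .config import PipelineConfig

        overrides.setdefault("triad", self.triad_spec)
        return PipelineConfig(**overrides)

    def write(self, out_dir: str | Path) -> None:
        """Write FASTA files in the layout TrainingBundle.from_directory reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for stem, members in (
            ("microcin", self.microcins),
            ("immunity", self.immunity),
            ("pcat", self.pcats),
            ("mfp", self.mfps),
        ):
            for suffix in (".faa", "_msa.afa"):
                with open(out / f"{stem}{suffix}", "w") as fh:
                    for name, seq in members:
                        fh.write(f">{name}\n{seq}\n")


def _sample_protein(rng: np.random.Generator, length: int) -> str:
    codes = rng.choice(20, size=length, p=BACKGROUND)
    seq = list(AA_ORDER[c] for c in codes)
    seq[0] = "M"
    return "".join(seq)


def _substitute(rng: np.random.Generator, residue: str) -> str:
    while True:
        new = AA_ORDER[rng.choice(20, p=BACKGROUND)]
        if new != residue:
            return new


def _mutate(
    rng: np.random.Generator, seq: str, rate: float, fixed: frozenset[int]
) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i not in fixed and rng.random() < rate:
            out[i] = _substitute(rng, out[i])
    return "".join(out)


def _mutate_to_identity(
    rng: np.random.Generator, seq: str, identity_pct: float, fixed: frozenset[int]
) -> str:
    """Substitute exactly round(L * (1 - identity/100)) non-fixed positions."""
    n_sub = int(round(len(seq) * (1.0 - identity_pct / 100.0)))
    mutable = [i for i in range(len(seq)) if i not in fixed]
    if n_sub > len(mutable):
        n_sub = len(mutable)
    out = list(seq)
    for i in rng.choice(len(mutable), size=n_sub, replace=False):
        pos = mutable[i]
        out[pos] = _substitute(rng, out[pos])
    return "".join(out)


def _fixed_positions(component: str, length: int, leader_len: int) -> frozenset[int]:
    if component == "microcin":
        # initiator Met and the double-glycine cleavage site stay put
        return frozenset({0, leader_len - 2, leader_len - 1})
    if component == "PCAT":
        return frozenset({0} | {p - 1 for p in TRIAD_POSITIONS})
    return frozenset({0})


def make_family(
    seed: int,
    n_members: int = 10,
    n_transporters: int = 8,
    divergence: float = 0.15,
    leader_len: int = 18,
) -> SyntheticFamily:
    """Generate a synthetic verified system, deterministic in ``seed``.

    ``n_members`` microcin precursors and immunity proteins,
    ``n_transporters`` PCAT/MFP pairs (the real training sets hold 10 and 8
    respectively). Members derive from a random ancestor by per-position
    substitution at rate ``divergence``; leader GG and PCAT triad residues
    are invariant.
    """
    if n_members < 2 or n_transporters < 2:
        raise DataError("families need at least 2 members")
    rng = np.random.default_rng(seed)
    lengths = {
        "microcin": int(rng.integers(75, 121)),
        "immunity": int(rng.integers(51, 217)),
        "PCAT": int(rng.integers(600, 801)),
        "MFP": int(rng.integers(375, 451)),
    }

    def build(component: str, prefix: str, count: int) -> list[tuple[str, str]]:
        L = lengths[component]
        ancestor = list(_sample_protein(rng, L))
        if component == "microcin":
            ancestor[leader_len - 2] = "G"
            ancestor[leader_len - 1] = "G" if rng.random() < 0.5 else "A"
        elif component == "PCAT":
            for aa, pos in zip("CHD", TRIAD_POSITIONS):
                ancestor[pos - 1] = aa
        ancestor = "".join(ancestor)
        fixed = _fixed_positions(component, L, leader_len)
        return [
            (f"{prefix}{i + 1:02d}", _mutate(rng, ancestor, divergence, fixed))
            for i in range(count)
        ]

    pcats = build("PCAT", "PCAT", n_transporters)
    return SyntheticFamily(
        seed=seed,
        microcins=build("microcin", "MCN", n_members),
        immunity=build("immunity", "IMM", n_members),
        pcats=pcats,
        mfps=build("MFP", "MFP", n_transporters),
        triad_spec=TriadSpec(reference_row=pcats[0][0]),
    )


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Protein to DNA with uniform synonymous codon choice; ATG start, TAA stop."""
    codons = []
    for i, aa in enumerate(protein.upper()):
        if i == 0 and aa == "M":
            codons.append("ATG")
            continue
        options = _CODONS_BY_AA.get(aa)
        if not options:
            raise DataError(f"cannot back-translate residue {aa!r}")
        codons.append(options[rng.integers(len(options))])
    return "".join(codons) + "TAA"


@dataclass
class PlantedGene:
    """One ground-truth gene in a synthetic genome."""

    sample_id: str
    contig_id: str
    start: int  # 1-based, inclusive, includes stop codon
    end: int
    strand: str
    component: str  # microcin | immunity | PCAT | MFP | decoy
    source_member: str
    target_identity: float
    intact: bool = True


@dataclass
class TruthManifest:
    """Ground truth for a planted genome."""

    rows: list[PlantedGene] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def component_rows(self, component: str) -> list[PlantedGene]:
        return [r for r in self.rows if r.component == component and r.intact]

    def complete_contigs(self) -> set[tuple[str, str]]:
        """Contigs with an intact microcin, PCAT and MFP."""
        have: dict[tuple[str, str], set[str]] = {}
        for r in self.rows:
            if r.intact and r.component in ("microcin", "PCAT", "MFP"):
                have.setdefault((r.sample_id, r.contig_id), set()).add(r.component)
        return {k for k, comps in have.items() if len(comps) == 3}

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=length))


def _spacer(rng: np.random.Generator, lo: int = 20, hi: int = 50) -> str:
    # random spacer ending in stops for the downstream gene's frame
    return _random_nt(rng, int(rng.integers(lo, hi + 1))) + _FRAME_GUARD


def plant_genome(
    seed: int,
    family: SyntheticFamily,
    n_operons: int = 1,
    identity_target: float = 100.0,
    n_decoys: int = 10,
    fragmentation: int = 0,
    sample_id: str | None = None,
    contig_len: int | None = None,
    leader_len: int = 18,
    operon_components: tuple[str, ...] = ("PCAT", "MFP", "microcin", "immunity"),
) -> tuple[Assembly, TruthManifest]:
    """Plant complete operons into random background; return genome + truth.

    Each operon contig carries PCAT, MFP, microcin and an adjacent immunity
    gene (in that gene order), each mutated to about ``identity_target``
    percent amino-acid identity of a random family member (PCAT triad,
    initiator Met and leader GG are preserved). ``n_decoys`` random genes
    are spread across contigs; ``fragmentation`` adds that many random
    contig breakpoints per contig. With ``n_operons=0`` a single decoy-only
    contig is emitted.
    """
    if not 0 < identity_target <= 100:
        raise DataError("identity_target must be in (0, 100]")
    rng = np.random.default_rng(seed)
    if sample_id is None:
        sample_id = f"synth{seed}"
    n_contigs = max(n_operons, 1)
    decoys_per_contig = [n_decoys // n_contigs] * n_contigs
    for i in range(n_decoys % n_contigs):
        decoys_per_contig[i] += 1

    contigs: dict[str, str] = {}
    manifest = TruthManifest()
    for ci in range(n_contigs):
        contig_id = f"ctg{ci + 1}"
        genes: list[tuple[str, str, float, str]] = []  # component, protein, ident, member
        if ci < n_operons:
            for component in operon_components:
                members = family.members(component)
                name, src = members[rng.integers(len(members))]
                fixed = _fixed_positions(component, len(src), leader_len)
                mutant = _mutate_to_identity(rng, src, identity_target, fixed)
                genes.append((component, mutant, identity_target, name))
        for _ in range(decoys_per_contig[ci]):
            length = int(rng.integers(40, 300))
            genes.append(("decoy", _sample_protein(rng, length), 100.0, "random"))

        parts = [_random_nt(rng, int(rng.integers(100, 301)))]
        pos = len(parts[0])
        rows: list[PlantedGene] = []
        for component, protein, ident, member in genes:
            spacer = _spacer(rng)
            nt = back_translate(protein, rng)
            start = pos + len(spacer) + 1
            end = start + len(nt) - 1
            parts.extend([spacer, nt])
            pos = end
            rows.append(
                PlantedGene(
                    sample_id=sample_id,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand="+",
                    component=component,
                    source_member=member,
                    target_identity=ident,
                )
            )
        parts.append(_random_nt(rng, int(rng.integers(100, 301))))
        sequence = "".join(parts)
        if contig_len is not None:
            if len(sequence) > contig_len:
                raise DataError(
                    f"planted operon needs {len(sequence)} nt but contig_len is {contig_len}"
                )
            sequence += _random_nt(rng, contig_len - len(sequence))
        contigs[contig_id] = sequence
        manifest.rows.extend(rows)

    if fragmentation > 0:
        contigs, manifest = _fragment(rng, contigs, manifest, fragmentation)
    return Assembly(sample_id=sample_id, contigs=contigs), manifest


def _fragment(
    rng: np.random.Generator,
    contigs: dict[str, str],
    manifest: TruthManifest,
    n_breaks: int,
) -> tuple[dict[str, str], TruthManifest]:
    """Split each contig at ``n_breaks`` random points; remap the manifest.

    Genes spanning a breakpoint are no longer intact; they stay in the
    manifest (assigned to the piece holding the gene start, coordinates
    clipped) with ``intact=False``.
    """
    new_contigs: dict[str, str] = {}
    new_manifest = TruthManifest()
    for contig_id, seq in contigs.items():
        cuts = sorted(int(c) for c in rng.integers(1, len(seq), size=n_breaks))
        bounds = [0] + cuts + [len(seq)]
        pieces = [
            (f"{contig_id}.p{i + 1}", bounds[i], bounds[i + 1])
            for i in range(len(bounds) - 1)
            if bounds[i + 1] > bounds[i]
        ]
        for pid, lo, hi in pieces:
            new_contigs[pid] = seq[lo:hi]
        for row in manifest.rows:
            if row.contig_id != contig_id:
                continue
            for pid, lo, hi in pieces:
                if lo < row.start <= hi:
                    intact = row.end <= hi
                    new_manifest.rows.append(
                        PlantedGene(
                            sample_id=row.sample_id,
                            contig_id=pid,
                            start=row.start - lo,
                            end=min(row.end, hi) - lo,
                            strand=row.strand,
                            component=row.component,
                            source_member=row.source_member,
                            target_identity=row.target_identity,
                            intact=intact,
                        )
                    )
                    break
    return new_contigs, new_manifest


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def evaluate_recovery(
    report: BestHitsReport,
    truth: TruthManifest,
    min_overlap: float = 0.5,
    components: tuple[str, ...] = ("microcin", "PCAT", "MFP"),
) -> dict[str, tuple[float | None, float | None]]:
    """Per-component (precision, recall) of a report against ground truth.

    A hit matches a truth row when both are on the same sample, contig and
    strand and their loci overlap reciprocally by at least ``min_overlap``.
    Undefined ratios (empty denominator) are returned as None.
    """
    out: dict[str, tuple[float | None, float | None]] = {}
    for component in components:
        truth_rows = truth.component_rows(component)
        hits = [h for h in report.best_hits if h.component == component]
        matched_truth: set[int] = set()
        matched_hits = 0
        for hit in hits:
            hit_matched = False
            for ti, row in enumerate(truth_rows):
                if (
                    row.sample_id == hit.sample_id
                    and row.contig_id == hit.contig_id
                    and row.strand == hit.locus.strand
                ):
                    ov = _overlap(row.start, row.end, hit.locus.start, hit.locus.end)
                    if (
                        ov >= min_overlap * (row.end - row.start + 1)
                        and ov >= min_overlap * hit.locus.length_nt
                    ):
                        matched_truth.add(ti)
                        hit_matched = True
            if hit_matched:
                matched_hits += 1
        precision = matched_hits / len(hits) if hits else None
        recall = len(matched_truth) / len(truth_rows) if truth_rows else None
        out[component] = (precision, recall)
    return out
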