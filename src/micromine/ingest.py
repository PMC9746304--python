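"""Assembly ingestion and protein-coding gene handling.

Reads multi-contig nucleotide FASTA, predicts open reading frames with a
built-in six-frame caller (or imports Prodigal ``.faa`` predictions), and
collapses the predicted proteome into a per-sample nonredundant set keyed by
a content hash of the amino-acid sequence, keeping every genomic occurrence
cross-referenced.

Coordinates are 1-based, inclusive, on the forward strand of the contig and
include the stop codon, matching the Prodigal ``.faa`` header dialect.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import DataError

__all__ = [
    "Assembly",
    "GeneLocus",
    "ProteinRecord",
    "NonRedundantSet",
    "read_assembly",
    "call_orfs",
    "import_predictions",
    "deduplicate",
    "protein_hash",
]

_NT_ALPHABET = set("ACGTN")
START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class GeneLocus:
    """A predicted gene's position on a contig (1-based, inclusive, forward coords)."""

    sample_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    gene_index: int  # ordinal along the contig by start coordinate, 1-based

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise DataError(
                f"invalid locus coordinates {self.start}..{self.end} on {self.contig_id}"
            )
        if self.strand not in ("+", "-"):
            raise DataError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class Assembly:
    """A genome assembly: a sample id and its contigs.

    ``contigs`` maps contig id to an uppercase nucleotide sequence over
    {A, C, G, T, N}.
    """

    sample_id: str
    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise DataError(f"contig {cid!r} in sample {self.sample_id!r} is empty")
            bad = set(seq) - _NT_ALPHABET
            if bad:
                raise DataError(
                    f"contig {cid!r} contains characters outside A/C/G/T/N: {sorted(bad)}"
                )


@dataclass(frozen=True)
class ProteinRecord:
    """A deduplicated predicted protein with all its genomic occurrences."""

    protein_id: str
    sequence: str
    loci: tuple[GeneLocus, ...]

    def __post_init__(self) -> None:
        if not self.loci:
            raise DataError("ProteinRecord requires at least one locus")
        if "*" in self.sequence:
            raise DataError("protein sequence contains an internal stop symbol")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def contains_ambiguous(self) -> bool:
        """True when the translation contains X (ambiguous nucleotides in the ORF)."""
        return "X" in self.sequence


@dataclass
class NonRedundantSet:
    """Per-sample nonredundant protein set; each distinct sequence appears once."""

    sample_id: str
    records: list[ProteinRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def n_loci(self) -> int:
        return sum(len(r.loci) for r in self.records)

    def by_id(self) -> dict[str, ProteinRecord]:
        return {r.protein_id: r for r in self.records}


def protein_hash(sequence: str) -> str:
    """Deterministic content hash of an amino-acid sequence.

    SHA-256 of the uppercased sequence, truncated to 24 hex digits and
    prefixed with a scheme version. Identical sequences map to identical ids
    on every platform, which is all the cross-referencing downstream needs.
    """
    digest = hashlib.sha256(sequence.upper().encode("ascii")).hexdigest()
    return f"v1_{digest[:24]}"


def read_assembly(path: str | Path, sample_id: str | None = None) -> Assembly:
    """Read a multi-contig nucleotide FASTA into an :class:`Assembly`.

    Contig ids are the first whitespace-delimited header token. Lowercase
    nucleotides are uppercased. Duplicate contig ids and empty files are
    errors.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name
        for suffix in (".gz", ".fa", ".fasta", ".fna"):
            if sample_id.endswith(suffix):
                sample_id = sample_id[: -len(suffix)]
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        cid = rec.id
        if cid in contigs:
            raise DataError(f"duplicate contig id {cid!r} in {path}")
        contigs[cid] = str(rec.seq).upper()
    if not contigs:
        raise DataError(f"no FASTA records in {path}")
    return Assembly(sample_id=sample_id, contigs=contigs)


def _scan_frame(seq: str, frame: int, min_len_aa: int) -> list[tuple[int, int]]:
    """ORFs in one forward frame: (start, end) 0-based nt, end exclusive, incl. stop.

    An ORF runs from the earliest start codon after the previous in-frame
    stop to the next in-frame stop (longest ORF per stop). ORFs without a
    stop codon (contig edge) are not reported.
    """
    orfs: list[tuple[int, int]] = []
    pending_start: int | None = None
    n = len(seq)
    for pos in range(frame, n - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            if pending_start is not None:
                aa_len = (pos - pending_start) // 3
                if aa_len >= min_len_aa:
                    orfs.append((pending_start, pos + 3))
                pending_start = None
        elif pending_start is None and codon in START_CODONS:
            pending_start = pos
    return orfs


def _translate_orf(nt: str) -> str:
    """Translate an ORF (stop codon included in ``nt``) with table 11.

    The initiator codon is reported as M regardless of ATG/GTG/TTG; ambiguous
    codons translate to X.
    """
    protein = str(Seq(nt[:-3]).translate(table=11))
    if protein:
        protein = "M" + protein[1:]
    return protein


def call_orfs(
    assembly: Assembly, min_len_aa: int = 30, *, require_stop: bool = True
) -> list[tuple[GeneLocus, str]]:
    """Six-frame ORF calling over all contigs of an assembly.

    Starts are ATG/GTG/TTG; each ORF ends at the next in-frame stop, which is
    required (partial ORFs at contig edges are skipped) and excluded from the
    protein. Reverse-strand ORFs are reported in forward-contig coordinates
    with strand ``-``. Gene indices are assigned per contig by start
    coordinate, 1-based.
    """
    if min_len_aa < 1:
        raise DataError("min_len_aa must be >= 1")
    out: list[tuple[GeneLocus, str]] = []
    for contig_id, seq in assembly.contigs.items():
        n = len(seq)
        raw: list[tuple[int, int, str, str]] = []  # start0, end0-excl, strand, nt
        for frame in range(3):
            for s, e in _scan_frame(seq, frame, min_len_aa):
                raw.append((s, e, "+", seq[s:e]))
        rc = str(Seq(seq).reverse_complement())
        for frame in range(3):
            for s, e in _scan_frame(rc, frame, min_len_aa):
                # map back to forward coordinates
                raw.append((n - e, n - s, "-", rc[s:e]))
        raw.sort(key=lambda t: (t[0], t[1], t[2]))
        for idx, (s, e, strand, nt) in enumerate(raw, start=1):
            locus = GeneLocus(
                sample_id=assembly.sample_id,
                contig_id=contig_id,
                start=s + 1,
                end=e,
                strand=strand,
                gene_index=idx,
            )
            out.append((locus, _translate_orf(nt)))
    return out


_PRODIGAL_HEADER = re.compile(
    r"^>(?P<gid>\S+)\s*#\s*(?P<start>\d+)\s*#\s*(?P<end>\d+)\s*#\s*(?P<strand>-?1)\s*#"
)


def import_predictions(
    path: str | Path, sample_id: str | None = None
) -> list[tuple[GeneLocus, str]]:
    """Import protein predictions from a Prodigal-style ``.faa`` file.

    Headers must carry ``# start # end # strand`` fields (strand 1/-1).
    Contig id and gene index are recovered from the Prodigal gene id
    ``<contig>_<n>``; trailing ``*`` is stripped from sequences.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    out: list[tuple[GeneLocus, str]] = []
    header: re.Match | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        gid = header.group("gid")
        if "_" in gid:
            contig_id, _, idx_str = gid.rpartition("_")
            try:
                gene_index = int(idx_str)
            except ValueError:
                contig_id, gene_index = gid, len(out) + 1
        else:
            contig_id, gene_index = gid, len(out) + 1
        seq = "".join(chunks).strip().rstrip("*").upper()
        locus = GeneLocus(
            sample_id=sample_id,
            contig_id=contig_id,
            start=int(header.group("start")),
            end=int(header.group("end")),
            strand="+" if header.group("strand") == "1" else "-",
            gene_index=gene_index,
        )
        out.append((locus, seq))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                m = _PRODIGAL_HEADER.match(line)
                if m is None:
                    raise DataError(
                        f"{path}:{lineno}: malformed Prodigal header: {line[:80]!r}"
                    )
                header, chunks, header_line = m, [], lineno
            elif line:
                if header is None:
                    raise DataError(f"{path}:{lineno}: sequence data before any header")
                chunks.append(line.strip())
    flush()
    return out


def deduplicate(
    proteins: Iterable[tuple[GeneLocus, str]], sample_id: str | None = None
) -> NonRedundantSet:
    """Collapse predicted proteins into a per-sample nonredundant set.

    One :class:`ProteinRecord` per distinct amino-acid sequence; loci of
    identical sequences are merged. All loci must share one sample id.
    """
    by_seq: dict[str, list[GeneLocus]] = {}
    for locus, seq in proteins:
        if sample_id is None:
            sample_id = locus.sample_id
        elif locus.sample_id != sample_id:
            raise DataError(
                f"mixed sample ids: {locus.sample_id!r} vs {sample_id!r}"
            )
        by_seq.setdefault(seq.upper(), []).append(locus)
    records = [
        ProteinRecord(
            protein_id=protein_hash(seq),
            sequence=seq,
            loci=tuple(sorted(loci, key=lambda l: (l.contig_id, l.start, l.end))),
        )
        for seq, loci in sorted(by_seq.items())
    ]
    return NonRedundantSet(sample_id=sample_id or "", records=records)
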