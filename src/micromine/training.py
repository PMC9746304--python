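"""Training sets: verified component sequences and their reference MSAs."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .errors import DataError

__all__ = ["COMPONENTS", "TrainingSet", "TrainingBundle", "read_fasta_pairs"]

COMPONENTS = ("microcin", "immunity", "PCAT", "MFP")


def read_fasta_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly aligned) protein FASTA as (name, sequence) pairs."""
    pairs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not pairs:
        raise DataError(f"no FASTA records in {path}")
    return pairs


@dataclass
class TrainingSet:
    """Verified sequences for one system component, plus a reference MSA.

    The MSA is required for components whose screen projects candidates onto
    reference columns (PCAT, MFP) or builds a profile HMM (microcin,
    immunity).
    """

    component: str
    sequences: list[tuple[str, str]]
    reference_msa: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise DataError(f"unknown component {self.component!r}")
        if not self.sequences:
            raise DataError(f"empty training set for {self.component}")

    @property
    def total_residues(self) -> int:
        return sum(len(s) for _, s in self.sequences)


@dataclass
class TrainingBundle:
    """All four component training sets."""

    microcin: TrainingSet
    immunity: TrainingSet
    pcat: TrainingSet
    mfp: TrainingSet

    def __post_init__(self) -> None:
        for attr, comp in (
            ("microcin", "microcin"),
            ("immunity", "immunity"),
            ("pcat", "PCAT"),
            ("mfp", "MFP"),
        ):
            ts = getattr(self, attr)
            if ts.component != comp:
                raise DataError(f"{attr} slot holds component {ts.component!r}")
        for attr in ("microcin", "pcat", "mfp"):
            if getattr(self, attr).reference_msa is None:
                raise DataError(f"training set {attr!r} is missing its reference MSA")

    @classmethod
    def from_directory(cls, path: str | Path) -> "TrainingBundle":
        """Load from a directory of FASTA files.

        Expects ``microcin.faa``, ``immunity.faa``, ``pcat.faa``, ``mfp.faa``
        and aligned ``<component>_msa.afa`` files (``immunity_msa.afa``
        optional).
        """
        path = Path(path)

        def load(stem: str, component: str, msa_required: bool) -> TrainingSet:
            seqs = read_fasta_pairs(path / f"{stem}.faa")
            msa_path = path / f"{stem}_msa.afa"
            msa = None
            if msa_path.exists():
                msa = read_fasta_pairs(msa_path)
            elif msa_required:
                raise DataError(f"missing reference MSA {msa_path}")
            return TrainingSet(component=component, sequences=seqs, reference_msa=msa)

        return cls(
            microcin=load("microcin", "microcin", True),
            immunity=load("immunity", "immunity", False),
            pcat=load("pcat", "PCAT", True),
            mfp=load("mfp", "MFP", True),
        )
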