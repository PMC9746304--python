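"""Pipeline configuration.

Default thresholds encode the screening rules: inclusive length gates per
component, an alignment-prescreen E-value cutoff of 1e-3, a profile-HMM
reporting cutoff of E <= 10, the 10% reference-overlap filter, the
six-neighbor immunity window, and the PCAT catalytic triad
(Cys32/His105/Asp121 in the reference-transporter numbering, position 1 =
initiator Met).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import DataError

__all__ = ["PipelineConfig", "TriadSpec"]


@dataclass(frozen=True)
class TriadSpec:
    """Expected catalytic-triad residues at reference-sequence positions.

    Positions are 1-based over the ungapped reference row of the PCAT MSA.
    """

    residues: tuple[tuple[str, int], ...] = (("C", 32), ("H", 105), ("D", 121))
    reference_row: str = "CvaB"

    def __post_init__(self) -> None:
        positions = [p for _, p in self.residues]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise DataError("triad positions must be strictly increasing")


@dataclass
class PipelineConfig:
    """All tunable screening parameters, YAML round-trippable."""

    microcin_len: tuple[int, int] = (30, 150)
    pcat_len: tuple[int, int] = (600, 800)
    mfp_len: tuple[int, int] = (375, 450)
    immunity_len: tuple[int, int] = (30, 250)
    prescreen_evalue_max: float = 1e-3
    hmm_evalue_max: float = 10.0
    overlap_gap_max: float = 0.10
    overlap_unaligned_max: float = 0.10
    overlap_rule: str = "either_exceeds_rejects"  # or "both_exceed_rejects"
    neighbor_window: int = 3
    triad: TriadSpec = field(default_factory=TriadSpec)
    calibration_seed: int = 1234
    calibration_n: int = 200
    min_orf_len_aa: int = 30
    tm_window: int = 19
    tm_threshold: float = 1.6

    def __post_init__(self) -> None:
        for name in ("microcin_len", "pcat_len", "mfp_len", "immunity_len"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise DataError(f"{name}: empty interval [{lo}, {hi}]")
            setattr(self, name, (int(lo), int(hi)))
        if self.overlap_rule not in ("either_exceeds_rejects", "both_exceed_rejects"):
            raise DataError(f"unknown overlap_rule {self.overlap_rule!r}")
        for name in ("overlap_gap_max", "overlap_unaligned_max"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise DataError(f"{name} must be in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["triad"] = {
            "residues": [[aa, pos] for aa, pos in self.triad.residues],
            "reference_row": self.triad.reference_row,
        }
        for name in ("microcin_len", "pcat_len", "mfp_len", "immunity_len"):
            d[name] = list(d[name])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "triad" in d:
            t = d["triad"]
            d["triad"] = TriadSpec(
                residues=tuple((aa, int(pos)) for aa, pos in t["residues"]),
                reference_row=t.get("reference_row", "CvaB"),
            )
        for name in ("microcin_len", "pcat_len", "mfp_len", "immunity_len"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)
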