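"""End-to-end per-assembly pipeline and the three best-hits output files.

For each assembly: predict or import proteins, build the per-sample
nonredundant set, run the four component screens, scan the gene
neighborhood of each per-contig best microcin for immunity candidates, and
collect contigs carrying a complete export system (microcin + PCAT + MFP).

Output is a ``best_hits`` directory with three TSVs:

1. ``01_best_hits.tsv`` — per-contig best hit for each component;
2. ``02_immunity_candidates.tsv`` — up to six neighbors per best microcin;
3. ``03_complete_systems.tsv`` — contigs with microcin AND PCAT AND MFP.

Rows are sorted (sample, contig, component) and numeric formatting is
fixed, so identical inputs give byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from joblib import Parallel, delayed

from .config import PipelineConfig
from .errors import DataError
from .hits import ComponentHit, best_hit_per_contig
from .homology.pairwise import ScoringParams, default_params
from .homology.phmm import ProfileHMM, build_phmm
from .immunity import ImmunityCandidate, filter_immunity, homology_immunity_hit, neighbor_candidates
from .ingest import Assembly, GeneLocus, NonRedundantSet, call_orfs, deduplicate
from .microcins import screen_microcins
from .training import TrainingBundle
from .transporters import screen_component

__all__ = [
    "BestHitsReport",
    "run_pipeline",
    "run_pipeline_from_genes",
    "write_report",
    "dump_proteins",
]

logger = logging.getLogger("micromine")


@dataclass
class BestHitsReport:
    """Aggregated pipeline output across samples."""

    best_hits: list[ComponentHit] = field(default_factory=list)
    immunity_candidates: list[ImmunityCandidate] = field(default_factory=list)
    complete_systems: list[tuple[str, str, str, str, str]] = field(default_factory=list)
    # (sample, contig, microcin_id, pcat_id, mfp_id)


def _build_models(bundle: TrainingBundle) -> dict[str, ProfileHMM | None]:
    """Family profile HMMs for the homology screens (microcin, immunity)."""
    models: dict[str, ProfileHMM | None] = {}
    models["microcin"] = build_phmm(bundle.microcin.reference_msa, source_msa_id="microcin")
    imm = bundle.immunity
    if imm.reference_msa is not None:
        models["immunity"] = build_phmm(imm.reference_msa, source_msa_id="immunity")
    elif len({len(s) for _, s in imm.sequences}) == 1 and len(imm.sequences) >= 2:
        # equal-length set doubles as an ungapped alignment
        models["immunity"] = build_phmm(imm.sequences, source_msa_id="immunity")
    else:
        models["immunity"] = None
    return models


def _process_sample(
    assembly: Assembly,
    bundle: TrainingBundle,
    config: PipelineConfig,
    models: dict[str, ProfileHMM | None],
    params: ScoringParams,
) -> BestHitsReport:
    genes = call_orfs(assembly, min_len_aa=config.min_orf_len_aa)
    return _process_genes(assembly.sample_id, genes, bundle, config, models, params)


def _process_genes(
    sample_id: str,
    genes: list[tuple[GeneLocus, str]],
    bundle: TrainingBundle,
    config: PipelineConfig,
    models: dict[str, ProfileHMM | None],
    params: ScoringParams,
) -> BestHitsReport:
    nrset = deduplicate(genes, sample_id=sample_id)
    logger.info(
        "sample=%s stage=ingest genes=%d nr_proteins=%d",
        sample_id, len(genes), len(nrset),
    )

    microcin_hits = best_hit_per_contig(
        screen_microcins(nrset, bundle.microcin, models["microcin"], config, params)
    )
    pcat_hits = screen_component(nrset, bundle.pcat, config, "PCAT", params)
    mfp_hits = screen_component(nrset, bundle.mfp, config, "MFP", params)
    if models["immunity"] is not None:
        immunity_hits = homology_immunity_hit(
            nrset, bundle.immunity, models["immunity"], config, params
        )
    else:
        immunity_hits = []
    logger.info(
        "sample=%s stage=screens microcin=%d pcat=%d mfp=%d immunity_homologs=%d",
        sample_id, len(microcin_hits), len(pcat_hits), len(mfp_hits),
        len(immunity_hits),
    )

    genes_by_contig: dict[str, list[tuple[GeneLocus, str]]] = {}
    for locus, seq in genes:
        genes_by_contig.setdefault(locus.contig_id, []).append((locus, seq))
    candidates: list[ImmunityCandidate] = []
    for mhit in microcin_hits:
        neighborhood = neighbor_candidates(
            genes_by_contig.get(mhit.contig_id, []),
            mhit.locus,
            window=config.neighbor_window,
        )
        candidates.extend(
            filter_immunity(
                neighborhood,
                microcin=mhit,
                lo=config.immunity_len[0],
                hi=config.immunity_len[1],
                tm_window=config.tm_window,
                tm_threshold=config.tm_threshold,
            )
        )

    by_contig: dict[str, dict[str, ComponentHit]] = {}
    for hit in microcin_hits + pcat_hits + mfp_hits:
        by_contig.setdefault(hit.contig_id, {})[hit.component] = hit
    complete = [
        (
            sample_id,
            contig,
            comps["microcin"].protein.protein_id,
            comps["PCAT"].protein.protein_id,
            comps["MFP"].protein.protein_id,
        )
        for contig, comps in sorted(by_contig.items())
        if {"microcin", "PCAT", "MFP"} <= comps.keys()
    ]
    return BestHitsReport(
        best_hits=microcin_hits + pcat_hits + mfp_hits + immunity_hits,
        immunity_candidates=candidates,
        complete_systems=complete,
    )


def run_pipeline(
    assemblies: list[Assembly],
    bundle: TrainingBundle,
    config: PipelineConfig | None = None,
    n_jobs: int = 1,
) -> BestHitsReport:
    """Run the full pipeline over assemblies; deterministic given the config.

    Samples are independent, so they can be processed in parallel
    (``n_jobs``); results are re-aggregated in sorted order, making worker
    count irrelevant to the output.
    """
    if config is None:
        config = PipelineConfig()
    models = _build_models(bundle)  # validates the bundle before any compute
    params = default_params()
    if n_jobs == 1 or len(assemblies) <= 1:
        partials = [
            _process_sample(a, bundle, config, models, params) for a in assemblies
        ]
    else:
        partials = Parallel(n_jobs=n_jobs)(
            delayed(_process_sample)(a, bundle, config, models, params)
            for a in assemblies
        )
    return _aggregate(partials)


def run_pipeline_from_genes(
    samples: list[tuple[str, list[tuple[GeneLocus, str]]]],
    bundle: TrainingBundle,
    config: PipelineConfig | None = None,
) -> BestHitsReport:
    """Run the screens on precomputed gene predictions (e.g. Prodigal .faa).

    Gene-neighborhood immunity scans use the imported loci and gene
    indices, so no nucleotide contigs are needed.
    """
    if config is None:
        config = PipelineConfig()
    models = _build_models(bundle)
    params = default_params()
    return _aggregate(
        [
            _process_genes(sid, genes, bundle, config, models, params)
            for sid, genes in samples
        ]
    )


def _aggregate(partials: list[BestHitsReport]) -> BestHitsReport:
    report = BestHitsReport()
    for part in partials:
        report.best_hits.extend(part.best_hits)
        report.immunity_candidates.extend(part.immunity_candidates)
        report.complete_systems.extend(part.complete_systems)
    report.best_hits.sort(key=lambda h: (h.sample_id, h.contig_id, h.component))
    report.immunity_candidates.sort(
        key=lambda c: (c.locus.sample_id, c.locus.contig_id, abs(c.offset), c.offset)
    )
    report.complete_systems.sort()
    return report


_SCHEMA_VERSION = "micromine-best-hits v1"

_F1_COLUMNS = [
    "sample", "contig", "component", "protein_id", "best_subject", "pident",
    "aln_evalue", "hmm_bits", "hmm_evalue", "verified_flag", "start", "end",
    "strand", "leader_motif_pos", "gap_fraction", "unaligned_fraction",
    "triad_pass",
]
_F2_COLUMNS = [
    "sample", "contig", "microcin_protein_id", "candidate_protein_id",
    "offset", "length_aa", "tm_helix_count", "same_strand",
]
_F3_COLUMNS = ["sample", "contig", "microcin_protein_id", "pcat_protein_id", "mfp_protein_id"]


def _fmt(value, spec: str = "") -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return format(value, spec or ".6g")
    return str(value)


def write_report(report: BestHitsReport, out_dir: str | Path) -> Path:
    """Write the three best-hits TSVs; returns the ``best_hits`` directory."""
    out = Path(out_dir) / "best_hits"
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {out}: {exc}") from exc

    with open(out / "01_best_hits.tsv", "w") as fh:
        fh.write(f"# {_SCHEMA_VERSION}\n")
        fh.write("\t".join(_F1_COLUMNS) + "\n")
        for h in report.best_hits:
            fh.write(
                "\t".join(
                    [
                        h.sample_id, h.contig_id, h.component,
                        h.protein.protein_id, h.best_subject,
                        _fmt(h.percent_identity, ".2f"),
                        _fmt(h.alignment.e_value, ".3g"),
                        _fmt(h.hmm_bits, ".2f"), _fmt(h.hmm_evalue, ".3g"),
                        _fmt(h.verified_flag), str(h.locus.start),
                        str(h.locus.end), h.locus.strand,
                        _fmt(h.leader_motif_pos),
                        _fmt(h.gap_fraction, ".4f"),
                        _fmt(h.unaligned_fraction, ".4f"),
                        _fmt(h.triad_pass),
                    ]
                )
                + "\n"
            )

    with open(out / "02_immunity_candidates.tsv", "w") as fh:
        fh.write(f"# {_SCHEMA_VERSION}\n")
        fh.write("\t".join(_F2_COLUMNS) + "\n")
        for c in report.immunity_candidates:
            fh.write(
                "\t".join(
                    [
                        c.locus.sample_id, c.locus.contig_id,
                        c.microcin_protein_id, c.protein.protein_id,
                        str(c.offset), str(c.length_aa), str(c.tm_helix_count),
                        _fmt(c.same_strand_as_microcin),
                    ]
                )
                + "\n"
            )

    with open(out / "03_complete_systems.tsv", "w") as fh:
        fh.write(f"# {_SCHEMA_VERSION}\n")
        fh.write("\t".join(_F3_COLUMNS) + "\n")
        for row in report.complete_systems:
            fh.write("\t".join(row) + "\n")
    return out


def dump_proteins(nrset: NonRedundantSet, out_dir: str | Path) -> None:
    """Write a nonredundant proteome as FASTA plus a locus cross-reference TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / f"{nrset.sample_id}.nr.faa", "w") as fh:
        for rec in nrset.records:
            fh.write(f">{rec.protein_id}\n{rec.sequence}\n")
    with open(out / f"{nrset.sample_id}.loci.tsv", "w") as fh:
        fh.write("protein_id\tsample\tcontig\tstart\tend\tstrand\tgene_index\n")
        for rec in nrset.records:
            for l in rec.loci:
                fh.write(
                    f"{rec.protein_id}\t{l.sample_id}\t{l.contig_id}\t{l.start}"
                    f"\t{l.end}\t{l.strand}\t{l.gene_index}\n"
                )
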