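import numpy as np
import pytest

from micromine.config import PipelineConfig, TriadSpec
from micromine.errors import DataError
from micromine.hits import ComponentHit, best_hit_per_contig, filter_by_length
from micromine.homology.pairwise import LocalAlignmentHit, local_align
from micromine.homology.profile_map import map_to_reference
from micromine.immunity import (
    filter_immunity,
    homology_immunity_hit,
    neighbor_candidates,
    predict_tm_helices,
)
from micromine.ingest import GeneLocus, NonRedundantSet, ProteinRecord, deduplicate, protein_hash
from micromine.microcins import leader_motif_position, screen_microcins
from micromine.synthetic import plant_genome
from micromine.transporters import check_triad, passes_overlap, screen_component, triad_columns

from conftest import random_protein


def record(seq, contig="c1", start=1, idx=1, sample="s"):
    return ProteinRecord(
        protein_id=protein_hash(seq),
        sequence=seq,
        loci=(GeneLocus(sample, contig, start, start + 3 * len(seq) + 2, "+", idx),),
    )


def nrset(seqs, sample="s"):
    return NonRedundantSet(
        sample_id=sample,
        records=[record(s, start=1 + 500 * i, idx=i + 1) for i, s in enumerate(seqs)],
    )


@pytest.mark.parametrize(
    "gate,lengths,kept",
    [
        ((30, 150), [29, 30, 150, 151], {30, 150}),
        ((600, 800), [599, 600, 800, 801], {600, 800}),
        ((375, 450), [374, 375, 450, 451], {375, 450}),
        ((30, 250), [29, 30, 250, 251], {30, 250}),
    ],
)
def test_length_gates_inclusive(gate, lengths, kept, rng):
    ns = nrset([random_protein(rng, n) for n in lengths])
    out = filter_by_length(ns, *gate)
    assert {r.length for r in out} == kept


def test_length_gate_degenerate_interval(rng):
    ns = nrset([random_protein(rng, n) for n in (74, 75, 76)])
    assert {r.length for r in filter_by_length(ns, 75, 75)} == {75}


def test_length_gate_empty_set():
    assert len(filter_by_length(nrset([]), 30, 150)) == 0


class TestScreenMicrocins:
    def test_planted_exact_copy_is_verified(self, family, bundle, microcin_model, config):
        target = family.microcins[2][1]
        ns = nrset([target, "M" + "A" * 60])
        hits = screen_microcins(ns, bundle.microcin, microcin_model, config)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.percent_identity == 100.0
        assert hit.verified_flag == "verified"
        assert hit.best_subject == family.microcins[2][0]
        assert hit.hmm_evalue is not None and hit.hmm_bits is not None

    def test_ten_percent_mutant_is_novel(self, family, bundle, microcin_model, config, params):
        rng = np.random.default_rng(5)
        src = family.microcins[0][1]
        n_sub = round(len(src) * 0.10)
        positions = rng.choice(len(src), size=n_sub, replace=False)
        mutant = list(src)
        for p in positions:
            mutant[p] = "W" if src[p] != "W" else "Y"
        mutant = "".join(mutant)
        hits = screen_microcins(nrset([mutant]), bundle.microcin, microcin_model, config)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.verified_flag == "novel"
        # identity recomputed by an independent pairwise alignment
        check = local_align(mutant, src, params)
        assert hit.percent_identity == pytest.approx(check.percent_identity, abs=1.0)
        assert 85 <= hit.percent_identity < 100

    def test_random_orfs_give_no_hits(self, family, bundle, microcin_model, config, rng):
        ns = nrset([random_protein(rng, int(rng.integers(31, 149))) for _ in range(30)])
        assert screen_microcins(ns, bundle.microcin, microcin_model, config) == []

    def test_empty_training_set_rejected(self, microcin_model, config, bundle):
        from micromine.training import TrainingSet

        with pytest.raises(DataError):
            bad = TrainingSet("microcin", [("x", "MAA")])
            bad.sequences = []
            screen_microcins(nrset(["M" + "A" * 50]), bad, microcin_model, config)


class TestBestHitPerContig:
    @staticmethod
    def hit(pident, contig="c1", start=1, evalue=1e-10):
        seq = "M" + "A" * 40
        aln = LocalAlignmentHit(
            "q", "s", 100, 40.0, evalue, pident, (1, 41), (1, 41), []
        )
        rec = ProteinRecord(
            protein_id=protein_hash(seq + str(start)),
            sequence=seq,
            loci=(GeneLocus("s", contig, start, start + 125, "+", 1),),
        )
        return ComponentHit(
            component="microcin",
            protein=rec,
            locus=rec.loci[0],
            best_subject="s",
            percent_identity=pident,
            alignment=aln,
        )

    def test_highest_identity_wins(self):
        out = best_hit_per_contig([self.hit(100.0), self.hit(85.0, start=500)])
        assert len(out) == 1 and out[0].percent_identity == 100.0

    def test_different_contigs_both_kept(self):
        out = best_hit_per_contig([self.hit(90.0), self.hit(85.0, contig="c2")])
        assert len(out) == 2

    def test_tie_breaks_on_lower_start(self):
        a, b = self.hit(90.0, start=300), self.hit(90.0, start=10)
        out = best_hit_per_contig([a, b])
        assert out[0].locus.start == 10

    def test_idempotent_subset(self):
        hits = [self.hit(90.0), self.hit(95.0, start=700), self.hit(80.0, contig="c2")]
        once = best_hit_per_contig(hits)
        assert best_hit_per_contig(once) == once
        assert all(h in hits for h in once)


class TestTriad:
    @staticmethod
    def toy_msa(ref_override=None, gaps_before_32=0):
        base = list("A" * 130)
        base[31], base[104], base[120] = "C", "H", "D"
        if ref_override:
            pos, aa = ref_override
            base[pos - 1] = aa
        ref = "-" * gaps_before_32 + "".join(base)
        other = "".join(base) + "-" * gaps_before_32
        return [("CvaB", ref), ("other", other)]

    def test_ungapped_reference_row_positions(self):
        spec = TriadSpec()
        assert triad_columns(self.toy_msa(), spec) == [32, 105, 121]

    def test_gaps_shift_columns(self):
        spec = TriadSpec()
        assert triad_columns(self.toy_msa(gaps_before_32=2), spec) == [34, 107, 123]

    def test_corrupt_reference_errors(self):
        with pytest.raises(DataError, match="expected C"):
            triad_columns(self.toy_msa(ref_override=(32, "S")), TriadSpec())

    def test_missing_reference_row_errors(self):
        with pytest.raises(DataError, match="CvaB"):
            triad_columns([("x", "ACD")], TriadSpec())

    def test_check_triad_identity_and_mutants(self, family, config):
        msa = family.pcats
        spec = config.triad
        columns = triad_columns(msa, spec)
        ref_seq = dict(msa)[spec.reference_row]
        assert check_triad(map_to_reference(msa, ref_seq), columns, spec)
        # conservative substitution D->E at the third triad column fails
        mutant = list(ref_seq)
        mutant[columns[2] - 1] = "E"
        assert not check_triad(map_to_reference(msa, "".join(mutant)), columns, spec)
        # a deletion leaving a GAP at the first triad column fails
        deleted = ref_seq[: columns[0] - 1] + ref_seq[columns[0] :]
        mapping = map_to_reference(msa, deleted)
        if mapping.residue_at_column(columns[0] - 1) != "C":
            assert not check_triad(mapping, columns, spec)

    def test_check_triad_ignores_off_column_mutations(self, family, config):
        msa = family.pcats
        spec = config.triad
        columns = triad_columns(msa, spec)
        ref_seq = dict(msa)[spec.reference_row]
        rng = np.random.default_rng(17)
        triad_idx = {c - 1 for c in columns}
        for _ in range(30):
            mutant = list(ref_seq)
            for pos in rng.choice(len(ref_seq), size=5, replace=False):
                if pos not in triad_idx:
                    mutant[pos] = "W" if mutant[pos] != "W" else "Y"
            assert check_triad(map_to_reference(msa, "".join(mutant)), columns, spec)


class TestOverlapRule:
    @pytest.mark.parametrize(
        "gap,unaligned,either_keeps,both_keeps",
        [
            (0.05, 0.05, True, True),
            (0.15, 0.05, False, True),
            (0.05, 0.15, False, True),
            (0.15, 0.15, False, False),
            (0.10, 0.10, True, True),  # thresholds are strict 'exceeds'
        ],
    )
    def test_rule_outcomes(self, gap, unaligned, either_keeps, both_keeps):
        either = PipelineConfig(overlap_rule="either_exceeds_rejects")
        both = PipelineConfig(overlap_rule="both_exceed_rejects")
        assert passes_overlap(gap, unaligned, either) is either_keeps
        assert passes_overlap(gap, unaligned, both) is both_keeps


class TestScreenComponent:
    def test_planted_exact_pcat_retained_with_triad(self, family, bundle, config):
        target = family.pcats[1][1]
        hits = screen_component(nrset([target]), bundle.pcat, config, "PCAT")
        assert len(hits) == 1
        assert hits[0].triad_pass is True
        assert hits[0].gap_fraction == 0.0

    def test_truncated_pcat_rejected_at_length_gate(self, family, bundle, config):
        truncated = family.pcats[1][1][:500]
        assert screen_component(nrset([truncated]), bundle.pcat, config, "PCAT") == []

    def test_triad_mutant_rejected_despite_identity(self, family, bundle, config):
        columns = triad_columns(family.pcats, config.triad)
        seq = list(family.pcats[0][1])
        seq[columns[0] - 1] = "A"  # Cys -> Ala at the first triad position
        hits = screen_component(nrset(["".join(seq)]), bundle.pcat, config, "PCAT")
        assert hits == []
        relaxed = screen_component(
            nrset(["".join(seq)]), bundle.pcat, config, "PCAT", triad_check=False
        )
        assert len(relaxed) == 1  # filter monotonicity: triad only removes hits

    def test_mfp_screen_recovers_member(self, family, bundle, config):
        hits = screen_component(nrset([family.mfps[3][1]]), bundle.mfp, config, "MFP")
        assert len(hits) == 1
        assert hits[0].component == "MFP"
        assert hits[0].triad_pass is None


class TestNeighborCandidates:
    @staticmethod
    def contig_genes(n, sample="s", contig="c1"):
        genes = []
        for i in range(n):
            start = 1 + i * 200
            genes.append(
                (GeneLocus(sample, contig, start, start + 149, "+", i + 1), "M" + "A" * 48)
            )
        return genes

    def test_interior_microcin_six_neighbors(self):
        genes = self.contig_genes(10)
        out = neighbor_candidates(genes, genes[4][0], window=3)
        assert [o for o, _, _ in out] == [-1, 1, -2, 2, -3, 3]

    def test_contig_edge_truncates(self):
        genes = self.contig_genes(10)
        out = neighbor_candidates(genes, genes[0][0], window=3)
        assert [o for o, _, _ in out] == [1, 2, 3]

    def test_single_gene_contig_empty(self):
        genes = self.contig_genes(1)
        assert neighbor_candidates(genes, genes[0][0], window=3) == []

    def test_microcin_not_on_contig_errors(self):
        genes = self.contig_genes(3)
        stranger = GeneLocus("s", "c1", 9999, 10148, "+", 99)
        with pytest.raises(DataError):
            neighbor_candidates(genes, stranger, window=3)

    def test_never_includes_anchor_and_bounded(self):
        genes = self.contig_genes(9)
        anchor = genes[4][0]
        out = neighbor_candidates(genes, anchor, window=3)
        assert len(out) <= 6
        assert all(l.start != anchor.start for _, l, _ in out)


class TestFilterImmunity:
    def test_inclusive_length_gate(self, rng):
        cands = []
        for i, n in enumerate([25, 30, 216, 250, 251]):
            locus = GeneLocus("s", "c1", 1 + i * 1000, i * 1000 + 3 * n + 3, "+", i + 1)
            cands.append((i - 2 or 1, locus, random_protein(rng, n)))
        out = filter_immunity(cands)
        assert sorted(c.length_aa for c in out) == [30, 216, 250]
        assert all(c.tm_helix_count >= 0 for c in out)


class TestPredictTmHelices:
    def test_hydrophobic_block_single_helix(self):
        assert predict_tm_helices("I" * 30) == 1

    def test_hydrophilic_sequence_no_helix(self):
        assert predict_tm_helices("E" * 30) == 0

    def test_two_islands(self):
        assert predict_tm_helices("I" * 19 + "E" * 30 + "I" * 19) == 2

    def test_short_sequence_zero(self):
        assert predict_tm_helices("MI") == 0

    def test_reversal_invariance_for_homopolymer_flanks(self):
        seq = "I" * 25 + "E" * 40 + "I" * 25
        assert predict_tm_helices(seq) == predict_tm_helices(seq[::-1])


class TestImmunityHomology:
    def test_planted_copy_recovered(self, family, bundle, config):
        from micromine.homology.phmm import build_phmm

        model = build_phmm(family.immunity)
        target = family.immunity[0][1]
        hits = homology_immunity_hit(nrset([target]), bundle.immunity, model, config)
        assert len(hits) == 1
        assert hits[0].percent_identity == 100.0
        assert hits[0].verified_flag is None

    def test_two_homologs_one_contig_single_best(self, family, bundle, config):
        from micromine.homology.phmm import build_phmm

        model = build_phmm(family.immunity)
        a = family.immunity[0][1]
        rng = np.random.default_rng(3)
        b = list(family.immunity[1][1])
        for p in rng.choice(len(b), size=6, replace=False):
            b[p] = "W" if b[p] != "W" else "Y"
        ns = nrset([a, "".join(b)])  # same contig c1
        hits = homology_immunity_hit(ns, bundle.immunity, model, config)
        assert len(hits) == 1
        assert hits[0].percent_identity == 100.0

    def test_no_homolog_no_hit(self, family, bundle, config, rng):
        from micromine.homology.phmm import build_phmm

        model = build_phmm(family.immunity)
        ns = nrset([random_protein(rng, 120) for _ in range(10)])
        assert homology_immunity_hit(ns, bundle.immunity, model, config) == []


def test_leader_motif_annotation(family):
    for _, seq in family.microcins:
        pos = leader_motif_position(seq)
        assert pos is not None
        assert seq[pos - 2] == "G" and seq[pos - 1] in ("G", "A")
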