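import math

import numpy as np
import pytest

from micromine.errors import DataError
from micromine.homology.pairwise import (
    bit_score_of,
    default_params,
    evalue_of,
    local_align,
)
from micromine.homology.phmm import (
    AA_ORDER,
    BACKGROUND,
    ProfileHMM,
    build_phmm,
    forward_bits,
    phmm_score,
)
from micromine.homology.profile_map import (
    ColumnMapping,
    map_to_reference,
    overlap_fractions,
)

import oracles
from conftest import random_protein


class TestLocalAlign:
    def test_aaa_self_alignment_blosum62(self, params):
        # three A/A matches at +4 each under the published BLOSUM62 table
        assert params.matrix["A", "A"] == 4
        hit = local_align("AAA", "AAA", params)
        assert hit.raw_score == 12
        assert hit.percent_identity == 100.0

    def test_self_alignment_full_span(self, params, rng):
        seq = random_protein(rng, 25)
        hit = local_align(seq, seq, params)
        assert hit.percent_identity == 100.0
        assert hit.query_span == hit.subject_span == (1, len(seq))

    def test_unrelated_sequences_yield_none(self, params):
        # brute force confirms no positive-scoring local alignment exists
        assert oracles.sw_affine_score("MICRACIN", "WWWWWW", params.matrix) == 0.0
        assert local_align("MICRACIN", "WWWWWW", params) is None

    def test_empty_sequence_returns_none(self, params):
        assert local_align("", "AAA", params) is None

    def test_matches_bruteforce_dp_on_random_pairs(self, params, rng):
        for _ in range(40):
            q = random_protein(rng, int(rng.integers(5, 31)))
            s = random_protein(rng, int(rng.integers(5, 31)))
            expected = oracles.sw_affine_score(q, s, params.matrix)
            hit = local_align(q, s, params)
            got = 0.0 if hit is None else hit.raw_score
            assert got == expected

    def test_percent_identity_counts_gap_columns(self, params):
        # force a gapped optimal alignment; denominator includes the gap
        hit = local_align("MKKKKKKWWWWW", "MKKKKKKAWWWWW", params)
        assert hit is not None
        ncols = hit.aligned_columns
        nident = sum(
            1
            for q, s in hit.aligned_pairs
            if q is not None and s is not None
            and "MKKKKKKWWWWW"[q - 1] == "MKKKKKKAWWWWW"[s - 1]
        )
        assert hit.percent_identity == pytest.approx(100 * nident / ncols)


class TestEvalues:
    def test_linear_in_database_size(self, params):
        assert evalue_of(40, 2000, 100, params) == pytest.approx(
            2 * evalue_of(40, 1000, 100, params)
        )

    def test_vanishes_for_large_scores(self, params):
        assert evalue_of(10_000, 1000, 100, params) < 1e-300

    def test_fixed_toy_matches_formula(self, params):
        got = evalue_of(40, 10_000, 100, params)
        assert got == pytest.approx(
            oracles.karlin_altschul_evalue(40, 100, 10_000, 0.267, 0.041)
        )

    def test_bit_score_finite_and_increasing(self, params):
        assert bit_score_of(50, params) > bit_score_of(40, params)
        assert math.isfinite(bit_score_of(40, params))


class TestBuildPhmm:
    def test_gapfree_identical_rows_all_match_states(self, rng):
        seq = random_protein(rng, 50)
        model = build_phmm([("a", seq), ("b", seq), ("c", seq)])
        assert model.n_match_states == 50

    def test_majority_gap_column_excluded(self, rng):
        seq = random_protein(rng, 10)
        rows = [
            ("a", seq[:4] + "-" + seq[5:]),
            ("b", seq[:4] + "-" + seq[5:]),
            ("c", seq),
        ]
        model = build_phmm(rows)
        assert model.n_match_states == 9
        assert 4 not in model.match_columns

    def test_emissions_normalize(self, family):
        model = build_phmm(family.microcins)
        probs = np.exp(model.match_logodds) * BACKGROUND
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_transitions_normalize(self, microcin_model):
        t = np.exp(microcin_model.log_trans)
        sums = t.sum(axis=2)
        valid = sums > 0  # rows for nonexistent states (e.g. D_0) stay empty
        assert np.allclose(sums[valid], 1.0)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(DataError):
            build_phmm([("a", "MKV"), ("b", "MK")])

    def test_roundtrip_serialization(self, microcin_model):
        clone = ProfileHMM.from_text(microcin_model.to_text())
        assert clone.n_match_states == microcin_model.n_match_states
        assert np.allclose(clone.match_logodds, microcin_model.match_logodds)
        mask = np.isfinite(microcin_model.log_trans)
        assert np.array_equal(mask, np.isfinite(clone.log_trans))
        assert np.allclose(clone.log_trans[mask], microcin_model.log_trans[mask])


class TestPhmmScore:
    def test_training_sequence_beats_its_shuffles(self, family, microcin_model):
        seq = family.microcins[0][1]
        bits = forward_bits(microcin_model, [seq])[0]
        rng = np.random.default_rng(7)
        letters = np.array(list(seq))
        shuffles = ["".join(letters[rng.permutation(len(letters))]) for _ in range(100)]
        assert bits > forward_bits(microcin_model, shuffles).max()

    def test_identical_seq_model_maximal_over_point_mutants(self, rng):
        # ten identical training copies, mirroring the verified-set size;
        # with Laplace pseudocounts the observed residue then dominates any
        # substitution at every position
        seq = random_protein(rng, 25)
        model = build_phmm([(f"m{i}", seq) for i in range(10)])
        base = forward_bits(model, [seq])[0]
        mutants = [
            seq[:i] + aa + seq[i + 1 :]
            for i in range(len(seq))
            for aa in AA_ORDER
            if aa != seq[i]
        ]
        assert base > forward_bits(model, mutants).max()

    def test_score_independent_of_calibration_n(self, family, microcin_model):
        seq = family.microcins[1][1]
        bits_a, e_a = phmm_score(microcin_model, seq, calibration_n=50, seed=3)
        bits_b, e_b = phmm_score(microcin_model, seq, calibration_n=150, seed=3)
        assert bits_a == bits_b
        assert e_a != e_b or e_a == 0.0

    def test_empty_sequence_rejected(self, microcin_model):
        with pytest.raises(DataError):
            phmm_score(microcin_model, "")

    def test_consensus_outscores_background_sequences(self, microcin_model, rng):
        consensus = microcin_model.consensus()
        ref = forward_bits(microcin_model, [consensus])[0]
        L = len(consensus)
        draws = [random_protein(rng, L) for _ in range(200)]
        assert (forward_bits(microcin_model, draws) < ref).mean() == 1.0


class TestMapToReference:
    def test_identity_candidate_full_mapping(self, family):
        msa = family.pcats
        candidate = msa[0][1]
        mapping = map_to_reference(msa, candidate)
        assert mapping.reference_column_count == len(msa[0][1])
        assert (mapping.residue_to_column >= 0).all()
        assert (mapping.column_to_residue >= 0).all()
        assert overlap_fractions(mapping) == (0.0, 0.0)

    def test_leading_extra_residues_marked_insertions(self, family, rng):
        msa = family.mfps
        candidate = random_protein(rng, 5) + msa[0][1]
        mapping = map_to_reference(msa, candidate)
        assert (mapping.residue_to_column == -1).sum() == 5

    def test_half_candidate_gives_half_gap_columns(self, family):
        msa = family.mfps
        row = msa[0][1]
        mapping = map_to_reference(msa, row[: len(row) // 2])
        gap_frac, unaligned = overlap_fractions(mapping)
        assert gap_frac == pytest.approx(1 - (len(row) // 2) / len(row), abs=0.02)
        assert unaligned == 0.0

    def test_keeplength_contract_and_monotonicity(self, family, rng):
        msa = family.microcins
        width = len(msa[0][1])
        for _ in range(10):
            candidate = random_protein(rng, int(rng.integers(20, 200)))
            mapping = map_to_reference(msa, candidate)
            assert mapping.reference_column_count == width
            assigned = mapping.residue_to_column[mapping.residue_to_column >= 0]
            assert (np.diff(assigned) > 0).all()

    def test_constructed_fraction_oracle(self):
        # 5 GAP columns of 100; 3 INSERTIONs among 98 residues
        r2c = np.arange(98)
        r2c[[10, 40, 70]] = -1
        cols = np.full(100, -1)
        assigned = [i for i in range(98) if i not in (10, 40, 70)]
        for c, r in zip(range(95), assigned):
            cols[c] = r
        mapping = ColumnMapping(100, "A" * 98, r2c, cols)
        gap_frac, unaligned = overlap_fractions(mapping)
        assert gap_frac == pytest.approx(5 / 100)
        assert unaligned == pytest.approx(3 / 98)

    def test_empty_candidate_rejected(self, family):
        with pytest.raises(DataError):
            map_to_reference(family.mfps, "")
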