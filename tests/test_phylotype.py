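"""Pairwise 16S identity and helix-38 deletion cluster assignment."""

import pytest

from achromatium.errors import (
    AlignmentError,
    InputError,
    UndefinedRatioError,
)
from achromatium.phylotype import (
    AlignedSequence,
    RegionAnnotation,
    assign_cluster,
    detect_helix38_deletion,
    identity_matrix,
    pairwise_identity,
    read_alignment,
)
from achromatium.synthetic import gen_alignment, write_alignment_fasta


def seq(sid, residues):
    return AlignedSequence(sid, residues)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity(seq("a", "ACGT"), seq("b", "ACGT")) == 100.0

    def test_one_mismatch_in_four(self):
        assert pairwise_identity(seq("a", "ACGT"), seq("b", "ACGA")) == 75.0

    def test_gap_column_excluded_from_denominator(self):
        assert pairwise_identity(seq("a", "AC-GT"), seq("b", "ACAGT")) == 100.0

    def test_all_columns_convention(self):
        assert pairwise_identity(
            seq("a", "AC-GT"), seq("b", "ACAGT"), denominator="all_columns"
        ) == 80.0

    def test_n_matches_nothing(self):
        assert pairwise_identity(seq("a", "ANGT"), seq("b", "ANGT")) == 75.0

    def test_u_normalized_to_t(self):
        assert pairwise_identity(seq("a", "ACGU"), seq("b", "ACGT")) == 100.0

    def test_symmetric(self):
        a, b = seq("a", "ACGTACG-"), seq("b", "ACCTAGGA")
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            pairwise_identity(seq("a", "ACGT"), seq("b", "ACG"))

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(UndefinedRatioError):
            pairwise_identity(seq("a", "AC--"), seq("b", "--GT"))

    def test_shared_gap_block_is_invariant(self):
        a, b = seq("a", "ACGTACGT"), seq("b", "ACCTACGA")
        before = pairwise_identity(a, b)
        after = pairwise_identity(
            seq("a", a.residues + "----"), seq("b", b.residues + "----")
        )
        assert before == after


class TestIdentityMatrix:
    def test_two_identical_sequences(self):
        m = identity_matrix([seq("a", "ACGT"), seq("b", "ACGT")])
        assert (m.values == 100.0).all()

    def test_diagonal_and_symmetry(self):
        seqs, _ = gen_alignment(4, 300, target_identity=92.0, seed=11)
        m = identity_matrix(seqs)
        assert (m.values.diagonal() == 100.0).all()
        assert (m.values == m.values.T).all()

    def test_recovers_generator_targets_exactly(self):
        seqs, truth = gen_alignment(3, 1500, target_identity=91.0, seed=4)
        # 135 differing columns per pair (0.09 * 1500), up to parity +/-1
        assert sorted(truth["substitutions_per_seq"]) == [67, 67, 68]
        m = identity_matrix(seqs)
        for pair, expected in truth["expected_identity"].items():
            i, j = pair.split("|")
            assert m.loc[i, j] == pytest.approx(expected, abs=1e-9)
            assert m.loc[i, j] == pytest.approx(91.0, abs=1.0)

    def test_single_sequence_rejected(self):
        with pytest.raises(InputError):
            identity_matrix([seq("a", "ACGT")])


class TestHelixDeletion:
    region = RegionAnnotation("helix38_v6", 10, 48)

    def test_fully_gapped_region(self):
        s = seq("a", "A" * 10 + "-" * 38 + "A" * 10)
        assert detect_helix38_deletion(s, self.region) is True

    def test_ungapped_region(self):
        s = seq("a", "A" * 58)
        assert detect_helix38_deletion(s, self.region) is False

    def test_partial_deletion_above_threshold(self):
        # 30 gap columns of a 38-column region: ~79% gapped
        s = seq("a", "A" * 10 + "-" * 30 + "A" * 18)
        assert detect_helix38_deletion(s, self.region) is True

    def test_region_out_of_bounds_rejected(self):
        with pytest.raises(InputError):
            detect_helix38_deletion(seq("a", "ACGT"), self.region)

    def test_cluster_labels(self):
        assert assign_cluster(True) == "A"
        assert assign_cluster(False) == "B"

    @pytest.mark.parametrize("coverage, expected", [(1.0, True), (0.8, True),
                                                    (0.1, False), (0.0, False)])
    def test_generator_round_trip(self, coverage, expected):
        region = RegionAnnotation("helix38_v6", 400, 438)
        seqs, truth = gen_alignment(
            3, 900, target_identity=92.0,
            deletion_spec=(region, coverage), seed=21,
        )
        calls = {
            s.seq_id: assign_cluster(detect_helix38_deletion(s, region))
            for s in seqs
        }
        for sid, has_del in truth["has_deletion"].items():
            assert calls[sid] == ("A" if (expected and has_del) else "B")


class TestAlignmentIO:
    def test_fasta_round_trip(self, tmp_path):
        seqs, _ = gen_alignment(3, 120, target_identity=95.0, seed=2)
        path = tmp_path / "aln.fasta"
        write_alignment_fasta(seqs, path)
        loaded = read_alignment(path)
        assert [s.residues for s in loaded] == [s.residues for s in seqs]

    def test_ragged_alignment_rejected(self, tmp_path):
        path = tmp_path / "ragged.fasta"
        path.write_text(">a\nACGT\n>b\nACG\n")
        with pytest.raises(AlignmentError):
            read_alignment(path)

    def test_invalid_symbols_rejected(self):
        with pytest.raises(InputError):
            AlignedSequence("a", "ACXT")
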