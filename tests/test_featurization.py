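"""Sequence reading, k-mer composition, negative sampling, pair assembly."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbfs import (
    AMINO_ACID,
    NUCLEOTIDE,
    FeatureSpec,
    InteractionMatrix,
    PairDataset,
    SequenceRecord,
    build_pair_dataset,
    featurize_sequences,
    kmer_composition,
    read_fasta,
    sample_negatives,
)

NUC2 = ["".join(t) for t in itertools.product("ACGT", repeat=2)]


class TestReadFasta:
    def test_wrapped_sequence_lines_are_joined(self, tiny_fasta):
        path = tiny_fasta([("a", "AC\nGT")])
        recs = read_fasta(path, NUCLEOTIDE)
        assert [(r.id, r.sequence) for r in recs] == [("a", "ACGT")]

    def test_order_preserved_and_uppercased(self, tiny_fasta):
        path = tiny_fasta([("b", "acgu"), ("a", "GGTT")])
        recs = read_fasta(path, NUCLEOTIDE)
        assert [r.id for r in recs] == ["b", "a"]
        assert recs[0].sequence == "ACGT"  # uppercased, U mapped to T

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError, match="no records"):
            read_fasta(path, NUCLEOTIDE)

    def test_duplicate_id_rejected(self, tiny_fasta):
        path = tiny_fasta([("x", "ACGT"), ("x", "GGCC")])
        with pytest.raises(ValueError, match="duplicate id 'x'"):
            read_fasta(path, NUCLEOTIDE)

    def test_foreign_symbol_names_offending_record(self, tiny_fasta):
        path = tiny_fasta([("ok", "ACGT"), ("bad", "AC!T")])
        with pytest.raises(ValueError, match="bad"):
            read_fasta(path, NUCLEOTIDE)

    def test_ambiguity_codes_tolerated(self, tiny_fasta):
        path = tiny_fasta([("n", "ACGTN")])
        assert read_fasta(path, NUCLEOTIDE)[0].sequence == "ACGTN"


class TestKmerComposition:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("AAAA", 1, {"A": 1.0}),
            ("ACGT", 1, {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}),
            ("ACGA", 2, {"AC": 1 / 3, "CG": 1 / 3, "GA": 1 / 3}),
        ],
    )
    def test_worked_examples(self, seq, k, expected):
        v = kmer_composition(seq, k, NUCLEOTIDE)
        names = ["".join(t) for t in itertools.product("ACGT", repeat=k)]
        got = {n: x for n, x in zip(names, v) if x > 0}
        assert got.keys() == expected.keys()
        for n in expected:
            assert got[n] == pytest.approx(expected[n], abs=1e-12)

    def test_sequence_shorter_than_k_rejected(self):
        with pytest.raises(ValueError, match="shorter than k"):
            kmer_composition("ACG", 4, NUCLEOTIDE)

    def test_ambiguous_windows_excluded_from_denominator(self):
        # ACGNA has 2-mers AC, CG, GN, NA; only AC and CG are valid windows
        v = kmer_composition("ACGNA", 2, NUCLEOTIDE)
        got = {n: x for n, x in zip(NUC2, v) if x > 0}
        assert got == {"AC": pytest.approx(0.5), "CG": pytest.approx(0.5)}

    @settings(deadline=None, max_examples=100)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=5, max_size=60),
        k=st.integers(min_value=1, max_value=3),
    )
    def test_frequency_vector_is_a_distribution(self, seq, k):
        try:
            v = kmer_composition(seq, k, NUCLEOTIDE)
        except ValueError:
            return  # no valid window: allowed rejection
        assert (v >= 0).all()
        assert v.sum() == pytest.approx(1.0, abs=1e-12)


class TestFeaturizeSequences:
    @pytest.mark.parametrize(
        "ks,alphabet,dim",
        [
            ((1, 2), NUCLEOTIDE, 20),
            ((1,), AMINO_ACID, 20),
        ],
    )
    def test_dimension_from_alphabet_powers(self, ks, alphabet, dim):
        spec = FeatureSpec(nucleotide_k=ks, amino_acid_k=ks)
        assert spec.dimension(alphabet) == dim

    def test_concatenated_pair_dimension(self):
        # nucleotide k in {1,2,3}, amino-acid k in {1,2}: 4+16+64+20+400
        spec = FeatureSpec(nucleotide_k=(1, 2, 3), amino_acid_k=(1, 2))
        assert spec.dimension(NUCLEOTIDE) + spec.dimension(AMINO_ACID) == 504

    def test_permutation_equivariance(self):
        recs = [
            SequenceRecord("a", "ACGTACGT", NUCLEOTIDE),
            SequenceRecord("b", "GGGGCCCC", NUCLEOTIDE),
            SequenceRecord("c", "ATATATAT", NUCLEOTIDE),
        ]
        spec = FeatureSpec(nucleotide_k=(1, 2))
        f1, n1 = featurize_sequences(recs, spec)
        f2, n2 = featurize_sequences(recs[::-1], spec)
        assert n1 == n2
        for r in recs:
            np.testing.assert_array_equal(f1[r.id], f2[r.id])

    def test_names_carry_prefix_and_kmer(self):
        recs = [SequenceRecord("a", "ACGT", NUCLEOTIDE)]
        _, names = featurize_sequences(recs, FeatureSpec(nucleotide_k=(2,)), prefix="lnc:")
        assert names[0] == "lnc:k2:AA" and len(names) == 16

    def test_offending_record_is_named(self):
        recs = [SequenceRecord("shorty", "AC", NUCLEOTIDE)]
        with pytest.raises(ValueError, match="shorty"):
            featurize_sequences(recs, FeatureSpec(nucleotide_k=(4,)))


class TestSampleNegatives:
    def test_all_ones_matrix_has_no_negatives(self):
        m = InteractionMatrix(["l1"], ["p1", "p2"], np.ones((1, 2)))
        with pytest.raises(ValueError, match="only 0"):
            sample_negatives(m, 1.0, seed=0)

    def test_single_zero_entry_is_forced(self):
        y = np.array([[1, 1], [1, 0]])
        m = InteractionMatrix(["l1", "l2"], ["p1", "p2"], y)
        # ratio 1/3 of 3 positives -> exactly one negative: the (l2,p2) cell
        assert sample_negatives(m, 1 / 3, seed=5) == [("l2", "p2")]

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(1)
        y = (rng.random((8, 8)) < 0.4).astype(int)
        m = InteractionMatrix([f"l{i}" for i in range(8)], [f"p{j}" for j in range(8)], y)
        assert sample_negatives(m, 1.0, seed=42) == sample_negatives(m, 1.0, seed=42)

    @pytest.mark.parametrize("seed", range(5))
    def test_never_returns_an_interacting_pair(self, seed):
        rng = np.random.default_rng(seed)
        y = (rng.random((6, 7)) < 0.5).astype(int)
        m = InteractionMatrix([f"l{i}" for i in range(6)], [f"p{j}" for j in range(7)], y)
        li = {v: i for i, v in enumerate(m.lnc_ids)}
        pi = {v: i for i, v in enumerate(m.prot_ids)}
        negs = sample_negatives(m, 0.5, seed=seed)
        assert len(negs) == len(set(negs)) == round(0.5 * y.sum())
        for l, p in negs:
            assert y[li[l], pi[p]] == 0

    def test_infeasible_ratio_states_maximum(self):
        y = np.array([[1, 0], [1, 1]])
        m = InteractionMatrix(["l1", "l2"], ["p1", "p2"], y)
        with pytest.raises(ValueError, match="only 1"):
            sample_negatives(m, 2.0, seed=0)


class TestBuildPairDataset:
    @pytest.fixture
    def feats(self):
        lnc = {"l1": np.zeros(20), "l2": np.ones(20)}
        prot = {"p1": np.full(20, 2.0)}
        return lnc, prot

    def test_rows_are_concatenations_with_labels(self, feats):
        lnc, prot = feats
        ds = build_pair_dataset(lnc, prot, [("l1", "p1")], [("l2", "p1")])
        assert ds.X.shape == (2, 40)
        np.testing.assert_array_equal(ds.labels, [1, 0])
        np.testing.assert_array_equal(ds.X[0], np.r_[np.zeros(20), np.full(20, 2.0)])
        assert ds.labels.sum() == 1
        assert all(n.startswith(("lnc:", "prot:")) for n in ds.feature_names)

    def test_unresolvable_id_is_named(self, feats):
        lnc, prot = feats
        with pytest.raises(KeyError, match="ghost"):
            build_pair_dataset(lnc, prot, [("ghost", "p1")], [])

    def test_zero_pairs_gives_empty_dataset_with_full_width(self, feats):
        lnc, prot = feats
        ds = build_pair_dataset(lnc, prot, [], [])
        assert ds.X.shape == (0, 40) and ds.n_samples == 0

    def test_duplicate_pairs_rejected(self, feats):
        lnc, prot = feats
        with pytest.raises(ValueError, match="duplicate pair_ids"):
            build_pair_dataset(lnc, prot, [("l1", "p1")], [("l1", "p1")])


class TestPairDatasetIO:
    def test_table_roundtrip(self, tmp_path, small_pair_dataset):
        path = tmp_path / "features.tsv"
        small_pair_dataset.write_table(path)
        back = PairDataset.read_table(path)
        np.testing.assert_allclose(back.X, small_pair_dataset.X)
        np.testing.assert_array_equal(back.labels, small_pair_dataset.labels)
        assert back.feature_names == small_pair_dataset.feature_names
        assert back.pair_ids == small_pair_dataset.pair_ids

    def test_header_contract_enforced(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\n1\t2\n")
        with pytest.raises(ValueError, match="pair_id"):
            PairDataset.read_table(path)


class TestInteractionMatrix:
    def test_entries_must_be_binary(self):
        with pytest.raises(ValueError, match="0 or 1"):
            InteractionMatrix(["l"], ["p"], np.array([[2]]))

    def test_from_pairs_marks_positives(self):
        m = InteractionMatrix.from_pairs([("l1", "p1"), ("l2", "p2")])
        assert m.y.sum() == 2
        assert set(m.positives()) == {("l1", "p1"), ("l2", "p2")}
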