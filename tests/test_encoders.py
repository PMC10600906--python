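import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    oracle_binary,
    oracle_cksnap,
    oracle_enac,
    oracle_kmer,
    oracle_ncp,
)
from m6apred.encoders import (
    EncodingScheme,
    FeatureMatrix,
    encode_binary,
    encode_cksnap,
    encode_dataset,
    encode_enac,
    encode_kmer,
    encode_ncp,
    encode_sequence,
    enumerate_schemes,
)
from m6apred.errors import (
    HeterogeneousLengthError,
    InvalidCharacterError,
    SequenceTooShortError,
)
from m6apred.seqio import SequenceRecord

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestBinary:
    def test_single_a(self):
        assert encode_binary("A").tolist() == [1, 0, 0, 0]

    def test_acgt(self):
        expected = [1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1]
        assert encode_binary("ACGT").tolist() == expected

    def test_length_41_gives_164(self):
        assert encode_binary("A" * 41).size == 164

    def test_u_equals_t(self):
        assert np.array_equal(encode_binary("ACGU"), encode_binary("ACGT"))

    def test_invalid_character(self):
        with pytest.raises(InvalidCharacterError):
            encode_binary("ACGN")

    @given(dna)
    def test_one_hot_blocks(self, seq):
        v = encode_binary(seq).reshape(-1, 4)
        assert np.all(v.sum(axis=1) == 1)
        assert set(np.unique(v)) <= {0.0, 1.0}


class TestKmer:
    def test_homopolymer(self):
        v = encode_kmer("AAAA", 2)
        assert v[0] == 1.0 and v[1:].sum() == 0

    def test_k1_frequencies(self):
        # frozen from the character-count oracle on a 20-nt example
        v = encode_kmer("ATAAGAGAAAAGAAAACCTT", 1)
        assert v.tolist() == pytest.approx([0.60, 0.10, 0.15, 0.15])

    def test_acgt_k2(self):
        v = encode_kmer("ACGT", 2)
        # AC, CG, GT each 1/3 (indices 1, 6, 11 lexicographically)
        assert v[1] == pytest.approx(1 / 3)
        assert v[6] == pytest.approx(1 / 3)
        assert v[11] == pytest.approx(1 / 3)
        assert v.sum() == pytest.approx(1.0)

    def test_too_short(self):
        with pytest.raises(SequenceTooShortError):
            encode_kmer("ACG", 4)

    @given(dna, st.integers(min_value=1, max_value=4))
    def test_matches_oracle(self, seq, k):
        if len(seq) < k:
            return
        assert encode_kmer(seq, k).tolist() == pytest.approx(oracle_kmer(seq, k))

    @given(dna, st.integers(min_value=1, max_value=4))
    def test_sums_to_one(self, seq, k):
        if len(seq) < k:
            return
        assert encode_kmer(seq, k).sum() == pytest.approx(1.0, abs=1e-9)


class TestEnac:
    def test_homopolymer(self):
        v = encode_enac("AAAA", 2).reshape(-1, 4)
        assert v.shape == (3, 4)
        assert np.allclose(v, [[1, 0, 0, 0]] * 3)

    def test_full_window(self):
        assert encode_enac("ACGT", 4).tolist() == pytest.approx([0.25] * 4)

    def test_aacc_w2(self):
        v = encode_enac("AACC", 2)
        assert v.tolist() == pytest.approx(
            [1, 0, 0, 0, 0.5, 0.5, 0, 0, 0, 1, 0, 0]
        )

    def test_too_short(self):
        with pytest.raises(SequenceTooShortError):
            encode_enac("AC", 3)

    @given(dna, st.integers(min_value=1, max_value=5))
    def test_matches_oracle(self, seq, w):
        if len(seq) < w:
            return
        assert encode_enac(seq, w).tolist() == pytest.approx(oracle_enac(seq, w))

    @given(dna, st.integers(min_value=1, max_value=5))
    def test_window_blocks_sum_to_one(self, seq, w):
        if len(seq) < w:
            return
        blocks = encode_enac(seq, w).reshape(-1, 4)
        assert np.allclose(blocks.sum(axis=1), 1.0, atol=1e-9)


class TestCksnap:
    def test_homopolymer_gap0(self):
        v = encode_cksnap("AAAA", 0)
        assert v[0] == 1.0 and v[1:].sum() == 0

    def test_acac_kmax1(self):
        v = encode_cksnap("ACAC", 1)
        gap0, gap1 = v[:16], v[16:]
        assert gap0[1] == pytest.approx(2 / 3)  # AC
        assert gap0[4] == pytest.approx(1 / 3)  # CA
        assert gap0.sum() == pytest.approx(1.0)
        assert gap1[0] == pytest.approx(0.5)  # AA
        assert gap1[5] == pytest.approx(0.5)  # CC

    def test_kmax5_width(self):
        assert encode_cksnap("ACGTACGT", 5).size == 96

    def test_too_short(self):
        with pytest.raises(SequenceTooShortError):
            encode_cksnap("ACG", 2)

    @given(dna, st.integers(min_value=0, max_value=4))
    def test_matches_oracle(self, seq, kmax):
        if len(seq) < kmax + 2:
            return
        assert encode_cksnap(seq, kmax).tolist() == pytest.approx(
            oracle_cksnap(seq, kmax)
        )

    @given(dna, st.integers(min_value=0, max_value=4))
    def test_gap_blocks_sum_to_one(self, seq, kmax):
        if len(seq) < kmax + 2:
            return
        blocks = encode_cksnap(seq, kmax).reshape(-1, 16)
        assert np.allclose(blocks.sum(axis=1), 1.0, atol=1e-9)


class TestNcp:
    @pytest.mark.parametrize(
        "base,triple",
        [("A", [1, 1, 1]), ("C", [0, 1, 0]), ("G", [1, 0, 0]), ("U", [0, 0, 1]),
         ("T", [0, 0, 1])],
    )
    def test_triples(self, base, triple):
        assert encode_ncp(base).tolist() == triple

    def test_concatenation(self):
        expected = [1, 1, 1, 0, 1, 0, 1, 0, 0, 0, 0, 1]
        assert encode_ncp("ACGU").tolist() == expected

    def test_invalid(self):
        with pytest.raises(InvalidCharacterError):
            encode_ncp("AXG")

    @given(dna)
    def test_matches_oracle(self, seq):
        assert encode_ncp(seq).tolist() == oracle_ncp(seq)

    @given(dna)
    def test_every_triple_canonical(self, seq):
        triples = {tuple(t) for t in encode_ncp(seq).reshape(-1, 3)}
        assert triples <= {(1, 1, 1), (0, 1, 0), (1, 0, 0), (0, 0, 1)}


class TestAlphabetEquivalence:
    @given(st.text(alphabet="ACGT", min_size=6, max_size=40))
    @settings(max_examples=50)
    def test_all_families_invariant_under_t_u_swap(self, seq):
        rna = seq.replace("T", "U")
        for scheme in enumerate_schemes():
            if len(seq) < 7 and scheme.family in ("cksnap",):
                continue
            a = encode_sequence(seq, scheme)
            b = encode_sequence(rna, scheme)
            assert np.array_equal(a, b), scheme.name


class TestSchemeGrid:
    def test_count_is_15(self):
        assert len(enumerate_schemes()) == 15

    def test_order(self):
        names = [s.name for s in enumerate_schemes()]
        assert names[0] == "binary"
        assert names[-1] == "ncp"
        assert names[1:5] == ["kmer-2", "kmer-3", "kmer-4", "kmer-5"]
        assert names[5:9] == ["enac-2", "enac-3", "enac-4", "enac-5"]
        assert names[9:14] == [f"cksnap-{k}" for k in range(1, 6)]

    def test_kmer4_appears_once(self):
        assert sum(s == EncodingScheme("kmer", 4) for s in enumerate_schemes()) == 1

    def test_dimension_law_l41(self):
        expected = {
            "binary": 164, "ncp": 123,
            "kmer-2": 16, "kmer-3": 64, "kmer-4": 256, "kmer-5": 1024,
            "enac-2": 160, "enac-3": 156, "enac-4": 152, "enac-5": 148,
            "cksnap-1": 32, "cksnap-2": 48, "cksnap-3": 64, "cksnap-4": 80,
            "cksnap-5": 96,
        }
        for scheme in enumerate_schemes():
            assert scheme.n_features(41) == expected[scheme.name]
            assert encode_sequence("A" * 41, scheme).size == expected[scheme.name]

    def test_bad_family_rejected(self):
        with pytest.raises(ValueError):
            EncodingScheme("pseknc")

    def test_bad_param_rejected(self):
        with pytest.raises(ValueError):
            EncodingScheme("kmer", 0)


class TestEncodeDataset:
    def test_shape_and_metadata(self, random_records):
        recs = random_records(n=2, length=4)
        X = encode_dataset(recs, EncodingScheme("binary"))
        assert X.values.shape == (2, 16)
        assert X.record_ids == ["r0", "r1"]
        assert X.labels.tolist() == [0, 1]
        assert len(X.feature_names) == 16
        assert X.feature_names[0] == "pos1_A"

    def test_zero_records_with_declared_length(self):
        X = encode_dataset([], EncodingScheme("enac", 3), length=41)
        assert X.values.shape == (0, 156)
        assert len(X.feature_names) == 156

    def test_zero_records_without_length_rejected(self):
        with pytest.raises(ValueError):
            encode_dataset([], EncodingScheme("binary"))

    def test_unequal_lengths_rejected(self):
        recs = [SequenceRecord("a", "ACGT", 1), SequenceRecord("b", "ACG", 0)]
        with pytest.raises(HeterogeneousLengthError):
            encode_dataset(recs, EncodingScheme("kmer", 2))

    def test_error_names_record(self):
        recs = [SequenceRecord("short1", "AC", 1), SequenceRecord("ok", "AC", 0)]
        with pytest.raises(SequenceTooShortError) as exc:
            encode_dataset(recs, EncodingScheme("kmer", 3))
        assert "short1" in str(exc.value)

    def test_feature_name_conventions(self, random_records):
        recs = random_records(n=1, length=8)
        kmer = encode_dataset(recs, EncodingScheme("kmer", 3))
        assert kmer.feature_names[0] == "AAA" and kmer.feature_names[-1] == "TTT"
        enac = encode_dataset(recs, EncodingScheme("enac", 2))
        assert enac.feature_names[0] == "win1_A"
        cksnap = encode_dataset(recs, EncodingScheme("cksnap", 1))
        assert cksnap.feature_names[0] == "gap0_AA"
        assert cksnap.feature_names[16] == "gap1_AA"
        ncp = encode_dataset(recs, EncodingScheme("ncp"))
        assert ncp.feature_names[:3] == ["pos1_ring", "pos1_hbond", "pos1_func"]

    def test_csv_round_trip(self, tmp_path, random_records):
        recs = random_records(n=5, length=10)
        X = encode_dataset(recs, EncodingScheme("cksnap", 2))
        path = tmp_path / "features.csv"
        X.to_csv(path)
        back = FeatureMatrix.from_csv(path)
        assert np.allclose(back.values, X.values)
        assert back.scheme == X.scheme
        assert back.record_ids == X.record_ids
        assert back.labels.tolist() == X.labels.tolist()
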