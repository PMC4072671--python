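"""Encoder correctness: hand-counted examples plus randomized invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import transpred as tp
from transpred.constants import AMINO_ACIDS
from transpred.features import ENCODER_DIMS, encode_dataset

random_sequence = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=200).map(
    lambda s: tp.ProteinSequence("h", s)
)


def comp(vec, name):
    return vec.values[vec.names.index(name)]


class TestAac:
    @pytest.mark.parametrize(
        "residues,expected",
        [
            ("AAAA", {"A": 100.0}),
            ("ACDE", {"A": 25.0, "C": 25.0, "D": 25.0, "E": 25.0}),
            ("AAC", {"A": 200 / 3, "C": 100 / 3}),
        ],
    )
    def test_hand_counted(self, residues, expected):
        vec = tp.encode_aac(tp.ProteinSequence("p", residues))
        for aa in AMINO_ACIDS:
            assert comp(vec, aa) == pytest.approx(expected.get(aa, 0.0))

    def test_homopolymer_independent_of_length(self):
        vecs = [tp.encode_aac(tp.ProteinSequence("p", "W" * k)) for k in (1, 7, 300)]
        for v in vecs[1:]:
            assert np.array_equal(v.values, vecs[0].values)

    @settings(max_examples=200, deadline=None)
    @given(random_sequence)
    def test_sums_to_100(self, seq):
        assert tp.encode_aac(seq).values.sum() == pytest.approx(100, abs=1e-9)


class TestDpc:
    @pytest.mark.parametrize(
        "residues,expected",
        [
            ("AAA", {"AA": 100.0}),
            ("ACAC", {"AC": 200 / 3, "CA": 100 / 3}),
            ("AC", {"AC": 100.0}),
        ],
    )
    def test_hand_counted(self, residues, expected):
        vec = tp.encode_dpc(tp.ProteinSequence("p", residues))
        nonzero = {n: v for n, v in zip(vec.names, vec.values) if v}
        assert set(nonzero) == set(expected)
        for k, v in expected.items():
            assert nonzero[k] == pytest.approx(v)

    def test_length_one_rejected(self):
        with pytest.raises(ValueError):
            tp.encode_dpc(tp.ProteinSequence("p", "A"))

    @settings(max_examples=200, deadline=None)
    @given(random_sequence)
    def test_sums_to_100(self, seq):
        assert tp.encode_dpc(seq).values.sum() == pytest.approx(100, abs=1e-9)


class TestPhc:
    def test_arginine_homopolymer(self, residue_classes):
        vec = tp.encode_phc(tp.ProteinSequence("p", "RRRR"), residue_classes)
        expected = {
            "charged": 100, "polar": 100, "neutral": 100,
            "positively_charged": 100, "large": 100,
        }
        for name in vec.names:
            assert comp(vec, name) == pytest.approx(expected.get(name, 0.0))

    def test_isoleucine_homopolymer(self, residue_classes):
        vec = tp.encode_phc(tp.ProteinSequence("p", "IIII"), residue_classes)
        expected = {"aliphatic": 100, "hydrophobic": 100, "small": 100}
        for name in vec.names:
            assert comp(vec, name) == pytest.approx(expected.get(name, 0.0))

    def test_mixed_membership_hand_count(self, residue_classes):
        vec = tp.encode_phc(tp.ProteinSequence("p", "DR"), residue_classes)
        expected = {
            "charged": 100, "negatively_charged": 50, "positively_charged": 50,
            "large": 50, "tiny": 50, "polar": 100, "neutral": 100,
        }
        for name in vec.names:
            assert comp(vec, name) == pytest.approx(expected.get(name, 0.0))

    def test_classes_overlap_so_no_constant_sum(self, residue_classes):
        v1 = tp.encode_phc(tp.ProteinSequence("p", "RRRR"), residue_classes)
        v2 = tp.encode_phc(tp.ProteinSequence("p", "GGGG"), residue_classes)
        assert v1.values.sum() != pytest.approx(v2.values.sum())


class TestAai:
    def test_homopolymer_equals_property_column(self, property_table):
        vec = tp.encode_aai(tp.ProteinSequence("p", "GGGG"), property_table)
        assert np.allclose(vec.values, property_table["G"].to_numpy())

    def test_two_residue_mean(self, property_table):
        vec = tp.encode_aai(tp.ProteinSequence("p", "AG"), property_table)
        expected = (property_table["A"] + property_table["G"]) / 2
        assert np.allclose(vec.values, expected.to_numpy())

    @settings(max_examples=50, deadline=None)
    @given(seq=random_sequence)
    def test_bounded_by_column_extremes(self, property_table, seq):
        vec = tp.encode_aai(seq, property_table)
        lo = property_table.min(axis=1).to_numpy()
        hi = property_table.max(axis=1).to_numpy()
        assert (vec.values >= lo - 1e-12).all() and (vec.values <= hi + 1e-12).all()


class TestPssmEncoder:
    def test_one_position_profile_hand_computed(self, small_pssm):
        # before scaling the A-row holds 1..20 (divided by L=1), rest 0;
        # min component 0 stays 0, max (A,Y)=20 maps to 1
        vec = tp.encode_pssm(small_pssm)
        a_row = vec.values[:20]
        assert vec.values.min() == 0.0 and vec.values.max() == 1.0
        assert a_row[-1] == 1.0  # (A, Y) held the largest raw sum
        unscaled = tp.encode_pssm(small_pssm, scale="none")
        assert np.array_equal(unscaled.values[:20], np.arange(1, 21))
        assert (unscaled.values[20:] == 0).all()

    def test_degenerate_constant_vector_maps_to_half(self):
        # an all-zero profile collapses the 400-vector to a constant,
        # triggering the defined max==min fallback
        profile = tp.PssmProfile("q", "ACD", np.zeros((3, 20), dtype=int))
        assert (tp.encode_pssm(profile).values == 0.5).all()

    def test_invariant_to_joint_permutation(self):
        rng = np.random.default_rng(5)
        residues = "ACDEFGHIKL"
        scores = rng.integers(-5, 10, size=(10, 20))
        perm = rng.permutation(10)
        p1 = tp.PssmProfile("q", residues, scores)
        p2 = tp.PssmProfile(
            "q", "".join(residues[i] for i in perm), scores[perm]
        )
        assert np.array_equal(tp.encode_pssm(p1).values, tp.encode_pssm(p2).values)


class TestHybrid:
    def test_aai_plus_pssm_is_449(self, property_table, small_pssm):
        aai = tp.encode_aai(tp.ProteinSequence("p", "AAAA"), property_table)
        pssm = tp.encode_pssm(small_pssm)
        hybrid = tp.encode_hybrid([aai, pssm])
        assert len(hybrid) == 449
        assert hybrid.encoder == "hybrid(AAI+PSSM)"
        assert hybrid.names[0].startswith("AAI:")

    def test_aac_plus_dpc_is_420(self):
        seq = tp.ProteinSequence("p", "ACDE")
        assert len(tp.encode_hybrid([tp.encode_aac(seq), tp.encode_dpc(seq)])) == 420

    def test_single_part_prefixes_names(self):
        aac = tp.encode_aac(tp.ProteinSequence("p", "ACDE"))
        one = tp.encode_hybrid([aac])
        assert np.array_equal(one.values, aac.values)
        assert one.names == tuple(f"AAC:{n}" for n in aac.names)

    def test_empty_parts_rejected(self):
        with pytest.raises(ValueError):
            tp.encode_hybrid([])


class TestDimensionsAndDeterminism:
    @pytest.mark.parametrize("encoder,dim", sorted(ENCODER_DIMS.items()))
    def test_declared_dimension(self, encoder, dim, property_table,
                                residue_classes, small_pssm):
        seq = tp.ProteinSequence("p", "ACDEFGHIKLMNPQRSTVWY")
        if encoder == "AAC":
            vec = tp.encode_aac(seq)
        elif encoder == "DPC":
            vec = tp.encode_dpc(seq)
        elif encoder == "PHC":
            vec = tp.encode_phc(seq, residue_classes)
        elif encoder == "AAI":
            vec = tp.encode_aai(seq, property_table)
        else:
            vec = tp.encode_pssm(small_pssm)
        assert len(vec) == dim

    @settings(max_examples=50, deadline=None)
    @given(seq=random_sequence)
    def test_encoders_deterministic(self, property_table, residue_classes, seq):
        for enc in (tp.encode_aac, tp.encode_dpc):
            assert np.array_equal(enc(seq).values, enc(seq).values)
        assert np.array_equal(
            tp.encode_phc(seq, residue_classes).values,
            tp.encode_phc(seq, residue_classes).values,
        )
        assert np.array_equal(
            tp.encode_aai(seq, property_table).values,
            tp.encode_aai(seq, property_table).values,
        )


class TestCompositionSummary:
    def test_identical_classes_zero_variance(self):
        seq = tp.ProteinSequence
        dataset = [
            (seq("a1", "ACDE"), "cation"), (seq("b1", "ACDE"), "sugar"),
        ]
        means, variance = tp.composition_summary(dataset)
        assert (variance == 0).all()
        assert len(variance) == 20

    def test_two_point_variance_hand_computed(self):
        seq = tp.ProteinSequence
        dataset = [
            (seq("a1", "AAAA"), "cation"), (seq("a2", "AAAA"), "cation"),
            (seq("b1", "CCCC"), "sugar"), (seq("b2", "CCCC"), "sugar"),
        ]
        means, variance = tp.composition_summary(dataset)
        # class means for A are {100, 0}: population variance 2500
        assert variance["A"] == pytest.approx(2500.0)
        assert variance["C"] == pytest.approx(2500.0)
        assert variance["D"] == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tp.composition_summary([(tp.ProteinSequence("a", "ACDE"), "cation")])


class TestTables:
    def test_property_table_shape_and_bounds(self, property_table):
        values = property_table.to_numpy()
        assert values.shape == (49, 20)
        assert values.min() >= 0 and values.max() <= 1
        assert np.isfinite(values).all()

    def test_residue_class_table_matches_published_sets(self, residue_classes):
        assert len(residue_classes) == 11
        assert residue_classes["charged"] == frozenset("DEKHR")
        assert residue_classes["aliphatic"] == frozenset("ILV")
        assert residue_classes["negatively_charged"] == frozenset("DE")
        # published table prints polar and neutral identically
        assert residue_classes["polar"] == residue_classes["neutral"]


class TestEncodeDataset:
    def test_matrix_shape_and_index(self, separable_dataset):
        sequences, _, X, _ = separable_dataset
        assert X.shape == (len(sequences), 20)

    def test_missing_pssm_listed(self):
        seqs = [tp.ProteinSequence("p1", "ACDE"), tp.ProteinSequence("p2", "ACDE")]
        with pytest.raises(ValueError, match="p2"):
            encode_dataset(seqs, "PSSM", pssms={"p1": None})

    def test_unknown_encoder_rejected(self):
        with pytest.raises(ValueError, match="unknown encoder"):
            encode_dataset([tp.ProteinSequence("p1", "ACDE")], "FOO")
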