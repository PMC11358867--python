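"""Barcode symmetry, the closed-form isomer count and its enumeration oracle."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bvstereo.barcodes import (
    BarcodeError,
    SubstituentSet,
    barcode_string,
    canonical_form,
    chirality_split,
    classify_chirality,
    compute_S,
    count_isomers,
    enumerate_isomers,
    enumerate_substitution_variations,
    parse_barcode,
    reflect,
    reorder_barcode,
    rotate,
)

barcodes = st.lists(st.integers(0, 3), min_size=10, max_size=10).map(tuple)


class TestSymmetryOps:
    def test_rotation_has_order_three(self):
        b = tuple(range(10))
        assert rotate(rotate(rotate(b))) == b

    def test_reflection_is_involution(self):
        b = tuple(range(10))
        assert reflect(reflect(b)) == b

    def test_group_relation_sigma_rho_sigma(self):
        # sigma . rho . sigma == rho^-1, so <rho, sigma> is dihedral of order 6
        b = tuple(range(10))
        assert reflect(rotate(reflect(b))) == rotate(rotate(b))

    @settings(deadline=None)
    @given(barcodes)
    def test_orbit_size_divides_three(self, b):
        orbit = {b, rotate(b), rotate(rotate(b))}
        assert len(orbit) in (1, 3)

    @settings(deadline=None)
    @given(barcodes)
    def test_canonical_idempotent_and_orbit_constant(self, b):
        c = canonical_form(b)
        assert canonical_form(c) == c
        assert canonical_form(rotate(b)) == c
        assert c in {b, rotate(b), rotate(rotate(b))}

    def test_parent_is_fixed_point(self):
        assert canonical_form("0000000000") == (0,) * 10

    def test_single_substituent_canonicalizes_to_one_arm(self):
        # all three beta placements share one canonical representative
        placements = {canonical_form(tuple(1 if i == p else 0 for i in range(10)))
                      for p in (1, 4, 7)}
        assert len(placements) == 1

    def test_string_parsing_round_trip(self):
        assert barcode_string(parse_barcode("0120120120")) == "0120120120"
        with pytest.raises(BarcodeError):
            parse_barcode("012")
        with pytest.raises(BarcodeError):
            parse_barcode("01201201xx")

    def test_reorder_hook(self):
        b = parse_barcode("0123456789")
        assert reorder_barcode(b, list(reversed(range(10)))) == tuple(
            reversed(range(10))
        )
        with pytest.raises(BarcodeError):
            reorder_barcode(b, [0] * 10)


class TestSubstituentSet:
    def test_smiles_merging_by_canonical_structure(self):
        s = SubstituentSet.from_spec(["OC:1", "CO:2"])
        assert len(s.entries) == 1
        assert s.entries[0].count == 3

    def test_hydrogen_complement(self):
        assert SubstituentSet.from_spec(["C:2"]).hydrogen_count == 8
        assert SubstituentSet.from_counts([]).hydrogen_count == 10

    def test_overfull_rejected(self):
        with pytest.raises(BarcodeError):
            SubstituentSet.from_counts([6, 5])

    def test_barcode_must_realize_counts(self):
        s = SubstituentSet.from_counts([2])
        with pytest.raises(BarcodeError):
            s.validate_barcode("1110000000")


class TestCounting:
    @pytest.mark.parametrize(
        "counts,expected_S",
        [([3, 1], 3), ([1, 1, 1], 0), ([], 1), ([3, 3], 6), ([2], 0),
         ([3], 3), ([4], 3), ([9], 1), ([3, 3, 3], 6)],
    )
    def test_symmetry_factor(self, counts, expected_S):
        assert compute_S(SubstituentSet.from_counts(counts)) == expected_S

    @pytest.mark.parametrize(
        "counts,expected",
        [([1, 1, 1], 240), ([3, 1], 282), ([2], 15), ([3], 42), ([4], 72),
         ([], 1), ([1], 4), ([1] * 10, 1209600)],
    )
    def test_closed_form_counts(self, counts, expected):
        assert count_isomers(SubstituentSet.from_counts(counts)) == expected

    @pytest.mark.parametrize(
        "counts", [[2], [3], [1], [1, 1], [2, 1], [1, 1, 1], [3, 1], [4]]
    )
    def test_enumeration_matches_closed_form(self, counts):
        s = SubstituentSet.from_counts(counts)
        isomers = enumerate_isomers(s)
        assert len(isomers) == count_isomers(s)
        assert isomers == sorted(isomers)
        assert len(set(isomers)) == len(isomers)
        # no two listed isomers are rotations of one another
        seen = set()
        for b in isomers:
            assert canonical_form(b) == b
            orbit = frozenset({b, rotate(b), rotate(rotate(b))})
            assert orbit not in seen
            seen.add(orbit)

    def test_monosubstituted_has_four_positions(self):
        # alpha, beta, gamma, delta
        assert count_isomers(SubstituentSet.from_counts([1])) == 4


class TestChirality:
    def test_dimethyl_split(self, me2):
        achiral, pairs = chirality_split(enumerate_isomers(me2))
        assert len(achiral) == 9
        assert len(pairs) == 3
        assert len(achiral) + 2 * len(pairs) == 15

    def test_beta_beta_prime_achiral(self):
        b = canonical_form((0, 1, 0, 0, 1, 0, 0, 0, 0, 0))
        assert classify_chirality(b).kind == "achiral"

    def test_gamma_gamma_prime_achiral(self):
        b = canonical_form((0, 0, 1, 0, 0, 1, 0, 0, 0, 0))
        assert classify_chirality(b).kind == "achiral"

    def test_beta_gamma_prime_chiral_with_reciprocal_partner(self):
        b = canonical_form((0, 1, 0, 0, 0, 1, 0, 0, 0, 0))
        cls = classify_chirality(b)
        assert cls.kind == "chiral"
        assert cls.partner != b
        back = classify_chirality(cls.partner)
        assert back.kind == "chiral"
        assert back.partner == b

    @pytest.mark.parametrize("counts", [[2], [1, 1], [3], [2, 1]])
    def test_split_is_partition_and_involution(self, counts):
        s = SubstituentSet.from_counts(counts)
        isomers = enumerate_isomers(s)
        achiral, pairs = chirality_split(isomers)
        assert len(achiral) + 2 * len(pairs) == len(isomers)
        for a, b in pairs:
            assert a != b
            assert classify_chirality(a).partner == b
            assert classify_chirality(b).partner == a


class TestVariations:
    def test_there_are_42(self):
        assert len(enumerate_substitution_variations()) == 42

    def test_known_rows(self):
        by_partition = {
            v.partition: v for v in enumerate_substitution_variations()
        }
        assert by_partition[(10,)].n_iso == 1
        assert by_partition[(7, 1, 1, 1)].n_iso == 240
        assert by_partition[(6, 3, 1)].n_iso == 282
        assert by_partition[(1,) * 10].n_iso == 1209600

    def test_symmetry_factor_range_and_count_integrality(self):
        for v in enumerate_substitution_variations():
            assert v.S in (0, 1, 3, 6)
            raw = math.factorial(10)
            for c in v.partition:
                raw //= math.factorial(c)
            assert (raw + 2 * v.S) % 3 == 0
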