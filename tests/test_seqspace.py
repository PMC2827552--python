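"""The embedding's exact identities are the load-bearing math: Hamming
preservation, the law of cosines, quartet conservation, and invariance to
the base-order convention."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kleevec import seqspace as ss
from kleevec.exceptions import EncodingError, MaskError, ShapeError

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)
paired_dna = st.integers(1, 80).flatmap(
    lambda n: st.tuples(st.text("ACGT", min_size=n, max_size=n),
                        st.text("ACGT", min_size=n, max_size=n))
)


class TestEncode:
    def test_unambiguous_bases_are_unit_quartets(self):
        v = ss.encode("ACGT")
        expected = np.eye(4).ravel()
        np.testing.assert_array_equal(v.values, expected)

    @pytest.mark.parametrize("char,compat", [
        ("N", "ACGT"), ("R", "AG"), ("Y", "CT"), ("S", "CG"), ("W", "AT"),
        ("K", "GT"), ("M", "AC"), ("B", "CGT"), ("D", "AGT"), ("H", "ACT"),
        ("V", "ACG"), ("-", "ACGT"), (".", "ACGT"),
    ])
    def test_ambiguity_codes_uniform_over_compatible(self, char, compat):
        q = ss.encode(char).values
        for i, base in enumerate(ss.CANONICAL_BASES):
            expect = 1.0 / len(compat) if base in compat else 0.0
            assert q[i] == expect
        assert q.sum() == pytest.approx(1.0, abs=1e-15)

    def test_501mer_gives_2004_entries(self):
        assert ss.encode("A" * 501).values.size == 2004

    def test_unresolvable_character_reports_position(self):
        with pytest.raises(EncodingError, match="position 3"):
            ss.encode("AC!T")
        with pytest.raises(EncodingError):
            ss.encode("")

    def test_unambiguous_squared_norm_is_n(self):
        v = ss.encode("ACGTTGCA")
        assert v.values @ v.values == pytest.approx(8.0, abs=0)

    @given(dna)
    @settings(max_examples=50, derandomize=True)
    def test_quartet_conservation(self, seq):
        sums = ss.quartet_sums(ss.encode(seq).values)
        np.testing.assert_allclose(sums, 1.0, atol=1e-15)

    def test_quartet_conservation_holds_with_ambiguity(self):
        sums = ss.quartet_sums(ss.encode("ANR-WB").values)
        np.testing.assert_allclose(sums, 1.0, atol=1e-15)


class TestDecode:
    def test_inverse_on_unambiguous(self):
        probs = ss.decode_probabilities(ss.encode("ACGT"))
        np.testing.assert_array_equal(probs, np.eye(4))

    def test_ensemble_mean_gives_frequencies(self):
        vs = np.array([ss.encode(c).values for c in ["A", "A", "C"]])
        probs = ss.decode_probabilities(vs.mean(axis=0))
        np.testing.assert_allclose(probs[0], [2 / 3, 1 / 3, 0, 0])

    def test_bad_length(self):
        with pytest.raises(ShapeError):
            ss.decode_probabilities(np.ones(7))


class TestConservedSites:
    def test_column_scan(self):
        mask = ss.find_conserved_sites(["ACGT", "ACGA"])
        assert mask.dropped_positions == (1, 2, 3)
        assert mask.kept_positions == (4,)

    def test_strict_rule_breaks_on_ambiguity(self):
        mask = ss.find_conserved_sites(["AN", "AA"])
        assert 1 in mask.dropped_positions  # col 1 all 'A'
        assert 2 in mask.kept_positions     # 'N' present -> not conserved

    def test_unambiguous_rule_ignores_ambiguity(self):
        mask = ss.find_conserved_sites(["AN", "AA"], rule="unambiguous")
        assert mask.dropped_positions == (1, 2)

    def test_identical_rows_drop_everything_then_mask_errors(self):
        mask = ss.find_conserved_sites(["ACGT", "ACGT"])
        assert mask.kept_positions == ()
        with pytest.raises(MaskError):
            ss.apply_mask(ss.encode("ACGT"), mask)


class TestApplyMask:
    def test_reference_drop_leaves_1360_entries(self):
        dropped = [p - 99 for p in ss.reference_conserved_sites()]
        mask = ss.SiteMask.from_dropped(dropped, 501)
        assert len(dropped) == 161
        out = ss.apply_mask(ss.encode("A" * 501), mask)
        assert out.values.size == 1360

    def test_empty_drop_is_identity(self):
        v = ss.encode("ACGT")
        mask = ss.SiteMask.from_dropped([], 4)
        np.testing.assert_array_equal(ss.apply_mask(v, mask).values, v.values)

    def test_quartets_preserved_in_order(self):
        v = ss.encode("ACGT")
        mask = ss.SiteMask.from_dropped([1, 3], 4)
        out = ss.apply_mask(v, mask)
        np.testing.assert_array_equal(
            out.values.reshape(2, 4),
            np.array([ss.encode("C").values, ss.encode("T").values]),
        )

    def test_size_mismatch(self):
        with pytest.raises(ShapeError):
            ss.apply_mask(ss.encode("ACGT"), ss.SiteMask.from_dropped([], 5))


class TestDistances:
    def test_hamming_examples(self):
        assert ss.hamming("ACGT", "ACGA") == 1
        assert ss.hamming("ACGT", "ACGT") == 0
        with pytest.raises(ShapeError):
            ss.hamming("AC", "ACG")

    def test_hamming_matches_loop_oracle(self, rng):
        from tests.conftest import random_sequence
        for _ in range(20):
            a = random_sequence(rng, 200)
            b = random_sequence(rng, 200)
            naive = sum(x != y for x, y in zip(a, b))
            assert ss.hamming(a, b) == naive

    def test_generalized_hamming_single_substitution(self):
        v, w = ss.encode("ACGT"), ss.encode("ACGA")
        assert ss.generalized_hamming(v, w) == pytest.approx(1.0, abs=0)
        assert ss.generalized_hamming(v, v) == 0.0

    @given(paired_dna)
    @settings(max_examples=100, derandomize=True)
    def test_hamming_preservation_exact(self, pair):
        a, b = pair
        va, vb = ss.encode(a), ss.encode(b)
        d = va.values - vb.values
        assert float(d @ d) == 2.0 * ss.hamming(a, b)  # exact, no tolerance
        assert ss.generalized_hamming(va, vb) == float(ss.hamming(a, b))

    @given(paired_dna)
    @settings(max_examples=100, derandomize=True)
    def test_correlation_is_one_minus_hamming_fraction(self, pair):
        a, b = pair
        rho = ss.correlation(ss.encode(a), ss.encode(b))
        assert rho == pytest.approx(1 - ss.hamming(a, b) / len(a), abs=1e-12)

    @given(paired_dna)
    @settings(max_examples=50, derandomize=True)
    def test_law_of_cosines(self, pair):
        a, b = pair
        va, vb = ss.encode(a).unit(), ss.encode(b).unit()
        lhs = float((va.values - vb.values) @ (va.values - vb.values))
        rho = ss.correlation(va, vb)
        assert lhs == pytest.approx(2 * (1 - rho), abs=1e-12)

    def test_all_sites_differ_gives_zero_correlation(self):
        assert ss.correlation(ss.encode("ACGT"), ss.encode("CAAC")) == 0.0

    def test_self_correlation_is_one(self):
        v = ss.encode("ACGNT")
        assert ss.correlation(v, v) == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("order", list(itertools.permutations("ACGT"))[:6])
    def test_convention_independence(self, order, rng):
        from tests.conftest import random_sequence
        conv = ss.EncodingConvention(tuple(order))
        a = random_sequence(rng, 60)
        b = random_sequence(rng, 60)
        default = ss.correlation(ss.encode(a), ss.encode(b))
        permuted = ss.correlation(ss.encode(a, conv), ss.encode(b, conv))
        assert permuted == pytest.approx(default, abs=1e-15)
        assert ss.generalized_hamming(ss.encode(a, conv), ss.encode(b, conv)) \
            == pytest.approx(ss.generalized_hamming(ss.encode(a), ss.encode(b)))


class TestSiteListIO:
    def test_round_trip_with_offset(self, tmp_path):
        p = tmp_path / "sites.txt"
        ss.save_site_list([143, 145, 599], p, header="demo")
        assert ss.load_site_list(p) == [143, 145, 599]
        assert ss.load_site_list(p, offset=-99) == [44, 46, 500]

    def test_reference_list_range(self):
        sites = ss.reference_conserved_sites()
        assert len(sites) == 161
        assert min(sites) >= 100 and max(sites) <= 600
        assert sites == sorted(sites)
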