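import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gintools.recombination_model import (
    PARENTAL_EXCISION,
    PARENTAL_INTEGRATION,
    AttCore,
    RecombinationConfig,
    RegistrationError,
    assemble_minimal_element,
    att_identity,
    circular_junction_seq,
    excise,
    integrate,
    rank_by_identity,
    register_cores,
    sample_excision_products,
)

from conftest import random_dna

dna = st.text(alphabet="ACGT", min_size=11, max_size=17)


def random_pair(rng, L=11, o=2, n_mismatch=3):
    """attI/attB of length L differing at n_mismatch overhang offsets."""
    attb = random_dna(rng, L)
    atti = list(attb)
    for k in rng.choice(6, size=n_mismatch, replace=False):
        atti[o + k] = "ACGT".replace(atti[o + k], "")[rng.integers(0, 3)]
    return AttCore("".join(atti), o, "attI"), AttCore(attb, o, "attB")


class TestAttCore:
    def test_overhang_centering_default(self):
        core = AttCore("ACGTACGTACG")  # L=11 -> offset 2
        assert core.overhang_offset == 2
        assert core.overhang == "GTACGT"

    def test_bad_offset(self):
        with pytest.raises(ValueError):
            AttCore("ACGTACGTACG", overhang_offset=9)

    def test_bad_alphabet(self):
        with pytest.raises(ValueError):
            AttCore("ACGTACGTACN")


class TestIntegrate:
    def test_identity_case(self):
        site = AttCore("GGATATATCCG", role="attB")
        res = integrate(AttCore(site.seq, role="attI"), site)
        assert res.attL.seq == res.attR.seq == site.seq
        assert res.heteroduplex_positions == ()

    def test_manual_string_surgery_oracle(self):
        # L=11, o=2, overhangs differ at offsets 0, 2, 5; both sites
        # resolved toward the host template
        attI = AttCore("GG" + "ATCGAT" + "CCG", 2, "attI")
        attB = AttCore("GG" + "TTGGAA" + "CCG", 2, "attB")
        res = integrate(attI, attB, resolution_choices=("host", "host"))
        assert res.heteroduplex_positions == (0, 2, 5)
        assert res.attL.seq == "GG" + "TTGGAA" + "CCG"
        assert res.attR.seq == "GG" + "TTGGAA" + "CCG"

    def test_arm_exchange_conserves_sequence(self, rng):
        # non-overhang positions of {attL, attR} are a permutation of
        # those of {attI, attB}
        for _ in range(20):
            attI, attB = random_pair(rng)
            res = integrate(attI, attB,
                            resolution_choices=PARENTAL_INTEGRATION)
            got = sorted([res.attL.left_arm + res.attL.right_arm,
                          res.attR.left_arm + res.attR.right_arm])
            exp = sorted([attB.left_arm + attI.right_arm,
                          attI.left_arm + attB.right_arm])
            assert got == exp

    def test_length_mismatch_rejected(self):
        with pytest.raises(RegistrationError):
            integrate(AttCore("ACGTACGTACG"), AttCore("ACGTACGTACGTA"))


class TestExcise:
    def test_identity_case(self):
        att = AttCore("GGATATATCCG", 2, "attL")
        res = excise(att, AttCore(att.seq, 2, "attR"))
        assert res.attI_restored.seq == res.attB_restored.seq == att.seq

    def test_element_resolution_restores_parental(self, rng):
        for _ in range(20):
            attI, attB = random_pair(rng)
            integ = integrate(attI, attB,
                              resolution_choices=PARENTAL_INTEGRATION)
            parental = excise(integ.attL, integ.attR,
                              resolution_choices=("element", "element"),
                              parental_attI=attI)
            assert parental.variant_class == "parental"
            host = excise(integ.attL, integ.attR,
                          resolution_choices=("host", "host"),
                          parental_attI=attI)
            assert host.variant_class == "attB_like_overhang"
            assert host.attI_restored.overhang == attB.overhang

    def test_inverse_property(self, rng):
        for _ in range(50):
            L = int(rng.integers(11, 18))
            o = int(rng.integers(0, L - 6 + 1))
            n_mm = int(rng.integers(0, 4))
            attI, attB = random_pair(rng, L=L, o=o, n_mismatch=n_mm)
            integ = integrate(attI, attB,
                              resolution_choices=PARENTAL_INTEGRATION)
            back = excise(integ.attL, integ.attR,
                          resolution_choices=PARENTAL_EXCISION)
            assert back.attI_restored.seq == attI.seq
            assert back.attB_restored.seq == attB.seq

    def test_per_position_contains_whole_overhang(self, rng):
        attI, attB = random_pair(rng)
        integ = integrate(attI, attB, resolution_choices=PARENTAL_INTEGRATION)
        k = len(integ.heteroduplex_positions)
        cfg = RecombinationConfig(resolution_mode="per_position")
        res = excise(integ.attL, integ.attR, cfg,
                     resolution_choices=(["element"] * k, ["host"] * k),
                     parental_attI=attI)
        whole = excise(integ.attL, integ.attR,
                       resolution_choices=PARENTAL_EXCISION,
                       parental_attI=attI)
        assert res.attI_restored.seq == whole.attI_restored.seq
        assert res.attB_restored.seq == whole.attB_restored.seq

    def test_per_position_intermediate_flagged_other(self, rng):
        attI, attB = random_pair(rng, n_mismatch=3)
        integ = integrate(attI, attB, resolution_choices=PARENTAL_INTEGRATION)
        res = excise(integ.attL, integ.attR,
                     resolution_choices=(["element", "host", "element"], ["host"] * 3),
                     parental_attI=attI)
        assert res.variant_class == "other"


class TestSampleExcisionProducts:
    def test_p_host_zero_all_parental(self, rng):
        attI, attB = random_pair(rng)
        integ = integrate(attI, attB, resolution_choices=PARENTAL_INTEGRATION)
        counts = sample_excision_products(
            integ.attL, integ.attR, 500,
            RecombinationConfig(p_host=0.0, seed=1), parental_attI=attI)
        assert counts["parental"] == 500

    def test_fifty_percent_parental(self, rng):
        # the unbiased whole-overhang model: half of excised circles carry
        # the parental attI, half the attB-like overhang
        attI, attB = random_pair(rng, n_mismatch=3)
        integ = integrate(attI, attB, resolution_choices=PARENTAL_INTEGRATION)
        counts = sample_excision_products(
            integ.attL, integ.attR, 10000,
            RecombinationConfig(p_host=0.5, seed=42), parental_attI=attI)
        frac = counts["parental"] / 10000
        assert abs(frac - 0.5) < 0.02
        assert counts["other"] == 0  # whole-overhang: dichotomy only

    def test_binomial_closed_form(self, rng):
        from scipy.stats import binom
        attI, attB = random_pair(rng)
        integ = integrate(attI, attB, resolution_choices=PARENTAL_INTEGRATION)
        n, p_host = 5000, 0.3
        counts = sample_excision_products(
            integ.attL, integ.attR, n,
            RecombinationConfig(p_host=p_host, seed=9), parental_attI=attI)
        lo, hi = binom.ppf([0.0005, 0.9995], n, 1 - p_host)
        assert lo <= counts["parental"] <= hi

    def test_reproducible_given_seed(self, rng):
        attI, attB = random_pair(rng)
        integ = integrate(attI, attB, resolution_choices=PARENTAL_INTEGRATION)
        runs = [sample_excision_products(integ.attL, integ.attR, 200,
                                         RecombinationConfig(seed=5),
                                         parental_attI=attI)
                for _ in range(2)]
        assert runs[0] == runs[1]


class TestAttIdentity:
    def test_identical(self):
        a = AttCore("ACGTACGTACG")
        assert att_identity(a, AttCore(a.seq)) == 1.0

    def test_direct_count(self):
        a = AttCore("AAAAAAAAAAA")
        b = AttCore("AAACAACAACA")
        assert att_identity(a, b) == pytest.approx(8 / 11)

    def test_host_resolution_monotonicity(self, rng):
        # host-templated excision never lowers identity to attB
        for _ in range(100):
            attI, attB = random_pair(rng, n_mismatch=int(rng.integers(0, 4)))
            integ = integrate(attI, attB,
                              resolution_choices=PARENTAL_INTEGRATION)
            hostvar = excise(integ.attL, integ.attR,
                             resolution_choices=("host", "host")).attI_restored
            assert att_identity(hostvar, attB) >= att_identity(attI, attB)

    def test_rank_by_identity(self, rng):
        attI, attB = random_pair(rng, n_mismatch=3)
        integ = integrate(attI, attB, resolution_choices=PARENTAL_INTEGRATION)
        hostvar = excise(integ.attL, integ.attR,
                         resolution_choices=("host", "host")).attI_restored
        ranked = rank_by_identity([attI, hostvar], attB)
        assert ranked[0].seq == hostvar.seq


class TestRegisterCores:
    def test_equal_length(self):
        a, b = register_cores("ACGTACGTACG", "ACGTACGAACG")
        assert len(a) == len(b) == 11

    def test_unequal_length_trims_to_overlap(self):
        a, b = register_cores("ACGTACGTACGTA", "ACGTACGTACG")
        assert len(a) == len(b)


class TestAssembleMinimalElement:
    def test_printed_segment_lengths(self, rng):
        # the two file-convention intervals used for the minimal element
        seq = random_dna(rng, 985000)
        _, report = assemble_minimal_element(seq, (983899, 984379),
                                             (960530, 966331))
        assert report["three_prime_length"] == 481
        assert report["five_prime_length"] == 5802

    def test_conservation_of_length(self):
        circle, report = assemble_minimal_element("ACGTACGTAC", (1, 4), (5, 10))
        assert circle == "ACGTACGTAC"
        assert report["circle_length"] == 10

    def test_out_of_bounds(self):
        with pytest.raises(ValueError):
            assemble_minimal_element("ACGT", (1, 10), (1, 2))


class TestCircularJunction:
    def test_flank_zero_returns_atti(self):
        attI = AttCore("ACGTACGTACG")
        assert circular_junction_seq("A" * 100, attI, flank=0) == attI.seq

    def test_junction_structure(self, rng):
        body = random_dna(rng, 200)
        attI = AttCore("ACGTACGTACG")
        j = circular_junction_seq(body, attI, flank=20)
        assert j == body[-20:] + attI.seq + body[:20]

    def test_junction_absent_from_linear_genome(self, rng):
        body = random_dna(rng, 200)
        attI, attB = random_pair(rng)
        integ = integrate(attI, attB, resolution_choices=PARENTAL_INTEGRATION)
        host = random_dna(rng, 300)
        linear = host[:150] + integ.attL.seq + body + integ.attR.seq + host[150:]
        j = circular_junction_seq(body, attI, flank=30)
        assert j not in linear


@given(seq=dna, data=st.data())
@settings(max_examples=50, deadline=None)
def test_integrate_excise_roundtrip_property(seq, data):
    o = data.draw(st.integers(0, len(seq) - 6))
    attB = AttCore(seq, o, "attB")
    k = data.draw(st.integers(0, 3))
    positions = data.draw(st.lists(st.integers(0, 5), min_size=k, max_size=k,
                                   unique=True))
    atti = list(seq)
    for p in positions:
        atti[o + p] = data.draw(st.sampled_from("ACGT".replace(atti[o + p], "")))
    attI = AttCore("".join(atti), o, "attI")
    integ = integrate(attI, attB, resolution_choices=PARENTAL_INTEGRATION)
    back = excise(integ.attL, integ.attR, resolution_choices=PARENTAL_EXCISION)
    assert back.attI_restored.seq == attI.seq
    assert back.attB_restored.seq == attB.seq
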