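"""Primer architecture, degeneracy arithmetic, Tm prediction, self-structure."""

import math

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from lampsmith import iupac
from lampsmith.primers import (
    AssemblyError,
    LampPrimer,
    LampPrimerSet,
    PrimerRegion,
    TmConditions,
    assemble_inner_primer,
    degeneracy_count,
    expand_degenerate,
    melting_temperature,
    reverse_complement,
    self_structure_score,
)

iupac_strings = st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=10)


class TestReverseComplement:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", "GCAT"),
        ("RAY", "RTY"),
    ])
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_against_biopython_oracle(self, qff):
        for p in qff.primers().values():
            assert reverse_complement(p.sequence) == str(
                Seq(p.sequence).reverse_complement())


class TestDegeneracy:
    def test_expand_examples(self):
        assert expand_degenerate("ACGT") == {"ACGT"}
        assert expand_degenerate("AR") == {"AA", "AG"}

    def test_bundled_bip_expands_to_eight(self, qff):
        variants = expand_degenerate(qff.bip.sequence)
        assert len(variants) == 8
        assert degeneracy_count(qff.bip.sequence) == 8

    def test_counts(self, qff):
        assert degeneracy_count(qff.f3.sequence) == 1
        assert degeneracy_count("NN") == 16

    @settings(max_examples=150, derandomize=True)
    @given(iupac_strings)
    def test_expansion_size_matches_count(self, seq):
        if degeneracy_count(seq) <= 4096:
            assert len(expand_degenerate(seq)) == degeneracy_count(seq)


class TestAssembly:
    def test_toy_parts(self):
        f1 = PrimerRegion(name="F1", span=(0, 3), strand="plus", sequence="AAA")
        f2 = PrimerRegion(name="F2", span=(10, 14), strand="plus", sequence="CCCC")
        p = assemble_inner_primer(f1, f2)
        assert p.sequence == "TTTCCCC" and p.length == 7

    def test_bundled_inner_primer_lengths(self, qff):
        fip = assemble_inner_primer(*qff.fip_parts, label="FIP")
        bip = assemble_inner_primer(*qff.bip_parts, label="BIP")
        assert fip.length == 44 and fip.sequence == qff.fip.sequence
        assert bip.length == 51 and bip.sequence == qff.bip.sequence

    def test_mismatched_parts_rejected(self):
        f1 = PrimerRegion(name="F1", span=(0, 3), strand="plus", sequence="AAA")
        b2 = PrimerRegion(name="B2", span=(5, 8), strand="minus", sequence="GGG")
        with pytest.raises(AssemblyError):
            assemble_inner_primer(f1, b2)

    @settings(max_examples=50, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=25),
           st.text(alphabet="ACGT", min_size=1, max_size=25))
    def test_length_additivity(self, a, b):
        f1 = PrimerRegion(name="F1", span=(0, len(a)), strand="plus", sequence=a)
        f2 = PrimerRegion(name="F2", span=(30, 30 + len(b)), strand="plus", sequence=b)
        assert assemble_inner_primer(f1, f2).length == len(a) + len(b)

    def test_set_invariant_enforced(self, qff):
        with pytest.raises(AssemblyError):
            LampPrimerSet(
                f3=qff.f3, b3=qff.b3,
                fip=LampPrimer(label="FIP", sequence="ACGTACGTACGT"),
                bip=qff.bip, fip_parts=qff.fip_parts, bip_parts=qff.bip_parts)


# independent nearest-neighbour oracle: unified duplex parameters with the
# entropy-additive monovalent salt term, written out from the published table
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}


def _tm_oracle(seq, na_mM=50.0, oligo_nM=100.0):
    dH = dS = 0.0
    for a, b in zip(seq, seq[1:]):
        h, s = _NN[a + b]
        dH += h
        dS += s
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dH += 2.3
            dS += 4.1
        else:
            dH += 0.1
            dS += -2.8
    dS += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    return 1000.0 * dH / (dS + 1.987 * math.log(oligo_nM * 1e-9)) - 273.15


class TestMeltingTemperature:
    def test_gc_monotonicity(self):
        at = melting_temperature("ATATATATATATATATATAT").tm
        gc = melting_temperature("GCGCGCGCGCGCGCGCGCGC").tm
        assert at < gc

    def test_independent_nearest_neighbour_oracle(self):
        cond = TmConditions(na_mM=50, mg_mM=0, dntps_mM=0, oligo_nM=100,
                            nn_table="santalucia1998", salt_correction=5)
        for seq in ["ATGCATGCATGCATGC", "TACAGGTTGAACAGTTTACCCAC",
                    "CCTCTTTTCGTTTGAGCAGTTGTATT"]:
            assert melting_temperature(seq, cond).tm == pytest.approx(
                _tm_oracle(seq), abs=0.1)

    def test_bundled_f3_matches_published_prediction(self, qff):
        # the published prediction's software/conditions are unstated, so the
        # consistency requirement is a +/- 3 degree band
        assert melting_temperature(qff.f3.sequence).tm == pytest.approx(60.3, abs=3.0)

    def test_degenerate_min_bounds_every_expansion(self, qff):
        est = melting_temperature(qff.bip.sequence)
        per_variant = [melting_temperature(v).tm
                       for v in expand_degenerate(qff.bip.sequence)]
        assert est.tm == pytest.approx(min(per_variant), abs=1e-9)
        assert all(est.tm <= t + 1e-9 for t in per_variant)
        assert est.tm_max == pytest.approx(max(per_variant), abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            melting_temperature("ACGT")


def _naive_dimer_run(seq):
    """DP oracle: longest antiparallel self-complementary run."""
    n = len(seq)
    best = 0
    memo = {}

    def f(i, j):
        if i >= n or j < 0 or not iupac.can_pair(seq[i], seq[j]):
            return 0
        if (i, j) not in memo:
            memo[(i, j)] = 1 + f(i + 1, j - 1)
        return memo[(i, j)]

    for i in range(n):
        for j in range(n):
            best = max(best, f(i, j))
    return best


def _naive_hairpin_stem(seq, min_loop=3):
    """Oracle: enumerate (stem start, stem length, loop length) directly."""
    n = len(seq)
    best = 0
    for i in range(n):
        for loop in range(min_loop, n):
            for l in range(1, n):
                j = i + 2 * l + loop - 1
                if j >= n:
                    break
                if all(iupac.can_pair(seq[i + k], seq[j - k]) for k in range(l)):
                    best = max(best, l)
    return best


class TestSelfStructure:
    def test_poly_a_has_no_structure(self):
        s = self_structure_score("AAAAAAAAAA")
        assert s.dimer_run == 0 and s.hairpin_stem == 0 and not s.three_prime_anchored

    def test_g5c5(self):
        # GGGGGCCCCC equals its own reverse complement, so two antiparallel
        # copies pair along the full length (run 10); intramolecular folding
        # is limited to a 3-pair stem by the minimum loop of 3
        s = self_structure_score("GGGGGCCCCC")
        assert s.dimer_run == _naive_dimer_run("GGGGGCCCCC") == 10
        assert s.hairpin_stem == _naive_hairpin_stem("GGGGGCCCCC") == 3

    def test_palindromic_12mer_is_three_prime_anchored(self):
        s = self_structure_score("ACGTACGTACGT", anchor_threshold=4)
        assert s.dimer_run == 12
        assert s.three_prime_anchored

    def test_brute_force_oracle_on_random_sequences(self, rng):
        for _ in range(25):
            seq = "".join("ACGT"[i] for i in rng.integers(4, size=int(rng.integers(8, 18))))
            s = self_structure_score(seq)
            assert s.dimer_run == _naive_dimer_run(seq), seq
            assert s.hairpin_stem == _naive_hairpin_stem(seq), seq

    def test_penalty_doubles_when_anchored(self):
        s = self_structure_score("ACGTACGTACGT")
        assert s.penalty == 2 * max(s.dimer_run, s.hairpin_stem)


class TestSerialisation:
    def test_json_roundtrip(self, qff, tmp_path):
        p = tmp_path / "set.json"
        qff.to_json(p)
        back = LampPrimerSet.from_json(p)
        assert back.fip.sequence == qff.fip.sequence
        assert back.bip_parts[1].sequence == qff.bip_parts[1].sequence
        assert back.region_footprints() == qff.region_footprints()

    def test_table_renders_degeneracy_one_as_none(self, qff):
        table = qff.to_table().set_index("label")
        assert table.loc["Btryoni_F3", "degeneracy"] == "None"
        assert table.loc["Btryoni_BIP", "degeneracy"] == 8
        assert table.loc["Btryoni_FIP", "length_bp"] == 44
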