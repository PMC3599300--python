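import math
import random

import pytest
from hypothesis import given, strategies as st

from speccount import (
    DigestSpec,
    MetricInputs,
    ProteinRecord,
    SpectrumIntensityIndex,
    distribution_factors,
    score_dnsaf,
    score_empai,
    score_nsaf,
    score_peptides,
    score_raw,
    score_sin,
)

from conftest import psm, random_instance
from oracles import naive_dnsaf, naive_empai, naive_nsaf, naive_sin

# digest bounds that guarantee at least one observable peptide for any
# random protein, so emPAI is defined on every generated instance
WIDE_BOUNDS = DigestSpec(min_length=1, max_length=60)


def inputs_for(proteins, psms, intensities=None, digest_spec=None):
    index = SpectrumIntensityIndex(intensities) if intensities else None
    return MetricInputs.assemble(
        psms, proteins, digest_spec=digest_spec, intensity_index=index
    )


def protein(pid, seq):
    return ProteinRecord(pid, "", seq)


class TestScoreRaw:
    def test_identity_on_counts(self):
        prots = [protein("A", "MPEPKAAAK"), protein("B", "WWWKGGGR")]
        inp = inputs_for(prots, [psm("MPEPK")] * 9 + [psm("WWWK")] * 6)
        assert score_raw(inp).scores == {"A": 9.0, "B": 6.0}

    def test_zero_count_protein_absent(self):
        prots = [protein("A", "MPEPKAAAK"), protein("B", "WWWKGGGR")]
        inp = inputs_for(prots, [psm("MPEPK")])
        assert "B" not in score_raw(inp).scores

    def test_empty_psms_empty_table(self):
        inp = inputs_for([protein("A", "MPEPKAAAK")], [psm("MPEPK", q=0.5)][:0])
        assert score_raw(inp).scores == {}


class TestScoreNsaf:
    def test_hand_example_two_proteins(self):
        # s/L: A = 10/100, B = 10/200 -> 2/3 vs 1/3
        prots = [protein("A", "AAAPEPK" + "G" * 93), protein("B", "WWWPEPK" + "G" * 193)]
        inp = inputs_for(prots, [psm("AAAPEPK")] * 10 + [psm("WWWPEPK")] * 10)
        t = score_nsaf(inp)
        assert t.scores["A"] == pytest.approx(2 / 3, abs=1e-12)
        assert t.scores["B"] == pytest.approx(1 / 3, abs=1e-12)

    def test_single_protein_is_one(self):
        inp = inputs_for([protein("A", "MPEPKAAAK")], [psm("MPEPK")])
        assert score_nsaf(inp).scores == {"A": 1.0}

    def test_symmetry_equal_counts_equal_lengths(self):
        prots = [protein("A", "AAAPEPK" + "G" * 13), protein("B", "WWWPEPK" + "G" * 13)]
        inp = inputs_for(prots, [psm("AAAPEPK")] * 5 + [psm("WWWPEPK")] * 5)
        assert score_nsaf(inp).scores == {"A": 0.5, "B": 0.5}

    def test_no_counts_is_an_error(self):
        inp = inputs_for([protein("A", "MPEPKAAAK")], [])
        with pytest.raises(ValueError, match="no scorable protein"):
            score_nsaf(inp)


class TestDistributionFactors:
    def test_hand_example(self, tiny_proteins):
        inp = inputs_for(
            tiny_proteins,
            [psm("MPEPK")] * 4 + [psm("WWWK")] * 1 + [psm("ELVISLIVESK")] * 5,
        )
        d = distribution_factors(inp.counts.unique, inp.pmap)
        assert d[("ELVISLIVESK", "A")] == pytest.approx(0.8)
        assert d[("ELVISLIVESK", "B")] == pytest.approx(0.2)

    def test_zero_unique_splits_equally(self, tiny_proteins):
        inp = inputs_for(tiny_proteins, [psm("ELVISLIVESK")] * 3)
        d = distribution_factors(inp.counts.unique, inp.pmap)
        assert d[("ELVISLIVESK", "A")] == 0.5
        assert d[("ELVISLIVESK", "B")] == 0.5

    def test_unique_peptides_have_no_factor(self, tiny_proteins):
        inp = inputs_for(tiny_proteins, [psm("MPEPK")])
        d = distribution_factors(inp.counts.unique, inp.pmap)
        assert ("MPEPK", "A") not in d.factors

    @given(st.randoms(use_true_random=False))
    def test_factors_sum_to_one_per_peptide(self, pyrandom):
        proteins, psms, _ = random_instance(pyrandom)
        inp = inputs_for(proteins, psms)
        d = distribution_factors(inp.counts.unique, inp.pmap)
        by_pep = {}
        for (pep, _prot), v in d.factors.items():
            by_pep[pep] = by_pep.get(pep, 0.0) + v
        for pep, s in by_pep.items():
            assert s == pytest.approx(1.0, abs=1e-12)


class TestScoreDnsaf:
    def test_hand_example_shared_five_spectra(self):
        # equal lengths; A: u=4, B: u=1, shared peptide 5 spectra
        # dNSAF_A = (4 + 0.8*5) / ((4+4) + (1+1)) = 0.8
        a = "MPEPKAAELVISLIVESKTTTR"  # 22 residues
        b = "QWERTYQWEELVISLIVESKFR"  # 22 residues
        prots = [protein("A", a), protein("B", b)]
        inp = inputs_for(
            prots, [psm("MPEPK")] * 4 + [psm("QWERTYQWEE")] * 1 + [psm("ELVISLIVESK")] * 5
        )
        t = score_dnsaf(inp)
        assert t.scores["A"] == pytest.approx(0.8, abs=1e-12)
        assert t.scores["B"] == pytest.approx(0.2, abs=1e-12)

    def test_single_protein_is_one(self):
        inp = inputs_for([protein("A", "MPEPKAAAK")], [psm("MPEPK")])
        assert score_dnsaf(inp).scores == {"A": 1.0}

    @given(st.randoms(use_true_random=False))
    def test_equals_nsaf_without_shared_peptides(self, pyrandom):
        proteins, psms, _ = random_instance(pyrandom)
        inp = inputs_for(proteins, psms)
        if inp.counts.shared_peptide or not inp.counts.total:
            return
        nsaf = score_nsaf(inp).scores
        dnsaf = score_dnsaf(inp).scores
        assert set(nsaf) == set(dnsaf)
        for k in nsaf:
            assert nsaf[k] == pytest.approx(dnsaf[k], abs=1e-14)


class TestScoreEmpai:
    def test_hand_example(self):
        # A: 2 of 10 observable; B: 4 of 10 observable
        a_peps = [f"{c}ACDEFGHI" "K" for c in "ACDEFGHILM"]  # 10 tryptic 10-mers
        b_peps = [f"{c}MNQSTVWY" "R" for c in "ACDEFGHILM"]
        prots = [protein("A", "".join(a_peps)), protein("B", "".join(b_peps))]
        psms = [psm(a_peps[0]), psm(a_peps[1]), psm(b_peps[0]), psm(b_peps[1]),
                psm(b_peps[2]), psm(b_peps[3])]
        inp = inputs_for(prots, psms, digest_spec=DigestSpec())
        t = score_empai(inp)
        ea, eb = 10**0.2 - 1, 10**0.4 - 1
        assert t.scores["A"] == pytest.approx(ea / (ea + eb), abs=1e-12)
        assert t.scores["B"] == pytest.approx(eb / (ea + eb), abs=1e-12)

    def test_identical_ratios_split_evenly(self):
        a_peps = ["AACDEFGHIK", "LLMNQSTVWR"]
        b_peps = ["CCDEFGHILK", "MMNQSTVWYR"]
        prots = [protein("A", "".join(a_peps)), protein("B", "".join(b_peps))]
        inp = inputs_for(prots, [psm(a_peps[0]), psm(b_peps[0])], digest_spec=DigestSpec())
        t = score_empai(inp)
        assert t.scores["A"] == pytest.approx(0.5)

    def test_no_observable_peptides_names_protein(self):
        prots = [protein("A", "MPEPKAAAK")]
        inp = inputs_for(prots, [psm("MPEPK")],
                         digest_spec=DigestSpec(min_length=30, max_length=50))
        with pytest.raises(ValueError, match="A"):
            score_empai(inp)

    def test_requires_digest_spec(self):
        inp = inputs_for([protein("A", "MPEPKAAAK")], [psm("MPEPK")])
        with pytest.raises(ValueError, match="observable"):
            score_empai(inp)


class TestScoreSin:
    def test_hand_example_single_protein(self):
        seq = "MPEPK" + "G" * 95  # L = 100
        prots = [protein("A", seq)]
        p1, p2 = psm("MPEPK"), psm("MPEPK")
        index = {p1.spectrum_key: 3.0, p2.spectrum_key: 7.0}
        inp = inputs_for(prots, [p1, p2], intensities=index)
        assert score_sin(inp).scores["A"] == pytest.approx(10.0 / (100 * 10.0))

    def test_intensity_scale_invariance(self, tiny_proteins):
        psms = [psm("MPEPK"), psm("WWWK"), psm("ELVISLIVESK")]
        index = {p.spectrum_key: 10.0 * (i + 1) for i, p in enumerate(psms)}
        base = score_sin(inputs_for(tiny_proteins, psms, intensities=index)).scores
        scaled_index = {k: 7.5 * v for k, v in index.items()}
        scaled = score_sin(
            inputs_for(tiny_proteins, psms, intensities=scaled_index)
        ).scores
        for k in base:
            assert scaled[k] == pytest.approx(base[k], rel=1e-12)

    def test_double_length_halves_score(self):
        a = "AAAPEPK" + "G" * 33  # L = 40
        b = "WWWPEPK" + "G" * 13  # L = 20
        prots = [protein("A", a), protein("B", b)]
        pa, pb = psm("AAAPEPK"), psm("WWWPEPK")
        index = {pa.spectrum_key: 5.0, pb.spectrum_key: 5.0}
        t = score_sin(inputs_for(prots, [pa, pb], intensities=index))
        assert t.scores["A"] == pytest.approx(t.scores["B"] / 2.0, rel=1e-12)

    def test_missing_intensity_names_spectrum(self):
        prots = [protein("A", "MPEPKAAAK")]
        p = psm("MPEPK")
        inp = inputs_for(prots, [p], intensities={("other", 1, 2): 1.0})
        with pytest.raises(KeyError, match=str(p.spectrum_key[1])):
            score_sin(inp)


class TestScorePeptides:
    def test_raw_counts(self):
        t = score_peptides([psm("AAK")] * 3 + [psm("CCK")], "RAW")
        assert t.scores == {"AAK": 3.0, "CCK": 1.0}
        assert t.level == "peptide"

    def test_sin_single_peptide_is_inverse_length(self):
        p = psm("MPEPK")
        t = score_peptides([p], "SIN", SpectrumIntensityIndex({p.spectrum_key: 42.0}))
        assert t.scores["MPEPK"] == pytest.approx(1.0 / 5.0)

    def test_empty_psms_empty_table(self):
        assert score_peptides([], "RAW").scores == {}

    def test_unsupported_metric_rejected(self):
        with pytest.raises(ValueError, match="RAW and SIN"):
            score_peptides([], "NSAF")


class TestOracleEquivalence:
    """Two-route check: package vs naive transcription of the formulas."""

    @pytest.mark.parametrize("seed", range(25))
    def test_all_metrics_match_naive(self, seed):
        rng = random.Random(seed)
        proteins, psms, intensities = random_instance(rng)
        inp = inputs_for(proteins, psms, intensities=intensities,
                         digest_spec=WIDE_BOUNDS)
        pairs = [
            (score_nsaf(inp).scores, naive_nsaf(proteins, psms)),
            (score_dnsaf(inp).scores, naive_dnsaf(proteins, psms)),
            (score_empai(inp).scores, naive_empai(proteins, psms, 1, 60)),
            (score_sin(inp).scores, naive_sin(proteins, psms, intensities)),
        ]
        for ours, naive in pairs:
            assert set(ours) == set(naive)
            for k in ours:
                assert ours[k] == pytest.approx(naive[k], abs=1e-12)


class TestInvariants:
    @given(st.randoms(use_true_random=False))
    def test_normalised_metrics_sum_to_one(self, pyrandom):
        proteins, psms, intensities = random_instance(pyrandom)
        inp = inputs_for(proteins, psms, intensities=intensities,
                         digest_spec=WIDE_BOUNDS)
        for scorer in (score_nsaf, score_dnsaf, score_empai):
            scores = scorer(inp).scores
            assert sum(scores.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(v >= 0 for v in scores.values())
        assert all(v >= 0 for v in score_sin(inp).scores.values())

    @given(st.randoms(use_true_random=False), st.integers(min_value=2, max_value=4))
    def test_count_scaling_invariance(self, pyrandom, c):
        """Duplicating every PSM c times leaves NSAF and dNSAF unchanged."""
        proteins, psms, _ = random_instance(pyrandom, max_psms=15)
        scaled = [
            type(p)((p.spectrum_key[0], 1000 * r + p.spectrum_key[1], p.spectrum_key[2]),
                    p.peptide, p.qvalue)
            for r in range(c)
            for p in psms
        ]
        for scorer in (score_nsaf, score_dnsaf):
            base = scorer(inputs_for(proteins, psms)).scores
            rep = scorer(inputs_for(proteins, scaled)).scores
            assert set(base) == set(rep)
            for k in base:
                assert rep[k] == pytest.approx(base[k], abs=1e-12)

    @given(st.randoms(use_true_random=False))
    def test_order_invariance(self, pyrandom):
        proteins, psms, intensities = random_instance(pyrandom)
        shuffled_prots = list(proteins)
        shuffled_psms = list(psms)
        pyrandom.shuffle(shuffled_prots)
        pyrandom.shuffle(shuffled_psms)
        a = score_nsaf(inputs_for(proteins, psms)).scores
        b = score_nsaf(inputs_for(shuffled_prots, shuffled_psms)).scores
        assert a == b
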