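import numpy as np
import pandas as pd
import pytest

from helpers import random_dna
from nahrkit.io import load_example_genotypes
from nahrkit.junction import revcomp
from nahrkit.repeatgt import (PcrProduct, allele_frequencies, classify_allele,
                              duplication_length, find_tandem_repeats,
                              insilico_pcr, percent)
from nahrkit.simdata import SimConfig, make_allele_pair, make_genotypes

SUB = {"A": "C", "C": "G", "G": "T", "T": "A"}


def flanked_array(rng, unit_len, copies, flank=500):
    """A tandem array in random flanks whose boundary bases are forced to
    break the period, so recovered copy numbers are exact."""
    unit = random_dna(rng, unit_len)
    left = list(random_dna(rng, flank))
    right = list(random_dna(rng, flank))
    if left[-unit_len:] and left[-1] == unit[-1]:
        left[-1] = SUB[left[-1]]
    if right[0] == unit[0]:
        right[0] = SUB[right[0]]
    return "".join(left) + unit * copies + "".join(right), unit, flank


class TestFindTandemRepeats:
    @pytest.mark.parametrize("unit_len", [10, 61, 100])
    @pytest.mark.parametrize("copies", [2, 3, 4])
    def test_exact_arrays_recovered_exactly(self, rng, unit_len, copies):
        seq, unit, flank = flanked_array(rng, unit_len, copies)
        reps = find_tandem_repeats(seq)
        assert len(reps) == 1
        r = reps[0]
        assert r.unit_length == unit_len
        assert r.copy_number == float(copies)
        assert (r.region.start, r.region.end) == (flank,
                                                  flank + unit_len * copies)
        assert r.consensus_unit == unit
        assert r.percent_match == 100.0

    def test_four_exact_61mers_in_random_1kb_flanks(self, rng):
        seq, unit, flank = flanked_array(rng, 61, 4, flank=1000)
        (r,) = find_tandem_repeats(seq)
        assert (r.unit_length, r.copy_number) == (61, 4.0)

    def test_2_vs_4_copy_arrays_differ_by_122(self, rng):
        s2, _, _ = flanked_array(rng, 61, 2)
        s4, _, _ = flanked_array(rng, 61, 4)
        (r2,) = find_tandem_repeats(s2)
        (r4,) = find_tandem_repeats(s4)
        assert r4.region.width - r2.region.width == 122

    def test_random_sequence_has_no_arrays(self, rng):
        seq = random_dna(rng, 2000)
        assert find_tandem_repeats(seq, min_unit=20) == []

    def test_diverged_copies_still_found_above_identity_floor(self, rng):
        unit = random_dna(rng, 61)
        copies = []
        for k in range(4):
            u = list(unit)
            u[7 + 11 * k] = SUB[u[7 + 11 * k]]
            copies.append("".join(u))
        seq = random_dna(rng, 300) + "".join(copies) + random_dna(rng, 300)
        reps = find_tandem_repeats(seq)
        assert reps and reps[0].unit_length == 61
        assert 80.0 <= reps[0].percent_match < 100.0


class TestDuplicationLength:
    def test_2_vs_4_copies_of_61mer_gives_122(self, rng):
        base = random_dna(rng, 1000)
        a, b = make_allele_pair(SimConfig(seed=31), base)
        assert duplication_length(a, b) == 122

    def test_identical_alleles_give_zero(self, rng):
        a = random_dna(rng, 600)
        assert duplication_length(a, a) == 0

    def test_3_vs_4_copies_gives_61(self, rng):
        base = random_dna(rng, 1000)
        cfg = SimConfig(seed=31, copies_allele_A=3, copies_allele_B=4)
        a, b = make_allele_pair(cfg, base)
        assert duplication_length(a, b) == 61

    def test_unrelated_sequences_rejected(self, rng):
        with pytest.raises(ValueError, match="diverged"):
            duplication_length(random_dna(rng, 300), random_dna(rng, 300))


class TestInsilicoPcr:
    def test_product_length_is_substring_arithmetic(self, rng):
        template = random_dna(rng, 500)
        fwd = template[100:120]          # 1-based 101-120
        rev = revcomp(template[331:350])  # rev_end = 350
        (prod,) = insilico_pcr(template, fwd, rev)
        assert (prod.fwd_start, prod.rev_end, prod.length) == (101, 350, 250)
        # oracle: direct substring search
        assert template.find(fwd) + 1 == prod.fwd_start
        assert template.find(revcomp(rev)) + len(rev) == prod.rev_end

    def test_missing_reverse_site_yields_no_product(self, rng):
        template = random_dna(rng, 500)
        fwd = template[100:120]
        assert insilico_pcr(template, fwd, random_dna(rng, 20)) == []

    def test_allele_pair_products_differ_by_the_duplication(self, rng):
        base = random_dna(rng, 1000)
        a, b = make_allele_pair(SimConfig(seed=13), base)
        locus = len(base) // 2
        fwd = base[locus - 120: locus - 100]
        rev = revcomp(base[locus + 80: locus + 100])
        (pa,) = insilico_pcr(a, fwd, rev)
        (pb,) = insilico_pcr(b, fwd, rev)
        assert pb.length - pa.length == 122

    def test_single_mismatch_tolerance(self, rng):
        template = random_dna(rng, 300)
        fwd = list(template[50:70])
        fwd[5] = SUB[fwd[5]]
        fwd = "".join(fwd)
        rev = revcomp(template[200:220])
        assert insilico_pcr(template, fwd, rev) == []
        assert len(insilico_pcr(template, fwd, rev, max_mismatch=1)) == 1

    def test_short_primer_rejected(self, rng):
        with pytest.raises(ValueError, match="15"):
            insilico_pcr(random_dna(rng, 100), "ACGTACGT", "ACGTACGTACGTACGT")


class TestClassifyAllele:
    def _prod(self, length):
        return PcrProduct("t", 1, length, length)

    def test_326_band_is_allele_A(self):
        assert classify_allele([self._prod(326)]) == "A"

    def test_446_band_is_allele_B(self):
        assert classify_allele([self._prod(446)]) == "B"

    def test_both_bands_call_heterozygote(self):
        assert classify_allele([self._prod(326), self._prod(446)]) == "A/B"

    def test_off_size_band_unknown(self):
        assert classify_allele([self._prod(390)]) == "unknown"

    def test_tolerance_window(self):
        assert classify_allele([self._prod(330)]) == "A"
        assert classify_allele([self._prod(332)]) == "unknown"

    def test_inseparable_expected_sizes_rejected(self):
        with pytest.raises(ValueError, match="separable"):
            classify_allele([self._prod(326)], expected={326: "A", 330: "B"})


class TestAlleleFrequencies:
    def test_coriell_panel_reproduces_printed_percentages(self):
        summary = allele_frequencies(load_example_genotypes("coriell"))
        assert summary.pooled_counts == {"A": 37, "B": 161}
        assert summary.n_alleles == 198
        assert summary.pooled_percent("A") == 18.7
        assert summary.pooled_percent("B") == 81.3
        assert "skipped" in summary.note  # single population

    def test_hgdp_panel_reproduces_printed_percentages(self):
        summary = allele_frequencies(load_example_genotypes("hgdp"), seed=0)
        assert summary.pooled_counts == {"A": 26, "B": 98}
        assert summary.pooled_percent("A") == 21.0
        assert summary.pooled_percent("B") == 79.0
        assert summary.method == "monte_carlo"  # sparse expected counts
        assert summary.p_value > 0.05  # frequencies homogeneous

    def test_percentages_sum_to_100_after_rounding(self):
        for seed in range(10):
            t = make_genotypes([("x", 37, 0.23), ("y", 15, 0.31)], seed=seed)
            s = allele_frequencies(t, n_permutations=200, seed=seed)
            assert sum(s.pooled_percent(lab) for lab in ("A", "B")) \
                == pytest.approx(100.0, abs=0.1)

    def test_perfectly_homogeneous_counts_give_chi2_zero(self):
        rows = []
        for pop in ("p1", "p2"):
            for i in range(10):
                rows.append((pop, f"{pop}_{i}", "A", "B"))
        t = pd.DataFrame(rows, columns=["population", "individual",
                                        "allele1", "allele2"])
        s = allele_frequencies(t)
        assert s.chi_square == pytest.approx(0.0)
        assert s.p_value == pytest.approx(1.0)
        assert s.df == 1

    def test_montecarlo_agrees_with_asymptotic_on_large_tables(self):
        t = make_genotypes([("a", 300, 0.3), ("b", 300, 0.35)], seed=5)
        s_asym = allele_frequencies(t)
        assert s_asym.method == "asymptotic"
        from nahrkit.repeatgt import _monte_carlo_p, _chi2_stat
        counts = np.array([[s_asym.per_population.loc[i, "count_A"],
                            s_asym.per_population.loc[i, "count_B"]]
                           for i in range(2)])
        p_mc = _monte_carlo_p(counts, 20_000, seed=5)
        assert p_mc == pytest.approx(s_asym.p_value, abs=0.02)

    def test_duplicate_individuals_rejected(self):
        t = pd.DataFrame([("p", "i1", "A", "B"), ("p", "i1", "B", "B")],
                         columns=["population", "individual",
                                  "allele1", "allele2"])
        with pytest.raises(ValueError, match="duplicate"):
            allele_frequencies(t)

    def test_stray_allele_labels_rejected(self):
        t = pd.DataFrame([("p", "i1", "A", "C")],
                         columns=["population", "individual",
                                  "allele1", "allele2"])
        with pytest.raises(ValueError, match="label"):
            allele_frequencies(t)


class TestPercentRendering:
    def test_half_up_rounding_matches_printed_convention(self):
        assert percent(37 / 198) == 18.7
        assert percent(161 / 198) == 81.3
        assert percent(26 / 124) == 21.0
        assert percent(98 / 124) == 79.0
        assert percent(0.1855) == 18.6  # floor cases still round half-up
        assert percent(0.18650000) == 18.7
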