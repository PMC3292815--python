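import numpy as np
import pytest
from hypothesis import given, strategies as st

from helpers import brute_force_cut
from nahrkit.genome import (HG18_CHROM_LENGTHS, JUNCTION_BREAKPOINTS,
                            GenomeInterval, parse_interval)
from nahrkit.junction import (best_cut, derivative_segment_sizes,
                              interval_midpoint_distance, resolve_junction,
                              revcomp)
from nahrkit.psv import call_psvs
from nahrkit.simdata import (RepeatPair, SimConfig, SimTruth, make_junction,
                             make_paralogs)


class TestBestCut:
    def test_clean_single_crossover(self):
        cut, disc = best_cut(["18", "18", "4", "4", "4"])
        assert (cut, disc) == (2, 0)

    def test_one_discordant_marker_is_conversion_signature(self):
        # exhaustive scan gives a unique minimum of 1 at cut 2
        states = ["18", "18", "4", "4", "18", "4", "4", "4"]
        cut, disc = best_cut(states)
        assert (cut, disc) == brute_force_cut(states) == (2, 1)

    def test_all_one_state_cuts_at_an_end(self):
        assert best_cut(["4"] * 5) == (0, 0)
        assert best_cut(["18"] * 5) == (5, 0)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_scan(self, seed):
        r = np.random.default_rng(seed)
        states = list(r.choice(["18", "4"], size=int(r.integers(1, 20))))
        assert best_cut(states) == brute_force_cut(states)


class TestResolveJunction:
    def test_recovers_true_crossover_interval(self, small_pair):
        junction, truth = make_junction(small_pair, "random")
        call = resolve_junction(junction, small_pair.ladder, small_pair)
        assert call.status == "resolved"
        assert call.discordance == 0 and not call.conversion_flag
        assert call.interval_18 == truth.interval_18
        assert call.interval_4 == truth.interval_4
        assert call.interval_18.contains_boundary(truth.crossover_pos_18)
        assert call.interval_4.contains_boundary(truth.crossover_pos_4)

    def test_resolves_junction_across_an_indel_polymorphism(self):
        pair = make_paralogs(SimConfig(ancestor_length=1500, flank_length=300,
                                       indel_rate=0.003, seed=17))
        assert any(p.kind == "indel" for p in pair.ladder)
        junction, truth = make_junction(pair, "random")
        call = resolve_junction(junction, pair.ladder, pair)
        assert call.status == "resolved"
        assert call.interval_18.contains_boundary(truth.crossover_pos_18)

    def test_zero_divergence_junction_is_unresolvable(self):
        pair = make_paralogs(SimConfig(ancestor_length=400, flank_length=100,
                                       target_divergence=0.0, indel_rate=0.0,
                                       seed=1))
        junction, _ = make_junction(pair, 200)
        call = resolve_junction(junction, pair.ladder, pair)
        assert call.status == "unresolvable"
        assert "no informative markers" in call.note

    def test_non_recombinant_sequence_flagged(self, small_pair):
        # the intact 18 haplotype matches every marker's 18 allele
        intact = small_pair.flank_18 + small_pair.paralog_18 \
            + small_pair.flank_4
        call = resolve_junction(intact, small_pair.ladder, small_pair)
        assert call.status == "non_recombinant"
        assert "18" in call.note

    def test_invariant_under_joint_reverse_complement(self, small_pair):
        """Reverse-complementing the whole system reads the derivative
        chromosome from its other end, so the paralog previously distal
        becomes proximal; the resolved interval mirrors exactly."""
        junction, truth = make_junction(small_pair, "random")
        call = resolve_junction(junction, small_pair.ladder, small_pair)

        rc_pair = RepeatPair(
            paralog_18=revcomp(small_pair.paralog_4),   # now proximal
            paralog_4=revcomp(small_pair.paralog_18),
            flank_18=revcomp(small_pair.flank_4),
            flank_4=revcomp(small_pair.flank_18),
            truth=SimTruth(seed=-1))
        rc_ladder = call_psvs(rc_pair.alignment)
        rc_call = resolve_junction(revcomp(junction), rc_ladder, rc_pair)
        assert rc_call.status == "resolved"
        assert rc_call.orientation_ok
        assert rc_call.discordance == call.discordance == 0
        # the rc proximal side is the original 4 side, mirrored
        assert rc_call.interval_18.width == call.interval_4.width
        n4 = len(small_pair.paralog_4)
        assert rc_call.interval_18.start == n4 - call.interval_4.end
        assert rc_call.interval_18.end == n4 - call.interval_4.start

    def test_flipped_junction_detected_and_resolved(self, small_pair):
        junction, truth = make_junction(small_pair, "random")
        call = resolve_junction(revcomp(junction), small_pair.ladder,
                                small_pair)
        assert not call.orientation_ok
        assert call.status == "resolved"
        assert call.interval_18.contains_boundary(truth.crossover_pos_18)


class TestMidpointDistance:
    def test_published_chr18_junctions_are_150_5_bp_apart(self):
        a = parse_interval(JUNCTION_BREAKPOINTS["18q-146C"]["chr18"])
        b = parse_interval(JUNCTION_BREAKPOINTS["18q-82C"]["chr18"])
        assert interval_midpoint_distance(a, b) == pytest.approx(150.5)

    def test_published_chr4_junctions_are_150_5_bp_apart(self):
        a = parse_interval(JUNCTION_BREAKPOINTS["18q-146C"]["chr4"])
        b = parse_interval(JUNCTION_BREAKPOINTS["18q-82C"]["chr4"])
        assert interval_midpoint_distance(a, b) == pytest.approx(150.5)

    def test_identical_intervals_distance_zero(self):
        iv = GenomeInterval("chr1", 100, 200)
        assert interval_midpoint_distance(iv, iv) == 0.0

    def test_chromosome_mismatch_rejected(self):
        with pytest.raises(ValueError, match="chromosome"):
            interval_midpoint_distance(GenomeInterval("chr1", 0, 10),
                                       GenomeInterval("chr2", 0, 10))


class TestDerivativeSegmentSizes:
    def test_toy_arithmetic(self):
        seg = derivative_segment_sizes(GenomeInterval("chrT", 600, 660),
                                       chrom_length=1000)
        assert seg.bp == 400  # 1000 - 601 + 1

    def test_distal_18q_loss_rounds_to_6_97_mb(self):
        for carrier in ("18q-146C", "18q-82C"):
            iv = parse_interval(JUNCTION_BREAKPOINTS[carrier]["chr18"])
            seg = derivative_segment_sizes(iv, arm="distal_loss")
            assert seg.mb == 6.97

    def test_distal_4q_gain_rounds_to_7_30_mb(self):
        for carrier in ("18q-146C", "18q-82C"):
            iv = parse_interval(JUNCTION_BREAKPOINTS[carrier]["chr4"])
            seg = derivative_segment_sizes(iv, arm="distal_gain")
            assert seg.mb == 7.30

    def test_either_interval_edge_gives_same_mb_for_these_loci(self):
        for carrier, chrom in (("18q-146C", "chr18"), ("18q-82C", "chr18"),
                               ("18q-146C", "chr4"), ("18q-82C", "chr4")):
            iv = parse_interval(JUNCTION_BREAKPOINTS[carrier][chrom])
            length = HG18_CHROM_LENGTHS[chrom]
            from_start = derivative_segment_sizes(iv, length).mb
            edge = GenomeInterval(chrom, iv.end - 1, iv.end)
            from_end = derivative_segment_sizes(edge, length).mb
            assert from_start == from_end

    def test_interval_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            derivative_segment_sizes(GenomeInterval("chrT", 900, 1100),
                                     chrom_length=1000)


class TestGenomeInterval:
    def test_published_coordinate_string_round_trips(self):
        iv = GenomeInterval("chr18", 69144349, 69144410)
        assert iv.render() == "chr18:69144350-69144410"
        assert parse_interval(iv.render()) == iv

    def test_minimal_one_bp_interval(self):
        iv = parse_interval("chr1:1-1")
        assert (iv.start, iv.end, iv.width) == (0, 1, 1)

    def test_zero_width_interval_marks_exact_breakpoint(self):
        iv = GenomeInterval("chr1", 100, 100)
        assert iv.width == 0
        assert parse_interval(iv.render()) == iv

    @given(start=st.integers(0, 10**9), width=st.integers(0, 10**6),
           chrom=st.sampled_from(["chr1", "chr18", "chr4", "scaffold_7"]))
    def test_render_parse_identity(self, start, width, chrom):
        iv = GenomeInterval(chrom, start, start + width)
        assert parse_interval(iv.render()) == iv

    def test_malformed_strings_rejected(self):
        for bad in ("chr1:5-2", "chr1:x-10", "chr1", "chr1:0-10"):
            with pytest.raises(ValueError):
                parse_interval(bad)
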