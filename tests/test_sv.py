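"""SV filtering, clonality, geometry, and breakpoint microhomology."""

import itertools

import numpy as np
import pytest

from conftest import oracle_microhomology
from glioprog.simulate import SimulationConfig, simulate_cohort, simulate_genome
from glioprog.sv import (
    SVJunction,
    breakpoints_match,
    clonality,
    filter_junctions,
    geometry,
    microhomology,
    repair_bin,
    sv_summary,
)


def junction(**kwargs):
    defaults = dict(
        sample="s1",
        chrom_a="chr1",
        pos_a=10_000,
        orient_a="+",
        chrom_b="chr2",
        pos_b=20_000,
        orient_b="-",
        junction_reads=10,
        total_depth_junction=50,
        span_reads_a=10,
        span_reads_b=10,
        total_depth_a=50,
        total_depth_b=50,
    )
    defaults.update(kwargs)
    return SVJunction(**defaults)


class TestFilterJunctions:
    def test_low_support_removed(self):
        kept = filter_junctions([junction(junction_reads=4)], n_cohort_samples=10)
        assert kept == []

    def test_recurrent_artifact_removed_strictly_over_cap(self):
        shared = [junction(sample=f"s{i}", pos_a=10_000 + i) for i in range(4)]
        kept = filter_junctions(shared, n_cohort_samples=10)
        assert kept == []  # 4/10 = 40% > 30%
        kept = filter_junctions(shared[:3], n_cohort_samples=10)
        assert len(kept) == 3  # 30% is not "over 30%"

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            filter_junctions([], n_cohort_samples=0)

    def test_raising_min_support_never_grows_the_set(self, rng):
        junctions = [
            junction(sample=f"s{i % 3}", pos_a=int(p), junction_reads=int(r))
            for i, (p, r) in enumerate(
                zip(rng.integers(0, 40_000, 30), rng.integers(0, 30, 30))
            )
        ]
        sizes = [
            len(filter_junctions(junctions, 10, min_support=m)) for m in range(0, 20)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestClonality:
    def test_junction_af_at_threshold_is_clonal(self):
        call = clonality(junction(junction_reads=10, total_depth_junction=50), [])
        assert (call.label, call.basis) == ("clonal", "junction_af")

    def test_span_af_requires_both_sides(self):
        j = junction(
            junction_reads=2,
            total_depth_junction=40,
            span_reads_a=10,
            total_depth_a=40,  # 0.25
            span_reads_b=9,
            total_depth_b=48,  # 0.1875
        )
        assert clonality(j, []).label == "subclonal"
        j2 = junction(
            junction_reads=2,
            total_depth_junction=40,
            span_reads_a=10,
            total_depth_a=40,
            span_reads_b=10,
            total_depth_b=48,
        )
        call = clonality(j2, [])
        assert (call.label, call.basis) == ("clonal", "span_af")

    def test_matched_breakpoint_rescues_low_af(self):
        j = junction(junction_reads=2, span_reads_a=2, span_reads_b=2)
        matched = junction(sample="s2", pos_a=10_150, pos_b=19_900)
        call = clonality(j, [matched])
        assert (call.label, call.basis, call.sharing) == (
            "clonal",
            "matched_breakpoint",
            "shared",
        )

    def test_matching_requires_orientation_compatibility(self):
        j = junction(junction_reads=2, span_reads_a=2, span_reads_b=2)
        flipped = junction(sample="s2", orient_a="-")
        call = clonality(j, [flipped])
        assert call.sharing == "private"

    def test_sharing_symmetry(self):
        j1 = junction(sample="s1")
        j2 = junction(sample="s2", pos_a=10_100, pos_b=20_100)
        c1 = clonality(j1, [j2])
        c2 = clonality(j2, [j1])
        assert c1.sharing == c2.sharing == "shared"
        assert c1.label == c2.label == "clonal"

    def test_raising_threshold_never_grows_clonal_set(self, rng):
        junctions = [
            junction(junction_reads=int(r), span_reads_a=0, span_reads_b=0)
            for r in rng.integers(0, 50, 40)
        ]
        counts = [
            sum(clonality(j, [], af_threshold=t).label == "clonal" for j in junctions)
            for t in (0.05, 0.1, 0.2, 0.4, 0.8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_all_zero_depth_without_match_rejected(self):
        j = junction(
            junction_reads=0,
            total_depth_junction=0,
            span_reads_a=0,
            span_reads_b=0,
            total_depth_a=0,
            total_depth_b=0,
        )
        with pytest.raises(ValueError):
            clonality(j, [])


class TestGeometry:
    @pytest.mark.parametrize(
        "chrom_b,pos_b,expected",
        [
            ("chr2", 100, "interchromosomal"),
            ("chr1", 1_999_999, "focal"),
            ("chr1", 2_000_000, "intrachromosomal_large"),
        ],
    )
    def test_classes_and_boundaries(self, chrom_b, pos_b, expected):
        j = junction(pos_a=0, chrom_b=chrom_b, pos_b=pos_b)
        assert geometry(j) == expected


class TestRepairBin:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (0, "none_or_short"),
            (2, "none_or_short"),
            (4, "none_or_short"),
            (5, "mmej_only"),
            (10, "mmej_only"),
            (18, "mmej_only"),
            (19, "long"),
            (20, "long"),
        ],
    )
    def test_bins(self, length, expected):
        assert repair_bin(length) == expected

    def test_length_one_violates_invariant(self):
        with pytest.raises(ValueError):
            repair_bin(1)


class TestMicrohomology:
    def test_planted_lengths_recovered_exactly(self, small_cohort):
        for name, events in small_cohort.truth.items():
            by_name = {j.name: j for j in small_cohort.samples[name].junctions}
            for ev in events:
                if ev.kind != "sv_junction":
                    continue
                mh = microhomology(by_name[ev.uid], small_cohort.genome)
                assert mh.length == ev.payload["microhomology"], ev.uid
                assert len(mh.sequence) == mh.length

    def test_equals_string_oracle_on_random_junctions(self, rng):
        """Random (unplanted) junctions across all four orientation pairs
        agree with the exhaustive string-comparison oracle."""
        genome = simulate_genome(SimulationConfig(seed=44, chrom_length=120_000))
        orient_pairs = list(itertools.product("+-", repeat=2))
        for i in range(400):
            oa, ob = orient_pairs[i % 4]
            j = junction(
                pos_a=int(rng.integers(100, 119_900)),
                orient_a=oa,
                chrom_b=["chr1", "chr2"][int(rng.integers(2))],
                pos_b=int(rng.integers(100, 119_900)),
                orient_b=ob,
            )
            mh = microhomology(j, genome)
            assert mh.length == oracle_microhomology(j, genome), j
            assert mh.length == 0 or 2 <= mh.length <= 20

    def test_censoring_at_max_length(self, toy_genome):
        # make a 25 bp perfect homology; the search stops and flags at 20
        seq = toy_genome.sequence("chr1", 976, 1001)
        toy_genome.replace("chr2", 1975, seq)
        j = junction(pos_a=1000, orient_a="+", chrom_b="chr2", pos_b=2000, orient_b="-")
        mh = microhomology(j, toy_genome)
        assert mh.length == 20
        assert mh.censored_at_max

    def test_contig_edge_reports_zero_with_flag(self, toy_genome):
        j = junction(pos_a=0, orient_a="+", chrom_b="chr2", pos_b=2000, orient_b="-")
        mh = microhomology(j, toy_genome)
        # pos 0 '+' has a single retained base: at most length-1 runs, never >=2
        assert mh.length in (0,)

    def test_sequence_is_fused_seam_5prime_to_3prime(self, toy_genome):
        toy_genome.replace("chr1", 995, "ACGTAC")  # A tail ends ...ACGTAC at 1000
        toy_genome.replace("chr2", 1994, "ACGTAC")  # B flank before 2000
        toy_genome.replace("chr1", 994, "T")
        toy_genome.replace("chr2", 1993, "G")
        j = junction(pos_a=1000, orient_a="+", chrom_b="chr2", pos_b=2000, orient_b="-")
        mh = microhomology(j, toy_genome)
        assert mh.length == 6
        assert mh.sequence == "ACGTAC"


class TestSummaryAndRecovery:
    def test_empty_sample_summary(self):
        summary = sv_summary([], [])
        assert summary["n_total"] == 0
        assert summary["focal_fraction"] == 0.0

    def test_counts_internally_consistent(self, small_cohort):
        genome = small_cohort.genome
        for patient, (pre_name, post_name) in small_cohort.pairs.items():
            own = small_cohort.samples[post_name].junctions
            other = small_cohort.samples[pre_name].junctions
            calls = [clonality(j, other) for j in own]
            homologies = [microhomology(j, genome) for j in own]
            summary = sv_summary(own, calls, homologies)
            assert summary["n_shared"] + summary["n_private"] == summary["n_total"]
            assert 0 <= summary["focal_fraction"] <= 1
            assert sum(summary["microhomology_histogram"].values()) == summary["n_total"]

    def test_noiseless_labels_match_truth_exactly(self, noiseless_cohort):
        """At noise 0, clonality and sharing recover the planted labels."""
        for patient, (pre_name, post_name) in noiseless_cohort.pairs.items():
            for own_name, other_name in (
                (pre_name, post_name),
                (post_name, pre_name),
            ):
                own = noiseless_cohort.samples[own_name].junctions
                other = noiseless_cohort.samples[other_name].junctions
                truth = {
                    ev.uid: ev
                    for ev in noiseless_cohort.truth[own_name]
                    if ev.kind == "sv_junction"
                }
                other_uids = {
                    ev.uid
                    for ev in noiseless_cohort.truth[other_name]
                    if ev.kind == "sv_junction"
                }
                for j in own:
                    call = clonality(j, other)
                    ev = truth[j.name]
                    expected_label = (
                        "clonal" if ev.clone_fraction >= 0.2 or j.name in other_uids
                        else "subclonal"
                    )
                    assert call.label == expected_label, j.name
                    expected_sharing = "shared" if j.name in other_uids else "private"
                    assert call.sharing == expected_sharing, j.name

    def test_clonal_recall_with_noise_at_half_clone_fraction(self):
        """Junction support sampled at clone fraction 0.5 and depth 50
        still yields near-perfect clonal recall at the 0.2 threshold."""
        cohort = simulate_cohort(
            SimulationConfig(
                seed=77,
                n_patients=3,
                subclonal_fraction=0.5,
                n_clonal_svs=0,
                n_subclonal_svs=25,
                sv_depth=50.0,
            )
        )
        total = recalled = 0
        for pre_name, post_name in cohort.pairs.values():
            for name in (pre_name, post_name):
                for j in cohort.samples[name].junctions:
                    call = clonality(j, [])
                    total += 1
                    recalled += call.label == "clonal"
        assert total >= 100
        assert recalled / total >= 0.95
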