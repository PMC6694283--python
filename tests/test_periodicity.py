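"""Metagene profile, frame proportions and coefficient of variation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ribothrough as rt
from ribothrough.periodicity import DEFAULT_PERIODIC_LENGTHS, EmptyRegion
from conftest import centered_footprint


class TestMetageneProfile:
    def test_window_spans_87_offsets(self):
        profile = rt.metagene_start_profile([], {"tx": 100})
        assert profile.shape[1] == 87
        assert profile.columns[0] == -24 and profile.columns[-1] == 62

    def test_empty_input_is_all_zero(self):
        profile = rt.metagene_start_profile([], {"tx": 100})
        assert (profile.values == 0).all()

    def test_p_sites_at_start_codon_fill_single_column(self):
        fps = [centered_footprint(100, "tx", read_id=f"r{i}") for i in range(9)]
        profile = rt.metagene_start_profile(fps, {"tx": 100})
        nonzero = profile.loc[29]
        assert nonzero[0] == pytest.approx(math.log(10))
        assert (profile.drop(columns=0).values == 0).all()

    def test_pooling_across_transcripts(self):
        fps = [centered_footprint(60, "a"), centered_footprint(203, "b")]
        profile = rt.metagene_start_profile(fps, {"a": 57, "b": 200})
        assert profile.loc[29, 3] == pytest.approx(math.log(3))


class TestFrameProportions:
    def test_pure_frame_zero(self, thousand_nt_annotation):
        rmap = rt.partition_regions(thousand_nt_annotation)
        fps = [centered_footprint(100 + off) for off in (15, 18, 21)]
        prof = rt.frame_proportions(fps, rmap, "cds", 100)
        assert prof.proportions == (1.0, 0.0, 0.0)
        assert prof.cv == pytest.approx(math.sqrt(3))

    def test_uniform_frames(self, thousand_nt_annotation):
        rmap = rt.partition_regions(thousand_nt_annotation)
        fps = [centered_footprint(100 + off) for off in (15, 16, 17)]
        prof = rt.frame_proportions(fps, rmap, "cds", 100)
        assert prof.proportions == (1 / 3, 1 / 3, 1 / 3)
        assert prof.cv == pytest.approx(0.0)

    def test_two_to_one_split(self, thousand_nt_annotation):
        rmap = rt.partition_regions(thousand_nt_annotation)
        fps = [centered_footprint(100 + off) for off in (15, 18, 16)]
        prof = rt.frame_proportions(fps, rmap, "cds", 100)
        assert prof.proportions == pytest.approx((2 / 3, 1 / 3, 0.0))

    def test_exclusion_zones_and_length_filter_respected(self, thousand_nt_annotation):
        rmap = rt.partition_regions(thousand_nt_annotation)
        inside = centered_footprint(115, length=29)        # first counting position
        excluded = centered_footprint(105, length=29)      # within start-codon zone
        wrong_len = centered_footprint(118, length=33)
        prof = rt.frame_proportions(
            [inside, excluded, wrong_len], rmap, "cds", 100, lengths={27, 28, 29}
        )
        assert prof.n == 1

    def test_empty_region_raises(self, thousand_nt_annotation):
        rmap = rt.partition_regions(thousand_nt_annotation)
        with pytest.raises(EmptyRegion):
            rt.frame_proportions([], rmap, "utr3_rest", 100)


class TestCoefficientOfVariation:
    @pytest.mark.parametrize(
        "props, expected",
        [
            ((1 / 3, 1 / 3, 1 / 3), 0.0),
            ((1.0, 0.0, 0.0), math.sqrt(3)),
            ((0.5, 0.3, 0.2), 0.45825756949558405),
        ],
    )
    def test_closed_forms(self, props, expected):
        assert rt.coefficient_of_variation(props) == pytest.approx(expected, abs=1e-12)

    def test_population_convention_differs_by_constant(self):
        props = (0.5, 0.3, 0.2)
        ratio = rt.coefficient_of_variation(props, ddof=1) / rt.coefficient_of_variation(props, ddof=0)
        assert ratio == pytest.approx(math.sqrt(3 / 2))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.permutations([0.61, 0.27, 0.12]))
    def test_permutation_invariant(self, props):
        assert rt.coefficient_of_variation(props) == pytest.approx(
            rt.coefficient_of_variation((0.61, 0.27, 0.12))
        )

    def test_monotone_in_frame_bias(self):
        cvs = [
            rt.coefficient_of_variation((p0, (1 - p0) / 2, (1 - p0) / 2))
            for p0 in np.linspace(1 / 3, 1.0, 12)
        ]
        assert all(b > a for a, b in zip(cvs, cvs[1:]))


class TestSelectPeriodicLengths:
    def test_default_fixed_set(self):
        assert rt.select_periodic_lengths() == {27, 28, 29}
        assert DEFAULT_PERIODIC_LENGTHS == frozenset({27, 28, 29})

    def test_auto_detects_biased_length(self, thousand_nt_annotation):
        ann = thousand_nt_annotation
        anns = {ann.transcript_id: ann}
        # length 28 reads all frame 0; length 27 reads spread evenly
        biased = [centered_footprint(100 + 15 + 3 * i, length=28, read_id=f"b{i}") for i in range(30)]
        uniform = [centered_footprint(100 + 15 + i, length=27, read_id=f"u{i}") for i in range(30)]
        assert rt.select_periodic_lengths(biased + uniform, anns, auto=True) == {28}

    def test_auto_on_uniform_data_warns_and_returns_empty(self, thousand_nt_annotation):
        ann = thousand_nt_annotation
        uniform = [centered_footprint(100 + 15 + i, length=27, read_id=f"u{i}") for i in range(30)]
        with pytest.warns(UserWarning):
            selected = rt.select_periodic_lengths(
                uniform, {ann.transcript_id: ann}, auto=True
            )
        assert selected == set()


class TestFrameStatisticsOnSimulatedData:
    def test_cds_frame0_converges_to_simulated_bias(self, mapped):
        ann, footprints, _, _ = mapped
        rmap = rt.partition_regions(ann)
        prof = rt.frame_proportions(footprints, rmap, "cds", ann.cds_start)
        # binomial 3-sigma band around p0 = 0.6 at n ~ 19,000
        assert prof.f0 == pytest.approx(0.6, abs=3 * math.sqrt(0.6 * 0.4 / prof.n))

    def test_riboseq_like_cv_pattern_across_regions(self, locus):
        spec, ann = locus
        reads_spec = rt.SimSpec(seed=23, n_reads=40_000)
        _, truth = rt.simulate_footprints(ann, reads_spec)
        fps = rt.true_footprints(ann, truth)
        rmap = rt.partition_regions(ann)
        table = rt.frame_table(fps, ann, rmap).set_index("region")
        # translated regions frame-biased, distal 3'UTR near-uniform
        assert table.loc["cds", "cv"] > 0.4
        assert table.loc["isr", "cv"] > 0.3
        assert table.loc["utr3_rest", "cv"] < 0.25
        assert table.loc["cds", "cv"] > 2 * table.loc["utr3_rest", "cv"]

    def test_rnaseq_like_simulation_gives_low_cv_everywhere(self, locus):
        _, ann = locus
        spec = rt.SimSpec(seed=29, n_reads=40_000, frame_probs=(1 / 3, 1 / 3, 1 / 3))
        _, truth = rt.simulate_footprints(ann, spec)
        fps = rt.true_footprints(ann, truth)
        table = rt.frame_table(fps, ann, rt.partition_regions(ann)).set_index("region")
        assert (table["cv"].dropna() < 0.25).all()
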