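"""The locus simulator: fragment maps, contact model, counts, reads, alleles."""

from dataclasses import replace

import numpy as np
import pytest

from fourc.digestion import annotate_secondary, digest
from fourc.intervals import GenomicInterval
from fourc.profile import ViewpointSpec, count_per_fragment, demultiplex
from fourc.rearrangement import RearrangementEvent
from fourc.simulate import (
    SyntheticLocusSpec,
    expected_intensity,
    make_truth,
    read_position,
    simulate_allele,
    simulate_counts,
    simulate_fragment_map,
    simulate_reads,
)


class TestFragmentMap:
    def test_same_seed_identical_maps(self, default_spec):
        m1, _ = simulate_fragment_map(default_spec)
        m2, _ = simulate_fragment_map(default_spec)
        assert np.array_equal(m1.starts("chrS"), m2.starts("chrS"))

    def test_mean_equal_to_length_gives_one_fragment(self, default_spec):
        spec = replace(default_spec, mean_fragment=default_spec.length)
        fmap, _ = simulate_fragment_map(spec)
        assert fmap.n_fragments("chrS") == 1

    def test_fragment_count_near_expectation(self, default_spec):
        fmap, _ = simulate_fragment_map(default_spec)
        n = fmap.n_fragments("chrS")
        assert 250 <= n <= 420  # 1 Mb / 3 kb mean

    def test_realized_sequence_digests_back_to_the_map(self, default_spec):
        spec = replace(default_spec, length=100_000, seed=2,
                       outer_left=20_000, outer_right=90_000,
                       tz=GenomicInterval("chrS", 50_000, 60_000))
        fmap, seq = simulate_fragment_map(spec, with_sequence=True)
        redig = digest(seq, "CATG", chrom="chrS")
        assert np.array_equal(redig.starts("chrS"), fmap.starts("chrS"))
        annotate_secondary(redig, {"chrS": seq}, "GATC")
        assert np.array_equal(redig.secondary("chrS"), fmap.secondary("chrS"))


class TestExpectedIntensity:
    def test_zero_distance_same_domain_is_beta(self, default_spec):
        spec = replace(default_spec, peaks=())
        vp = spec.viewpoints[0]
        mu = expected_intensity(spec, vp, np.array([vp.position]))
        assert mu[0] == pytest.approx(spec.beta)

    def test_symmetry_within_domain(self, default_spec):
        spec = replace(default_spec, peaks=())
        vp = spec.viewpoints[0]  # at 320 kb, domain A spans 140-480 kb around it
        mu = expected_intensity(spec, vp, np.array([vp.position - 50_000, vp.position + 50_000]))
        assert mu[0] == pytest.approx(mu[1])

    def test_cross_domain_plug_in_value(self, default_spec):
        spec = replace(default_spec, peaks=())
        vp = spec.viewpoints[0]
        mid = vp.position + 250_000  # 570 kb: domain B, 250 kb away
        mu = expected_intensity(spec, vp, np.array([mid]))
        assert mu[0] == pytest.approx(spec.gamma / 251)

    def test_monotone_decay_within_domain(self, default_spec):
        spec = replace(default_spec, peaks=())
        vp = spec.viewpoints[0]
        mids = np.arange(vp.position, 475_000, 1_000)
        mu = expected_intensity(spec, vp, mids)
        assert np.all(np.diff(mu) < 0)

    def test_tz_contacts_both_sides(self, default_spec):
        """A viewpoint inside the TZ sees elevated contacts toward both domains."""
        spec = replace(default_spec, peaks=())
        tz_vp = ViewpointSpec("tzvp", "chrS", 490_000, "GGG", "heart")
        mids = np.array([300_000, 700_000])  # deep in A and in B
        mu_tz = expected_intensity(spec, tz_vp, mids)
        mu_a = expected_intensity(spec, spec.viewpoints[0], np.array([700_000]))
        # TZ viewpoint contacts domain B far more than the A viewpoint does at
        # comparable separation, and contacts both sides above gamma decay
        d = np.abs(mids - 490_000) / 1000
        assert np.all(mu_tz > spec.gamma * (1 + d) ** -1)

    def test_tissue_specific_peak(self, default_spec):
        vp_heart = default_spec.viewpoints[1]
        vp_brain = replace(vp_heart, tissue="brain")
        peak_pos = default_spec.peaks[0].position
        mu_h = expected_intensity(default_spec, vp_heart, np.array([peak_pos]))
        mu_b = expected_intensity(default_spec, vp_brain, np.array([peak_pos]))
        assert mu_h[0] == pytest.approx(mu_b[0] * (1 + default_spec.peaks[0].amplitude))


class TestCounts:
    def test_fixed_seed_reproducible(self, default_spec):
        fmap, _ = simulate_fragment_map(default_spec)
        c1, _ = simulate_counts(default_spec, default_spec.viewpoints[0], fmap)
        c2, _ = simulate_counts(default_spec, default_spec.viewpoints[0], fmap)
        assert np.array_equal(c1, c2)

    def test_total_equals_library_size(self, default_spec):
        fmap, _ = simulate_fragment_map(default_spec)
        counts, _ = simulate_counts(default_spec, default_spec.viewpoints[0], fmap)
        assert counts.sum() == default_spec.library_size

    def test_low_dispersion_fractions_converge_to_model(self, default_spec):
        spec = replace(default_spec, phi=0.0, library_size=1_000_000)
        fmap, _ = simulate_fragment_map(spec)
        counts, mu = simulate_counts(spec, spec.viewpoints[0], fmap)
        assert np.max(np.abs(counts / counts.sum() - mu / mu.sum())) < 0.01

    def test_own_domain_signal_exceeds_cross_domain(self, default_spec):
        fmap, _ = simulate_fragment_map(default_spec)
        mids = fmap.midpoints("chrS")
        counts, _ = simulate_counts(default_spec, default_spec.viewpoints[1], fmap)
        # matched 150-200 kb band on each side of vpB (620 kb): the right
        # side stays in domain B, the left side has crossed the TZ
        own = counts[(mids > 770_000) & (mids < 820_000)].mean()
        cross = counts[(mids > 420_000) & (mids < 470_000)].mean()
        assert own > cross


class TestReads:
    def _small(self, default_spec):
        return replace(default_spec, library_size=5_000, length=200_000,
                       outer_left=30_000, outer_right=170_000,
                       tz=GenomicInterval("chrS", 95_000, 105_000),
                       peaks=(), viewpoints=(
                           ViewpointSpec("vpA", "chrS", 60_000, "ACGT", "heart"),
                           ViewpointSpec("vpB", "chrS", 140_000, "TGCAC", "heart"),
                       ))

    def test_zero_counts_empty_output(self, default_spec):
        spec = self._small(default_spec)
        fmap, _ = simulate_fragment_map(spec)
        reads, _ = simulate_reads(spec, {"vpA": np.zeros(fmap.n_fragments("chrS"), dtype=int)}, fmap)
        assert reads == []

    def test_read_length_constant_and_tag_planted(self, default_spec):
        spec = self._small(default_spec)
        fmap, _ = simulate_fragment_map(spec)
        counts = {vp.name: simulate_counts(spec, vp, fmap)[0] for vp in spec.viewpoints}
        reads, _ = simulate_reads(spec, counts, fmap, read_length=36)
        assert {len(seq) for _, seq, _ in reads} == {36}
        tags = {vp.tag for vp in spec.viewpoints}
        assert all(any(seq.startswith(t) for t in tags) for _, seq, _ in reads)

    def test_pipeline_round_trip_reproduces_counts(self, default_spec):
        """simulate_reads -> demultiplex -> count_per_fragment is lossless."""
        spec = self._small(default_spec)
        fmap, _ = simulate_fragment_map(spec)
        counts = {vp.name: simulate_counts(spec, vp, fmap)[0] for vp in spec.viewpoints}
        reads, truth = simulate_reads(spec, counts, fmap)
        assigned, unassigned = demultiplex(reads, list(spec.viewpoints))
        assert not unassigned
        for vp in spec.viewpoints:
            positions = [truth.read_positions[rid.split()[0]] for rid, _, _ in assigned[vp.name]]
            recovered = count_per_fragment(positions, fmap, "chrS")
            assert np.array_equal(recovered, counts[vp.name])
        # positions are also recoverable from the read ids themselves
        rid = reads[0][0]
        assert read_position(rid) == truth.read_positions[rid.split()[0]]


class TestAlleles:
    def test_no_events_preserves_geometry(self, default_spec):
        aspec, amap = simulate_allele(default_spec, [])
        assert aspec.length == default_spec.length
        assert aspec.tz == replace(default_spec.tz)
        assert [vp.position for vp in aspec.viewpoints] == [vp.position for vp in default_spec.viewpoints]

    def test_tz_deletion_merges_domains(self, default_spec):
        events = [RearrangementEvent("deletion", GenomicInterval("chrS", 460_000, 560_000))]
        aspec, _ = simulate_allele(default_spec, events)
        assert aspec.tz is None
        assert aspec.length == 900_000
        truth = make_truth(aspec)
        assert truth.domain_intervals["vpA"] == truth.domain_intervals["vpB"]
        assert truth.domain_intervals["vpA"].length == aspec.outer_right - aspec.outer_left

    def test_inversion_moves_enhancer_across_tz(self, default_spec):
        events = [RearrangementEvent("inversion", GenomicInterval("chrS", 460_000, 560_000))]
        aspec, _ = simulate_allele(default_spec, events)
        peak = aspec.peaks[0].position
        assert default_spec.domain_of(default_spec.peaks[0].position) == "B"
        assert aspec.domain_of(peak) == "A"
        # viewpoints stay on their own sides
        assert aspec.domain_of(aspec.viewpoints[0].position) == "A"
        assert aspec.domain_of(aspec.viewpoints[1].position) == "B"

    def test_viewpoint_deleting_event_rejected(self, default_spec):
        events = [RearrangementEvent("deletion", GenomicInterval("chrS", 300_000, 350_000))]
        with pytest.raises(ValueError, match="viewpoint"):
            simulate_allele(default_spec, events)


def test_parameter_validation():
    with pytest.raises(ValueError, match="parameters"):
        SyntheticLocusSpec(alpha=-1.0)
    with pytest.raises(ValueError, match="outer_left"):
        SyntheticLocusSpec(tz=GenomicInterval("chrS", 100, 200), outer_left=150)
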