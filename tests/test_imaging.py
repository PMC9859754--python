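"""Image-analysis operations: background, alignment, ratios, condensates, traces."""

import numpy as np
import pytest
from scipy.ndimage import grey_opening

from oracles import best_alignment_shift_bruteforce
from tiptraffic.imaging import (CondensateRecord, IntensityProfile, TraceSet,
                                average_profiles, bin_and_align,
                                client_recruitment, condition_ratio,
                                detect_condensates, subtract_background,
                                trace_velocities)
from tiptraffic.synth import (RenderConfig, parametric_comet_profile,
                              synth_condensate_image, synth_traces)


def comet(length_um=8.0, **kw):
    return parametric_comet_profile(length_um, **kw)[0]


def shifted(profile, shift_px):
    """Same profile translated by shift_px (circular-free, edge-padded)."""
    v = np.roll(profile.values, shift_px)
    if shift_px > 0:
        v[:shift_px] = profile.values[0]
    elif shift_px < 0:
        v[shift_px:] = profile.values[-1]
    return IntensityProfile(v, profile.pixel_size_um, profile.condition)


class TestSubtractBackground:
    def test_constant_image_becomes_zero(self):
        out = subtract_background(np.full((40, 40), 7.0), radius_px=5)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 50, (40, 40))
        a = subtract_background(img, radius_px=8)
        b = subtract_background(img + 123.0, radius_px=8)
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_isolated_spot_preserved_vs_grey_opening(self):
        img = np.zeros((60, 60))
        img[28:32, 28:32] = 100.0
        out = subtract_background(img, radius_px=20)
        # oracle: subtraction of a direct grey-level opening
        ball = np.hypot(*np.mgrid[-20:21, -20:21]) <= 20
        oracle = img - grey_opening(img, footprint=ball)
        assert abs(out[29, 29] - oracle[29, 29]) <= 1.0  # within 1% of peak
        assert out[29, 29] >= 99.0

    def test_radius_must_fit_image(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((10, 10)), radius_px=30)


class TestBinAndAlign:
    def test_known_shifts_recovered_exactly(self):
        base = comet()
        profiles = [base, shifted(base, 3), shifted(base, -2)]
        pset = bin_and_align(profiles, seed=0)
        ref = int(pset.reference[0])
        rel = pset.offsets_px - pset.offsets_px[0]
        # whoever is the reference, relative corrections undo {0,+3,-2}
        np.testing.assert_array_equal(rel, [0, -3, 2])
        assert pset.offsets_px[ref] == 0
        # residual after alignment is numerically zero in the overlap:
        # the bin mean equals the reference profile over the common support
        mean = average_profiles(pset)[0]
        lo = max(pset.offsets_px)
        ref_vals = pset.profiles[ref].values
        assert np.allclose(
            mean.values, ref_vals[lo:lo + mean.values.size], atol=1e-9)

    def test_single_profile_identity(self):
        pset = bin_and_align([comet()])
        assert pset.offsets_px.tolist() == [0]
        assert pset.n_bins == 1

    def test_matches_bruteforce_search(self):
        tri = IntensityProfile(
            np.concatenate([np.arange(15.0), np.arange(15.0)[::-1]]), 0.1)
        other = shifted(tri, 1)
        pset = bin_and_align([tri, other], seed=1)
        ref = int(pset.reference[0])
        i_other = 1 - ref
        expected = best_alignment_shift_bruteforce(
            pset.profiles[ref].values, pset.profiles[i_other].values, 10)
        assert pset.offsets_px[i_other] == expected

    def test_length_binning_respects_halfwidth(self):
        profiles = [comet(5.0), comet(5.3), comet(9.0), comet(9.4)]
        pset = bin_and_align(profiles, bin_halfwidth_um=0.64)
        assert pset.n_bins == 2
        for i, p in enumerate(profiles):
            c = pset.bin_centers_um[pset.bin_index[i]]
            assert abs(p.length_um - c) <= 0.64 + 1e-9

    def test_realignment_is_idempotent(self):
        # windows cut from one long comet at staggered starts, so applying
        # the recovered offsets yields a perfectly aligned set
        master = comet(14.0)
        win = lambda s: IntensityProfile(master.values[s:s + 80],
                                         master.pixel_size_um)
        starts = [30, 34, 27]
        profiles = [win(s) for s in starts]
        first = bin_and_align(profiles, seed=2)
        aligned = [win(starts[i] - int(first.offsets_px[i]))
                   for i in range(3)]
        second = bin_and_align(aligned, seed=2)
        assert np.all(second.offsets_px == 0)

    def test_alignment_is_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        profiles = [
            IntensityProfile(p.values + rng.normal(0, 5, p.values.size).clip(-50, None) + 60, p.pixel_size_um)
            for p in [comet(), shifted(comet(), 2), shifted(comet(), -4)]
        ]
        a = bin_and_align(profiles, seed=9)
        b = bin_and_align(profiles, seed=9)
        np.testing.assert_array_equal(a.offsets_px, b.offsets_px)
        assert np.array_equal(a.reference, b.reference)


class TestAverageProfiles:
    def test_identical_profiles_average_to_themselves(self):
        base = comet()
        mean = average_profiles(bin_and_align([base] * 4))[0]
        np.testing.assert_allclose(mean.values, base.values)

    def test_pointwise_mean(self):
        a = IntensityProfile(np.array([0.0, 2.0]), 0.1)
        b = IntensityProfile(np.array([2.0, 0.0]), 0.1)
        pset = bin_and_align([a, b], max_shift_px=0)
        np.testing.assert_allclose(average_profiles(pset)[0].values, [1.0, 1.0])

    def test_noisy_comets_average_to_ground_truth(self):
        truth = comet()
        rng = np.random.default_rng(3)
        n, sigma = 40, 8.0
        profiles = [
            IntensityProfile(np.clip(truth.values + rng.normal(0, sigma,
                             truth.values.size), 0, None), 0.107)
            for _ in range(n)
        ]
        mean = average_profiles(bin_and_align(profiles, seed=0))[0]
        se = sigma / np.sqrt(n)
        assert np.all(np.abs(mean.values - truth.values) < 3.5 * se + 0.1)


class TestConditionRatio:
    def test_ratio_arithmetic(self):
        mk = lambda v: IntensityProfile(np.full(30, float(v)), 0.1)
        out = condition_ratio([mk(4), mk(8)], [mk(1), mk(3)], (0.0, 2.0))
        np.testing.assert_allclose(out, [2.0, 4.0])

    def test_self_ratio_has_unit_mean(self):
        rng = np.random.default_rng(1)
        profiles = [IntensityProfile(rng.uniform(10, 20, 50), 0.1)
                    for _ in range(30)]
        out = condition_ratio(profiles, profiles, (0.0, 3.0))
        assert out.mean() == pytest.approx(1.0)

    def test_recovers_generated_end_and_lattice_ratios(self):
        """End ratio 4x and lattice ratio 2x built into the generator are
        recovered within 10% despite noise."""
        rng = np.random.default_rng(7)

        def batch(lattice, amp, n):
            out = []
            for _ in range(n):
                p = comet(lattice_level=lattice, end_amplitude=amp)
                noisy = np.clip(p.values + rng.normal(0, 4, p.values.size),
                                0, None)
                out.append(IntensityProfile(noisy, p.pixel_size_um))
            return out

        low = batch(100.0, 300.0, 40)
        high = batch(200.0, 1200.0, 40)   # lattice x2; end peak x4
        lattice_ratio = condition_ratio(high, low, (2.0, 6.0)).mean()
        end_ratio = condition_ratio(high, low, (0.0, 0.5)).mean()
        assert lattice_ratio == pytest.approx(2.0, rel=0.10)
        # the end window mixes peak and lattice signal; compare to the
        # generator's own end-window ratio rather than the bare amplitude fold
        truth_hi = comet(lattice_level=200.0, end_amplitude=1200.0)
        truth_lo = comet(lattice_level=100.0, end_amplitude=300.0)
        expected_end = (truth_hi.region_mean((0.0, 0.5))
                        / truth_lo.region_mean((0.0, 0.5)))
        assert end_ratio == pytest.approx(expected_end, rel=0.10)

    def test_zero_low_mean_signalled(self):
        zero = IntensityProfile(np.zeros(20), 0.1)
        with pytest.raises(ZeroDivisionError):
            condition_ratio([zero], [zero], (0.0, 1.0))


class TestDetectCondensates:
    cfg = RenderConfig(psf_fwhm_um=0.0, background=0.0, seed=0)

    def test_blank_image_gives_empty_list(self):
        assert detect_condensates(np.zeros((64, 64)), 0.05) == []

    def test_two_disks_recovered_with_geometry(self):
        tag, _, truth = synth_condensate_image(
            2, radii_px=8.0, tag_intensities=1.0, recruitment_factor=0.0,
            cfg=self.cfg, shape=(128, 128))
        records = detect_condensates(tag, 0.05)
        assert len(records) == 2
        centers = np.array(truth.params["centers"])
        found = np.array([r.centroid for r in records])
        d = np.linalg.norm(found[:, None] - centers[None], axis=-1).min(axis=1)
        assert np.all(d <= 0.5)
        for r in records:
            assert r.major_axis_px == pytest.approx(16.0, rel=0.10)
            assert r.minor_axis_px == pytest.approx(16.0, rel=0.10)

    def test_subthreshold_disk_ignored(self):
        tag, _, _ = synth_condensate_image(
            1, radii_px=6.0, tag_intensities=0.03, recruitment_factor=0.0,
            cfg=self.cfg, shape=(64, 64))
        assert detect_condensates(tag, 0.05) == []

    def test_count_monotone_in_threshold(self):
        # disks of graded brightness drop out one by one as the cut rises
        tag, _, _ = synth_condensate_image(
            4, radii_px=6.0, tag_intensities=[0.1, 0.3, 0.6, 0.9],
            recruitment_factor=0.0, cfg=self.cfg, shape=(160, 160))
        counts = [len(detect_condensates(tag, th))
                  for th in (0.05, 0.2, 0.5, 0.8, 0.95)]
        assert counts == [4, 3, 2, 1, 0]

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValueError):
            detect_condensates(np.zeros((8, 8)), 0.0)


class TestClientRecruitment:
    cfg = RenderConfig(psf_fwhm_um=0.0, background=0.0, seed=1)

    def records(self, f):
        tag, client, _ = synth_condensate_image(
            3, radii_px=7.0, tag_intensities=0.8, recruitment_factor=f,
            cfg=self.cfg, shape=(128, 128))
        return detect_condensates(tag, 0.05), tag, client

    def test_zero_client_image_gives_zero(self):
        records, tag, _ = self.records(1.0)
        out = client_recruitment(records, np.zeros_like(tag))
        np.testing.assert_allclose(out, 0.0)

    def test_client_equal_to_tag_reproduces_tag_means(self):
        records, tag, _ = self.records(1.0)
        out = client_recruitment(records, tag)
        np.testing.assert_allclose(out, [r.mean_tag for r in records])

    def test_recruitment_factor_recovered(self):
        records, tag, client = self.records(1.7)
        ratio = client_recruitment(records, client) / np.array(
            [r.mean_tag for r in records])
        np.testing.assert_allclose(ratio, 1.7, rtol=0.05)

    def test_geometry_mismatch_rejected(self):
        records, _, _ = self.records(1.0)
        with pytest.raises(ValueError, match="shape"):
            client_recruitment(records, np.zeros((5, 5)))


class TestTraceVelocities:
    def test_constant_velocity_traces(self):
        traces, _ = synth_traces(10, velocity_distribution=0.23,
                                 noise_sd_um=0.0, seed=0)
        median, sem = trace_velocities(traces)
        assert median == pytest.approx(0.23)
        assert sem == pytest.approx(0.0, abs=1e-12)

    def test_two_point_trace_slope(self):
        median, _ = trace_velocities([np.array([[0.0, 0.0], [10.0, 1.2]])])
        assert median == pytest.approx(0.12)

    def test_negative_velocities_supported(self):
        traces, _ = synth_traces(5, velocity_distribution=-0.1,
                                 noise_sd_um=0.0, seed=0)
        assert trace_velocities(traces)[0] == pytest.approx(-0.1)

    def test_generator_median_recovered_at_n148(self):
        traces, truth = synth_traces(148, seed=99)
        median, _ = trace_velocities(traces)
        assert median == pytest.approx(truth.params["median_velocity"],
                                       rel=0.05)

    def test_degenerate_traces_rejected(self):
        with pytest.raises(ValueError):
            TraceSet([np.array([[0.0, 1.0], [0.0, 2.0]])])
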