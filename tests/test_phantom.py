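"""Phantom generator: anatomy rasterization, breathing tracks, frame warps."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from stinr.phantom import (AnatomyParams, SCENARIO_IDS, breathing_track,
                           build_reference_anatomy, compose_basis_dvf,
                           default_motion_basis, generate_dynamic_sequence,
                           generate_prior_4dct, onboard_params, render_frame)
from stinr.volume import make_volume
from stinr.warp import warp_volume


class TestReferenceAnatomy:
    def test_tumor_mask_count_matches_sphere_volume(self):
        # 15 mm radius at 3 mm spacing: (4/3) pi 5^3 ~= 524 voxels
        ref = build_reference_anatomy(AnatomyParams())
        count = ref.masks["tumor"].sum()
        assert abs(count - 524) / 524 < 0.10

    def test_half_radius_tumor_count_scales_by_eighth(self):
        base = build_reference_anatomy(AnatomyParams()).masks["tumor"].sum()
        small = build_reference_anatomy(
            onboard_params("S7", AnatomyParams())).masks["tumor"].sum()
        assert abs(small - base / 8) / (base / 8) < 0.15

    def test_air_outside_body(self, anatomy32, params32):
        pts = anatomy32.world_coords()
        rho = np.sqrt(((pts / np.asarray(params32.body_axes)) ** 2).sum(-1))
        assert np.all(anatomy32.data[rho > 1.1] == 0.0)

    def test_attenuations_within_display_window(self, anatomy32):
        assert anatomy32.data.min() >= 0.0
        assert anatomy32.data.max() <= 0.05

    def test_tumor_outside_lung_rejected(self):
        with pytest.raises(ValueError, match="lung"):
            AnatomyParams(tumor_center=(0.0, 0.0, 0.0))

    def test_deterministic(self, params32, anatomy32):
        again = build_reference_anatomy(params32)
        assert np.array_equal(again.data, anatomy32.data)


class TestBreathingTrack:
    @pytest.mark.parametrize("scenario", [s for s in SCENARIO_IDS
                                          if s != "static"])
    def test_scan_starts_at_end_expiration(self, scenario):
        tr = breathing_track(scenario, 64, 11.0)
        assert tr.signal[0] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tr.coeffs[0], 0.0, atol=1e-12)

    def test_pure_periodic_signal_repeats_every_cycle(self):
        # before its mid-scan baseline step, S1 breathes a pure 5 s cycle:
        # 55 frames at 11 fps land exactly on the grid
        tr = breathing_track("S1", 660, 11.0)
        period_frames = 55
        pre_step = 275  # frames well before the step at t = 30 s
        assert np.allclose(tr.signal[:pre_step - period_frames],
                           tr.signal[period_frames:pre_step],
                           atol=1e-9)

    def test_monotone_scenario_never_decreases(self):
        tr = breathing_track("S6", 220, 11.0)
        assert np.all(np.diff(tr.signal) >= -1e-12)

    def test_signal_is_affine_in_first_coefficient(self):
        tr = breathing_track("S4", 200, 11.0)
        assert np.allclose(tr.signal, tr.coeffs[:, 0])

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            breathing_track("S99", 10, 11.0)

    def test_baseline_step_magnitudes(self):
        s1 = breathing_track("S1", 660, 11.0)
        s2 = breathing_track("S2", 660, 11.0)
        # the second-half envelope floor is the baseline shift
        assert s1.signal[360:].min() == pytest.approx(3.0, abs=0.2)
        assert s2.signal[360:].min() == pytest.approx(8.0, abs=0.2)

    def test_jitter_reproducible(self):
        a = breathing_track("S1", 100, 11.0, seed=5, jitter=0.1)
        b = breathing_track("S1", 100, 11.0, seed=5, jitter=0.1)
        c = breathing_track("S1", 100, 11.0, seed=6, jitter=0.1)
        assert np.array_equal(a.signal, b.signal)
        assert not np.array_equal(a.signal, c.signal)


class TestRenderFrame:
    def test_zero_coefficients_identity(self, anatomy32, basis32):
        fields = basis32.evaluate(anatomy32.shape, anatomy32.spacing)
        fr = render_frame(anatomy32, fields, np.zeros(3))
        assert np.allclose(fr.volume.data, anatomy32.data, atol=1e-6)
        assert np.array_equal(fr.tumor_mask, anatomy32.masks["tumor"])

    def test_pure_si_translation_shifts_centroid_three_voxels(self):
        p = AnatomyParams()  # 3 mm spacing
        ref = build_reference_anatomy(p)
        fields = np.zeros((1, *ref.shape, 3))
        fields[0, ..., 2] = 1.0  # uniform SI unit displacement
        fr = render_frame(ref, fields, [9.0])
        c0 = ndimage.center_of_mass(ref.masks["tumor"])
        c1 = ndimage.center_of_mass(fr.tumor_mask)
        # pull-back by +9 mm SI moves content 3 voxels toward -z
        assert c1[2] - c0[2] == pytest.approx(-3.0, abs=0.05)
        assert c1[0] == pytest.approx(c0[0], abs=0.05)

    def test_disjoint_supports_compose(self, anatomy32):
        nz = anatomy32.shape[2]
        fields = np.zeros((2, *anatomy32.shape, 3))
        fields[0, :, :, : nz // 2, 2] = 1.0
        fields[1, :, :, nz // 2:, 1] = 1.0
        coeffs = [5.0, -4.0]
        fr = render_frame(anatomy32, fields, coeffs)
        oracle = warp_volume(
            anatomy32, compose_basis_dvf(fields, coeffs))
        assert np.allclose(fr.volume.data, oracle.data)

    def test_frame_volume_consistent_with_its_dvf(self, anatomy32, basis32):
        fields = basis32.evaluate(anatomy32.shape, anatomy32.spacing)
        fr = render_frame(anatomy32, fields, [8.0, 2.0, 1.0])
        rewarped = warp_volume(anatomy32, fr.dvf_gt)
        assert np.allclose(fr.volume.data, rewarped.data, atol=1e-6)
        assert fr.tumor_mask.sum() > 0


class TestPrior4DCT:
    def test_ee_phase_equals_reference(self, params32, basis32):
        ref, phases, dvfs, coeffs = generate_prior_4dct(params32, basis32)
        assert phases[0] is ref
        assert len(phases) == 10 and len(dvfs) == 9

    def test_peak_inhale_has_max_amplitude(self, params32, basis32):
        _, _, _, coeffs = generate_prior_4dct(params32, basis32)
        assert np.argmax(np.abs(coeffs[:, 0])) == 5  # phase 5 of 10

    def test_dvfs_lie_in_basis_span(self, params32, basis32):
        _, _, dvfs, _ = generate_prior_4dct(params32, basis32)
        stack = np.stack([d.ravel() for d in dvfs])
        rank = np.linalg.matrix_rank(stack, tol=1e-8 * np.abs(stack).max())
        assert rank <= basis32.k


class TestDynamicSequence:
    def test_default_protocol_is_660_frames_at_11_fps(self):
        tr = breathing_track("S1", 660, 11.0)
        assert len(tr.times) == 660
        assert np.allclose(np.diff(tr.times), 1.0 / 11.0)

    def test_first_frame_equals_onboard_reference(self, params32, basis32):
        ref, frames, track = generate_dynamic_sequence(
            "S1", params32, basis32, n_frames=4, fps=11.0)
        assert track.signal[0] == 0.0
        assert np.allclose(frames[0].volume.data, ref.data, atol=1e-6)

    def test_s8_reference_shift_is_six_mm_per_axis(self, params32, basis32):
        prior = build_reference_anatomy(params32)
        ref8, _, _ = generate_dynamic_sequence("S8", params32, basis32,
                                               n_frames=1, fps=11.0)
        c_prior = np.array(ndimage.center_of_mass(prior.masks["tumor"]))
        c_s8 = np.array(ndimage.center_of_mass(ref8.masks["tumor"]))
        shift_mm = (c_s8 - c_prior) * params32.spacing
        assert np.all(np.abs(shift_mm - 6.0) < params32.spacing)

    def test_mask_volume_conserved_under_scan_range_warps(
            self, anatomy32, basis32):
        fields = basis32.evaluate(anatomy32.shape, anatomy32.spacing)
        n0 = anatomy32.masks["tumor"].sum()
        for coeffs in ([12.0, 4.0, 2.0], [-6.0, -2.0, -1.0], [10.0, 0, 0]):
            fr = render_frame(anatomy32, fields, coeffs)
            assert abs(int(fr.tumor_mask.sum()) - n0) / n0 < 0.20

    def test_determinism_bit_identical(self, params32, basis32):
        a = generate_dynamic_sequence("S5", params32, basis32, n_frames=3,
                                      fps=11.0, seed=3, jitter=0.05)
        b = generate_dynamic_sequence("S5", params32, basis32, n_frames=3,
                                      fps=11.0, seed=3, jitter=0.05)
        assert np.array_equal(a[1][2].volume.data, b[1][2].volume.data)
        assert np.array_equal(a[2].signal, b[2].signal)
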