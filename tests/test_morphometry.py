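"""Interpeak distances, lengths, and focus intensity quantification."""

import numpy as np
import pytest

import centropol as cp
from centropol.errors import (
    BoundaryPeakError,
    MeasurementError,
    NoPeakError,
    ParameterError,
)

from conftest import rng_for, small_params


def _profile_stack(profiles, pitch=30.0):
    """Stack whose row y=1 holds the given per-channel 1D profiles."""
    profs = np.asarray(profiles, dtype=np.float32)
    c, n = profs.shape
    v = np.zeros((c, 1, 3, n), dtype=np.float32)
    v[:, 0, 1, :] = profs
    roles = {i: r for i, r in enumerate(["marker", "wall"][:c])}
    return cp.ImageStack(v, voxel_pitch_nm=pitch, voxel_pitch_z_nm=100.0,
                         channel_roles=roles)


def _gauss(n, mu, sigma):
    x = np.arange(n)
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


class TestInterpeak:
    def test_identical_profiles_give_zero(self):
        g = _gauss(100, 50, 4)
        stack = _profile_stack([g, g])
        seg = (0, 1, 99, 1, 0)
        res = cp.interpeak_distance(stack, seg, 0, 1, 1.0)
        assert res.d_nm == pytest.approx(0.0, abs=1e-9)

    def test_offset_gaussians_recovered_subpixel(self):
        """Peaks at samples 50 and 53 (sigma 2): d = 3 sample pitches
        within 0.1."""
        stack = _profile_stack([_gauss(100, 53, 2), _gauss(100, 50, 2)])
        seg = (0, 1, 99, 1, 0)
        res = cp.interpeak_distance(stack, seg, 0, 1, 1.0)
        lp = cp.extract_line_profile(stack, seg)
        sample_pitch = lp.positions_nm[1] - lp.positions_nm[0]
        assert res.d_nm == pytest.approx(3 * stack.voxel_pitch_nm,
                                         abs=0.1 * sample_pitch)

    def test_render_measure_calibrate_chain_recovers_60nm(self):
        """A 60 nm pre-expansion lateral offset rendered at expansion 4
        comes back within 10% through profile + subpixel + calibration."""
        stack, true_off = cp.generate_interpeak_pair(
            60.0, expansion_factor=4.0, noise=cp.NoiseModel(peak_snr=None))
        nx = stack.voxels.shape[3]
        c = (nx - 1) / 2
        z = (stack.voxels.shape[1] - 1) // 2
        res = cp.interpeak_distance(stack, (1, c, nx - 2, c, z),
                                    "marker", "wall", 4.0)
        assert res.d_nm == pytest.approx(60.0, rel=0.10)

    def test_scaling_either_channel_leaves_d_unchanged(self):
        stack = _profile_stack([_gauss(100, 53, 2), _gauss(100, 48, 3)])
        seg = (0, 1, 99, 1, 0)
        d0 = cp.interpeak_distance(stack, seg, 0, 1, 1.0).d_nm
        stack.voxels[0] *= 7.0
        d1 = cp.interpeak_distance(stack, seg, 0, 1, 1.0).d_nm
        assert d1 == pytest.approx(d0, abs=1e-12)

    def test_boundary_peak_rejected(self):
        ramp = np.linspace(0, 1, 60)
        stack = _profile_stack([ramp, _gauss(60, 30, 3)])
        with pytest.raises(BoundaryPeakError):
            cp.interpeak_distance(stack, (0, 1, 59, 1, 0), 0, 1, 1.0)

    def test_flat_profile_has_no_peak(self):
        # a low-contrast ripple: prominence ~1.4 MAD, below the 3-MAD gate
        flat = 1.0 + 0.01 * np.sin(np.linspace(0, 6 * np.pi, 80))
        stack = _profile_stack([flat, _gauss(80, 40, 3)])
        with pytest.raises(NoPeakError):
            cp.interpeak_distance(stack, (0, 1, 79, 1, 0), 0, 1, 1.0)


class TestLength:
    def test_noiseless_rod_within_one_calibrated_axial_voxel(self):
        p = cp.preset_centriole(centriole_length_nm=432.0, seed=5,
                                noise=cp.NoiseModel(peak_snr=None))
        stack, _ = cp.generate_centriole(p)
        L = cp.measure_length(stack, p.expansion_factor, mode="daughter")
        vox = stack.voxel_pitch_z_nm / p.expansion_factor
        assert abs(L - 432.0) <= vox

    def test_mother_mode_uses_appendage_peak(self):
        p = cp.preset_centriole(include_appendage=True, seed=6,
                                noise=cp.NoiseModel(peak_snr=None))
        stack, _ = cp.generate_centriole(p)
        L = cp.measure_length(stack, p.expansion_factor, mode="mother")
        assert L == pytest.approx(427.0, abs=15.0)

    def test_mother_mode_without_appendage_channel_errors(self):
        stack, _ = cp.generate_centriole(small_params(seed=7))
        with pytest.raises(MeasurementError):
            cp.measure_length(stack, 4.0, mode="mother")

    def test_degenerate_z_frame_is_an_error_not_zero(self):
        stack, _ = cp.generate_centriole(small_params(seed=8))
        with pytest.raises(MeasurementError):
            cp.measure_length(stack, 4.0, mode="daughter", z_frame=(5.0, 5.5))

    def test_inplane_rotation_invariance(self):
        stack, _ = cp.generate_centriole(small_params(seed=9))
        L0 = cp.measure_length(stack, 4.0)
        rot = cp.ImageStack(np.rot90(stack.voxels, axes=(2, 3)).copy(),
                            voxel_pitch_nm=stack.voxel_pitch_nm,
                            voxel_pitch_z_nm=stack.voxel_pitch_z_nm,
                            channel_roles=dict(stack.channel_roles))
        L1 = cp.measure_length(rot, 4.0)
        assert L1 == pytest.approx(L0, abs=stack.voxel_pitch_z_nm / 4.0)

    def test_calibration_linearity(self):
        stack, _ = cp.generate_centriole(small_params(seed=10))
        assert cp.measure_length(stack, 2.0) == pytest.approx(
            2 * cp.measure_length(stack, 4.0), rel=1e-12)


class TestFocusIntensity:
    def _uniform_stack(self, base, amp, nz=3, n=41, r_spot=4.0):
        v = np.full((1, nz, n, n), base, dtype=np.float32)
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        spot = np.hypot(xx - n // 2, yy - n // 2) <= r_spot
        v[0, :, spot] += amp
        return cp.ImageStack(v, voxel_pitch_nm=30, voxel_pitch_z_nm=500,
                             channel_roles={0: "marker"}), int(spot.sum()) * nz

    def test_disk_on_uniform_background_closed_form(self):
        stack, n_spot = self._uniform_stack(2.0, 5.0)
        res = cp.quantify_focus_intensity(stack, (20, 20), 6.0, 14.0,
                                          channel="marker")
        assert res.value == pytest.approx(5.0 * n_spot, rel=1e-6)
        assert not res.clipped

    def test_empty_image_gives_zero(self):
        v = np.zeros((1, 2, 31, 31), dtype=np.float32)
        stack = cp.ImageStack(v, voxel_pitch_nm=30, voxel_pitch_z_nm=500,
                              channel_roles={0: "marker"})
        res = cp.quantify_focus_intensity(stack, (15, 15), 5.0, 10.0,
                                          channel="marker")
        assert res.value == 0.0

    def test_additive_offset_invariance_exact(self):
        stack, _ = self._uniform_stack(2.0, 5.0)
        r0 = cp.quantify_focus_intensity(stack, (20, 20), 6.0, 14.0,
                                         channel="marker")
        shifted = cp.ImageStack(stack.voxels + 11.0,
                                voxel_pitch_nm=30, voxel_pitch_z_nm=500,
                                channel_roles={0: "marker"})
        r1 = cp.quantify_focus_intensity(shifted, (20, 20), 6.0, 14.0,
                                         channel="marker")
        assert r1.value == pytest.approx(r0.value, abs=1e-3)

    def test_clipped_annulus_flagged(self):
        stack, _ = self._uniform_stack(2.0, 5.0)
        res = cp.quantify_focus_intensity(stack, (3, 3), 2.0, 8.0,
                                          channel="marker")
        assert res.clipped

    def test_noisy_spot_mean_recovery_within_5pct(self):
        """Gaussian spot at SNR ~10 over 60 noise draws: mean recovered
        integral within 5% of the noiseless one."""
        from scipy.ndimage import gaussian_filter

        n = 41
        spot = np.zeros((5, n, n))
        spot[2, 20, 20] = 1000.0
        spot = gaussian_filter(spot, (1.2, 2.5, 2.5))
        noiseless = cp.ImageStack(spot[None].astype(np.float32),
                                  voxel_pitch_nm=30, voxel_pitch_z_nm=500,
                                  channel_roles={0: "marker"})
        truth = cp.quantify_focus_intensity(noiseless, (20, 20), 10.0, 18.0,
                                            channel="marker").value
        peak = spot.max()
        vals = []
        for i in range(60):
            rng = rng_for(71, i)
            # shot noise at peak SNR 10 (100 expected photons at the peak)
            noisy = rng.poisson(spot / peak * 100.0) * peak / 100.0
            st = cp.ImageStack(noisy[None].astype(np.float32),
                               voxel_pitch_nm=30, voxel_pitch_z_nm=500,
                               channel_roles={0: "marker"})
            vals.append(cp.quantify_focus_intensity(
                st, (20, 20), 10.0, 18.0, channel="marker").value)
        assert np.mean(vals) == pytest.approx(truth, rel=0.05)

    def test_bad_radii_rejected(self):
        stack, _ = self._uniform_stack(1.0, 1.0)
        with pytest.raises(ParameterError):
            cp.quantify_focus_intensity(stack, (20, 20), 8.0, 6.0,
                                        channel="marker")
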