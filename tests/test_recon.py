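import numpy as np
import pytest

from helix_txac.forward_sim import (EVENT_DTYPE, ListModeData, ScanConfig,
                                    siddon_batch, simulate_transmission_scan)
from helix_txac.geometry import DetectorRing
from helix_txac.phantoms import GridSpec, make_cylinder_phantom
from helix_txac.recon import (ReconConfig, SinogramGeometry, SinogramStack,
                              acf_sinogram, bin_events,
                              expected_transmission_sinograms, fbp,
                              reconstruct_mumap, ssrb)

GEOM = SinogramGeometry(n_radial=61, radial_width_mm=3.0, n_angles=48)


def _make_events(ring, pairs, times=None):
    ev = np.zeros(len(pairs), dtype=EVENT_DTYPE)
    if times is None:
        times = np.arange(len(pairs), dtype=float)
    ev["t"] = times
    ev["ring_a"], ev["idx_a"], ev["ring_b"], ev["idx_b"] = \
        np.array(pairs, dtype=np.int64).T
    return ListModeData(ev, ring, exposure=float(len(pairs)))


class TestBinning:
    def test_single_diametral_event_lands_at_s_zero(self, small_ring):
        n = small_ring.crystals_per_ring
        data = _make_events(small_ring, [(1, 0, 1, n // 2)])
        stack = bin_events(data, small_ring, GEOM)
        pr, ar, sr = np.nonzero(stack.counts)
        assert len(pr) == 1
        assert sr[0] == (GEOM.n_radial - 1) // 2  # s = 0 bin
        assert stack.total_counts == 1

    def test_counts_conserved_through_binning_and_ssrb(self, small_ring,
                                                       small_traj):
        data = simulate_transmission_scan(
            None, small_traj, small_ring, ScanConfig(3e4, 4.0, seed=61))
        stack = bin_events(data, small_ring, GEOM)
        assert stack.total_counts + stack.n_discarded == len(data)
        two_d = ssrb(stack)
        assert two_d.total_counts == stack.total_counts  # exact integers
        limited = ssrb(stack, max_ring_difference=1)
        kept = sum(stack.counts[k].sum()
                   for k, (r1, r2) in enumerate(stack.ring_pairs)
                   if abs(int(r1) - int(r2)) <= 1)
        assert limited.total_counts == kept

    def test_rotating_lors_shifts_angle_histogram(self, small_ring):
        """Rotating every LOR by one crystal (= one angular bin here)
        shifts the azimuth histogram by exactly one bin."""
        n = small_ring.crystals_per_ring
        geom = SinogramGeometry(n_radial=61, radial_width_mm=3.0,
                                n_angles=n // 2)
        pairs = [(1, i, 1, (i + n // 2 + 7) % n) for i in range(0, 40)]
        rot = [(1, i + 1, 1, (i + 1 + n // 2 + 7) % n) for i in range(0, 40)]
        h0 = bin_events(_make_events(small_ring, pairs), small_ring,
                        geom).counts.sum(axis=(0, 2))
        h1 = bin_events(_make_events(small_ring, rot), small_ring,
                        geom).counts.sum(axis=(0, 2))
        assert np.array_equal(np.roll(h0, 1), h1)

    def test_endpoint_swap_invariance(self, small_ring):
        n = small_ring.crystals_per_ring
        a = _make_events(small_ring, [(0, 3, 2, 3 + n // 2 + 5)])
        b = _make_events(small_ring, [(2, 3 + n // 2 + 5, 0, 3)])
        sa = bin_events(a, small_ring, GEOM)
        sb = bin_events(b, small_ring, GEOM)
        assert np.array_equal(sa.counts, sb.counts)


class TestSSRB:
    def test_direct_and_midpoint_plane_assignment(self, small_ring):
        n = small_ring.crystals_per_ring
        data = _make_events(small_ring, [(2, 0, 2, n // 2),   # direct: plane 4
                                         (1, 5, 3, 5 + n // 2)])  # -> plane 4
        stack = bin_events(data, small_ring, GEOM)
        two_d = ssrb(stack)
        assert two_d.counts.shape[0] == 2 * small_ring.n_rings - 1
        per_plane = two_d.counts.sum(axis=(1, 2))
        assert per_plane[4] == 2 and per_plane.sum() == 2

    def test_plane_z_matches_ring_midpoints(self, small_ring):
        data = _make_events(small_ring,
                            [(0, 0, 0, small_ring.crystals_per_ring // 2)])
        two_d = ssrb(bin_events(data, small_ring, GEOM))
        assert two_d.plane_z[0] == pytest.approx(small_ring.ring_z(0))
        assert two_d.plane_z[-1] == pytest.approx(
            small_ring.ring_z(small_ring.n_rings - 1))
        assert np.all(np.diff(two_d.plane_z)
                      == pytest.approx(small_ring.ring_spacing / 2.0))

    def test_excessive_ring_difference_rejected(self, small_ring):
        data = _make_events(small_ring,
                            [(0, 0, 0, small_ring.crystals_per_ring // 2)])
        stack = bin_events(data, small_ring, GEOM)
        with pytest.raises(ValueError):
            ssrb(stack, max_ring_difference=small_ring.n_rings)


class TestAcf:
    def _stack2d(self, counts, exposure):
        return SinogramStack(counts=np.asarray(counts, float), geom=GEOM,
                             kind="2d", plane_z=np.zeros(1),
                             plane_spacing_mm=5.0, exposure=exposure)

    def test_equal_scans_give_zero_log_ratio(self):
        c = np.full((1, GEOM.n_angles, GEOM.n_radial), 50.0)
        acf = acf_sinogram(self._stack2d(c, 1.0), self._stack2d(c, 1.0))
        assert np.allclose(acf.counts, 0.0)

    def test_e_fold_attenuation_gives_unity(self):
        b = np.full((1, GEOM.n_angles, GEOM.n_radial), 2.0e4)
        t = b * np.exp(-1.0)
        acf = acf_sinogram(self._stack2d(b, 1.0), self._stack2d(t, 1.0))
        # pseudo-count of 0.5 on ~2e4 counts perturbs the log by < 1e-4
        assert np.allclose(acf.counts, 1.0, atol=1e-3)

    def test_blank_normalization_by_exposure(self):
        b = np.full((1, GEOM.n_angles, GEOM.n_radial), 3.0e4)
        t = np.full((1, GEOM.n_angles, GEOM.n_radial), 1.0e4)
        # blank acquired at 3x the exposure of the transmission scan
        acf = acf_sinogram(self._stack2d(b, 3.0), self._stack2d(t, 1.0))
        assert np.allclose(acf.counts, 0.0, atol=1e-3)

    def test_all_zero_blank_rejected(self):
        z = np.zeros((1, GEOM.n_angles, GEOM.n_radial))
        with pytest.raises(ValueError, match="blank"):
            acf_sinogram(self._stack2d(z, 1.0), self._stack2d(z, 1.0))

    def test_mask_policy_interpolates_holes(self):
        b = np.full((1, GEOM.n_angles, GEOM.n_radial), 1.0e4)
        t = np.full((1, GEOM.n_angles, GEOM.n_radial), 1.0e4 * np.exp(-1.0))
        t[0, 0, 30] = 0.0  # dead bin
        acf = acf_sinogram(self._stack2d(b, 1.0), self._stack2d(t, 1.0),
                           zero_policy="mask")
        assert acf.counts[0, 0, 30] == pytest.approx(1.0, abs=1e-6)


class TestFbp:
    def test_zero_sinogram_gives_zero_image(self):
        img = fbp(np.zeros((GEOM.n_angles, GEOM.n_radial)), GEOM)
        assert np.allclose(img, 0.0)

    @staticmethod
    def _disk_sinogram(geom, mu_cm, radius_mm, center=(0.0, 0.0)):
        """Analytic Radon transform of a uniform disk."""
        s = geom.s_centers[None, :]
        psi = geom.angle_centers[:, None]
        s_eff = s - (center[0] * np.cos(psi) + center[1] * np.sin(psi))
        chord = 2.0 * np.sqrt(np.maximum(radius_mm ** 2 - s_eff ** 2, 0.0))
        return (mu_cm / 10.0) * chord  # mu per mm x chord in mm

    def test_disk_value_recovered_in_central_roi(self):
        geom = SinogramGeometry(n_radial=101, radial_width_mm=2.0,
                                n_angles=120)
        sino = self._disk_sinogram(geom, 0.096, 45.0)
        img = fbp(sino, geom, ReconConfig(n_pixels=100, pixel_size_mm=2.0))
        xs = (np.arange(100) + 0.5) * 2.0 - 100.0
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        roi = np.hypot(X, Y) < 22.5  # central 50% of the disk radius
        assert img[roi].mean() == pytest.approx(0.096, rel=0.02)

    def test_shift_equivariance_via_centroid(self):
        geom = SinogramGeometry(n_radial=101, radial_width_mm=2.0,
                                n_angles=120)
        cfg = ReconConfig(n_pixels=100, pixel_size_mm=2.0)
        shift = (14.0, -22.0)
        img = fbp(self._disk_sinogram(geom, 0.1, 30.0, shift), geom, cfg)
        xs = (np.arange(100) + 0.5) * 2.0 - 100.0
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        w = np.clip(img, 0, None)
        cx = (X * w).sum() / w.sum()
        cy = (Y * w).sum() / w.sum()
        assert (cx, cy) == pytest.approx(shift, abs=1.0)

    def test_matches_skimage_iradon(self):
        """Independent cross-check of the FBP implementation."""
        from skimage.transform import iradon
        geom = SinogramGeometry(n_radial=101, radial_width_mm=2.0,
                                n_angles=120)
        sino = self._disk_sinogram(geom, 0.096, 45.0)
        ours = fbp(sino, geom, ReconConfig(n_pixels=101, pixel_size_mm=2.0,
                                           window="ramp", cutoff=1.0))
        theta = np.degrees(geom.angle_centers)
        theirs = iradon(sino.T, theta=theta, filter_name="ramp",
                        output_size=101, circle=False).T
        theirs *= 10.0 / 2.0  # their pixel units (radial bins) -> cm^-1
        xs = (np.arange(101) - 50.0) * 2.0
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        roi = np.hypot(X, Y) < 35.0
        diff = np.abs(ours[roi] - theirs[roi]).max()
        assert diff < 0.05 * 0.096


class TestEndToEnd:
    def test_noiseless_log_ratio_matches_forward_projection(self, desk_ring,
                                                            desk_traj):
        """Forward-model consistency: the per-bin log blank/transmission
        ratio equals the bin-averaged Siddon projection to 2%."""
        vol = make_cylinder_phantom(90.0, 157.0, "water",
                                    GridSpec.default(200.0, 2.0))
        geom = SinogramGeometry()
        b2, t2, k2 = expected_transmission_sinograms(
            vol, desk_traj, desk_ring, geom, n_decays=6_000_000, seed=5)
        acf = acf_sinogram(b2, t2, zero_policy="mask", blank_scale=1.0)
        sel = (b2.counts >= 10) & (k2.counts > 0.3)
        assert sel.sum() > 500
        rel = np.abs(acf.counts[sel] / k2.counts[sel] - 1.0)
        assert np.percentile(rel, 95) < 0.02

    def test_blank_vs_blank_reconstructs_to_null(self, desk_ring, desk_traj):
        cfg_a = ScanConfig(2.0e5, 5.0, seed=71)
        cfg_b = ScanConfig(2.0e5, 5.0, seed=72)
        a = simulate_transmission_scan(None, desk_traj, desk_ring, cfg_a)
        b = simulate_transmission_scan(None, desk_traj, desk_ring, cfg_b)
        res = reconstruct_mumap(a, b, desk_ring, SinogramGeometry(),
                                ReconConfig())
        core = res.values[30:70, 30:70, 5:10]
        assert abs(core.mean()) < 0.002

    def test_doubling_exposure_shrinks_noise_sqrt2(self, desk_ring,
                                                   desk_traj):
        """ROI std scales like 1/sqrt(counts): doubling both scans'
        exposures should shrink it by about sqrt(2)."""
        vol = make_cylinder_phantom(90.0, 157.0, "water",
                                    GridSpec.default(200.0, 2.0))
        # coarse sinogram keeps per-bin counts in the Poisson-dominated
        # regime where the 1/sqrt(N) law applies at these exposures
        geom = SinogramGeometry(n_radial=61, radial_width_mm=3.0, n_angles=48)
        cfg = ReconConfig(n_pixels=66, pixel_size_mm=3.0)
        noise = []
        for scale, seed in ((1.0, 81), (2.0, 85)):
            # two independent replicates per exposure: the std of their
            # difference isolates the stochastic part from the fixed
            # discretization structure of the reconstruction
            recs = []
            for rep in range(2):
                b = simulate_transmission_scan(
                    None, desk_traj, desk_ring,
                    ScanConfig(4.0e5 * scale, 5.0, seed=seed + 2 * rep))
                t = simulate_transmission_scan(
                    vol, desk_traj, desk_ring,
                    ScanConfig(2.0e5 * scale, 5.0, seed=seed + 2 * rep + 1))
                res = reconstruct_mumap(b, t, desk_ring, geom, cfg)
                recs.append(res.values[27:39, 27:39, 6:9])
            noise.append((recs[0] - recs[1]).std() / np.sqrt(2.0))
        ratio = noise[0] / noise[1]
        assert ratio == pytest.approx(np.sqrt(2.0), rel=0.20)
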