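"""Traction force microscopy chain: alignment, PIV, FTTC, summaries."""

import numpy as np
import pytest

from mechanopheno.synthgen import (SyntheticTractionSpec, TractionPatch,
                                   _render_beads, build_patch_traction)
from mechanopheno.tfm import (
    BeadImagePair, DisplacementField, TractionField, align_to_reference,
    forward_displacement, fttc_traction, piv_displacement,
    summarize_traction)


def make_field(u, v, spacing=1.0):
    ny, nx = u.shape
    return DisplacementField(grid_x=np.arange(nx) * spacing,
                             grid_y=np.arange(ny) * spacing,
                             u=u, v=v,
                             valid_mask=np.ones(u.shape, dtype=bool))


def paired_patch_field(rng, n=64, spacing=1.0, E=10000.0):
    """Random directed Gaussian patches in +/- pairs (zero net force)."""
    gx = np.arange(n) * spacing
    tx = np.zeros((n, n))
    ty = np.zeros((n, n))
    X, Y = np.meshgrid(gx, gx)
    for _ in range(rng.integers(1, 4)):
        cx, cy = rng.uniform(0.25 * n, 0.75 * n, 2) * spacing
        w = rng.uniform(3, 8) * spacing
        amp = rng.uniform(50, 300)
        th = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(5, 10) * spacing
        for sgn in (+1, -1):
            g = amp * np.exp(-((X - cx - sgn * off * np.cos(th))**2
                               + (Y - cy - sgn * off * np.sin(th))**2)
                             / (2 * w**2))
            tx += sgn * g * np.cos(th)
            ty += sgn * g * np.sin(th)
    return TractionField(grid_x=gx, grid_y=gx, t_x=tx, t_y=ty, E_gel=E)


class TestAlignment:
    def test_identical_frame_zero_shift(self, rng):
        ref = rng.normal(100, 10, (128, 128))
        aligned, cref, shifts = align_to_reference(ref.copy(), ref)
        np.testing.assert_allclose(shifts, 0, atol=1e-6)
        np.testing.assert_allclose(aligned[0], cref)

    def test_cyclic_shift_recovered_exactly(self, rng):
        pos = rng.uniform([0, 0], [255, 255], (600, 2))
        ref = _render_beads((256, 256), pos, 2.0, 400.0) + 100
        frame = np.roll(np.roll(ref, 4, axis=0), -7, axis=1)
        aligned, cref, shifts = align_to_reference(frame, ref)
        # the applied correction undoes the (4, -7) roll
        np.testing.assert_allclose(shifts[0], [-4.0, 7.0], atol=0.05)
        assert np.abs(aligned[0] - cref).max() < 1e-6 * ref.max()

    def test_huge_shift_fails(self, rng):
        pos = rng.uniform([0, 0], [127, 127], (300, 2))
        ref = _render_beads((128, 128), pos, 2.0, 400.0) + 100
        frame = np.roll(ref, 50, axis=1)
        with pytest.raises(RuntimeError, match="alignment failure"):
            align_to_reference(frame, ref)


class TestPIV:
    def test_identical_images_zero_field(self, rng):
        pos = rng.uniform([0, 0], [127, 127], (300, 2))
        img = _render_beads((128, 128), pos, 2.0, 400.0) + 100
        d = piv_displacement(BeadImagePair(img, img, pixel_size=1.0))
        np.testing.assert_allclose(d.u, 0, atol=1e-8)
        np.testing.assert_allclose(d.v, 0, atol=1e-8)

    def test_uniform_subpixel_shift(self, rng):
        """A 0.3 px global shift is recovered within 0.1 px on average."""
        pos = rng.uniform([0, 0], [255, 255], (1300, 2))
        ref = _render_beads((256, 256), pos, 2.0, 400.0) + 100
        dfm = _render_beads((256, 256), pos + [0.3, 0], 2.0, 400.0) + 100
        d = piv_displacement(BeadImagePair(ref, dfm, pixel_size=1.0))
        assert abs(d.u.mean() - 0.3) < 0.1
        assert abs(d.v.mean()) < 0.1

    def test_translation_equivariance(self, rng):
        """Shifting both images by the same integer vector leaves the
        displacement field unchanged on the common support."""
        pos = rng.uniform([0, 0], [255, 255], (1300, 2))
        ref = _render_beads((256, 256), pos, 2.0, 400.0) + 100
        dfm = _render_beads((256, 256), pos + [1.7, 0.6], 2.0, 400.0) + 100
        d0 = piv_displacement(BeadImagePair(ref, dfm, pixel_size=1.0))
        sh = np.roll(np.roll(ref, 32, 0), 32, 1), \
            np.roll(np.roll(dfm, 32, 0), 32, 1)
        d1 = piv_displacement(BeadImagePair(sh[0], sh[1], pixel_size=1.0))
        a = d0.u[:-2, :-2][d0.valid_mask[:-2, :-2] & d1.valid_mask[2:, 2:]]
        b = d1.u[2:, 2:][d0.valid_mask[:-2, :-2] & d1.valid_mask[2:, 2:]]
        np.testing.assert_allclose(a, b, atol=0.05)

    def test_ground_truth_recovery(self, traction_scene):
        """PIV error below 20% of the true displacement rms."""
        from scipy.ndimage import map_coordinates
        px = traction_scene["spec"].pixel_size
        d = piv_displacement(BeadImagePair(traction_scene["ref"],
                                           traction_scene["dfm"],
                                           pixel_size=px))
        GX, GY = np.meshgrid(d.grid_x / px, d.grid_y / px)
        disp = traction_scene["disp"]
        ut = map_coordinates(disp.u, [GY.ravel(), GX.ravel()],
                             order=1).reshape(d.u.shape)
        vt = map_coordinates(disp.v, [GY.ravel(), GX.ravel()],
                             order=1).reshape(d.u.shape)
        err = np.sqrt(np.mean((d.u - ut)**2 + (d.v - vt)**2))
        assert err < 0.2 * np.sqrt(np.mean(ut**2 + vt**2))

    def test_window_validation(self, rng):
        img = rng.normal(100, 5, (64, 64))
        with pytest.raises(ValueError, match=">= 16"):
            piv_displacement(BeadImagePair(img, img, pixel_size=1.0),
                             window=8)
        with pytest.raises(ValueError, match="larger than image"):
            piv_displacement(BeadImagePair(img, img, pixel_size=1.0),
                             window=128)


class TestForwardModel:
    def test_zero_traction_zero_displacement(self):
        gx = np.arange(32.0)
        t = TractionField(grid_x=gx, grid_y=gx, t_x=np.zeros((32, 32)),
                          t_y=np.zeros((32, 32)), E_gel=1e4)
        d = forward_displacement(t)
        assert np.all(d.magnitude == 0)

    def test_linearity(self, rng):
        t = paired_patch_field(rng)
        t2 = TractionField(grid_x=t.grid_x, grid_y=t.grid_y,
                           t_x=3 * t.t_x, t_y=3 * t.t_y, E_gel=t.E_gel)
        d1, d2 = forward_displacement(t), forward_displacement(t2)
        np.testing.assert_allclose(d2.u, 3 * d1.u, rtol=1e-12, atol=1e-18)

    def test_single_frequency_amplitude(self):
        """Plane-wave traction against the hand-evaluated Green's tensor:
        for t = A cos(kx) x_hat and nu = 1/2, u = 1.5 A / (E k) cos(kx)."""
        n, E, A = 64, 1e4, 100.0
        gx = np.arange(float(n))
        k = 2 * np.pi * 4 / n
        tx = A * np.cos(k * gx)[None, :] * np.ones((n, 1))
        t = TractionField(grid_x=gx, grid_y=gx, t_x=tx,
                          t_y=np.zeros((n, n)), E_gel=E)
        d = forward_displacement(t)
        expected = 2 * (1 + 0.5) * (1 - 0.5) / (E * k) * A
        assert d.u.max() == pytest.approx(expected, rel=1e-10)
        np.testing.assert_allclose(d.v, 0, atol=1e-12)


class TestFTTC:
    def test_zero_displacement_zero_traction(self):
        d = make_field(np.zeros((32, 32)), np.zeros((32, 32)))
        t = fttc_traction(d, E_gel=1e4, lam=0.0)
        assert np.all(t.magnitude == 0)

    def test_round_trip_on_random_patch_fields(self, rng):
        """forward then inverse (lam=0) reproduces band-limited
        force-balanced fields to < 5% relative L2 error."""
        for _ in range(20):
            t = paired_patch_field(rng)
            d = forward_displacement(t)
            t2 = fttc_traction(d, E_gel=t.E_gel, lam=0.0)
            num = np.sum((t2.t_x - t.t_x)**2 + (t2.t_y - t.t_y)**2)
            den = np.sum(t.t_x**2 + t.t_y**2)
            assert np.sqrt(num / den) < 0.05

    def test_stiffness_scaling(self, rng):
        d = make_field(rng.normal(0, 0.05, (32, 32)),
                       rng.normal(0, 0.05, (32, 32)))
        t1 = fttc_traction(d, E_gel=9000.0, lam=0.0)
        t2 = fttc_traction(d, E_gel=30000.0, lam=0.0)
        np.testing.assert_allclose(t2.t_x, t1.t_x * 30 / 9, rtol=1e-9)

    def test_regularization_monotonicity(self, rng):
        t = paired_patch_field(rng)
        d = forward_displacement(t)
        norms = [np.sum(fttc_traction(d, t.E_gel, lam=lam).magnitude**2)
                 for lam in [0.0, 1e-10, 1e-8, 1e-6, 1e-4]]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_zero_mean_enforced(self, rng):
        d = make_field(rng.normal(0, 0.1, (48, 48)),
                       rng.normal(0, 0.1, (48, 48)))
        t = fttc_traction(d, E_gel=1e4)
        assert abs(t.t_x.mean()) < 1e-12 * np.abs(t.t_x).max()
        assert abs(t.t_y.mean()) < 1e-12 * np.abs(t.t_y).max()

    def test_invalid_nodes_interpolated(self, rng):
        t = paired_patch_field(rng)
        d = forward_displacement(t)
        u = d.u.copy()
        mask = np.ones(u.shape, dtype=bool)
        u[10, 10] = np.nan
        mask[10, 10] = False
        d2 = DisplacementField(grid_x=d.grid_x, grid_y=d.grid_y, u=u,
                               v=d.v, valid_mask=mask)
        t2 = fttc_traction(d2, E_gel=t.E_gel, lam=0.0)
        assert np.all(np.isfinite(t2.magnitude))

    def test_all_invalid_raises(self):
        d = DisplacementField(grid_x=np.arange(8.0), grid_y=np.arange(8.0),
                              u=np.zeros((8, 8)), v=np.zeros((8, 8)),
                              valid_mask=np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError, match="invalid"):
            fttc_traction(d, E_gel=1e4)


class TestSummarizeTraction:
    def _const_field(self, c):
        gx = np.arange(8.0)
        return TractionField(grid_x=gx, grid_y=gx,
                             t_x=np.full((8, 8), c),
                             t_y=np.zeros((8, 8)), E_gel=1e4)

    def test_constant_magnitude(self):
        s = summarize_traction([self._const_field(42.0)])
        assert s.temporal_mean == pytest.approx(42.0)

    def test_mean_of_frame_medians(self):
        s = summarize_traction([self._const_field(100.0),
                                self._const_field(300.0)])
        np.testing.assert_allclose(s.frame_medians, [100.0, 300.0])
        assert s.temporal_mean == pytest.approx(200.0)
        assert (min(s.frame_medians) <= s.temporal_mean
                <= max(s.frame_medians))

    def test_mask_restricts_median(self, rng):
        t = paired_patch_field(rng)
        mask = t.magnitude > np.percentile(t.magnitude, 80)
        s_all = summarize_traction([t])
        s_mask = summarize_traction([t], mask=mask)
        assert s_mask.temporal_mean > s_all.temporal_mean

    def test_empty_mask_rejected(self, rng):
        t = paired_patch_field(rng)
        with pytest.raises(ValueError, match="empty"):
            summarize_traction([t], mask=np.zeros(t.t_x.shape, dtype=bool))
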