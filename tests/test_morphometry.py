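"""Channel preprocessing, segmentation and object measurement."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse

from mechanopheno.morphometry import (
    ChannelImage, area_occupied, measure_objects, preprocess, segment_fa,
    segment_primary, segment_secondary)
from mechanopheno.synthgen import SyntheticFASceneSpec, gen_fa_scene


def channel(data, tag="nuclei", px=1.0):
    return ChannelImage(np.asarray(data, dtype=float), tag, px)


class TestPreprocess:
    def test_rescale_preserves_ranks(self, rng):
        img = channel(rng.uniform(0, 1000, (64, 64)))
        out = preprocess(img, saturation=0.0)
        assert np.array_equal(np.argsort(img.data.ravel()),
                              np.argsort(out.data.ravel()))
        assert out.data.min() == 0.0 and out.data.max() == 1.0

    def test_rescale_idempotent(self, rng):
        img = channel(rng.uniform(0, 1000, (64, 64)))
        once = preprocess(img, saturation=0.0)
        twice = preprocess(once, saturation=0.0)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_tophat_suppresses_large_background(self):
        img = np.zeros((128, 128))
        img[32:96, 32:96] = 200.0            # large plateau
        rr, cc = draw_disk((64, 64), 3)
        img[rr, cc] = 500.0                  # small bright spot
        out = preprocess(channel(img, "fa"), saturation=0.0,
                         apply_tophat=True, tophat_radius=8)
        spot = out.data[64, 64]
        plateau = out.data[40, 40]
        assert plateau < 0.05 * spot
        assert spot > 0.3

    def test_constant_image_returned_with_warning(self):
        out = preprocess(channel(np.full((16, 16), 3.0)))
        assert "warning" in out.preprocessing
        np.testing.assert_array_equal(out.data, 3.0)

    def test_saturation_validation(self):
        with pytest.raises(ValueError):
            preprocess(channel(np.zeros((4, 4))), saturation=60)


class TestSegmentPrimary:
    def test_blank_image_empty_map(self):
        lm = segment_primary(channel(np.zeros((32, 32))))
        assert lm.n_objects == 0

    def test_disjoint_nuclei_counted_with_areas(self):
        img = np.zeros((256, 256))
        radii = [10, 14, 18]
        for i, r in enumerate(radii):
            rr, cc = draw_disk((40 + 80 * i, 128), r)
            img[rr, cc] = 500.0
        lm = segment_primary(channel(img), min_area=10.0)
        assert lm.n_objects == 3
        meas = measure_objects(lm).table.sort_values("area_um2")
        for got, r in zip(meas["area_um2"], sorted(radii)):
            assert got == pytest.approx(np.pi * r**2, rel=0.05)

    def test_min_area_monotonicity(self):
        img = np.zeros((128, 128))
        for i, r in enumerate([3, 6, 9]):
            rr, cc = draw_disk((30 + 40 * i, 64), r)
            img[rr, cc] = 500.0
        counts = [segment_primary(channel(img), min_area=a).n_objects
                  for a in [0.0, 30.0, 100.0, 1e4]]
        assert counts == sorted(counts, reverse=True)

    def test_manual_removal_repacks_labels(self):
        img = np.zeros((128, 128))
        for i in range(3):
            rr, cc = draw_disk((30 + 40 * i, 64), 8)
            img[rr, cc] = 500.0
        lm = segment_primary(channel(img), min_area=10.0)
        lm2 = segment_primary(channel(img), min_area=10.0,
                              manual_removals=[2])
        assert lm.n_objects == 3 and lm2.n_objects == 2
        assert sorted(np.unique(lm2.labels)) == [0, 1, 2]


class TestSegmentSecondary:
    def test_single_cell_inherits_seed_label(self):
        cell = np.zeros((96, 96))
        rr, cc = draw_disk((48, 48), 30)
        cell[rr, cc] = 300.0
        nuc = np.zeros((96, 96))
        rr, cc = draw_disk((48, 48), 8)
        nuc[rr, cc] = 800.0
        seeds = segment_primary(channel(nuc), min_area=10.0)
        cells = segment_secondary(channel(cell, "cell"), seeds)
        assert cells.n_objects == 1
        # cell body covers the blob
        assert np.count_nonzero(cells.labels) == pytest.approx(
            np.count_nonzero(cell > 0), rel=0.02)

    def test_two_seeds_partition_touching_blob(self):
        cell = np.zeros((96, 160))
        rr, cc = draw_ellipse(48, 80, 30, 70)
        cell[rr, cc] = 300.0
        nuc = np.zeros((96, 160))
        for x in (40, 120):
            rr, cc = draw_disk((48, x), 8)
            nuc[rr, cc] = 800.0
        seeds = segment_primary(channel(nuc), min_area=10.0)
        cells = segment_secondary(channel(cell, "cell"), seeds)
        assert cells.n_objects == 2
        # the two cells exactly partition the blob
        blob = cell > 0
        union = cells.labels > 0
        np.testing.assert_array_equal(union, blob)

    def test_no_foreground_cells_equal_seeds(self):
        nuc = np.zeros((64, 64))
        rr, cc = draw_disk((32, 32), 8)
        nuc[rr, cc] = 800.0
        seeds = segment_primary(channel(nuc), min_area=10.0)
        cells = segment_secondary(channel(np.zeros((64, 64)), "cell"), seeds)
        np.testing.assert_array_equal(cells.labels > 0, seeds.labels > 0)


class TestSegmentFA:
    def test_scene_recovery(self, fa_scene):
        spec = fa_scene["spec"]
        px = spec.pixel_size
        pre = preprocess(ChannelImage(fa_scene["fa"], "fa", px),
                         apply_tophat=True, tophat_radius=8)
        seeds = segment_primary(
            preprocess(ChannelImage(fa_scene["nuclei"], "nuclei", px)),
            min_area=10.0)
        cells = segment_secondary(
            preprocess(ChannelImage(fa_scene["cell"], "cell", px)), seeds)
        fas = segment_fa(pre, cells)
        assert fas.n_objects >= 0.95 * spec.n_fa

    def test_fa_outside_cells_excluded(self, rng):
        fa = np.zeros((96, 96))
        rr, cc = draw_disk((20, 20), 4)
        fa[rr, cc] = 500.0                 # inside cell
        rr, cc = draw_disk((80, 80), 4)
        fa[rr, cc] = 500.0                 # outside cell
        cell_lab = np.zeros((96, 96), dtype=int)
        cell_lab[:48, :48] = 1
        from mechanopheno.morphometry import LabelMap
        cells = LabelMap(cell_lab, "cell", 1.0)
        fas = segment_fa(channel(fa, "fa"), cells, min_area=0.0,
                         max_area=1e6)
        assert fas.n_objects == 1
        assert np.all(cell_lab[fas.labels > 0] == 1)

    def test_size_window_monotone(self, fa_scene):
        spec = fa_scene["spec"]
        px = spec.pixel_size
        pre = preprocess(ChannelImage(fa_scene["fa"], "fa", px),
                         apply_tophat=True, tophat_radius=8)
        seeds = segment_primary(
            preprocess(ChannelImage(fa_scene["nuclei"], "nuclei", px)),
            min_area=10.0)
        cells = segment_secondary(
            preprocess(ChannelImage(fa_scene["cell"], "cell", px)), seeds)
        loose = segment_fa(pre, cells, min_area=0.0, max_area=np.inf)
        strict = segment_fa(pre, cells, min_area=0.5, max_area=10.0)
        assert strict.n_objects <= loose.n_objects


class TestMeasurements:
    def test_disc_eccentricity_near_zero(self):
        img = np.zeros((64, 64))
        rr, cc = draw_disk((32, 32), 20)
        img[rr, cc] = 500.0
        m = measure_objects(segment_primary(channel(img), min_area=10.0))
        assert m.table["eccentricity"][0] < 0.05

    def test_ellipse_eccentricity_matches_analytic(self):
        img = np.zeros((64, 64))
        rr, cc = draw_ellipse(32, 32, 10, 20)
        img[rr, cc] = 500.0
        m = measure_objects(segment_primary(channel(img), min_area=10.0))
        assert m.table["eccentricity"][0] == pytest.approx(
            np.sqrt(0.75), abs=0.02)

    def test_square_area_in_physical_units(self):
        img = np.zeros((32, 32))
        img[10:20, 10:20] = 500.0
        lm = segment_primary(channel(img, px=0.5), min_area=0.0)
        m = measure_objects(lm)
        assert m.table["area_um2"][0] == pytest.approx(25.0)

    def test_rotation_invariance(self, fa_scene):
        spec = fa_scene["spec"]
        px = spec.pixel_size
        img = channel(fa_scene["fa"], "fa", px)
        rot = channel(np.rot90(fa_scene["fa"]), "fa", px)
        def run(ci):
            pre = preprocess(ci, apply_tophat=True, tophat_radius=8)
            from mechanopheno.morphometry import LabelMap
            full = LabelMap(np.ones(ci.data.shape, dtype=np.int32),
                            "cell", px)
            fas = segment_fa(pre, full)
            t = measure_objects(fas).table
            return t.sort_values("area_um2").reset_index(drop=True)
        a, b = run(img), run(rot)
        assert len(a) == len(b)
        np.testing.assert_array_equal(a["area_um2"], b["area_um2"])
        np.testing.assert_allclose(a["eccentricity"], b["eccentricity"],
                                   atol=0.02)

    def test_fa_containment_invariant(self, fa_scene):
        spec = fa_scene["spec"]
        px = spec.pixel_size
        pre = preprocess(ChannelImage(fa_scene["fa"], "fa", px),
                         apply_tophat=True, tophat_radius=8)
        seeds = segment_primary(
            preprocess(ChannelImage(fa_scene["nuclei"], "nuclei", px)),
            min_area=10.0)
        cells = segment_secondary(
            preprocess(ChannelImage(fa_scene["cell"], "cell", px)), seeds)
        fas = segment_fa(pre, cells)
        assert np.all(cells.labels[fas.labels > 0] > 0)
        fa_area = measure_objects(fas).table["area_um2"].sum()
        cell_area = measure_objects(cells).table["area_um2"].sum()
        assert fa_area <= cell_area


class TestAreaOccupied:
    def test_extremes_and_half_plane(self):
        from mechanopheno.morphometry import LabelMap
        z = np.zeros((10, 10), dtype=int)
        assert area_occupied(LabelMap(z, "cell", 1.0)) == 0.0
        assert area_occupied(LabelMap(np.ones_like(z), "cell", 1.0)) == 1.0
        half = z.copy()
        half[:5] = 1
        assert area_occupied(LabelMap(half, "cell", 1.0)) == 0.5
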