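"""Corner detection, disc landmarks, and height/diameter parameters."""

import numpy as np
import pytest

from ivdquant.geometry import (AdjacencyError, CornerDetectionError,
                               CornerSet, detect_vb_corners, disc_hdr,
                               disc_height, disc_height_index,
                               disc_landmarks, measure_spine,
                               vertebral_diameter, vertebral_height)
from ivdquant.maskio import BinaryRegion, LabelMask
from ivdquant.phantom import generate_phantom, healthy_spec


def _rect_region(shape=(40, 60), r0=10, c0=10, h=20, w=40, cid=1):
    arr = np.zeros(shape, dtype=bool)
    arr[r0:r0 + h, c0:c0 + w] = True
    return BinaryRegion(arr, cid)


class TestCornerDetection:
    def test_axis_aligned_rectangle_roles_and_accuracy(self):
        region = _rect_region(shape=(30, 50), r0=5, c0=5, h=20, w=40)
        cs = detect_vb_corners(region)
        expect = {"L_sa": (5, 5), "L_sp": (5, 44),
                  "L_ia": (24, 5), "L_ip": (24, 44)}
        for name, true in expect.items():
            err = np.linalg.norm(getattr(cs, name) - np.array(true))
            assert err <= 1.5, (name, getattr(cs, name), true)

    def test_rotated_rectangle_within_tolerance(self):
        t = np.deg2rad(10.0)
        rr, cc = np.mgrid[0:60, 0:80]
        cen = np.array([30.0, 40.0])
        u = (cc - cen[1]) * np.cos(t) + (rr - cen[0]) * np.sin(t)
        v = -(cc - cen[1]) * np.sin(t) + (rr - cen[0]) * np.cos(t)
        region = BinaryRegion((np.abs(u) <= 20) & (np.abs(v) <= 10), 1)
        cs = detect_vb_corners(region)
        for name, (su, sv) in {"L_sa": (-1, -1), "L_sp": (1, -1),
                               "L_ia": (-1, 1), "L_ip": (1, 1)}.items():
            dc = su * 20 * np.cos(t) - sv * 10 * np.sin(t)
            dr = su * 20 * np.sin(t) + sv * 10 * np.cos(t)
            true = cen + np.array([dr, dc])
            assert np.linalg.norm(getattr(cs, name) - true) <= 1.5, name

    def test_disk_has_no_corners(self):
        rr, cc = np.mgrid[0:60, 0:60]
        region = BinaryRegion((rr - 30) ** 2 + (cc - 30) ** 2 <= 22 ** 2, 1)
        with pytest.raises(CornerDetectionError):
            detect_vb_corners(region)


class TestVertebraMeasures:
    def test_horizontal_midpoints(self):
        cs = CornerSet((0, 0), (0, 39), (19, 0), (19, 39))
        assert vertebral_diameter(cs) == pytest.approx(39.0)

    def test_3_4_5_triangle(self):
        cs = CornerSet((0, 0), (3, 4), (0, 0), (3, 4))
        assert vertebral_diameter(cs) == pytest.approx(5.0)

    def test_height_from_area(self):
        region = _rect_region(h=20, w=40)
        assert vertebral_height(region, 39.0) == pytest.approx(800 / 39)

    def test_identity_vh_times_vd_is_area(self):
        region = _rect_region(h=20, w=40)
        vd = 37.2
        assert vertebral_height(region, vd) * vd == pytest.approx(800.0)

    def test_vd_must_be_positive(self):
        with pytest.raises(ValueError):
            vertebral_height(_rect_region(), 0.0)

    def test_phantom_vertebra_recovery(self, healthy_sample):
        m = measure_spine(healthy_sample.image, healthy_sample.mask)
        for role, v in m.vertebrae.items():
            t = healthy_sample.truth[role]
            assert abs(v.VD - t.VD) / t.VD <= 0.02
            assert abs(v.VH - t.VH) / t.VH <= 0.03


def _stack(disc_h=12, disc_w=50, vb_h=20, shape=None, ellipse=False):
    """Disc between two aligned rectangle 'vertebrae'; returns regions."""
    shape = shape or (2 * vb_h + disc_h + 20, disc_w + 20)
    r0, c0 = 10, 10
    up = np.zeros(shape, bool)
    up[r0:r0 + vb_h, c0:c0 + disc_w] = True
    dr0 = r0 + vb_h
    disc = np.zeros(shape, bool)
    if ellipse:
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        cen = (dr0 + (disc_h - 1) / 2, c0 + (disc_w - 1) / 2)
        disc = (((cc - cen[1]) / (disc_w / 2)) ** 2
                + ((rr - cen[0]) / (disc_h / 2)) ** 2) <= 1
    else:
        disc[dr0:dr0 + disc_h, c0:c0 + disc_w] = True
    lr0 = dr0 + disc_h
    low = np.zeros(shape, bool)
    low[lr0:lr0 + vb_h, c0:c0 + disc_w] = True
    up_cs = CornerSet((r0, c0), (r0, c0 + disc_w - 1),
                      (dr0 - 1, c0), (dr0 - 1, c0 + disc_w - 1))
    low_cs = CornerSet((lr0, c0), (lr0, c0 + disc_w - 1),
                       (lr0 + vb_h - 1, c0), (lr0 + vb_h - 1, c0 + disc_w - 1))
    return BinaryRegion(disc, 8), up_cs, low_cs


class TestDiscLandmarks:
    def test_rectangle_between_rectangles(self):
        disc, up, low = _stack()
        lm = disc_landmarks(disc, up, low)
        # anterior/posterior midpoints at mid-height of left/right edges
        assert lm.D_a[1] == pytest.approx(10.0)
        assert lm.D_p[1] == pytest.approx(59.0)
        assert lm.diameter == pytest.approx(49.0)
        assert lm.max_diameter == pytest.approx(49.0)

    def test_ellipse_major_axis(self):
        disc, up, low = _stack(ellipse=True)
        lm = disc_landmarks(disc, up, low)
        assert lm.max_diameter == pytest.approx(49.0, abs=1.0)

    def test_gap_beyond_tolerance_raises(self):
        disc, up, low = _stack()
        shifted = CornerSet(up.L_sa - [8, 0], up.L_sp - [8, 0],
                            up.L_ia - [8, 0], up.L_ip - [8, 0])
        with pytest.raises(AdjacencyError):
            disc_landmarks(disc, shifted, low)


class TestDiscHeight:
    def test_central_band_pixel_count(self):
        disc, up, low = _stack()
        lm = disc_landmarks(disc, up, low)
        area_central, dh = disc_height(disc, lm, mu=0.8)
        assert area_central == 480.0          # 40 columns x 12 rows
        assert dh == pytest.approx(480 / 39.2)

    def test_mu_one_uses_whole_disc(self):
        disc, up, low = _stack()
        lm = disc_landmarks(disc, up, low)
        _, dh = disc_height(disc, lm, mu=1.0)
        assert dh == pytest.approx(600 / 49)

    def test_ellipse_dh_below_minor_axis(self):
        disc, up, low = _stack(ellipse=True)
        lm = disc_landmarks(disc, up, low)
        _, dh = disc_height(disc, lm, mu=0.8)
        assert dh < 12.0

    def test_invalid_mu(self):
        disc, up, low = _stack()
        lm = disc_landmarks(disc, up, low)
        with pytest.raises(ValueError):
            disc_height(disc, lm, mu=0.0)


class TestRatios:
    def test_dhi(self):
        assert disc_height_index(10, 20, 30) == pytest.approx(0.4)
        assert disc_height_index(25, 25, 25) == pytest.approx(1.0)

    def test_dhi_denominator(self):
        with pytest.raises(ValueError):
            disc_height_index(10, 0, 0)

    def test_hdr(self):
        assert disc_hdr(12, 48) == pytest.approx(0.25)
        assert disc_hdr(7, 7) == pytest.approx(1.0)

    def test_hdr_from_rectangle_stack(self):
        disc, up, low = _stack()
        lm = disc_landmarks(disc, up, low)
        _, dh = disc_height(disc, lm)
        assert disc_hdr(dh, lm.max_diameter) == pytest.approx(480 / 39.2 / 49)


class TestSpacing:
    def test_lengths_scale_ratios_invariant(self):
        disc, up, low = _stack()
        lm = disc_landmarks(disc, up, low)
        _, dh1 = disc_height(disc, lm)
        _, dh2 = disc_height(disc, lm, spacing_mm=(0.5, 0.5))
        assert dh2 == pytest.approx(0.5 * dh1)
        assert vertebral_diameter(up, (0.5, 0.5)) == pytest.approx(
            0.5 * vertebral_diameter(up))
        # unit-free ratios unchanged
        hdr1 = disc_hdr(dh1, lm.max_diameter)
        hdr2 = disc_hdr(dh2, 0.5 * lm.max_diameter)
        assert hdr1 == pytest.approx(hdr2)


class TestMaxDiameterOracle:
    def test_extreme_projection_matches_all_pairs(self):
        disc, up, low = _stack(ellipse=True)
        lm = disc_landmarks(disc, up, low)
        from ivdquant.geometry import _boundary
        bnd = _boundary(disc).astype(float)
        d = np.sqrt(((bnd[:, None, :] - bnd[None, :, :]) ** 2).sum(-1))
        assert lm.max_diameter == pytest.approx(d.max(), abs=1.0)


class TestMeasureSpine:
    def test_healthy_phantom_all_discs(self, healthy_sample):
        m = measure_spine(healthy_sample.image, healthy_sample.mask)
        assert len(m.discs) == 5
        assert not m.errors
        hard = [f for f in m.flags]
        assert hard == []

    def test_missing_csf_flags_but_measures_geometry(self, healthy_sample):
        pix = healthy_sample.mask.pixels.copy()
        pix[pix == 13] = 0
        m = measure_spine(healthy_sample.image,
                          LabelMask(pix, healthy_sample.mask.class_map))
        assert "csf_absent" in m.flags
        assert len(m.discs) == 5
        for d in m.discs.values():
            assert d.delta_si is None
            assert d.DH > 0

    def test_rotation_equivariance_of_dh(self, healthy_sample):
        m0 = measure_spine(healthy_sample.image, healthy_sample.mask)
        tilted = generate_phantom(healthy_spec(tilt_deg=10.0))
        m1 = measure_spine(tilted.image, tilted.mask)
        for role in m0.discs:
            a, b = m0.discs[role].DH, m1.discs[role].DH
            assert abs(a - b) / a <= 0.02

    def test_shrinking_disc_strictly_decreases_measures(self):
        prev = None
        for h in (18, 14, 10, 6):
            ph = generate_phantom(healthy_spec(disc_size=(76, h)))
            m = measure_spine(ph.image, ph.mask)
            d = m.discs["DISC_L3L4"]
            if prev is not None:
                assert d.DH < prev.DH
                assert d.DHI < prev.DHI
                assert d.HDR < prev.HDR
            prev = d
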