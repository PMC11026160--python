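"""Mask construction, interpolation and physical-distance morphology."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from vesiquant import (
    GeometryError,
    Mask3D,
    PlanarROI,
    VoxelVolume,
    boolean_op,
    build_layers,
    dilate_physical,
    erode_physical,
    internal_tissue_mask,
    interpolate_roi_stack,
    rasterize_polygon,
)


def circle_poly(cy: float, cx: float, r: float, n: int = 64) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([cy + r * np.sin(th), cx + r * np.cos(th)], axis=1)


SQUARE = np.array([[0.5, 0.5], [0.5, 10.5], [10.5, 10.5], [10.5, 0.5]])


class TestRasterizePolygon:
    def test_rectangle_pixel_count(self):
        assert rasterize_polygon(SQUARE, (20, 20)).sum() == 100

    def test_triangle_matches_point_in_polygon_oracle(self):
        tri = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
        mask = rasterize_polygon(tri, (10, 10))
        # oracle: strict interior / closure point-in-polygon via shapely;
        # pixels exactly on the boundary may fall either way by convention
        from shapely.geometry import Point, Polygon

        poly = Polygon(tri)
        inner, outer = poly.buffer(-1e-9), poly.buffer(1e-9)
        for y in range(10):
            for x in range(10):
                p = Point(y, x)
                if inner.contains(p):
                    assert mask[y, x], (y, x)
                elif not outer.contains(p):
                    assert not mask[y, x], (y, x)

    def test_orientation_invariance(self):
        a = rasterize_polygon(SQUARE, (20, 20))
        b = rasterize_polygon(SQUARE[::-1], (20, 20))
        assert (a == b).all()

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            rasterize_polygon([[0, 0], [1, 1], [0, 0]], (5, 5))

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0.0, 0.0], [4.0, 4.0], [0.0, 4.0], [4.0, 0.0]])
        with pytest.raises(ValueError):
            rasterize_polygon(bowtie, (6, 6))


class TestInterpolateROIStack:
    def test_constant_square_gives_prism(self):
        rois = [PlanarROI(0, SQUARE), PlanarROI(15, SQUARE)]
        m = interpolate_roi_stack(rois, (16, 20, 20), (2.5, 1, 1))
        per_plane = m.data.reshape(16, -1).sum(axis=1)
        assert (per_plane == 100).all()

    def test_annotated_planes_reproduced_exactly(self):
        rois = [PlanarROI(0, circle_poly(32, 32, 10)), PlanarROI(10, circle_poly(28, 36, 17))]
        m = interpolate_roi_stack(rois, (11, 64, 64), (2.5, 1, 1))
        for r in rois:
            expected = rasterize_polygon(r.polygon, (64, 64))
            assert (m.data[r.plane_index] == expected).all()

    def test_concentric_circles_interpolate_radius(self):
        rois = [PlanarROI(0, circle_poly(32, 32, 10)), PlanarROI(10, circle_poly(32, 32, 20))]
        m = interpolate_roi_stack(rois, (11, 64, 64), (1, 1, 1))
        r5 = np.sqrt(m.data[5].sum() / np.pi)
        assert r5 == pytest.approx(15.0, abs=1.0)

    def test_single_plane_no_extrapolation(self):
        m = interpolate_roi_stack([PlanarROI(3, SQUARE)], (8, 20, 20), (1, 1, 1))
        assert m.data[3].sum() == 100
        assert m.data.sum() == 100

    def test_duplicate_plane_rejected(self):
        rois = [PlanarROI(2, SQUARE), PlanarROI(2, circle_poly(10, 10, 4))]
        with pytest.raises(ValueError):
            interpolate_roi_stack(rois, (5, 20, 20), (1, 1, 1))


class TestPhysicalMorphology:
    def test_zero_distance_is_identity(self):
        m = Mask3D(np.random.default_rng(0).random((6, 6, 6)) > 0.5, (2.5, 1, 1))
        assert (dilate_physical(m, 0).data == m.data).all()
        assert (erode_physical(m, 0).data == m.data).all()

    def test_single_voxel_anisotropic_dilation_count(self):
        # spacing (2.5,1,1), distance 2.5 µm: 21 in-plane voxels within
        # radius 2.5 px plus the two axial neighbours = 23
        m = np.zeros((7, 7, 7), bool)
        m[3, 3, 3] = True
        d = dilate_physical(Mask3D(m, (2.5, 1, 1)), 2.5)
        assert d.count() == 23
        # brute-force distance check over the full 7³ neighbourhood
        zz, yy, xx = np.mgrid[0:7, 0:7, 0:7]
        dist = np.sqrt((2.5 * (zz - 3)) ** 2 + (yy - 3.0) ** 2 + (xx - 3.0) ** 2)
        assert (d.data == (dist <= 2.5)).all()

    def test_dilation_monotone_in_distance(self, rng):
        m = Mask3D(rng.random((10, 12, 12)) > 0.9, (2.5, 1, 1))
        d1, d2 = dilate_physical(m, 2.0), dilate_physical(m, 4.5)
        assert (d1.data <= d2.data).all()
        assert (m.data <= d1.data).all()

    def test_erode_ball_matches_analytic_volume(self):
        sp = (20.0, 20.0, 20.0)
        zz, yy, xx = np.mgrid[0:70, 0:70, 0:70]
        r = np.sqrt(sum(((a - 34.5) * 20.0) ** 2 for a in (zz, yy, xx)))
        ball = Mask3D(r <= 600, sp)
        eroded = erode_physical(ball, 500)
        vol = eroded.count() * 20.0**3
        analytic = 4 / 3 * np.pi * 100**3
        assert vol == pytest.approx(analytic, rel=0.15)  # coarse-voxel tolerance

    def test_opening_is_subset(self, rng):
        m = Mask3D(rng.random((8, 16, 16)) > 0.6, (2.5, 1, 1))
        opened = dilate_physical(erode_physical(m, 2.0), 2.0)
        assert (opened.data <= m.data).all()

    def test_negative_distance_rejected(self):
        m = Mask3D(np.ones((2, 2, 2), bool), (1, 1, 1))
        with pytest.raises(ValueError):
            dilate_physical(m, -1)
        with pytest.raises(ValueError):
            erode_physical(m, -1)

    def test_anisotropy_invariance_of_sphere_dilation(self):
        # dilating a sphere by the same physical distance on different
        # grids changes the voxel bookkeeping, not the physical volume
        vols = []
        for sp in [(2.5, 1.0, 1.0), (1.0, 1.0, 1.0)]:
            shape = tuple(int(round(50 / s)) * 2 + 1 for s in sp)
            centre = [(n - 1) / 2 for n in shape]
            grids = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
            r = np.sqrt(sum(((g - c) * s) ** 2 for g, c, s in zip(grids, centre, sp)))
            d = dilate_physical(Mask3D(r <= 12.0, sp), 6.0)
            vols.append(d.count() * float(np.prod(sp)))
        assert vols[0] == pytest.approx(vols[1], rel=0.05)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), dist=st.floats(0.5, 5.0))
    def test_dilation_erosion_duality(self, seed, dist):
        rng = np.random.default_rng(seed)
        m = Mask3D(rng.random((8, 10, 10)) > 0.7, (2.5, 1, 1))
        lhs = erode_physical(m, dist).data
        rhs = ~dilate_physical(Mask3D(~m.data, m.spacing), dist).data
        assert (lhs == rhs).all()


class TestBooleanOp:
    def test_subtract_cardinality_of_nested_masks(self):
        outer = np.zeros((4, 10, 10), bool)
        outer[1:3, 1:8, 1:8] = True
        inner = np.zeros_like(outer)
        inner[1, 1:6, 1:6] = True  # nested subset of outer
        a = Mask3D(outer, (1, 1, 1))
        b = Mask3D(inner, (1, 1, 1))
        diff = boolean_op(a, b, "subtract")
        assert diff.count() == a.count() - b.count()

    def test_idempotence_and_annihilation(self, rng):
        m = Mask3D(rng.random((5, 8, 8)) > 0.5, (1, 1, 1))
        assert (boolean_op(m, m, "and").data == m.data).all()
        assert boolean_op(m, m, "xor").count() == 0

    @pytest.mark.parametrize("op,npfn", [
        ("and", np.logical_and),
        ("or", np.logical_or),
        ("subtract", lambda a, b: a & ~b),
        ("xor", np.logical_xor),
    ])
    def test_matches_whole_volume_oracle(self, op, npfn, rng):
        for _ in range(5):
            a = Mask3D(rng.random((16, 16, 16)) > 0.5, (2.5, 1, 1))
            b = Mask3D(rng.random((16, 16, 16)) > 0.5, (2.5, 1, 1))
            assert (boolean_op(a, b, op).data == npfn(a.data, b.data)).all()

    def test_geometry_mismatch_rejected(self):
        a = Mask3D(np.ones((2, 4, 4), bool), (1, 1, 1))
        b = Mask3D(np.ones((2, 4, 5), bool), (1, 1, 1))
        with pytest.raises(GeometryError):
            boolean_op(a, b, "or")


@pytest.fixture(scope="module")
def ball_layers():
    sp = (2.0, 2.0, 2.0)
    zz, yy, xx = np.mgrid[0:80, 0:80, 0:80]
    r = np.sqrt(sum(((a - 39.5) * 2.0) ** 2 for a in (zz, yy, xx)))
    bc = Mask3D(r <= 40, sp)
    empty = Mask3D(np.zeros_like(bc.data), sp)
    return r, build_layers(bc, urothelium=empty, tumour=empty, thickness_um=10, n_layers=3)


class TestBuildLayers:
    def test_empty_annotations_make_tl_equal_l(self, ball_layers):
        _, ls = ball_layers
        for k in (1, 2, 3):
            assert (ls[f"TL{k}"].data == ls[f"L{k}"].data).all()
        assert (ls["HL"].data == ls["L1"].data).all()

    def test_shell_volumes_match_analytic(self, ball_layers):
        r, ls = ball_layers
        for k, (r0, r1) in enumerate([(40, 50), (50, 60), (60, 70)], start=1):
            analytic = 4 / 3 * np.pi * (r1**3 - r0**3)
            measured = ls[f"L{k}"].count() * 8.0
            assert measured == pytest.approx(analytic, rel=0.10)

    def test_layer_conservation_telescopes(self, ball_layers):
        _, ls = ball_layers
        total = sum(ls[f"L{k}"].count() for k in (1, 2, 3))
        assert total == ls.shells[-1].count() - ls.shells[0].count()
        union = np.zeros_like(ls.shells[0].data)
        for k in (1, 2, 3):
            union |= ls[f"L{k}"].data
        union |= ls.shells[0].data
        assert (union == ls.shells[-1].data).all()

    def test_layers_pairwise_disjoint(self, ball_layers):
        _, ls = ball_layers
        s = sum(ls[f"L{k}"].data.astype(int) for k in (1, 2, 3))
        assert s.max() <= 1

    def test_empty_seed_rejected(self):
        sp = (1, 1, 1)
        empty = Mask3D(np.zeros((4, 4, 4), bool), sp)
        with pytest.raises(ValueError):
            build_layers(empty, urothelium=empty, tumour=empty)


@pytest.fixture(scope="module")
def hollow_ball():
    sp = (20.0, 20.0, 20.0)
    zz, yy, xx = np.mgrid[0:70, 0:70, 0:70]
    r = np.sqrt(sum(((a - 34.5) * 20.0) ** 2 for a in (zz, yy, xx)))
    return r, sp


class TestInternalTissueMask:
    def test_hollow_ball_shell_minus_rind(self, hollow_ball):
        r, sp = hollow_ball
        af = np.where((r > 400) & (r <= 600), 20000, 100).astype(np.uint16)
        m = internal_tissue_mask(VoxelVolume(af, sp), erosion_um=100)
        expected = (r > 400) & (r <= 500)
        agreement = (m.data & expected).sum() / max(m.count(), expected.sum())
        assert agreement > 0.95
        assert not m.data[r <= 380].any()  # lumen removed

    def test_solid_ball_warns_and_erodes(self, hollow_ball):
        r, sp = hollow_ball
        af = np.where(r <= 600, 20000, 100).astype(np.uint16)
        with pytest.warns(UserWarning, match="no enclosed cavity"):
            m = internal_tissue_mask(VoxelVolume(af, sp), erosion_um=100)
        assert m.count() == pytest.approx((r <= 500).sum(), rel=0.05)

    def test_all_zero_volume_empty_mask(self):
        with pytest.warns(UserWarning):
            m = internal_tissue_mask(VoxelVolume(np.zeros((5, 5, 5)), (1, 1, 1)))
        assert m.count() == 0
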