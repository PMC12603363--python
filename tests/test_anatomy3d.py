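"""Tests for voxel trait quantification on labeled leaf volumes."""

import numpy as np
import pytest

from oakleaf.anatomy3d import (
    DEFAULT_LEGEND,
    AnatomyError,
    LabeledVolume,
    anatomy_traits,
    interface_surface_area,
    leaf_thickness,
    segmentation_f1,
    tissue_volumes,
)

L = DEFAULT_LEGEND


def vol_from(grid, voxel_edge=0.65):
    return LabeledVolume(grid=np.asarray(grid, dtype=np.uint8),
                         voxel_edge=voxel_edge)


def slab_leaf(nz=4, nx=5, e=2, dp=3, ds=3, fill_p=None, fill_s=None):
    """Flat slab leaf: epidermis / palisade / spongy / epidermis stacks."""
    ny = 2 * e + dp + ds
    g = np.empty((nz, ny, nx), dtype=np.uint8)
    g[:, :e] = L["adaxial_epidermis"]
    g[:, e:e + dp] = fill_p if fill_p is not None else L["palisade"]
    g[:, e + dp:e + dp + ds] = fill_s if fill_s is not None else L["spongy"]
    g[:, e + dp + ds:] = L["abaxial_epidermis"]
    return g


class TestTissueVolumes:
    def test_fraction_counting(self):
        g = np.full((10, 10, 10), L["ias"], dtype=np.uint8)
        g.ravel()[:600] = L["palisade"]
        g.ravel()[600:900] = L["spongy"]
        g.ravel()[900:] = L["ias"]
        v = tissue_volumes(vol_from(g))
        assert v["v_p"] / v["v_mes"] == pytest.approx(0.6)
        assert v["v_s"] / v["v_mes"] == pytest.approx(0.3)
        assert v["v_ias"] / v["v_mes"] == pytest.approx(0.1)

    def test_physical_volume_scaling(self):
        g = np.full((10, 10, 10), L["palisade"], dtype=np.uint8)
        v = tissue_volumes(vol_from(g, voxel_edge=0.65))
        assert v["v_mes"] == pytest.approx(1000 * 0.65 ** 3)
        assert v["v_mes"] == pytest.approx(274.625)

    def test_all_background_gives_zero_and_ratio_error(self):
        g = np.zeros((4, 4, 4), dtype=np.uint8)
        v = tissue_volumes(vol_from(g))
        assert v["v_mes"] == 0.0
        with pytest.raises(AnatomyError):
            anatomy_traits(vol_from(g))


class TestInterfaceArea:
    def test_single_voxel_in_airspace(self):
        g = np.full((5, 5, 5), L["ias"], dtype=np.uint8)
        g[2, 2, 2] = L["palisade"]
        a = interface_surface_area(vol_from(g), {"palisade"})
        assert a == pytest.approx(6 * 0.65 ** 2)
        assert a == pytest.approx(2.535)

    def test_two_adjacent_voxels(self):
        g = np.full((5, 5, 5), L["ias"], dtype=np.uint8)
        g[2, 2, 2] = g[2, 2, 3] = L["palisade"]
        a = interface_surface_area(vol_from(g), {"palisade"})
        assert a == pytest.approx(10 * 0.4225)

    def test_no_airspace_gives_zero(self):
        g = np.full((4, 4, 4), L["palisade"], dtype=np.uint8)
        assert interface_surface_area(vol_from(g), {"palisade"}) == 0.0

    def test_empty_cell_classes_rejected(self):
        g = np.full((4, 4, 4), L["ias"], dtype=np.uint8)
        with pytest.raises(AnatomyError):
            interface_surface_area(vol_from(g), set())

    def test_face_count_invariant_under_grid_symmetries(self):
        rng = np.random.default_rng(5)
        g = rng.choice([L["palisade"], L["spongy"], L["ias"]],
                       size=(6, 7, 8)).astype(np.uint8)
        ref = interface_surface_area(vol_from(g), {"palisade", "spongy"})
        for perm in ((1, 2, 0), (2, 0, 1), (0, 2, 1)):
            assert interface_surface_area(
                vol_from(np.transpose(g, perm)), {"palisade", "spongy"}
            ) == pytest.approx(ref)
        for axis in range(3):
            assert interface_surface_area(
                vol_from(np.flip(g, axis)), {"palisade", "spongy"}
            ) == pytest.approx(ref)

    def test_sphere_estimators_face_bias_and_mesh_accuracy(self):
        r = 10
        n = 2 * r + 8
        z, y, x = np.mgrid[:n, :n, :n]
        c = (n - 1) / 2
        g = np.full((n, n, n), L["ias"], dtype=np.uint8)
        g[(z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= r * r] = L["palisade"]
        vol = vol_from(g, voxel_edge=1.0)
        true_area = 4 * np.pi * r ** 2
        mesh = interface_surface_area(vol, {"palisade"}, method="mesh")
        face = interface_surface_area(vol, {"palisade"}, method="face")
        assert mesh == pytest.approx(true_area, rel=0.05)
        assert 1.3 < face / true_area < 1.7  # documented staircase bias ~1.5


class TestLeafThickness:
    def test_uniform_slab_exact(self):
        g = slab_leaf(nz=3, nx=4, e=50, dp=70, ds=61)   # 231 rows
        t = leaf_thickness(vol_from(g), seed=0)
        assert t == pytest.approx(231 * 0.65)
        assert t == pytest.approx(150.15)

    def test_tilted_slab_sampled_matches_exhaustive(self):
        nz, nx, ny = 8, 40, 60
        g = np.zeros((nz, ny, nx), dtype=np.uint8)
        for x in range(nx):
            top = 5 + x // 8            # gentle tilt along columns
            bottom = top + 40
            g[:, top:top + 3, x] = L["adaxial_epidermis"]
            g[:, top + 3:bottom - 3, x] = L["palisade"]
            g[:, bottom - 3:bottom, x] = L["abaxial_epidermis"]
        vol = vol_from(g)
        exact = leaf_thickness(vol, exhaustive=True)
        sampled = leaf_thickness(vol, n_columns=10, n_slices=8, seed=3)
        assert sampled == pytest.approx(exact, rel=0.01)

    def test_missing_epidermis_errors(self):
        g = np.full((4, 10, 4), L["palisade"], dtype=np.uint8)
        g[:, :2] = L["adaxial_epidermis"]
        with pytest.raises(AnatomyError):
            leaf_thickness(vol_from(g))


class TestAnatomyTraits:
    def test_ratio_partition_identity(self):
        fill = np.zeros((3, 6, 100), dtype=np.uint8)
        g = slab_leaf(nz=3, nx=100, e=2, dp=3, ds=3)
        # carve IAS into exactly 10% of mesophyll voxels
        g[:, 2:5, :20] = L["ias"]                      # 180 of 1800 voxels
        vol = vol_from(g)
        tr = anatomy_traits(vol)
        assert tr.p_to_m + tr.s_to_m + tr.theta_ias == pytest.approx(1.0,
                                                                     abs=1e-15)
        assert tr.theta_ias == pytest.approx(0.1)
        assert tr.s_to_p == pytest.approx(tr.s_to_m / tr.p_to_m)
        assert tr.sa_mes_total == pytest.approx(tr.sa_mes_p + tr.sa_mes_s)

    def test_single_cell_voxel_surface_density(self):
        g = np.full((10, 10, 10), L["ias"], dtype=np.uint8)
        g[5, 5, 5] = L["palisade"]
        v = tissue_volumes(vol_from(g))
        a = interface_surface_area(vol_from(g), {"palisade"})
        assert a / v["v_mes"] == pytest.approx(2.535 / 274.625)

    def test_zero_palisade_is_error(self):
        g = slab_leaf(fill_p=L["spongy"])
        with pytest.raises(AnatomyError):
            anatomy_traits(vol_from(g))

    def test_voxel_edge_scaling(self):
        g = slab_leaf(nz=4, nx=6, e=2, dp=4, ds=4)
        g[:, 4:6, :2] = L["ias"]
        t1 = anatomy_traits(vol_from(g, voxel_edge=0.65), exhaustive_thickness=True)
        t2 = anatomy_traits(vol_from(g, voxel_edge=1.30), exhaustive_thickness=True)
        assert t2.l_leaf == pytest.approx(2 * t1.l_leaf)
        # areas x4, volumes x8 -> surface densities halve; ratios unchanged
        assert t2.sa_mes_total == pytest.approx(t1.sa_mes_total / 2)
        for attr in ("theta_ias", "p_to_m", "s_to_m", "s_to_p"):
            assert getattr(t2, attr) == pytest.approx(getattr(t1, attr))


class TestSegmentationF1:
    def test_perfect_prediction(self):
        g = slab_leaf()
        f1 = segmentation_f1(vol_from(g), vol_from(g))
        assert all(v == 1.0 for v in f1.values())

    def test_fully_disjoint(self):
        a = np.full((4, 4, 4), L["palisade"], dtype=np.uint8)
        b = np.full((4, 4, 4), L["spongy"], dtype=np.uint8)
        f1 = segmentation_f1(vol_from(a), vol_from(b))
        assert f1["palisade"] == 0.0
        assert f1["spongy"] == 0.0

    def test_constructed_confusion(self):
        truth = np.full((1, 2, 10), L["ias"], dtype=np.uint8)
        pred = truth.copy()
        truth[0, 0, :] = L["palisade"]            # 10 true palisade
        pred[0, 0, :8] = L["palisade"]            # TP=8, FN=2
        pred[0, 1, :2] = L["palisade"]            # FP=2
        f1 = segmentation_f1(vol_from(pred), vol_from(truth))
        assert f1["palisade"] == pytest.approx(0.8)

    def test_shape_mismatch(self):
        a = vol_from(np.zeros((2, 2, 2), dtype=np.uint8))
        b = vol_from(np.zeros((2, 2, 3), dtype=np.uint8))
        with pytest.raises(AnatomyError):
            segmentation_f1(a, b)
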