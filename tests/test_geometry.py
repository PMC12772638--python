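"""Diameters, volumes, meatal axis and directional extents."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vsreport import (
    clean_mask,
    directional_extents,
    inplane_diameter,
    max_diameter,
    measure_session,
    meatal_axis,
    region_volumes,
)
from vsreport.geometry import MeatalAxis

from conftest import volume_from_labels


def brute_force_diameter(mask: np.ndarray, spacing) -> float:
    """O(n^2) oracle: max pairwise distance between foreground pixel centers.

    Maximizes the squared distance and takes one square root, the same
    final operation as the implementation, so equality can be exact.
    """
    pts = np.argwhere(mask).astype(float) * np.asarray(spacing)
    if len(pts) < 2:
        return 0.0
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = diff[..., 0] ** 2 + diff[..., 1] ** 2
    return math.sqrt(d2.max())


class TestInplaneDiameter:
    def test_empty_and_single_pixel(self):
        d = inplane_diameter(np.zeros((5, 5), dtype=bool), (1.0, 1.0))
        assert d.length == 0.0 and d.endpoint_a is None
        m = np.zeros((5, 5), dtype=bool)
        m[2, 3] = True
        d = inplane_diameter(m, (1.0, 1.0))
        assert d.length == 0.0 and d.endpoint_a == (2.0, 3.0)

    def test_three_four_five(self):
        m = np.zeros((8, 8), dtype=bool)
        m[1, 1] = m[4, 5] = True
        assert inplane_diameter(m, (1.0, 1.0)).length == pytest.approx(5.0)

    def test_anisotropic_spacing(self):
        m = np.zeros((4, 4), dtype=bool)
        m[0, 0] = m[3, 0] = True
        assert inplane_diameter(m, (0.5, 2.0)).length == pytest.approx(1.5)

    def test_endpoints_realize_length(self):
        rng = np.random.default_rng(3)
        m = rng.random((30, 30)) < 0.3
        d = inplane_diameter(m, (0.7, 1.1))
        assert math.dist(d.endpoint_a, d.endpoint_b) == pytest.approx(d.length)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        m = np.zeros((40, 40), dtype=bool)
        n = rng.integers(2, 220)
        idx = rng.integers(0, 40, size=(n, 2))
        m[idx[:, 0], idx[:, 1]] = True
        spacing = tuple(rng.uniform(0.3, 1.5, 2))
        assert inplane_diameter(m, spacing).length == brute_force_diameter(m, spacing)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_brute_force_property(self, data):
        pts = data.draw(
            st.lists(
                st.tuples(st.integers(0, 25), st.integers(0, 25)),
                min_size=1,
                max_size=120,
            )
        )
        m = np.zeros((26, 26), dtype=bool)
        for i, j in pts:
            m[i, j] = True
        assert inplane_diameter(m, (1.0, 1.0)).length == brute_force_diameter(m, (1.0, 1.0))

    def test_collinear_points(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2, 1:8] = True
        assert inplane_diameter(m, (1.0, 1.0)).length == pytest.approx(6.0)


class TestMaxDiameter:
    def test_voxelized_sphere_near_analytic(self):
        r_mm, sp = 10.0, 0.5
        n = int(2 * r_mm / sp) + 5
        c = (n - 1) / 2
        ii, jj, kk = np.indices((n, n, n))
        sphere = ((ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2) * sp**2 <= r_mm**2
        vol = volume_from_labels(sphere.astype(int), (sp, sp, sp))
        assert 19.0 <= max_diameter(vol, "whole").length <= 21.0

    def test_whole_geq_extrameatal(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 3, size=(15, 15, 8))
        vol = volume_from_labels(labels)
        assert (
            max_diameter(vol, "whole").length
            >= max_diameter(vol, "extrameatal").length
        )

    def test_intrameatal_only_equals_whole(self):
        labels = np.zeros((10, 10, 5), dtype=int)
        labels[2:7, 3:6, 1:4] = 1
        vol = volume_from_labels(labels)
        dw = max_diameter(vol, "whole")
        di = max_diameter(vol, "intrameatal")
        assert dw.length == di.length and dw.slice_index == di.slice_index

    def test_tie_breaks_to_smallest_slice(self):
        labels = np.zeros((10, 10, 5), dtype=int)
        labels[2:5, 2, 1] = 1  # identical bars on slices 1 and 3
        labels[2:5, 2, 3] = 1
        assert max_diameter(volume_from_labels(labels), "whole").slice_index == 1

    def test_subset_monotonicity(self):
        rng = np.random.default_rng(5)
        labels = (rng.random((12, 12, 6)) < 0.2).astype(int)
        vol = volume_from_labels(labels)
        bigger = labels.copy()
        bigger[0, 0, :] = 1
        vol2 = volume_from_labels(bigger)
        assert max_diameter(vol2, "whole").length >= max_diameter(vol, "whole").length


class TestCleanMask:
    def test_small_island_removed(self):
        labels = np.zeros((20, 20, 20), dtype=int)
        labels[2:7, 2:7, 2:6] = 1  # 100-voxel blob
        labels[15, 15, 15] = 2
        labels[15, 15, 16] = 2  # 2-voxel island
        out = clean_mask(volume_from_labels(labels), min_voxels=5)
        assert (out.labels == 2).sum() == 0
        assert (out.labels == 1).sum() == 100

    def test_labels_preserved_within_kept_component(self):
        labels = np.zeros((10, 10, 10), dtype=int)
        labels[2:5, 2:5, 2:5] = 1
        labels[5, 2:5, 2:5] = 2  # touching -> same 26-component
        out = clean_mask(volume_from_labels(labels), min_voxels=0)
        assert (out.labels == 2).sum() == 9

    def test_empty_passthrough(self):
        out = clean_mask(volume_from_labels(np.zeros((5, 5, 5), dtype=int)))
        assert not out.labels.any()

    def test_equal_size_tie_break_lexicographic_centroid(self):
        labels = np.zeros((20, 20, 5), dtype=int)
        labels[10:13, 10:13, 1] = 1  # centroid (11, 11, 1)
        labels[2:5, 15:18, 1] = 1  # centroid (3, 16, 1) -> lexicographically smaller
        out = clean_mask(volume_from_labels(labels), min_voxels=0)
        assert out.labels[3, 16, 1] == 1 and out.labels[11, 11, 1] == 0

    def test_largest_component_kept(self):
        labels = np.zeros((20, 20, 5), dtype=int)
        labels[1:3, 1:3, 1:3] = 1  # 8 voxels
        labels[10:14, 10:14, 1:4] = 2  # 48 voxels
        out = clean_mask(volume_from_labels(labels), min_voxels=5)
        assert (out.labels == 1).sum() == 0 and (out.labels == 2).sum() == 48


class TestMeatalAxis:
    def test_collinear_interface_along_x(self):
        labels = np.zeros((20, 20, 3), dtype=int)
        labels[3:15, 5, 1] = 2
        labels[3:15, 4, 1] = 1  # interface row varies along x only
        ax = meatal_axis(volume_from_labels(labels))
        assert ax is not None
        assert abs(ax.u_par[0]) == pytest.approx(1.0)
        assert ax.u_par[0] * ax.u_perp[0] + ax.u_par[1] * ax.u_perp[1] == pytest.approx(0.0)

    def test_no_extrameatal_undefined(self):
        labels = np.zeros((10, 10, 3), dtype=int)
        labels[2:5, 2:5, 1] = 1
        assert meatal_axis(volume_from_labels(labels)) is None

    def test_single_interface_voxel_undefined(self):
        labels = np.zeros((10, 10, 3), dtype=int)
        labels[4, 4, 1] = 1
        labels[5, 4, 1] = 2
        assert meatal_axis(volume_from_labels(labels)) is None

    def test_unit_orthonormal(self):
        labels = np.zeros((20, 20, 3), dtype=int)
        labels[5:12, 5:8, 1] = 1
        labels[5:12, 8, 1] = 2
        ax = meatal_axis(volume_from_labels(labels))
        assert np.hypot(*ax.u_par) == pytest.approx(1.0)
        assert np.hypot(*ax.u_perp) == pytest.approx(1.0)


class TestDirectionalExtents:
    def test_rectangle_projections_pixel_center(self):
        sx = sy = 1.0
        labels = np.zeros((20, 20, 3), dtype=int)
        labels[2:4, 2:4, 1] = 1  # intrameatal 2x2 patch
        labels[6:12, 2:4, 1] = 2  # extrameatal 6x2 rectangle along x
        axis = MeatalAxis(u_par=(1.0, 0.0), u_perp=(0.0, 1.0), n_interface_voxels=4)
        d_i, d_ep, d_eq = directional_extents(
            volume_from_labels(labels), axis, reference_slice=1
        )
        assert d_ep == pytest.approx(6.0 - sx)
        assert d_eq == pytest.approx(2.0 - sy)
        assert d_i == pytest.approx(2.0 - sx)

    def test_fallback_slice_when_compartment_absent(self):
        labels = np.zeros((20, 20, 5), dtype=int)
        labels[5:9, 5, 1] = 1  # intrameatal only on slice 1
        labels[5:9, 6, 1] = 2
        labels[5:15, 5:9, 3] = 2  # big extrameatal blob defines reference slice 3
        vol = volume_from_labels(labels)
        axis = meatal_axis(vol)
        d_i, _, _ = directional_extents(vol, axis, reference_slice=3)
        assert d_i > 0  # taken from the interface-richest slice

    def test_axis_required(self):
        with pytest.raises(ValueError, match="no meatal axis"):
            directional_extents(
                volume_from_labels(np.zeros((5, 5, 5), dtype=int)), None
            )


class TestVolumes:
    def test_unit_conversion(self):
        labels = np.zeros((10, 10, 10), dtype=int)
        labels.ravel()[:1000] = 1
        vi, ve, vw = region_volumes(volume_from_labels(labels))
        assert vw == pytest.approx(1.0) and vi == pytest.approx(1.0) and ve == 0.0

    def test_empty(self):
        assert region_volumes(volume_from_labels(np.zeros((4, 4, 4), dtype=int))) == (
            0.0,
            0.0,
            0.0,
        )

    def test_sphere_within_5pct_of_analytic(self):
        r_mm, sp = 10.0, 0.5
        n = int(2 * r_mm / sp) + 5
        c = (n - 1) / 2
        ii, jj, kk = np.indices((n, n, n))
        sphere = ((ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2) * sp**2 <= r_mm**2
        _, _, vw = region_volumes(volume_from_labels(sphere.astype(int), (sp, sp, sp)))
        assert vw == pytest.approx(4.18879, rel=0.05)

    def test_additivity_and_spacing_scaling(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, size=(9, 9, 9))
        v1 = region_volumes(volume_from_labels(labels, (1.0, 1.0, 1.0)))
        v2 = region_volumes(volume_from_labels(labels, (2.0, 2.0, 2.0)))
        assert v1[2] == v1[0] + v1[1]
        assert v2[2] == pytest.approx(8 * v1[2])


class TestMeasureSession:
    def test_empty_mask(self):
        m = measure_session(volume_from_labels(np.zeros((6, 6, 6), dtype=int)))
        assert m.d_wt == 0.0 and m.v_whole == 0.0 and m.n_axial_slices == 0
        assert m.d_em is None and m.reference_slice is None

    def test_entirely_intrameatal(self):
        labels = np.zeros((12, 12, 6), dtype=int)
        labels[3:8, 3:8, 2:4] = 1
        m = measure_session(volume_from_labels(labels))
        assert m.entirely_intrameatal
        assert m.d_em is None and m.d_intra_par is None
        assert m.d_wt > 0

    def test_invariants_on_two_compartment_mask(self, measured_timeline):
        _, _, measurements, _, _ = measured_timeline
        for m in measurements:
            assert m.v_whole == pytest.approx(m.v_intra + m.v_extra, abs=1e-12)
            assert m.d_em is not None and m.d_wt >= m.d_em
            assert not m.entirely_intrameatal
            assert m.n_axial_slices > 1
            assert m.d_intra_par is not None and m.d_extra_perp > 0
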