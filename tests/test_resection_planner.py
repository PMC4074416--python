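"""Margin regions, resection surfaces and opening prediction on analytic phantoms."""

import dataclasses

import numpy as np
import pytest

import nephroplan as npl
from nephroplan import (
    LabelMask,
    MarginSchedule,
    detect_opening,
    distance_from_mask,
    plan_all_margins,
    removed_region,
    resection_surface,
)

VOXEL_DIAG = np.sqrt(3) * 0.8  # one voxel diagonal of the 0.8 mm phantom grids


def nested_spheres(spacing=0.5, r_tumor=10.0, r_kidney=30.0):
    sp = np.full(3, spacing)
    n = int(np.ceil(2 * (r_kidney + 3) / spacing))
    center = (n - 1) * spacing / 2
    idx = np.indices((n, n, n)).reshape(3, -1).T * spacing
    d = np.linalg.norm(idx - center, axis=1).reshape((n, n, n))
    kidney = LabelMask(d <= r_kidney, sp, np.zeros(3))
    tumor = LabelMask(d <= r_tumor, sp, np.zeros(3))
    return kidney, tumor


class TestRemovedRegion:
    def test_margin_below_voxel_step_returns_tumor_only(self):
        kidney, tumor = nested_spheres(spacing=1.0)
        removed = removed_region(kidney, tumor, margin=0.5)
        np.testing.assert_array_equal(removed.data, tumor.data)

    def test_nested_spheres_volume_matches_analytic(self):
        kidney, tumor = nested_spheres(spacing=0.5)
        removed = removed_region(kidney, tumor, margin=5.0)
        analytic = 4 / 3 * np.pi * 15.0**3
        assert abs(removed.volume_mm3() - analytic) / analytic <= 0.03

    def test_monotone_nesting_across_margins(self, small_phantom):
        _, masks, _ = small_phantom
        prev = None
        for m in (1.0, 2.5, 4.0):
            cur = removed_region(masks["kidney"], masks["tumor"], m).data
            if prev is not None:
                assert (prev <= cur).all()
            prev = cur

    def test_tumor_always_included_even_outside_kidney(self):
        kidney, tumor = nested_spheres(spacing=1.0)
        # shift tumor so it protrudes beyond the kidney (exophytic component)
        shifted = np.roll(tumor.data, 25, axis=0)
        tumor2 = kidney.like(shifted)
        removed = removed_region(kidney, tumor2, margin=2.0)
        assert (removed.data & tumor2.data).sum() == tumor2.data.sum()
        # domain bound: removed within kidney-union-tumor
        assert not (removed.data & ~(kidney.data | tumor2.data)).any()

    def test_empty_tumor_rejected(self):
        kidney, tumor = nested_spheres(spacing=1.0)
        with pytest.raises(ValueError, match="empty tumor"):
            removed_region(kidney, kidney.like(np.zeros_like(kidney.data)), 2.0)

    def test_misaligned_masks_rejected(self):
        kidney, tumor = nested_spheres(spacing=1.0)
        shifted = LabelMask(tumor.data, tumor.spacing, tumor.origin + 1.0)
        with pytest.raises(ValueError, match="misaligned"):
            removed_region(kidney, shifted, 2.0)


class TestResectionSurface:
    def test_interior_tumor_gives_closed_sphere_like_surface(self):
        kidney, tumor = nested_spheres(spacing=0.5)
        removed = removed_region(kidney, tumor, margin=5.0)
        surf = resection_surface(kidney, removed)
        assert surf.is_watertight()
        analytic_area = 4 * np.pi * 15.0**2
        assert abs(surf.area() - analytic_area) / analytic_area <= 0.05

    def test_protruding_tumor_capsule_faces_excluded(self):
        kidney, tumor = nested_spheres(spacing=1.0)
        tumor2 = kidney.like(np.roll(tumor.data, 25, axis=0))
        removed = removed_region(kidney, tumor2, margin=3.0)
        full = npl.extract_mesh(removed)
        surf = resection_surface(kidney, removed)
        assert 0 < surf.n_faces < full.n_faces

    def test_total_nephrectomy_has_empty_interface(self):
        kidney, _ = nested_spheres(spacing=1.0)
        with pytest.warns(UserWarning, match="empty"):
            surf = resection_surface(kidney, kidney)
        assert surf.is_empty()


class TestDetectOpening:
    def test_disjoint_masks_closed(self):
        a = LabelMask(np.zeros((6, 6, 6), dtype=bool))
        b = LabelMask(np.zeros((6, 6, 6), dtype=bool))
        a.data[1, 1, 1] = True
        b.data[4, 4, 4] = True
        res = detect_opening(a, b)
        assert not res.open and res.opening_voxel_count == 0
        assert res.opening_centroid is None and res.opening_extent is None

    def test_single_shared_voxel_centroid_and_zero_extent(self):
        tract = LabelMask(np.zeros((12, 12, 12), dtype=bool), (2, 1, 1), (0, 0, 0))
        removed = LabelMask(np.zeros((12, 12, 12), dtype=bool), (2, 1, 1), (0, 0, 0))
        tract.data[5, 5, 5] = True
        removed.data[5, 5, 5] = True
        removed.data[6, 5, 5] = True
        res = detect_opening(tract, removed)
        assert res.open and res.opening_voxel_count == 1
        np.testing.assert_allclose(res.opening_centroid, [10.0, 5.0, 5.0])
        assert res.opening_extent == 0.0

    def test_extent_is_max_pairwise_distance(self, rng):
        tract = LabelMask(np.zeros((20, 20, 20), dtype=bool))
        pts = rng.integers(0, 20, size=(30, 3))
        tract.data[tuple(pts.T)] = True
        res = detect_opening(tract, tract.like(np.ones_like(tract.data)))
        world = np.argwhere(tract.data).astype(float)
        brute = max(
            np.linalg.norm(p - q) for p in world for q in world
        )
        assert res.opening_extent == pytest.approx(brute)

    def test_opening_centroid_near_analytic_closest_point(self, small_phantom):
        """Tube passing 2.5 mm from the tumor: margin 4 opens the tract near
        the analytic closest point on the tube surface."""
        vol, masks, gap = small_phantom
        dist = distance_from_mask(masks["tumor"])
        open_margin = None
        for m in (1.0, 2.0, 3.0, 4.0, 5.0):
            removed = removed_region(masks["kidney"], masks["tumor"], m, dist)
            res = detect_opening(masks["tract"], removed)
            if res.open:
                open_margin = m
                break
        assert open_margin is not None
        # analytic closest point: tumor center (46,28,25), tube axis x=32.5,
        # z=25 -> closest tube-surface point at (34.5, 28, 25)
        np.testing.assert_allclose(
            res.opening_centroid, [34.5, 28.0, 25.0], atol=2 * VOXEL_DIAG
        )


class TestPlanAllMargins:
    def test_gap_2p5_phantom_report(self, small_phantom):
        vol, masks, gap = small_phantom
        assert gap == pytest.approx(2.5)
        plans, report = plan_all_margins(
            masks["kidney"], masks["tumor"], masks["tract"], ct=vol
        )
        # voxel-center metric overestimates the analytic 2.5 mm gap by at
        # most one voxel diagonal
        assert 2.5 <= report.min_tract_distance <= 2.5 + VOXEL_DIAG
        expected = next(m for m in (1, 2, 3, 4, 5) if report.min_tract_distance <= m)
        assert report.min_opening_margin == expected
        assert 3 <= report.min_opening_margin <= 4
        assert report.status_text == (
            f"Open with {report.min_opening_margin:.0f} mm margin"
        )

    def test_far_tract_not_open_sentinel(self, small_spec):
        spec = dataclasses.replace(
            small_spec,
            tract_polyline=((16.0, 14.0, 23.0), (25.0, 20.0, 25.0),
                            (25.0, 36.0, 25.0), (16.0, 42.0, 27.0)),
        )
        _, masks, gap = npl.generate_phantom(spec)
        assert gap > 5.0 + VOXEL_DIAG
        _, report = plan_all_margins(masks["kidney"], masks["tumor"], masks["tract"])
        assert report.min_opening_margin is None
        assert report.status_text == "Not open with 5 mm margin"

    def test_tract_touching_tumor_opens_at_first_margin(self, small_phantom):
        _, masks, _ = small_phantom
        touching = masks["tract"].like(
            np.roll(masks["tract"].data, 10, axis=0)  # push tube into tumor
        )
        if not (touching.data & masks["tumor"].data).any():
            pytest.skip("roll did not reach the tumor")
        with pytest.warns(UserWarning, match="inside the tumor"):
            _, report = plan_all_margins(masks["kidney"], masks["tumor"], touching)
        assert report.min_opening_margin == 1.0
        assert report.min_tract_distance == 0.0

    def test_open_status_monotone_and_consistent(self, small_phantom):
        _, masks, _ = small_phantom
        _, report = plan_all_margins(masks["kidney"], masks["tumor"], masks["tract"])
        flags = [m.open for m in report.per_margin]
        assert flags == sorted(flags)
        for m in report.per_margin:
            assert m.open == (report.min_tract_distance <= m.margin)

    def test_per_margin_regions_match_independent_recomputation(self, small_phantom):
        _, masks, _ = small_phantom
        plans, _ = plan_all_margins(masks["kidney"], masks["tumor"], masks["tract"])
        for plan in plans:
            indep = removed_region(masks["kidney"], masks["tumor"], plan.margin)
            np.testing.assert_array_equal(plan.removed_region.data, indep.data)
            # plan invariants: tumor within removed within kidney-union-tumor
            assert (masks["tumor"].data <= plan.removed_region.data).all()
            assert (
                plan.removed_region.data
                <= (masks["kidney"].data | masks["tumor"].data)
            ).all()
            np.testing.assert_array_equal(
                plan.remnant_kidney.data,
                masks["kidney"].data & ~plan.removed_region.data,
            )

    def test_min_margin_equals_brute_force_on_small_grids(self, rng):
        """Schedule answer == smallest margin >= brute-force pairwise distance."""
        for _ in range(5):
            shape = (20, 20, 20)
            sp = rng.choice([0.5, 1.0, 1.5], size=3)
            kidney = LabelMask(np.ones(shape, dtype=bool), sp, (0, 0, 0))
            tumor = kidney.like(np.zeros(shape, dtype=bool))
            tract = kidney.like(np.zeros(shape, dtype=bool))
            tumor.data[4:8, 4:8, 4:8] = True
            i, j, k = rng.integers(10, 18, size=3)
            tract.data[i : i + 2, j : j + 2, k : k + 2] = True
            _, report = plan_all_margins(kidney, tumor, tract)
            tv = np.argwhere(tumor.data) * sp
            uv = np.argwhere(tract.data) * sp
            brute = min(
                np.linalg.norm(t - u) for t in tv for u in uv
            )
            assert report.min_tract_distance == pytest.approx(brute, abs=1e-9)
            expected = next((m for m in (1, 2, 3, 4, 5) if brute <= m), None)
            assert report.min_opening_margin == expected

    def test_resection_surface_ct_values_mark_the_opening(self, small_phantom):
        """Vertices of the cut surface inside the tract carry contrast-level
        CT values (> clinical threshold range); parenchyma vertices do not."""
        vol, masks, _ = small_phantom
        plans, report = plan_all_margins(
            masks["kidney"], masks["tumor"], masks["tract"],
            MarginSchedule((5.0,)), ct=vol,
        )
        surf = plans[0].resection_surface
        assert surf.vertex_scalars is not None
        depth_in_tract = npl.mesh_geometry.sample_mask_depth(
            masks["tract"], surf.vertices
        )
        inside_tract = depth_in_tract > 0.8
        assert inside_tract.any()
        assert (surf.vertex_scalars[inside_tract] > 420).mean() > 0.9
        far = depth_in_tract == 0
        assert (surf.vertex_scalars[far] < 350).mean() > 0.9
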