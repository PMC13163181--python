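"""Scene simulator contracts: placement, rendering, dataset generation."""

import math

import numpy as np
import pytest

import polypcam as pc
from polypcam.simulator import (
    DEPTH_BIN_RANGES_MM,
    FovCell,
    PlacementSpec,
    PolypSpec,
    generate_dataset,
    make_scene_sample,
    place_camera,
    place_polyp,
    silhouette_boundary_points,
)
from polypcam.geometry import build_colon


# ------------------------------------------------------------------- specs


def test_polyp_spec_validation():
    with pytest.raises(ValueError):
        PolypSpec(max_diameter_mm=1.0)
    with pytest.raises(ValueError):
        PolypSpec(max_diameter_mm=20.0)
    with pytest.raises(ValueError):
        PolypSpec(max_diameter_mm=6.0, morphology="flat", cap_height_mm=4.0)


def test_placement_depth_bin_ranges(rng):
    for bin_name, (lo, hi) in DEPTH_BIN_RANGES_MM.items():
        p = PlacementSpec(depth_bin=bin_name)
        for _ in range(20):
            assert lo <= p.sample_depth(rng) <= hi
    with pytest.raises(ValueError):
        PlacementSpec(depth_bin="medium", depth_mm=40.0)


# ------------------------------------------------------------- place_polyp


def test_sessile_polyp_has_exact_diameter():
    colon = build_colon(radius_mm=20.0)
    scene, centre = place_polyp(colon, PolypSpec(8.0, "sessile"), wall_z_mm=80.0)
    sph = scene.polyp_primitives[0]
    assert sph.radius_mm * 2 == pytest.approx(8.0, abs=0.05)
    assert np.linalg.norm(np.asarray(sph.centre) - centre) < 1e-9


def test_flat_cap_protrusion_height():
    colon = build_colon(radius_mm=20.0)
    h = 1.0
    scene, centre = place_polyp(
        colon, PolypSpec(6.0, "flat", cap_height_mm=h), wall_z_mm=80.0, wall_angle_rad=0.3
    )
    sph = scene.polyp_primitives[0]
    tube = colon.tube
    # protrusion: sphere reaches h into the lumen at the anchor azimuth
    reach = tube.radius_mm - (np.hypot(sph.centre[0], sph.centre[1]) - sph.radius_mm)
    assert reach == pytest.approx(h, abs=1e-9)


def test_pedunculated_head_offset_along_normal():
    colon = build_colon(radius_mm=20.0)
    stalk = 4.0
    scene, centre = place_polyp(
        colon, PolypSpec(8.0, "pedunculated", stalk_length_mm=stalk), wall_z_mm=80.0
    )
    head = scene.polyp_primitives[-1]
    anchor = colon.tube.wall_point(80.0, 0.0)
    n_in = colon.tube.inward_normal(80.0, 0.0)
    expected = anchor + (stalk + 4.0) * n_in
    assert np.asarray(head.centre) == pytest.approx(expected, abs=1e-9)


def test_polyp_larger_than_lumen_rejected():
    colon = build_colon(radius_mm=10.0)
    with pytest.raises(ValueError):
        place_polyp(colon, PolypSpec(16.0, "sessile"))


# ------------------------------------------------------------ place_camera


@pytest.mark.parametrize("cell", ["center", "top-left", "bottom-right", "middle-left"])
def test_polyp_projects_into_requested_cell(cell, fisheye_camera):
    sample = make_scene_sample(
        PolypSpec(7.0, "sessile", polyp_id="c"),
        PlacementSpec(cell, "medium"),
        fisheye_camera,
        seed=21,
    )
    det = pc.detect_from_mask(sample.polyp_mask)
    row, col = FovCell(cell).grid_rc
    w3 = fisheye_camera.image_width_px / 3
    h3 = fisheye_camera.image_height_px / 3
    cx, cy = det.centroid
    # allow a small spill: the cell constrains the polyp-centre projection,
    # the silhouette centroid can shift slightly
    assert col * w3 - 8 <= cx <= (col + 1) * w3 + 8
    assert row * h3 - 8 <= cy <= (row + 1) * h3 + 8


def test_realised_depth_within_bin(fisheye_camera):
    for seed in range(3):
        s = make_scene_sample(
            PolypSpec(6.0, "sessile", polyp_id="d"),
            PlacementSpec("center", "medium"),
            fisheye_camera,
            seed=seed,
        )
        assert 15.0 <= s.depth_mm <= 35.0
        # realised camera-to-centre distance matches the request
        d = np.linalg.norm(s.pose.position - s.polyp_center)
        assert d == pytest.approx(s.depth_mm, abs=0.1)


def test_distinct_seeds_distinct_poses(fisheye_camera):
    spec = PolypSpec(6.0, "sessile", polyp_id="j")
    place = PlacementSpec("center", "medium")
    s1 = make_scene_sample(spec, place, fisheye_camera, seed=1)
    s2 = make_scene_sample(spec, place, fisheye_camera, seed=2)
    assert not np.allclose(s1.pose.position, s2.pose.position)


# ------------------------------------------------------------------ render


def test_depth_mask_consistency(fisheye_camera):
    """min depth over the mask + polyp radius ~ camera-to-centre distance."""
    for seed in (3, 4):
        s = make_scene_sample(
            PolypSpec(9.0, "sessile", polyp_id="k"),
            PlacementSpec("center", "medium"),
            fisheye_camera,
            seed=seed,
        )
        d_min = s.depth_gt.values_mm[s.polyp_mask].min()
        assert d_min + 4.5 == pytest.approx(s.depth_mm, abs=0.5)


def test_projected_sphere_extent_oracle(hemisphere_sample, pinhole_camera):
    """On-axis pinhole silhouette extent equals 2 f r / sqrt(d^2 - r^2)."""
    det = pc.detect_from_mask(hemisphere_sample.polyp_mask)
    f = pinhole_camera.focal_length_px
    expected = 2 * f * 4.0 / math.sqrt(25.0**2 - 4.0**2)
    assert det.pixel_extent == pytest.approx(expected, abs=1.5)
    refined = pc.refine_silhouette_extent(hemisphere_sample, det)
    assert refined == pytest.approx(expected, abs=0.25)


def test_brightness_zero_blackout(pinhole_camera):
    spec = PolypSpec(8.0, "sessile", polyp_id="b")
    dark = make_scene_sample(
        spec, PlacementSpec("center", "medium", depth_mm=25.0, brightness=0.0), pinhole_camera, seed=7
    )
    lit = make_scene_sample(
        spec, PlacementSpec("center", "medium", depth_mm=25.0, brightness=1.0), pinhole_camera, seed=7
    )
    assert dark.rgb.max() == 0
    assert lit.rgb.max() > 0
    np.testing.assert_array_equal(dark.polyp_mask, lit.polyp_mask)
    np.testing.assert_array_equal(dark.depth_gt.values_mm, lit.depth_gt.values_mm)


def test_equidistant_compresses_off_axis_extent():
    """Peripheral objects image smaller under r = f·θ than under r = f·tanθ."""
    spec = PolypSpec(8.0, "sessile", polyp_id="p")
    place = PlacementSpec("top-left", "medium", depth_mm=20.0)
    cam_eq = pc.CameraModel.for_fov(100.0, "equidistant", width=256, height=256, fov_normal_deg=100.0)
    cam_pin = pc.CameraModel.for_fov(
        100.0, "pinhole", width=256, height=256, fov_fisheye_deg=170.0
    )
    s_eq = make_scene_sample(spec, place, cam_eq, seed=13)
    s_pin = make_scene_sample(spec, place, cam_pin, seed=13)
    e_eq = pc.detect_from_mask(s_eq.polyp_mask).pixel_extent
    e_pin = pc.detect_from_mask(s_pin.polyp_mask).pixel_extent
    assert e_eq < e_pin


def test_background_is_invalid_not_zero_distance(fisheye_camera):
    s = make_scene_sample(
        PolypSpec(6.0, "sessile", polyp_id="m"),
        PlacementSpec("center", "far"),
        fisheye_camera,
        seed=5,
    )
    assert np.all(s.depth_gt.values_mm[s.depth_gt.valid] > 0)


# -------------------------------------------------------- generate_dataset


def test_dataset_counts_and_manifest():
    polyps = [PolypSpec(4.0 + i, "sessile", polyp_id=f"P{i}") for i in range(3)]
    placements = [PlacementSpec("center", "medium"), PlacementSpec("top-left", "medium")]
    cam = pc.CameraModel.for_fov(170.0, "equidistant", width=128, height=128)
    samples, manifest = generate_dataset(polyps, placements, reps_per_config=2, seed=3, camera=cam)
    assert len(samples) == 3 * 2 * 2
    assert len(manifest) == 12
    assert set(manifest.columns) >= {"polyp_id", "true_size_mm", "depth_bin", "fov_cell", "brightness", "seed"}


def test_dataset_seed_determinism():
    polyps = [PolypSpec(6.0, "sessile", polyp_id="A")]
    placements = [PlacementSpec("center", "medium")]
    cam = pc.CameraModel.for_fov(170.0, "equidistant", width=128, height=128)
    _, m1 = generate_dataset(polyps, placements, reps_per_config=3, seed=9, camera=cam)
    s2, m2 = generate_dataset(polyps, placements, reps_per_config=3, seed=9, camera=cam)
    assert m1.equals(m2)
    s3, m3 = generate_dataset(polyps, placements, reps_per_config=3, seed=10, camera=cam)
    assert not m1.depth_mm.equals(m3.depth_mm)


def test_dataset_rejects_duplicate_ids():
    polyps = [PolypSpec(6.0, polyp_id="X"), PolypSpec(8.0, polyp_id="X")]
    with pytest.raises(ValueError):
        generate_dataset(polyps, [PlacementSpec()], seed=0)


def test_resolution_invariance_of_mask_extent():
    """Halving resolution and focal length together halves the extent."""
    spec = PolypSpec(8.0, "sessile", polyp_id="r")
    place = PlacementSpec("center", "medium", depth_mm=25.0)
    cam_hi = pc.CameraModel.for_fov(60.0, "pinhole", width=512, height=512)
    cam_lo = pc.CameraModel.for_fov(60.0, "pinhole", width=256, height=256)
    e_hi = pc.detect_from_mask(make_scene_sample(spec, place, cam_hi, seed=6).polyp_mask).pixel_extent
    e_lo = pc.detect_from_mask(make_scene_sample(spec, place, cam_lo, seed=6).polyp_mask).pixel_extent
    assert e_hi / 2 == pytest.approx(e_lo, abs=1.0)
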