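"""Measure a single synthetic polyp and walk through the sizing chain.

Renders an 8 mm sessile polyp at 25 mm under a 170° fish-eye endoscope
camera, detects it from its silhouette mask, and runs the depth-based
sizing: distance from the depth map, fish-eye-corrected pixel extent,
triangle-similarity size, and the polyp-thickness correction.
"""

import polypcam as pc

camera = pc.CameraModel.for_fov(170.0, "equidistant", width=256, height=256)
sample = pc.make_scene_sample(
    pc.PolypSpec(max_diameter_mm=8.0, morphology="sessile", polyp_id="demo"),
    pc.PlacementSpec(fov_cell="center", depth_bin="medium", depth_mm=25.0),
    camera,
    seed=11,
)

detection = pc.detect_from_mask(sample.polyp_mask)
estimate = pc.measure_polyp(detection, sample.depth_gt, camera, depth_statistic="min")

print(f"true diameter        : 8.00 mm at {sample.depth_mm:.1f} mm")
print(f"pixel extent         : {estimate.obj_pixel:.1f} px (raw Feret)")
print(f"corrected extent     : {estimate.obj_pixel_corrected:.1f} px (angular Feret)")
print(f"surface distance     : {estimate.obj_distance_mm:.2f} mm (region minimum)")
print(f"initial size         : {estimate.size_initial_mm:.2f} mm (triangle similarity)")
print(f"estimated radius     : {estimate.obj_radius_mm:.2f} mm")
print(f"final size           : {estimate.size_final_mm:.2f} mm (thickness-corrected)")
print()
print(
    "The initial size uses the distance to the polyp's near surface and "
    "underestimates; adding the estimated radius recovers the distance to "
    "the polyp body and brings the final size close to the true 8 mm."
)
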