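"""Depth-bin × FOV-cell measurement campaign at desk scale.

Measures five polyps (4–11 mm) at three lens-to-polyp distance bins
(near < 15 mm, medium 15–35 mm, far > 35 mm) and nine field-of-view
positions, twice per condition in each of two sessions, using a depth
provider whose noise is calibrated to 7.9% average relative error.
Prints the per-bin summary table and the 27-cell PE landscape.
"""

import polypcam as pc
from polypcam.harness import ExperimentConfig, grid_tables, run_grid_experiment

config = ExperimentConfig(seed=42)
result = run_grid_experiment(config)

tables = grid_tables(result)
cols = ["stratum", "n", "pe_mean", "pe_q1", "pe_q3", "ccc", "icc"]
print("--- by depth bin ---")
print(tables["by_depth"][cols].round(2).to_string(index=False))
print()
print("--- mean PE (%) per depth bin x FOV cell ---")
grid = result["measurements"].groupby(["depth_bin", "fov_cell"]).pe.mean().unstack()
print(grid.round(1).to_string())
print()
best = result["measurements"].groupby(["depth_bin", "fov_cell"]).pe.mean().idxmin()
print(f"lowest-PE cell this run: {best[0]} depth, {best[1]} FOV")
print(
    "Medium distance and the centre FOV tend to measure best: close polyps "
    "suffer thickness-correction bias, far ones pixel quantisation, and "
    "peripheral positions carry larger depth-prediction error."
)
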