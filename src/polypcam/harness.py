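"""Experiment orchestration: the two validation campaigns.

* :func:`run_mds_sweep` — the virtual-model-style sweep: a roster of
  polyps, many images each with varying brightness and position, pooled
  agreement statistics plus per-size-category breakdowns.
* :func:`run_grid_experiment` — the repeated-measurement design: every
  polyp measured at 3 depth bins × 9 FOV cells, twice per condition, in
  two sessions, with per-bin / per-cell / per-(bin×cell) agreement
  reports and the between-session ICC.
* :func:`compare_depth_reference` — depth-distance accuracy at the
  centre FOV against a graduated-instrument-style reference (quantised
  true distance).

Repeat sessions re-draw placement jitter and depth noise from
session-specific seeds, mirroring a measurement campaign repeated at a
later date on the same physical targets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .camera import CameraModel, FisheyeMode, Projection, SizeEstimate, measure_polyp
from .depth import DepthMap, NoiseKind, NoiseModel, calibrate_sigma, noisy_depth, perfect_depth
from .detection import Detection, detect_from_mask
from .metrics import (
    AgreementReport,
    PairedMeasurements,
    agreement_report,
    percentage_and_measurement_error,
)
from .simulator import (
    DEPTH_BIN_RANGES_MM,
    DepthBin,
    FovCell,
    Morphology,
    PlacementSpec,
    PolypSpec,
    SceneSample,
    make_scene_sample,
)

__all__ = [
    "ExperimentConfig",
    "default_grid_roster",
    "default_mds_roster",
    "measure_sample",
    "run_mds_sweep",
    "run_grid_experiment",
    "compare_depth_reference",
]


def default_grid_roster(n: int = 5) -> list[PolypSpec]:
    """Sessile polyps spanning the 4–11 mm phantom size range."""
    sizes = np.linspace(4.0, 11.0, n)
    return [
        PolypSpec(max_diameter_mm=float(s), morphology=Morphology.SESSILE, polyp_id=f"G{i:02d}")
        for i, s in enumerate(sizes)
    ]


def default_mds_roster(n: int = 15) -> list[PolypSpec]:
    """Pedunculated/flat polyps spanning the 2–16 mm virtual-model range."""
    sizes = np.linspace(2.0, 16.0, n)
    roster = []
    for i, s in enumerate(sizes):
        if i % 2 == 0:
            spec = PolypSpec(
                max_diameter_mm=float(s),
                morphology=Morphology.PEDUNCULATED,
                stalk_length_mm=min(5.0, 1.0 + s / 3),
                polyp_id=f"M{i:02d}",
            )
        else:
            spec = PolypSpec(
                max_diameter_mm=float(s),
                morphology=Morphology.FLAT,
                cap_height_mm=min(1.5, 0.35 * s),
                polyp_id=f"M{i:02d}",
            )
        roster.append(spec)
    return roster


@dataclass
class ExperimentConfig:
    """Configuration shared by both campaigns.

    Defaults are the desk-scale study conditions: 5 sessile polyps of
    4–11 mm, all 27 depth-bin × FOV-cell conditions, 2 repetitions per
    condition, 2 sessions, a 256×256 equidistant 170° camera, and a
    noisy depth provider calibrated to 7.9% whole-image ARE with
    low-frequency spatial structure and peripheral error growth.
    """

    polyps: Sequence[PolypSpec] = field(default_factory=default_grid_roster)
    depth_bins: Sequence[DepthBin] = (DepthBin.NEAR, DepthBin.MEDIUM, DepthBin.FAR)
    fov_cells: Sequence[FovCell] = tuple(FovCell)
    reps_per_condition: int = 2
    sessions: int = 2
    seed: int = 0
    camera: Optional[CameraModel] = None
    depth_provider: str = "noisy"  # "perfect" | "noisy"
    target_are_pct: float = 7.9
    noise_kind: NoiseKind = NoiseKind.LOW_FREQUENCY_FIELD
    noise_correlation_px: float = 64.0
    noise_radial_growth: float = 2.0
    noise_depth_growth: float = 1.0
    noise_depth_opt_mm: float = 25.0
    noise_depth_scale_mm: float = 20.0
    depth_statistic: str = "min"
    fisheye_mode: Optional[str] = None  # None -> projection-appropriate default
    tube_radius_mm: float = 20.0
    brightness_levels: Sequence[float] = (0.6, 1.0, 1.4)
    forceps_quantum_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.sessions < 1:
            raise ValueError("sessions must be >= 1")
        if self.reps_per_condition < 1:
            raise ValueError("reps_per_condition must be >= 1")
        if self.camera is None:
            self.camera = CameraModel.for_fov(170.0, Projection.EQUIDISTANT)
        self.depth_bins = tuple(DepthBin(b) for b in self.depth_bins)
        self.fov_cells = tuple(FovCell(c) for c in self.fov_cells)

    def noise_model(self) -> Optional[NoiseModel]:
        if self.depth_provider == "perfect":
            return None
        sigma = calibrate_sigma(
            self.target_are_pct,
            kind=self.noise_kind,
            radial_growth=self.noise_radial_growth,
            depth_growth=self.noise_depth_growth,
            depth_opt_mm=self.noise_depth_opt_mm,
            depth_scale_mm=self.noise_depth_scale_mm,
            shape=(self.camera.image_height_px, self.camera.image_width_px),
        )
        return NoiseModel(
            kind=self.noise_kind,
            sigma=sigma,
            correlation_px=self.noise_correlation_px,
            radial_growth=self.noise_radial_growth,
            depth_growth=self.noise_depth_growth,
            depth_opt_mm=self.noise_depth_opt_mm,
            depth_scale_mm=self.noise_depth_scale_mm,
        )


def _sample_seed(base: int, *keys: int) -> int:
    return int(np.random.SeedSequence((base, *keys)).generate_state(1)[0] % (2**31 - 1))


def measure_sample(
    sample: SceneSample,
    noise: Optional[NoiseModel] = None,
    noise_rng: Optional[np.random.Generator] = None,
    depth_statistic: str = "min",
    fisheye_mode: Optional[str] = None,
) -> tuple[SizeEstimate, Detection]:
    """Detect from the mask, predict depth, run the sizing chain."""
    det = detect_from_mask(sample.polyp_mask)
    if noise is None:
        depth = perfect_depth(sample)
    else:
        depth = noisy_depth(sample.depth_gt, noise, rng=noise_rng)
    est = measure_polyp(
        det,
        depth,
        sample.camera,
        fisheye_mode=fisheye_mode,
        depth_statistic=depth_statistic,
    )
    return est, det


def _measure_conditions(
    config: ExperimentConfig,
    conditions: Sequence[tuple[PolypSpec, PlacementSpec]],
    session: int,
) -> pd.DataFrame:
    """Render and measure every condition × rep for one session."""
    noise = config.noise_model()
    rows = []
    for idx, (polyp, placement) in enumerate(conditions):
        for rep in range(config.reps_per_condition):
            s = _sample_seed(config.seed, session, idx, rep)
            sample = make_scene_sample(
                polyp, placement, config.camera, seed=s, tube_radius_mm=config.tube_radius_mm
            )
            noise_rng = np.random.default_rng(_sample_seed(config.seed, session, idx, rep, 7)) if noise else None
            est, det = measure_sample(
                sample,
                noise=noise,
                noise_rng=noise_rng,
                depth_statistic=config.depth_statistic,
                fisheye_mode=config.fisheye_mode,
            )
            rows.append(
                {
                    "session": session,
                    "polyp_id": polyp.polyp_id,
                    "true_size_mm": polyp.max_diameter_mm,
                    "morphology": polyp.morphology.value,
                    "depth_bin": placement.depth_bin.value,
                    "fov_cell": placement.fov_cell.value,
                    "brightness": placement.brightness,
                    "rep": rep,
                    "depth_mm": sample.depth_mm,
                    "obj_pixel": est.obj_pixel,
                    "obj_pixel_corrected": est.obj_pixel_corrected,
                    "obj_distance_mm": est.obj_distance_mm,
                    "size_initial_mm": est.size_initial_mm,
                    "obj_radius_mm": est.obj_radius_mm,
                    "size_mm": est.size_final_mm,
                    "truncated": est.truncated,
                    "seed": s,
                }
            )
    df = pd.DataFrame(rows)
    df["pe"] = (df.size_mm - df.true_size_mm).abs() / df.true_size_mm * 100.0
    df["me_mm"] = df.size_mm - df.true_size_mm
    return df


def _report_for(df: pd.DataFrame, sessions: int) -> AgreementReport:
    """Agreement report pooling all rows; ICC across sessions when 2."""
    s1 = df[df.session == 1].sort_values(["polyp_id", "depth_bin", "fov_cell", "rep"])
    pairs1 = PairedMeasurements(s1.size_mm.to_numpy(), s1.true_size_mm.to_numpy())
    if sessions >= 2:
        s2 = df[df.session == 2].sort_values(["polyp_id", "depth_bin", "fov_cell", "rep"])
        pairs2 = PairedMeasurements(s2.size_mm.to_numpy(), s2.true_size_mm.to_numpy())
        return agreement_report(pairs1, session2=pairs2)
    return agreement_report(pairs1)


def run_grid_experiment(config: ExperimentConfig) -> dict:
    """The depth-bin × FOV-cell repeated-measurement campaign.

    Returns a dict with the measurement table and agreement reports
    keyed ``total``, ``bin:<near|medium|far>``, ``cell:<name>``, and
    ``grid:<bin>:<cell>``.  Reports pool both sessions; the ICC in each
    report compares the two sessions on identical targets.
    """
    if config.sessions < 2:
        raise ValueError("the grid experiment needs 2 sessions for the ICC")
    conditions = [
        (polyp, PlacementSpec(fov_cell=cell, depth_bin=bin_))
        for polyp in config.polyps
        for bin_ in config.depth_bins
        for cell in config.fov_cells
    ]
    frames = [
        _measure_conditions(config, conditions, session)
        for session in range(1, config.sessions + 1)
    ]
    df = pd.concat(frames, ignore_index=True)

    reports: dict[str, AgreementReport] = {"total": _report_for(df, config.sessions)}
    for bin_ in config.depth_bins:
        reports[f"bin:{bin_.value}"] = _report_for(df[df.depth_bin == bin_.value], config.sessions)
    for cell in config.fov_cells:
        reports[f"cell:{cell.value}"] = _report_for(df[df.fov_cell == cell.value], config.sessions)
    for bin_ in config.depth_bins:
        for cell in config.fov_cells:
            sub = df[(df.depth_bin == bin_.value) & (df.fov_cell == cell.value)]
            reports[f"grid:{bin_.value}:{cell.value}"] = _report_for(sub, config.sessions)
    return {"measurements": df, "reports": reports}


def grid_tables(result: dict) -> dict[str, pd.DataFrame]:
    """Flatten grid-experiment reports into publication-shaped tables.

    ``by_depth`` has rows near/medium/far/total; ``by_cell`` the nine
    FOV cells + total; ``grid`` the 27 bin × cell combinations.
    """
    reports: dict[str, AgreementReport] = result["reports"]

    def rows(prefix: str, names: list[str]) -> pd.DataFrame:
        out = []
        for name in names:
            rep = reports[f"{prefix}{name}"] if name != "total" else reports["total"]
            row = rep.to_csv_row()
            row.insert(0, "stratum", name)
            out.append(row)
        return pd.concat(out, ignore_index=True)

    by_depth = rows("bin:", [b.value for b in DepthBin] + ["total"])
    by_cell = rows("cell:", [c.value for c in FovCell] + ["total"])
    grid = rows("grid:", [k[len("grid:"):] for k in reports if k.startswith("grid:")])
    return {"by_depth": by_depth, "by_cell": by_cell, "grid": grid}


def run_mds_sweep(config: ExperimentConfig, images_per_polyp: int = 10) -> dict:
    """Virtual-model-style sweep: many images per polyp, varied
    brightness and position, pooled agreement statistics.

    Positions are drawn uniformly over the 9 FOV cells and the three
    depth bins; brightness cycles through ``config.brightness_levels``.
    """
    if images_per_polyp < 1:
        raise ValueError("images_per_polyp must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 101)))
    cells = list(FovCell)
    bins = list(DepthBin)
    conditions = []
    for polyp in config.polyps:
        for j in range(images_per_polyp):
            placement = PlacementSpec(
                fov_cell=cells[rng.integers(len(cells))],
                depth_bin=bins[rng.integers(len(bins))],
                brightness=config.brightness_levels[j % len(config.brightness_levels)],
            )
            conditions.append((polyp, placement))
    one_shot = ExperimentConfig(**{**config.__dict__, "reps_per_condition": 1, "sessions": 1})
    df = _measure_conditions(one_shot, conditions, session=1)

    pairs = PairedMeasurements(df.size_mm.to_numpy(), df.true_size_mm.to_numpy())
    report = agreement_report(pairs)
    by_category = {}
    cats = {
        "lt5": df.true_size_mm < 5,
        "5to10": (df.true_size_mm >= 5) & (df.true_size_mm < 10),
        "ge10": df.true_size_mm >= 10,
    }
    for name, sel in cats.items():
        sub = df[sel]
        if len(sub) >= 2:
            by_category[name] = percentage_and_measurement_error(
                PairedMeasurements(sub.size_mm.to_numpy(), sub.true_size_mm.to_numpy())
            )
    return {"measurements": df, "report": report, "pe_by_category": by_category}


def compare_depth_reference(config: ExperimentConfig, reps: int = 2) -> dict:
    """Depth-distance accuracy at the centre FOV across the three bins.

    The system's depth reading is the thickness-corrected distance
    (near-surface depth + estimated radius); the reference emulates a
    graduated instrument reading of the true lens-to-polyp-centre
    distance, quantised to ``config.forceps_quantum_mm``.
    """
    noise = config.noise_model()
    q = config.forceps_quantum_mm
    rows = []
    for session in range(1, config.sessions + 1):
        for b_idx, bin_ in enumerate(config.depth_bins):
            for p_idx, polyp in enumerate(config.polyps):
                for rep in range(reps):
                    s = _sample_seed(config.seed, 500 + session, b_idx, p_idx, rep)
                    placement = PlacementSpec(fov_cell=FovCell.CENTER, depth_bin=bin_)
                    sample = make_scene_sample(
                        polyp, placement, config.camera, seed=s, tube_radius_mm=config.tube_radius_mm
                    )
                    noise_rng = np.random.default_rng(_sample_seed(config.seed, 600 + session, b_idx, p_idx, rep)) if noise else None
                    est, _ = measure_sample(
                        sample,
                        noise=noise,
                        noise_rng=noise_rng,
                        depth_statistic=config.depth_statistic,
                        fisheye_mode=config.fisheye_mode,
                    )
                    d_cam = est.obj_distance_mm + est.obj_radius_mm
                    d_ref = round(sample.depth_mm / q) * q if q > 0 else sample.depth_mm
                    rows.append(
                        {
                            "session": session,
                            "polyp_id": polyp.polyp_id,
                            "depth_bin": bin_.value,
                            "depth_true_mm": sample.depth_mm,
                            "depth_cam_mm": d_cam,
                            "depth_ref_mm": d_ref,
                        }
                    )
    df = pd.DataFrame(rows)
    df["pe_depth"] = (df.depth_cam_mm - df.depth_ref_mm).abs() / df.depth_ref_mm * 100.0
    df["me_depth_mm"] = df.depth_cam_mm - df.depth_ref_mm
    summary = {"total": _depth_summary(df)}
    for bin_ in config.depth_bins:
        summary[bin_.value] = _depth_summary(df[df.depth_bin == bin_.value])
    return {"measurements": df, "summary": summary}


def _depth_summary(df: pd.DataFrame) -> dict:
    q1, q3 = np.quantile(df.pe_depth, [0.25, 0.75])
    return {
        "n": int(len(df)),
        "pe_mean": float(df.pe_depth.mean()),
        "pe_iqr": (float(q1), float(q3)),
        "me_mean_mm": float(df.me_depth_mm.mean()),
    }
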