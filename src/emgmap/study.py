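"""Multi-subject simulated studies mirroring the experimental protocol.

Two study designs: a wrist flexion/extension study in two hand positions
(prone vs neutral) that quantifies module-map displacement and amplitude
ratios, and a single-finger study that quantifies the spatial separability
of per-finger activity areas.  Each simulated subject gets its own generator
seed; analysis parameters are shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import synthetic
from .nnmf import classify_modules, fit_nnmf, select_module_count
from .pipeline import (
    TaskResult,
    _fit_on_tasks,
    condition_comparison,
    finger_separability,
    main_cluster,
    match_modules,
    module_maps,
    process_task,
)
from .segmentation import cog_shift, weight_ratio

__all__ = ["WristSubjectResult", "wrist_study", "finger_study", "median_cmc_active"]


def median_cmc_active(task: TaskResult) -> float:
    """Median CMC over channels whose envelope peak exceeds 2x the noise floor."""
    if not task.active_mask.any():
        raise ValueError("no active channels")
    return float(np.median(task.cmc_per_channel[task.active_mask]))


@dataclass
class WristSubjectResult:
    """Per-subject outcome of the two-position wrist study."""

    seed: int
    vaf3: float  # VAF of the N=3 factorization, neutral position
    median_cmc: float
    n_star: int | None  # selected module count (when requested)
    vaf_curve: dict[int, float] = field(default_factory=dict)
    shift_extensor: float = np.nan  # ulnar-radial COG shift, IED (planted shift run)
    ratio_extensor: float = np.nan  # prone/neutral barycenter ratio (no-shift run)
    ratio_flexor: float = np.nan


def _decompose(task: TaskResult, n_modules: int, n_restarts: int, seed: int):
    dec, _ = _fit_on_tasks(
        {"wrist_flex_ext": task}, n_modules=n_modules,
        n_restarts=n_restarts, seed=seed,
    )
    return dec


def wrist_study(
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8),
    n_restarts: int = 20,
    analysis_seed: int = 1,
    condition_shift_x: float = 0.8,
    select_modules: bool = False,
) -> list[WristSubjectResult]:
    """Run the wrist flexion/extension study over simulated subjects.

    Per subject: the neutral-position recording is processed and factorized
    (N = 3, best of ``n_restarts``); the prone recording with the planted
    ulnar--radial displacement gives the matched extensor-module COG shift;
    a second prone recording with zero displacement (gains only) gives the
    prone/neutral barycenter-weight ratios of the extensor and flexor
    modules.  With ``select_modules`` the module count is additionally
    selected over 1..10 on the neutral data.
    """
    results = []
    for seed in seeds:
        cfg = synthetic.wrist_config(seed, condition_shift_x=condition_shift_x)
        sim_n = synthetic.simulate_recording(cfg, "neutral")
        task_n = process_task(sim_n.emg, sim_n.angle_raw, sim_n.kinematics_fs)
        dec_n = _decompose(task_n, 3, n_restarts, analysis_seed)
        res = WristSubjectResult(
            seed=seed,
            vaf3=dec_n.vaf,
            median_cmc=median_cmc_active(task_n),
            n_star=None,
        )
        if select_modules:
            bad = task_n.bad_mask
            M = task_n.mean_env[~bad]
            M = M[M.max(axis=1) > 0]
            n_star, curve, _ = select_module_count(
                M, n_restarts=n_restarts, seed=analysis_seed
            )
            res.n_star = n_star
            res.vaf_curve = curve

        labels = classify_modules(dec_n.S, dec_n.A)
        grid = task_n.grid
        maps_n = module_maps(dec_n, grid)

        # planted-shift condition
        sim_p = synthetic.simulate_recording(cfg, "prone")
        task_p = process_task(sim_p.emg, sim_p.angle_raw, sim_p.kinematics_fs)
        dec_p = _decompose(task_p, 3, n_restarts, analysis_seed)
        matches = {i: j for i, j, _ in match_modules(dec_n, dec_p)}
        ext = labels.get("extensor")
        if ext is not None and ext in matches:
            maps_p = module_maps(dec_p, grid)
            cl_n = main_cluster(maps_n[ext])
            cl_p = main_cluster(maps_p[matches[ext]])
            if cl_n is not None and cl_p is not None:
                res.shift_extensor = cog_shift(cl_p, cl_n, axis="x")

        # zero-shift condition: gains only (the neutral leg is unchanged)
        cfg0 = synthetic.wrist_config(seed, condition_shift_x=0.0)
        sim_p0 = synthetic.simulate_recording(cfg0, "prone")
        task_p0 = process_task(sim_p0.emg, sim_p0.angle_raw, sim_p0.kinematics_fs)
        dec_p0 = _decompose(task_p0, 3, n_restarts, analysis_seed)
        matches0 = {i: j for i, j, _ in match_modules(dec_n, dec_p0)}
        maps_p0 = module_maps(dec_p0, grid)
        for label in ("extensor", "flexor"):
            i = labels.get(label)
            if i is None or i not in matches0:
                continue
            cl_n = main_cluster(maps_n[i])
            cl_p = main_cluster(maps_p0[matches0[i]])
            if cl_n is None or cl_p is None:
                continue
            try:
                ratio = weight_ratio(maps_p0[matches0[i]], cl_p.cog, maps_n[i], cl_n.cog)
            except ValueError:
                continue
            if label == "extensor":
                res.ratio_extensor = ratio
            else:
                res.ratio_flexor = ratio
        results.append(res)
    return results


def finger_study(
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8),
    n_restarts: int = 20,
) -> list[dict]:
    """Single-finger separability study over simulated subjects.

    Per subject, the four finger tasks are analyzed independently and the
    middle-finger extension cluster is compared against every other finger
    (overlap under both normalizations, COG distance in IED units).
    """
    out = []
    for seed in seeds:
        sep = finger_separability(seed, n_restarts=n_restarts)
        overlaps = sep["overlaps_vs_middle"]
        out.append({
            "seed": seed,
            "overlaps": overlaps,
            "all_overlap_values": [v for pair in overlaps.values() for v in pair],
            "min_cog_distance": min(sep["cog_distances_vs_middle"].values()),
            "median_cmc": sep["median_cmc_active"],
        })
    return out
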