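"""End-to-end analysis pipeline and condition comparisons.

Chains the stages -- simulate (or load), preprocess, cycle segmentation,
NNMF module extraction, map segmentation -- per subject and task, and
provides the higher-level comparisons the analysis is about: module matching
across hand positions, COG shifts, barycenter-weight ratios, finger
separability, and the ring-vs-COG electrode-subset regression comparison.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .cycles import (
    cmc,
    detect_cycles,
    exclude_outlier_cycles,
    mean_envelope,
    resample_sync,
    time_normalize,
)
from .grid import GridLayout
from .nnmf import (
    ModuleDecomposition,
    classify_modules,
    concatenate_tasks,
    fit_nnmf,
    module_similarity,
    select_module_count,
    subtract_baseline,
)
from .preprocess import preprocess_emg
from .recording import EmgRecording
from .segmentation import (
    ActivityCluster,
    CoefficientMap,
    cog_shift,
    overlap,
    segment_map,
    weight_ratio,
)

__all__ = [
    "TaskResult",
    "PipelineConfig",
    "process_task",
    "module_maps",
    "main_cluster",
    "match_modules",
    "condition_comparison",
    "finger_separability",
    "reconstruction_dataset",
    "run_pipeline",
]


@dataclass
class TaskResult:
    """Per-task products of the preprocessing and cycle stages."""

    mean_env_raw: np.ndarray  # channels x 500, before baseline removal
    mean_env: np.ndarray  # channels x 500, baseline-subtracted
    cmc_per_channel: np.ndarray
    active_mask: np.ndarray  # channels with peak envelope > 2x noise floor
    bad_mask: np.ndarray
    n_cycles_found: int
    n_cycles_kept: int
    excluded_fraction: float
    grid: GridLayout
    mean_angle: np.ndarray  # 500-point mean angle cycle
    env_ds: np.ndarray | None = None  # decimated envelope (channels x t)
    angle_ds: np.ndarray | None = None
    cycle_ids_ds: np.ndarray | None = None


def process_task(
    rec: EmgRecording,
    angle_raw: np.ndarray,
    kinematics_fs: float,
    delta: float = 2.0,
    n_points: int = 500,
    keep_envelope: bool = False,
    envelope_decimate: int = 32,
) -> TaskResult:
    """Preprocess one task recording and segment it into normalized cycles.

    Band-pass, power-line removal, envelope extraction and bad-channel
    masking; cycle detection on the resampled joint angle (2 deg rule),
    range-of-motion outlier exclusion (Tukey fences), 500-point time
    normalization; per-channel CMC over kept cycles; mean envelope with
    noise-floor baseline removed.  ``active_mask`` marks channels whose mean
    envelope peak exceeds twice the grid noise floor (the median per-channel
    5th-percentile envelope).
    """
    env = preprocess_emg(rec)
    trace = resample_sync(angle_raw, kinematics_fs, rec.fs)
    n = min(trace.angle.size, env.env.shape[1])
    trace.angle = trace.angle[:n]
    env.env = env.env[:, :n]

    cycles = detect_cycles(trace, delta=delta)
    cycles = exclude_outlier_cycles(cycles)
    cycles = time_normalize(env, trace, cycles, n_points=n_points)

    cmc_ch = np.array([cmc(cycles.norm_env[ch]) for ch in range(env.n_channels)])
    m_env_raw = mean_envelope(cycles.norm_env)
    baseline = np.percentile(m_env_raw, 5, axis=1)
    noise_floor = float(np.median(baseline))
    active = (m_env_raw.max(axis=1) > 2 * noise_floor) & ~env.bad_mask
    m_env = subtract_baseline(m_env_raw)
    m_env[env.bad_mask] = 0.0

    env_ds = angle_ds = ids_ds = None
    if keep_envelope:
        kept = cycles.kept_boundaries()
        parts, aparts, idparts = [], [], []
        for cid, (s, e) in enumerate(kept):
            sl = slice(s, e, envelope_decimate)
            parts.append(env.env[:, sl])
            aparts.append(trace.angle[sl])
            idparts.append(np.full(parts[-1].shape[1], cid))
        env_ds = np.concatenate(parts, axis=1)
        angle_ds = np.concatenate(aparts)
        ids_ds = np.concatenate(idparts)

    return TaskResult(
        mean_env_raw=m_env_raw,
        mean_env=m_env,
        cmc_per_channel=cmc_ch,
        active_mask=active,
        bad_mask=env.bad_mask.copy(),
        n_cycles_found=cycles.n_cycles,
        n_cycles_kept=cycles.n_kept,
        excluded_fraction=float(cycles.meta.get("excluded_fraction", 0.0)),
        grid=env.grid,
        mean_angle=cycles.norm_angle.mean(axis=0),
        env_ds=env_ds,
        angle_ds=angle_ds,
        cycle_ids_ds=ids_ds,
    )


def _fit_on_tasks(
    tasks: dict[str, TaskResult],
    n_modules: int | None,
    n_restarts: int,
    seed: int,
    vaf_threshold: float = 0.90,
) -> tuple[ModuleDecomposition, dict[int, float]]:
    """Concatenate task mean envelopes (bad channels dropped) and factorize."""
    bad = np.zeros(next(iter(tasks.values())).bad_mask.shape, dtype=bool)
    for t in tasks.values():
        bad |= t.bad_mask
    keep_ids = np.flatnonzero(~bad)
    mean_envs = {name: t.mean_env[keep_ids] for name, t in tasks.items()}
    M, blocks = concatenate_tasks(mean_envs)
    nonzero = M.max(axis=1) > 0
    keep_ids = keep_ids[nonzero]
    M = M[nonzero]
    if n_modules is None:
        n_star, curve, decs = select_module_count(
            M, n_restarts=n_restarts, seed=seed, vaf_threshold=vaf_threshold,
            task_blocks=blocks, channel_ids=keep_ids,
        )
        return decs[n_star], curve
    dec = fit_nnmf(
        M, n_modules, n_restarts=n_restarts, seed=seed,
        task_blocks=blocks, channel_ids=keep_ids,
    )
    return dec, {n_modules: dec.vaf}


def module_maps(dec: ModuleDecomposition, grid: GridLayout) -> list[CoefficientMap]:
    """Spatial coefficient map of every module, with dropped channels masked."""
    maps = []
    for j in range(dec.n_modules):
        vals = np.zeros(grid.n_channels)
        mask = np.ones(grid.n_channels, dtype=bool)
        vals[dec.channel_ids] = dec.A[:, j]
        mask[dec.channel_ids] = False
        maps.append(CoefficientMap.from_channels(vals, grid, bad_mask=mask))
    return maps


def main_cluster(cmap: CoefficientMap) -> ActivityCluster | None:
    """The activity cluster carrying the most weight on a module map."""
    clusters = segment_map(cmap)
    if not clusters:
        return None
    return max(clusters, key=lambda c: c.total_weight)


def match_modules(
    dec_a: ModuleDecomposition,
    dec_b: ModuleDecomposition,
    threshold: float = 0.7,
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching of temporal modules by Pearson correlation.

    Links above the threshold are taken in decreasing correlation order;
    each module participates in at most one match.
    """
    links = module_similarity(dec_a.S, dec_b.S, threshold=threshold)
    links.sort(key=lambda t: -t[2])
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for i, j, r in links:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j, r))
    return out


@dataclass
class ConditionComparison:
    """Prone-vs-neutral outcome for one simulated subject and task."""

    shifts_x: dict[str, float]  # per module label, IED units
    ratios: dict[str, float]  # barycenter-weight ratio prone/neutral
    cogs_neutral: dict[str, tuple[float, float]]
    cogs_prone: dict[str, tuple[float, float]]
    vaf_neutral: float
    vaf_prone: float
    matches: list[tuple[int, int, float]]


def condition_comparison(
    cfg: "synthetic.SimConfig",
    conditions: tuple[str, str] = ("neutral", "prone"),
    n_modules: int = 3,
    n_restarts: int = 20,
    seed: int = 0,
) -> ConditionComparison:
    """Run the full pipeline in two hand positions and compare module maps.

    Modules are matched across conditions by temporal correlation (> 0.7);
    for each matched module labelled by its activation timing
    (extensor/flexor), the ulnar--radial COG displacement of the main
    activity cluster and the prone/neutral barycenter-weight ratio are
    computed.
    """
    decs = {}
    for cond in conditions:
        sim = synthetic.simulate_recording(cfg, condition=cond)
        task = process_task(sim.emg, sim.angle_raw, sim.kinematics_fs)
        dec, _ = _fit_on_tasks(
            {"task": task}, n_modules=n_modules, n_restarts=n_restarts, seed=seed
        )
        decs[cond] = (dec, task.grid)
    dec_n, grid = decs[conditions[0]]
    dec_p, _ = decs[conditions[1]]
    matches = match_modules(dec_n, dec_p)
    labels_n = classify_modules(dec_n.S, dec_n.A)
    index_to_label = {v: k for k, v in labels_n.items()}

    maps_n = module_maps(dec_n, grid)
    maps_p = module_maps(dec_p, grid)
    shifts, ratios, cogs_n, cogs_p = {}, {}, {}, {}
    for i, j, _r in matches:
        label = index_to_label.get(i, f"module{i}")
        cl_n = main_cluster(maps_n[i])
        cl_p = main_cluster(maps_p[j])
        if cl_n is None or cl_p is None:
            continue
        shifts[label] = cog_shift(cl_p, cl_n, axis="x")
        cogs_n[label] = cl_n.cog
        cogs_p[label] = cl_p.cog
        try:
            ratios[label] = weight_ratio(maps_p[j], cl_p.cog, maps_n[i], cl_n.cog)
        except ValueError:
            pass
    return ConditionComparison(
        shifts_x=shifts,
        ratios=ratios,
        cogs_neutral=cogs_n,
        cogs_prone=cogs_p,
        vaf_neutral=dec_n.vaf,
        vaf_prone=dec_p.vaf,
        matches=matches,
    )


def finger_separability(
    seed: int,
    fingers: tuple[str, ...] = ("index", "middle", "ring", "little"),
    n_restarts: int = 20,
    n_cycles: int | None = None,
) -> dict:
    """Extension activity areas of the four fingers and their separation.

    For each single-finger task the pipeline extracts two modules
    (extension/flexion), segments the extensor map and keeps its main
    cluster.  Returns per-finger clusters plus the overlap (both
    normalizations) and COG distances of the middle finger against each of
    the others.
    """
    clusters: dict[str, ActivityCluster] = {}
    truth_centers: dict[str, tuple[float, float]] = {}
    cmc_by_finger: dict[str, float] = {}
    for finger in fingers:
        overrides = {} if n_cycles is None else {"n_cycles": n_cycles}
        cfg = synthetic.finger_config(finger, seed, **overrides)
        sim = synthetic.simulate_recording(cfg)
        task = process_task(sim.emg, sim.angle_raw, sim.kinematics_fs)
        if task.active_mask.any():
            cmc_by_finger[finger] = float(
                np.median(task.cmc_per_channel[task.active_mask])
            )
        dec, _ = _fit_on_tasks(
            {finger: task}, n_modules=2, n_restarts=n_restarts, seed=seed
        )
        labels = classify_modules(dec.S, dec.A)
        maps = module_maps(dec, task.grid)
        cl = main_cluster(maps[labels["extensor"]])
        if cl is None:
            raise RuntimeError(f"no extensor cluster found for {finger}")
        clusters[finger] = cl
        truth_centers[finger] = tuple(sim.truth["source_centers"][0])
    others = [f for f in fingers if f != "middle"]
    overlaps = {f: overlap(clusters["middle"], clusters[f]) for f in others}
    distances = {
        f: float(np.hypot(
            clusters["middle"].cog[0] - clusters[f].cog[0],
            clusters["middle"].cog[1] - clusters[f].cog[1],
        ))
        for f in others
    }
    return {
        "clusters": clusters,
        "overlaps_vs_middle": overlaps,
        "cog_distances_vs_middle": distances,
        "truth_centers": truth_centers,
        "median_cmc_active": cmc_by_finger,
    }


def reconstruction_dataset(
    task: TaskResult, channel_indices: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, cycle_ids) for angle regression from a stored task envelope."""
    if task.env_ds is None:
        raise ValueError("task was processed without keep_envelope=True")
    X = task.env_ds[channel_indices].T
    return X, task.angle_ds, task.cycle_ids_ds


# ---------------------------------------------------------------------------
# multi-subject orchestration


@dataclass
class PipelineConfig:
    """Configuration of a multi-subject simulated study run."""

    out_dir: str = "emgmap_run"
    seed: int = 1
    subjects: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5, 6, 7, 8])
    kind: str = "wrist"  # wrist | fingers
    condition_shift_x: float = 0.8
    prone_gains: tuple[float, float, float] = (1.4, 0.5, 1.0)
    n_modules: int = 3
    n_restarts: int = 20
    n_cycles: int | None = None  # override the preset cycle counts (small runs)
    run_reconstruction: bool = False

    def to_yaml(self) -> str:
        import yaml

        d = asdict(self)
        d["prone_gains"] = list(d["prone_gains"])
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        import yaml

        d = yaml.safe_load(text) or {}
        if "prone_gains" in d:
            d["prone_gains"] = tuple(d["prone_gains"])
        return cls(**d)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured study and write the report bundle.

    Emits, under ``cfg.out_dir``: the resolved config (YAML), a per-subject
    condition-comparison table (COG shift and weight ratio per module, CSV),
    a CMC/cycle summary table (CSV), and a JSON summary with the medians.
    Deterministic given ``cfg.seed`` and the subject list.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(cfg.to_yaml())

    rows = []
    cmc_rows = []
    for subj in cfg.subjects:
        overrides = {} if cfg.n_cycles is None else {"n_cycles": cfg.n_cycles}
        if cfg.kind == "wrist":
            sim_cfg = synthetic.wrist_config(
                subj, condition_shift_x=cfg.condition_shift_x,
                prone_gains=cfg.prone_gains, **overrides,
            )
            comp = condition_comparison(
                sim_cfg, n_modules=cfg.n_modules,
                n_restarts=cfg.n_restarts, seed=cfg.seed,
            )
            for label in comp.shifts_x:
                rows.append({
                    "subject": subj,
                    "module": label,
                    "cog_shift_x_ied": comp.shifts_x[label],
                    "weight_ratio_prone_neutral": comp.ratios.get(label, np.nan),
                    "vaf_neutral": comp.vaf_neutral,
                    "vaf_prone": comp.vaf_prone,
                })
            sim = synthetic.simulate_recording(sim_cfg)
            task = process_task(sim.emg, sim.angle_raw, sim.kinematics_fs)
            cmc_rows.append({
                "subject": subj,
                "task": "wrist_flex_ext",
                "n_cycles_found": task.n_cycles_found,
                "n_cycles_kept": task.n_cycles_kept,
                "excluded_fraction": task.excluded_fraction,
                "median_cmc_active": float(
                    np.median(task.cmc_per_channel[task.active_mask])
                ),
            })
        elif cfg.kind == "fingers":
            sep = finger_separability(subj, n_restarts=cfg.n_restarts,
                                      n_cycles=cfg.n_cycles)
            for f, (ov_small, ov_large) in sep["overlaps_vs_middle"].items():
                rows.append({
                    "subject": subj,
                    "pair": f"middle-{f}",
                    "overlap_pct_smallest": ov_small,
                    "overlap_pct_largest": ov_large,
                    "cog_distance_ied": sep["cog_distances_vs_middle"][f],
                })
        else:
            raise ValueError(f"unknown study kind {cfg.kind!r}")

    table = pd.DataFrame(rows)
    table.to_csv(out / "comparison.csv", index=False)
    summary: dict = {"kind": cfg.kind, "n_subjects": len(cfg.subjects)}
    if cfg.kind == "wrist" and not table.empty:
        ext = table[table["module"] == "extensor"]
        flex = table[table["module"] == "flexor"]
        summary.update({
            "median_cog_shift_extensor_ied": float(ext["cog_shift_x_ied"].median()),
            "median_weight_ratio_extensor": float(
                ext["weight_ratio_prone_neutral"].median()
            ),
            "median_weight_ratio_flexor": float(
                flex["weight_ratio_prone_neutral"].median()
            ),
            "median_vaf": float(table["vaf_neutral"].median()),
        })
        pd.DataFrame(cmc_rows).to_csv(out / "cmc.csv", index=False)
    if cfg.kind == "fingers" and not table.empty:
        summary.update({
            "median_overlap_pct_smallest": float(
                table["overlap_pct_smallest"].median()
            ),
            "median_overlap_pct_largest": float(table["overlap_pct_largest"].median()),
            "median_min_cog_distance_ied": float(
                table.groupby("subject")["cog_distance_ied"].min().median()
            ),
        })
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
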