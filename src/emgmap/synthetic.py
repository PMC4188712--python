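"""Synthetic grid-sEMG and joint-angle generator with planted ground truth.

Every downstream stage of the pipeline (preprocessing, cycle segmentation,
NNMF module extraction, map segmentation, angle reconstruction) is validated
against data from this module, because the quantities the analysis estimates
-- source positions on the grid, temporal activation modules, condition
shifts and gains -- are planted here and emitted alongside the signals.

The signal model: each muscle source has a Gaussian spatial footprint on the
electrode grid and a nonnegative temporal activation profile defined over the
normalized movement cycle (500 phase points).  The interference-pattern EMG
of a source is surrogate broadband noise (Gaussian, band-limited 20-450 Hz)
amplitude-modulated by that profile; a channel records the weighted sum over
sources plus additive band-limited noise and 50 Hz power-line interference.
Joint angles follow trapezoidal flexion/extension cycles (2 s holds) with
per-cycle amplitude and timing jitter.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .grid import GridLayout
from .recording import EmgRecording

__all__ = [
    "PlantedSource",
    "CycleSpec",
    "SimConfig",
    "SyntheticRecording",
    "raised_cosine_profile",
    "spatial_weights",
    "simulate_kinematics",
    "simulate_emg",
    "simulate_recording",
    "wrist_config",
    "finger_config",
    "FINGER_CENTERS",
]

N_PHASE = 500  # normalized-cycle length shared with the analysis pipeline


def raised_cosine_profile(
    bumps: list[tuple[float, float, float]],
    plateaus: list[tuple[float, float, float]] | None = None,
    n: int = N_PHASE,
) -> np.ndarray:
    """Build a nonnegative activation profile over the normalized cycle.

    ``bumps`` are (center, width, height) raised-cosine bursts in phase units
    [0, 1); ``plateaus`` are (start, end, height) tonic segments with
    raised-cosine tapered edges (taper width 0.04).  Overlapping components
    take the pointwise maximum, so plateaus do not double-count with bursts.
    """
    phase = np.arange(n) / n
    out = np.zeros(n)
    for center, width, height in bumps:
        d = np.abs(phase - center)
        inside = d < width / 2
        comp = np.zeros(n)
        comp[inside] = height * 0.5 * (1 + np.cos(2 * np.pi * d[inside] / width))
        out = np.maximum(out, comp)
    taper = 0.04
    for start, end, height in plateaus or []:
        comp = np.zeros(n)
        core = (phase >= start + taper) & (phase <= end - taper)
        comp[core] = height
        lead = (phase >= start) & (phase < start + taper)
        comp[lead] = height * 0.5 * (1 - np.cos(np.pi * (phase[lead] - start) / taper))
        trail = (phase > end - taper) & (phase <= end)
        comp[trail] = height * 0.5 * (1 - np.cos(np.pi * (end - phase[trail]) / taper))
        out = np.maximum(out, comp)
    return out


@dataclass(frozen=True)
class PlantedSource:
    """Ground-truth muscle source: Gaussian footprint + activation profile.

    ``center`` is in continuous electrode-grid units (1 unit = 1 IED);
    ``sigma`` the isotropic spatial spread in IED; ``temporal_profile`` the
    nonnegative activation over the 500-point normalized cycle;
    ``gain_per_condition`` multiplies the source amplitude per condition
    label (at least one condition must have gain 1, the reference).
    """

    center: tuple[float, float]
    sigma: float
    temporal_profile: np.ndarray
    gain_per_condition: dict[str, float] = field(
        default_factory=lambda: {"neutral": 1.0}
    )
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "temporal_profile", np.asarray(self.temporal_profile, dtype=float)
        )
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if (self.temporal_profile < 0).any():
            raise ValueError("temporal profile must be nonnegative")
        if not any(np.isclose(g, 1.0) for g in self.gain_per_condition.values()):
            raise ValueError("at least one condition must have reference gain 1")

    def shifted(self, dx: float) -> "PlantedSource":
        return replace(self, center=(self.center[0] + dx, self.center[1]))


@dataclass(frozen=True)
class CycleSpec:
    """Trapezoidal movement-cycle timing and targets."""

    hold_s: float = 2.0
    transition_s: float = 0.75
    angle_flex: float = 30.0
    angle_ext: float = -30.0
    angle_rest: float = 0.0

    def __post_init__(self) -> None:
        if self.transition_s <= 0:
            raise ValueError("transitions must have positive duration")
        if np.isclose(self.angle_flex, self.angle_ext):
            raise ValueError("flexion and extension targets must be distinct")

    @property
    def nominal_duration_s(self) -> float:
        return 2 * self.hold_s + 2 * self.transition_s


@dataclass(frozen=True)
class SimConfig:
    """Full study-condition description for one synthetic task recording."""

    grid: GridLayout = GridLayout()
    sources: tuple[PlantedSource, ...] = ()
    n_cycles: int = 20
    cycle: CycleSpec = CycleSpec()
    fs: float = 2048.0
    noise_snr_db: float = 15.0
    noise_sigma: float | None = None  # overrides the SNR-derived noise level
    amp_jitter: float = 0.10
    time_jitter: float = 0.05
    rom_jitter: float = 0.01
    angle_noise_deg: float = 0.15
    powerline_amp: float = 0.2
    bad_channels: tuple[tuple[int, int], ...] = ((1, 2), (1, 5), (14, 7))
    condition_shift_x: float = 0.0
    seed: int = 0
    kinematics_fs: float = 50.0

    def __post_init__(self) -> None:
        if self.fs <= 2 * 450:
            raise ValueError("sampling rate must exceed twice the 450 Hz bandwidth")
        if self.n_cycles < 2:
            raise ValueError("need at least 2 cycles")


@dataclass
class SyntheticRecording:
    """One simulated task: EMG + glove trace + everything planted."""

    emg: EmgRecording
    angle_raw: np.ndarray  # glove-rate joint angle, degrees
    kinematics_fs: float
    truth: dict

    @property
    def grid(self) -> GridLayout:
        return self.emg.grid


def _rngs(cfg: SimConfig, condition: str) -> dict[str, np.random.Generator]:
    """Named independent RNG streams derived from the config seed.

    Kinematics and cycle-level jitter are condition-independent (the same
    subject performs the same movement), while carriers/noise differ between
    recordings of different conditions.
    """
    base = np.random.SeedSequence(cfg.seed)
    kin, emg_entropy = base.spawn(2)
    cond_seq = np.random.SeedSequence(
        entropy=emg_entropy.entropy,
        spawn_key=(zlib.crc32(condition.encode()),),
    )
    carriers, noise, power, bad = cond_seq.spawn(4)
    return {
        "kinematics": np.random.default_rng(kin),
        "carriers": np.random.default_rng(carriers),
        "noise": np.random.default_rng(noise),
        "powerline": np.random.default_rng(power),
        "bad": np.random.default_rng(bad),
    }


def spatial_weights(
    source: PlantedSource, grid: GridLayout, condition: str | None = None
) -> np.ndarray:
    """Gaussian channel-weight map of a source, shape (n_cols, n_rows).

    ``weight(x, y) = gain * exp(-((x-cx)^2 + (y-cy)^2) / (2 sigma^2))`` with
    the condition gain (reference gain 1 when ``condition`` is None).  Warns
    when the center lies more than ``3 sigma`` outside the grid (the source
    is then mostly invisible to the array).
    """
    cx, cy = source.center
    gain = 1.0 if condition is None else source.gain_per_condition[condition]
    margin = 3 * source.sigma
    if (
        cx < 1 - margin
        or cx > grid.n_cols + margin
        or cy < 1 - margin
        or cy > grid.n_rows + margin
    ):
        warnings.warn(
            f"source center {source.center} lies >3 sigma outside the grid",
            stacklevel=2,
        )
    xs = np.arange(1, grid.n_cols + 1, dtype=float)[:, None]
    ys = np.arange(1, grid.n_rows + 1, dtype=float)[None, :]
    return gain * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * source.sigma**2))


def _cycle_durations(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    z = np.clip(rng.standard_normal(cfg.n_cycles), -3, 3)
    return cfg.cycle.nominal_duration_s * (1 + cfg.time_jitter * z)


def simulate_kinematics(cfg: SimConfig) -> tuple[np.ndarray, dict]:
    """Trapezoidal joint-angle trace at ``cfg.fs`` plus ground-truth cycle times.

    Each cycle: rise (extension -> flexion target), 2 s flexion hold, fall,
    2 s extension hold; per-cycle duration scaled by the timing jitter and
    hold targets by the ROM jitter.  The trace starts from rest, descends to
    the extension plateau before the first cycle, and ends with the start of
    one extra rise so that the final full cycle has a detectable end boundary.

    Returns ``(angle, truth)`` where ``truth['onsets']`` are the analytic
    times (samples) at which the angle first exceeds the preceding extension
    plateau by 2 deg -- the same event the cycle detector looks for -- and
    ``truth['boundaries']`` the implied (start, end) pairs of the
    ``n_cycles`` complete cycles.
    """
    rng = _rngs(cfg, "neutral")["kinematics"]
    c = cfg.cycle
    durations = _cycle_durations(cfg, rng)
    flex = c.angle_flex * (1 + cfg.rom_jitter * np.clip(rng.standard_normal(cfg.n_cycles), -3, 3))
    ext = c.angle_ext * (1 + cfg.rom_jitter * np.clip(rng.standard_normal(cfg.n_cycles), -3, 3))

    # piecewise-linear knots (time_s, angle_deg)
    knots_t = [0.0, 0.5]
    knots_a = [c.angle_rest, c.angle_rest]
    t = 0.5 + c.transition_s  # descend from rest to the first extension plateau
    knots_t.append(t)
    knots_a.append(c.angle_ext)
    t += 1.0  # pre-cycle extension hold
    knots_t.append(t)
    knots_a.append(c.angle_ext)

    onset_times = []
    rise_starts = []
    prev_ext = c.angle_ext
    delta_ref = 2.0
    for k in range(cfg.n_cycles):
        frac = durations[k] / c.nominal_duration_s
        t_rise, t_hold = c.transition_s * frac, c.hold_s * frac
        rise_starts.append(t)
        slope = (flex[k] - prev_ext) / t_rise
        onset_times.append(t + delta_ref / slope)
        t += t_rise
        knots_t.append(t)
        knots_a.append(flex[k])
        t += t_hold
        knots_t.append(t)
        knots_a.append(flex[k])
        t += t_rise
        knots_t.append(t)
        knots_a.append(ext[k])
        prev_ext = ext[k]
        t += t_hold
        knots_t.append(t)
        knots_a.append(ext[k])
    # one extra partial rise so the last complete cycle has an end boundary
    rise_starts.append(t)
    slope = (c.angle_flex - prev_ext) / c.transition_s
    onset_times.append(t + delta_ref / slope)
    t += 0.35 * c.transition_s
    knots_t.append(t)
    knots_a.append(prev_ext + 0.35 * c.transition_s * slope)
    t += 0.3
    knots_t.append(t)
    knots_a.append(knots_a[-1])

    n_samples = int(np.ceil(t * cfg.fs)) + 1
    times = np.arange(n_samples) / cfg.fs
    angle = np.interp(times, knots_t, knots_a)

    onsets = np.array([int(round(ot * cfg.fs)) for ot in onset_times])
    boundaries = [(int(onsets[k]), int(onsets[k + 1])) for k in range(cfg.n_cycles)]
    truth = {
        "onsets": onsets,
        "boundaries": boundaries,
        "rise_starts": np.array([int(round(rs * cfg.fs)) for rs in rise_starts]),
        "durations_s": durations,
        "flex_targets": flex,
        "ext_targets": ext,
    }
    return angle, truth


def _bandlimited_noise(
    rng: np.random.Generator, shape: tuple[int, ...], fs: float
) -> np.ndarray:
    """Zero-mean Gaussian noise band-limited to 20-450 Hz, unit variance."""
    sos = sps.butter(4, [20.0, 450.0], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(shape), axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _source_modulators(cfg: SimConfig, truth: dict, n_samples: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Per-source activation modulators sampled on the recording time axis.

    The temporal profile lives on the normalized-cycle phase axis (0..500);
    the phase of sample t inside cycle k is its fractional position between
    the cycle's onset and the next onset, so planted modules sit on exactly
    the axis the pipeline reconstructs.  Cycle-wise amplitude jitter is
    applied per source.
    """
    onsets = truth["onsets"]
    n_sources = len(cfg.sources)
    mod = np.zeros((n_sources, n_samples))
    phase_axis = np.arange(N_PHASE) / N_PHASE
    z = np.clip(rng.standard_normal((n_sources, cfg.n_cycles)), -3, 3)
    for k in range(cfg.n_cycles):
        s, e = onsets[k], min(onsets[k + 1], n_samples)
        if s >= n_samples:
            break
        phase = (np.arange(s, e) - s) / (onsets[k + 1] - s)
        for j, src in enumerate(cfg.sources):
            prof = np.interp(phase, phase_axis, src.temporal_profile, period=1.0)
            mod[j, s:e] = prof * (1 + cfg.amp_jitter * z[j, k])
    return mod


def _reference_peak_power(cfg: SimConfig) -> float:
    """Mean source-driven power at the most strongly driven channel, unit gains.

    Acts as the fixed acquisition-level reference for the SNR: tasks whose
    sources are weaker than the unit-gain reference (e.g. single fingers at
    half gain) face the same absolute noise floor and therefore a lower
    effective SNR, as in a real recording chain.
    """
    power = np.zeros(cfg.grid.n_channels)
    for src in cfg.sources:
        w = spatial_weights(src, cfg.grid).T.reshape(-1)  # channel order
        # unit gain: scale profile to unit peak so gain conventions cancel
        peak = src.temporal_profile.max()
        prof = src.temporal_profile / peak if peak > 0 else src.temporal_profile
        power += w**2 * np.mean(prof**2)
    return float(power.max())


def simulate_emg(
    cfg: SimConfig,
    condition: str = "neutral",
    kinematics: tuple[np.ndarray, dict] | None = None,
) -> tuple[EmgRecording, dict]:
    """Synthesize the grid EMG for one task recording and one condition.

    Per channel: ``sum_s w_s(ch) * m_s(t) * carrier_s(t) + noise + powerline``
    with independent band-limited carriers per source.  For a non-reference
    condition, source centers are displaced by ``condition_shift_x`` along
    the ulnar--radial axis and amplitudes multiplied by the condition gain.
    Bad channels are replaced by low-amplitude noise uncorrelated with the
    sources.
    """
    for src in cfg.sources:
        if condition not in src.gain_per_condition:
            raise KeyError(
                f"condition {condition!r} has no gain for source {src.label!r}"
            )
    if kinematics is None:
        kinematics = simulate_kinematics(cfg)
    angle, truth = kinematics
    n_samples = angle.shape[0]
    rngs = _rngs(cfg, condition)

    # the spatial displacement applies to the non-reference condition only
    dx = 0.0 if condition == _reference_condition(cfg) else cfg.condition_shift_x

    weights = np.zeros((cfg.grid.n_channels, len(cfg.sources)))
    true_centers = []
    for j, src in enumerate(cfg.sources):
        src_c = src.shifted(dx)
        w = spatial_weights(src_c, cfg.grid, condition=condition)
        weights[:, j] = cfg.grid.from_grid(w)
        true_centers.append(src_c.center)

    mod = _source_modulators(cfg, truth, n_samples, rngs["carriers"])
    carriers = _bandlimited_noise(rngs["carriers"], (len(cfg.sources), n_samples), cfg.fs)
    signal = weights @ (mod * carriers)

    if cfg.noise_sigma is not None:
        sigma_n = cfg.noise_sigma
    else:
        sigma_n = np.sqrt(_reference_peak_power(cfg) / 10 ** (cfg.noise_snr_db / 10))
    noise = sigma_n * _bandlimited_noise(
        rngs["noise"], (cfg.grid.n_channels, n_samples), cfg.fs
    )
    data = signal + noise

    if cfg.powerline_amp > 0:
        t = np.arange(n_samples) / cfg.fs
        phase = rngs["powerline"].uniform(0, 2 * np.pi)
        per_ch = rngs["powerline"].uniform(0.8, 1.2, cfg.grid.n_channels)
        data += cfg.powerline_amp * per_ch[:, None] * np.sin(
            2 * np.pi * 50.0 * t + phase
        )[None, :]

    true_bad = np.zeros(cfg.grid.n_channels, dtype=bool)
    for x, y in cfg.bad_channels:
        idx = cfg.grid.channel_index(x, y)
        true_bad[idx] = True
        data[idx] = 0.3 * sigma_n * rngs["bad"].standard_normal(n_samples)

    rec = EmgRecording(
        data=data,
        fs=cfg.fs,
        grid=cfg.grid,
        meta={"condition": condition, "seed": cfg.seed},
    )
    emg_truth = {
        "source_centers": np.array(true_centers),
        "source_sigmas": np.array([s.sigma for s in cfg.sources]),
        "source_gains": np.array(
            [s.gain_per_condition[condition] for s in cfg.sources]
        ),
        "source_profiles": np.array([s.temporal_profile for s in cfg.sources]),
        "source_labels": [s.label for s in cfg.sources],
        "bad_channels": true_bad,
        "noise_sigma": sigma_n,
        "condition_shift_x": dx,
    }
    return rec, emg_truth


def _reference_condition(cfg: SimConfig) -> str:
    for cond in cfg.sources[0].gain_per_condition if cfg.sources else {}:
        if all(np.isclose(s.gain_per_condition.get(cond, np.nan), 1.0) for s in cfg.sources):
            return cond
    return "neutral"


def simulate_recording(cfg: SimConfig, condition: str = "neutral") -> SyntheticRecording:
    """Full synthetic task: EMG at ``cfg.fs`` plus the glove-rate angle trace.

    The glove trace is the trapezoid decimated to ``cfg.kinematics_fs`` with
    additive Gaussian measurement noise, as recorded hardware would deliver;
    the pipeline is expected to resample and re-detect cycles itself.
    """
    angle, kin_truth = simulate_kinematics(cfg)
    rec, emg_truth = simulate_emg(cfg, condition, kinematics=(angle, kin_truth))
    rng = _rngs(cfg, condition)["noise"]
    step = cfg.fs / cfg.kinematics_fs
    idx = np.arange(0, angle.shape[0], step)
    angle_raw = np.interp(idx, np.arange(angle.shape[0]), angle)
    angle_raw = angle_raw + cfg.angle_noise_deg * rng.standard_normal(angle_raw.shape)
    truth = {**kin_truth, **emg_truth}
    return SyntheticRecording(
        emg=rec, angle_raw=angle_raw, kinematics_fs=cfg.kinematics_fs, truth=truth
    )


# ---------------------------------------------------------------------------
# study-condition presets


def _wrist_sources(
    rng: np.random.Generator,
    prone_gains: tuple[float, float, float] = (1.4, 0.5, 1.0),
    center_jitter: float = 0.2,
) -> tuple[PlantedSource, ...]:
    """Three wrist flexion/extension sources: extensor, flexor, stabilizer.

    Profiles include a burst at the dynamic phase plus a tonic component
    during the hold the muscle maintains (posture against load), which is
    what makes the joint angle recoverable from instantaneous envelopes.
    Centers are jittered per subject by up to ``center_jitter`` IED.
    """
    jit = lambda: rng.uniform(-center_jitter, center_jitter)  # noqa: E731
    extensor = PlantedSource(
        center=(4.5 + jit(), 4.5 + jit()),
        sigma=1.2,
        temporal_profile=raised_cosine_profile(
            [(0.62, 0.28, 1.0)], [(0.66, 0.97, 0.35)]
        ),
        gain_per_condition={"neutral": 1.0, "prone": prone_gains[0]},
        label="extensor",
    )
    flexor = PlantedSource(
        center=(10.5 + jit(), 4.0 + jit()),
        sigma=1.2,
        temporal_profile=raised_cosine_profile(
            [(0.18, 0.24, 0.95)], [(0.15, 0.48, 0.33)]
        ),
        gain_per_condition={"neutral": 1.0, "prone": prone_gains[1]},
        label="flexor",
    )
    stabilizer = PlantedSource(
        center=(7.0 + jit(), 6.5 + jit()),
        sigma=1.0,
        temporal_profile=raised_cosine_profile(
            [(0.45, 0.18, 0.85), (0.90, 0.12, 0.7)]
        ),
        gain_per_condition={"neutral": 1.0, "prone": prone_gains[2]},
        label="stabilizer",
    )
    return (extensor, flexor, stabilizer)


def wrist_config(
    seed: int,
    condition_shift_x: float = 0.8,
    prone_gains: tuple[float, float, float] = (1.4, 0.5, 1.0),
    **overrides,
) -> SimConfig:
    """Default wrist flexion/extension study conditions (20 cycles).

    The prone condition displaces all sources by ``condition_shift_x`` IED in
    the ulnar--radial direction and applies the per-source prone gains
    (defaults: extensor 1.4, flexor 0.5, stabilizer 1.0).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 201)))
    sources = _wrist_sources(rng, prone_gains=prone_gains)
    params = dict(
        sources=sources,
        n_cycles=20,
        condition_shift_x=condition_shift_x,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


FINGER_CENTERS = {
    "index": (4.0, 5.0),
    "middle": (9.0, 4.5),
    "ring": (5.8, 4.2),
    "little": (6.5, 6.0),
}


def finger_config(
    finger: str,
    seed: int,
    gain_scale: float = 0.5,
    center_jitter: float = 0.2,
    **overrides,
) -> SimConfig:
    """Single-finger flexion/extension task (12 cycles, half-gain sources).

    The extensor source sits at the finger-specific location (the planted
    middle-finger center keeps >=2.5 IED distance from every other finger);
    a common flexor source sits on the opposite aspect of the grid.  Source
    gains are scaled to half the wrist level, against the same absolute
    noise floor.
    """
    if finger not in FINGER_CENTERS:
        raise ValueError(f"unknown finger {finger!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence((seed, 73, zlib.crc32(finger.encode())))
    )
    jit = lambda: rng.uniform(-center_jitter, center_jitter)  # noqa: E731
    cx, cy = FINGER_CENTERS[finger]
    extensor = PlantedSource(
        center=(cx + jit(), cy + jit()),
        sigma=1.0,
        temporal_profile=raised_cosine_profile(
            [(0.62, 0.28, gain_scale)], [(0.66, 0.97, 0.35 * gain_scale)]
        ),
        gain_per_condition={"neutral": 1.0},
        label=f"{finger}_extensor",
    )
    flexor = PlantedSource(
        center=(12.5 + jit(), 3.5 + jit()),
        sigma=1.1,
        temporal_profile=raised_cosine_profile(
            [(0.18, 0.24, 0.9 * gain_scale)], [(0.15, 0.48, 0.3 * gain_scale)]
        ),
        gain_per_condition={"neutral": 1.0},
        label="finger_flexor",
    )
    params = dict(sources=(extensor, flexor), n_cycles=12, seed=seed)
    params.update(overrides)
    return SimConfig(**params)
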