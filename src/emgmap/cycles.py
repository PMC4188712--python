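"""Movement-cycle segmentation from joint kinematics and envelope normalization.

The glove angle trace is resampled to the EMG rate, movement cycles are cut
at flexion onsets (angle exceeding the preceding extension plateau by 2 deg),
outlier cycles are excluded on range of motion, and per-cycle envelopes are
time-normalized to 500 phase points.  Waveform repeatability across cycles is
quantified by the coefficient of multiple correlation (CMC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import EnvelopeMatrix

__all__ = [
    "JointTrace",
    "CycleSet",
    "resample_sync",
    "detect_cycles",
    "exclude_outlier_cycles",
    "time_normalize",
    "cmc",
    "mean_envelope",
]


@dataclass
class JointTrace:
    """Joint angle in degrees on the EMG time axis."""

    angle: np.ndarray
    fs: float
    joint: str = ""
    movement: str = ""

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        if self.angle.size == 0:
            raise ValueError("empty angle trace")
        if not np.isfinite(self.angle).all():
            raise ValueError("angle trace contains non-finite values")


@dataclass
class CycleSet:
    """Cycle boundaries plus normalized envelope/angle tensors.

    ``boundaries`` are half-open ``[start, end)`` sample intervals;
    ``kept_mask`` marks cycles surviving outlier exclusion; after
    :func:`time_normalize`, ``norm_env`` is channels x kept-cycles x 500 and
    ``norm_angle`` kept-cycles x 500.
    """

    boundaries: list[tuple[int, int]]
    rom: np.ndarray
    kept_mask: np.ndarray
    norm_env: np.ndarray | None = None
    norm_angle: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        starts = [b[0] for b in self.boundaries]
        ends = [b[1] for b in self.boundaries]
        if any(e <= s for s, e in self.boundaries):
            raise ValueError("boundaries must be nonempty half-open intervals")
        if any(starts[i + 1] < ends[i] for i in range(len(starts) - 1)):
            raise ValueError("boundaries must be non-overlapping and increasing")

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries)

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    def kept_boundaries(self) -> list[tuple[int, int]]:
        return [b for b, k in zip(self.boundaries, self.kept_mask) if k]


def resample_sync(
    angle_raw: np.ndarray,
    source_fs: float,
    target_fs: float = 2048.0,
    joint: str = "",
    movement: str = "",
) -> JointTrace:
    """Resample a glove-rate angle trace to the EMG rate (linear interpolation).

    Duration is preserved to within one output sample.  Synchronization of
    the two streams is assumed upstream (in hardware via a shared auxiliary
    channel; exact in synthetic data).
    """
    angle_raw = np.asarray(angle_raw, dtype=float)
    if angle_raw.size == 0:
        raise ValueError("empty angle trace")
    t_src = np.arange(angle_raw.size) / source_fs
    n_out = int(np.floor(t_src[-1] * target_fs)) + 1
    t_out = np.arange(n_out) / target_fs
    return JointTrace(
        angle=np.interp(t_out, t_src, angle_raw),
        fs=target_fs,
        joint=joint,
        movement=movement,
    )


def detect_cycles(
    trace: JointTrace, delta: float = 2.0, polarity: int = 1
) -> CycleSet:
    """Cut movement cycles at flexion onsets.

    A two-state machine tracks the running extremum of the extension hold:
    while armed, the running minimum is updated and an onset is declared at
    the first sample exceeding ``minimum + delta``; the machine then re-arms
    only once the angle has fallen ``delta`` below its running maximum (the
    next extension phase has begun).  Cycle k spans ``[onset_k, onset_{k+1})``
    and the partial segments before the first / after the last onset are
    discarded.  With ``polarity=-1`` flexion is taken as decreasing angle.
    """
    a = polarity * trace.angle
    onsets: list[int] = []
    armed = True
    run_min = a[0]
    run_max = -np.inf
    for i in range(a.size):
        if armed:
            if a[i] < run_min:
                run_min = a[i]
            elif a[i] > run_min + delta:
                onsets.append(i)
                armed = False
                run_max = a[i]
        else:
            if a[i] > run_max:
                run_max = a[i]
            elif a[i] < run_max - delta:
                armed = True
                run_min = a[i]
    if len(onsets) < 2:
        raise ValueError("no cycles: fewer than 2 flexion onsets found")
    boundaries = [(onsets[k], onsets[k + 1]) for k in range(len(onsets) - 1)]
    rom = np.array([trace.angle[s:e].max() - trace.angle[s:e].min()
                    for s, e in boundaries])
    return CycleSet(
        boundaries=boundaries,
        rom=rom,
        kept_mask=np.ones(len(boundaries), dtype=bool),
        meta={"delta": delta, "polarity": polarity},
    )


def exclude_outlier_cycles(cycles: CycleSet, k: float = 1.5) -> CycleSet:
    """Exclude cycles whose range of motion falls outside the Tukey fences.

    Fences are ``[Q1 - k*IQR, Q3 + k*IQR]`` of the per-task ROM distribution
    (k = 1.5).  Raises when more than 60% of cycles would be excluded.
    """
    if cycles.n_cycles < 4:
        raise ValueError("need at least 4 cycles for outlier exclusion")
    q1, q3 = np.percentile(cycles.rom, [25, 75])
    iqr = q3 - q1
    keep = (cycles.rom >= q1 - k * iqr) & (cycles.rom <= q3 + k * iqr)
    if (~keep).sum() > 0.6 * cycles.n_cycles:
        raise ValueError("more than 60% of cycles excluded: task invalid")
    out = CycleSet(
        boundaries=cycles.boundaries,
        rom=cycles.rom,
        kept_mask=cycles.kept_mask & keep,
        meta={**cycles.meta, "excluded_fraction": float((~keep).mean())},
    )
    return out


def time_normalize(
    env: EnvelopeMatrix,
    trace: JointTrace,
    cycles: CycleSet,
    n_points: int = 500,
) -> CycleSet:
    """Resample each kept cycle onto ``n_points`` equispaced phase points.

    Linear interpolation per channel and for the angle; the first and last
    phase points coincide with the cycle's first and last samples.  Returns
    a new :class:`CycleSet` with ``norm_env`` (channels x kept x n_points)
    and ``norm_angle`` (kept x n_points) filled in.
    """
    kept = cycles.kept_boundaries()
    if not kept:
        raise ValueError("no kept cycles")
    n_ch = env.n_channels
    norm_env = np.empty((n_ch, len(kept), n_points))
    norm_angle = np.empty((len(kept), n_points))
    for c, (s, e) in enumerate(kept):
        if e - s < 2:
            raise ValueError(f"cycle {c} shorter than 2 samples")
        pos = np.linspace(s, e - 1, n_points)
        base = np.arange(s, e)
        norm_angle[c] = np.interp(pos, base, trace.angle[s:e])
        for ch in range(n_ch):
            norm_env[ch, c] = np.interp(pos, base, env.env[ch, s:e])
    return CycleSet(
        boundaries=cycles.boundaries,
        rom=cycles.rom,
        kept_mask=cycles.kept_mask.copy(),
        norm_env=norm_env,
        norm_angle=norm_angle,
        meta={**cycles.meta, "n_points": n_points},
    )


def cmc(norm: np.ndarray) -> float:
    """Coefficient of multiple correlation of a cycles x phase waveform set.

    Within-day form: with C cycles, T phase points, ``y_ct`` the waveform,
    ``ybar_t`` the across-cycle mean at phase t and ``ybar`` the grand mean,

        CMC = sqrt(max(0, 1 - [sum (y_ct - ybar_t)^2 / (C(T-1))]
                            / [sum (y_ct - ybar)^2 / (CT-1)]))

    1 for identical non-constant cycles; near 0 for unrelated waveforms
    (clipped at 0 when the within/between ratio exceeds 1).
    """
    y = np.asarray(norm, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2:
        raise ValueError("need a cycles x phase array with >= 2 cycles")
    c_n, t_n = y.shape
    ybar_t = y.mean(axis=0)
    ybar = y.mean()
    denom = np.sum((y - ybar) ** 2) / (c_n * t_n - 1)
    if denom == 0:
        raise ValueError("flat waveform: zero total variance")
    num = np.sum((y - ybar_t) ** 2) / (c_n * (t_n - 1))
    return float(np.sqrt(max(0.0, 1.0 - num / denom)))


def mean_envelope(norm_env: np.ndarray) -> np.ndarray:
    """Mean envelope across kept cycles: channels x phase."""
    norm_env = np.asarray(norm_env)
    if norm_env.ndim != 3 or norm_env.shape[1] < 1:
        raise ValueError("norm_env must be channels x cycles x phase, >=1 cycle")
    return norm_env.mean(axis=1)
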