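"""Cycle detection, outlier exclusion, time normalization and CMC tests."""

from __future__ import annotations

import numpy as np
import pytest

import emgmap as eg
from emgmap.cycles import (
    CycleSet,
    JointTrace,
    cmc,
    detect_cycles,
    exclude_outlier_cycles,
    mean_envelope,
    resample_sync,
    time_normalize,
)


def _trapezoid_train(n_cycles=5, fs=2048.0, rise=0.5, hold=1.0,
                     flex=30.0, ext=-30.0):
    """Deterministic trapezoid train starting from the extension plateau."""
    knots_t, knots_a = [0.0], [ext]
    t = 0.5
    knots_t.append(t)
    knots_a.append(ext)
    for _ in range(n_cycles + 1):
        t += rise
        knots_t.append(t)
        knots_a.append(flex)
        t += hold
        knots_t.append(t)
        knots_a.append(flex)
        t += rise
        knots_t.append(t)
        knots_a.append(ext)
        t += hold
        knots_t.append(t)
        knots_a.append(ext)
    times = np.arange(int(t * fs)) / fs
    return np.interp(times, knots_t, knots_a)


class TestResampleSync:
    def test_constant_preserved(self):
        out = resample_sync(np.full(100, 12.5), 50.0, 2048.0)
        assert np.allclose(out.angle, 12.5)
        assert out.fs == 2048.0

    def test_linear_ramp_exact(self):
        ramp = np.linspace(0, 60, 200)
        out = resample_sync(ramp, 50.0, 2048.0)
        t = np.arange(out.angle.size) / 2048.0
        expected = 60 * t / (199 / 50.0)
        assert np.allclose(out.angle, expected, atol=1e-9)

    def test_sinusoid_error_small(self):
        t50 = np.arange(150) / 50.0
        out = resample_sync(30 * np.sin(2 * np.pi * 1.0 * t50), 50.0, 2048.0)
        t = np.arange(out.angle.size) / 2048.0
        assert np.abs(out.angle - 30 * np.sin(2 * np.pi * t)).max() < 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            resample_sync(np.array([]), 50.0)


class TestDetectCycles:
    def test_trapezoid_train_counts(self):
        angle = _trapezoid_train(n_cycles=20)
        cycles = detect_cycles(JointTrace(angle=angle, fs=2048.0))
        assert cycles.n_cycles == 20

    def test_onsets_near_threshold_crossings(self):
        fs = 2048.0
        angle = _trapezoid_train(n_cycles=5, fs=fs)
        cycles = detect_cycles(JointTrace(angle=angle, fs=fs))
        # analytic crossing of ext+2deg on each rise: slope 120 deg/s
        rise, hold = 0.5, 1.0
        first_rise_start = 0.5
        period = 2 * rise + 2 * hold
        for k, (s, _e) in enumerate(cycles.boundaries):
            t_true = first_rise_start + k * period + 2.0 / 120.0
            assert abs(s - t_true * fs) <= 10

    def test_monotone_trace_rejected(self):
        angle = np.linspace(0, 50, 10000)
        with pytest.raises(ValueError, match="no cycles"):
            detect_cycles(JointTrace(angle=angle, fs=2048.0))

    def test_subthreshold_rise_ignored(self):
        # a 1.5 deg bump after the hold must not produce an onset
        fs = 2048.0
        angle = _trapezoid_train(n_cycles=3, fs=fs)
        bump = np.zeros_like(angle)
        hold_center = int(2.75 * fs)  # inside the first extension hold
        bump[hold_center : hold_center + 200] = 1.5
        n_plain = detect_cycles(JointTrace(angle=angle, fs=fs)).n_cycles
        n_bump = detect_cycles(JointTrace(angle=angle + bump, fs=fs)).n_cycles
        assert n_bump == n_plain

    def test_generator_truth_recovered(self, wrist_sim):
        cfg, sim = wrist_sim
        trace = resample_sync(sim.angle_raw, sim.kinematics_fs, cfg.fs)
        cycles = detect_cycles(trace)
        assert cycles.n_cycles == cfg.n_cycles
        truth_onsets = sim.truth["onsets"]
        for (s, _e), t in zip(cycles.boundaries, truth_onsets[:-1]):
            assert abs(s - t) <= 25  # noisy glove trace at 50 samples/s


class TestOutlierExclusion:
    def _cycles(self, rom):
        rom = np.asarray(rom, dtype=float)
        bounds = [(i * 100, (i + 1) * 100) for i in range(rom.size)]
        return CycleSet(boundaries=bounds, rom=rom,
                        kept_mask=np.ones(rom.size, dtype=bool))

    def test_identical_roms_all_kept(self):
        out = exclude_outlier_cycles(self._cycles(np.full(10, 60.0)))
        assert out.kept_mask.all()

    def test_single_half_rom_cycle_excluded(self):
        rom = np.full(20, 60.0)
        rom[7] = 30.0
        out = exclude_outlier_cycles(self._cycles(rom))
        assert not out.kept_mask[7]
        assert out.kept_mask.sum() == 19

    def test_two_planted_outliers_among_12(self):
        rom = np.full(12, 58.0) + np.linspace(-1, 1, 12)
        rom[2], rom[9] = 20.0, 95.0
        out = exclude_outlier_cycles(self._cycles(rom))
        assert not out.kept_mask[2] and not out.kept_mask[9]
        assert out.kept_mask.sum() == 10

    def test_mass_exclusion_rejected(self):
        # quartile fences track the majority, so the guard fires only when
        # the fences are pathologically tight relative to the spread
        rom = np.arange(10, dtype=float) * 10
        with pytest.raises(ValueError, match="60%"):
            exclude_outlier_cycles(self._cycles(rom), k=-0.2)

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError):
            exclude_outlier_cycles(self._cycles([60, 60, 60]))


class TestTimeNormalize:
    def _setup(self, n_samples=4096, n_ch=3):
        grid = eg.GridLayout(n_cols=3, n_rows=1)
        env = eg.EnvelopeMatrix(
            env=np.abs(np.random.default_rng(0).standard_normal((n_ch, n_samples))),
            fs=2048.0, grid=grid,
        )
        trace = JointTrace(angle=np.linspace(0, 30, n_samples), fs=2048.0)
        return env, trace

    def test_exactly_500_points(self):
        env, trace = self._setup()
        cycles = CycleSet(boundaries=[(0, 4096)], rom=np.array([30.0]),
                          kept_mask=np.array([True]))
        out = time_normalize(env, trace, cycles)
        assert out.norm_env.shape == (3, 1, 500)
        assert out.norm_angle.shape == (1, 500)

    def test_constant_envelope_constant_cycle(self):
        env, trace = self._setup()
        env.env[:] = 2.5
        cycles = CycleSet(boundaries=[(100, 2100)], rom=np.array([1.0]),
                          kept_mask=np.array([True]))
        out = time_normalize(env, trace, cycles)
        assert np.allclose(out.norm_env, 2.5)

    def test_linear_envelope_affine_invariance(self):
        env, trace = self._setup()
        env.env[0] = np.linspace(1, 3, env.env.shape[1])
        cycles = CycleSet(boundaries=[(0, 4096)], rom=np.array([1.0]),
                          kept_mask=np.array([True]))
        out = time_normalize(env, trace, cycles)
        assert out.norm_env[0, 0, 0] == pytest.approx(1.0, abs=1e-9)
        assert out.norm_env[0, 0, -1] == pytest.approx(3.0, abs=1e-9)
        diffs = np.diff(out.norm_env[0, 0])
        assert np.allclose(diffs, diffs[0], atol=1e-9)

    def test_short_cycle_rejected(self):
        env, trace = self._setup()
        cycles = CycleSet(boundaries=[(5, 6)], rom=np.array([1.0]),
                          kept_mask=np.array([True]))
        with pytest.raises(ValueError):
            time_normalize(env, trace, cycles)


def _cmc_bruteforce(y):
    """Independent loop implementation of the within-day CMC formula."""
    c, t = y.shape
    ybar_t = [sum(y[i][j] for i in range(c)) / c for j in range(t)]
    ybar = sum(sum(row) for row in y) / (c * t)
    num = sum((y[i][j] - ybar_t[j]) ** 2 for i in range(c) for j in range(t))
    den = sum((y[i][j] - ybar) ** 2 for i in range(c) for j in range(t))
    ratio = (num / (c * (t - 1))) / (den / (c * t - 1))
    return np.sqrt(max(0.0, 1.0 - ratio))


class TestCmc:
    def test_identical_cycles_give_one(self):
        y = np.tile(np.sin(np.linspace(0, 3, 500)), (5, 1))
        assert cmc(y) == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_near_null_value(self, rng):
        # unrelated cycles: the within/total variance ratio tends to 1-1/C,
        # so the null CMC concentrates at sqrt(1/C) (0.224 for C=20)
        vals = np.array([cmc(rng.standard_normal((20, 500))) for _ in range(20)])
        assert np.all(vals < 0.3)
        assert np.median(vals) == pytest.approx(np.sqrt(1 / 20), abs=0.03)
        vals50 = np.array([cmc(rng.standard_normal((50, 500))) for _ in range(10)])
        assert np.all(vals50 < 0.2)

    def test_matches_bruteforce_oracle(self, rng):
        t = np.linspace(0, 1, 41)
        y = np.vstack([t, 2 * t])
        assert cmc(y) == pytest.approx(_cmc_bruteforce(y), abs=1e-12)
        y2 = rng.standard_normal((4, 37)) + np.sin(np.linspace(0, 5, 37))
        assert cmc(y2) == pytest.approx(_cmc_bruteforce(y2), abs=1e-12)

    def test_scale_and_offset_invariance(self, rng):
        y = rng.standard_normal((6, 100)) + np.cos(np.linspace(0, 4, 100))
        assert cmc(3.7 * y) == pytest.approx(cmc(y), abs=1e-12)
        assert cmc(y + 11.0) == pytest.approx(cmc(y), abs=1e-12)

    def test_flat_waveform_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            cmc(np.full((3, 100), 2.0))


class TestMeanEnvelope:
    def test_single_cycle_identity(self, rng):
        x = np.abs(rng.standard_normal((4, 1, 500)))
        assert np.array_equal(mean_envelope(x), x[:, 0])

    def test_two_cycles_average(self, rng):
        a = np.abs(rng.standard_normal((4, 1, 500)))
        x = np.concatenate([a, 3 * a], axis=1)
        assert np.allclose(mean_envelope(x), 2 * a[:, 0], atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        x = np.abs(rng.standard_normal((3, 7, 50)))
        loop = np.zeros((3, 50))
        for ch in range(3):
            for ph in range(50):
                loop[ch, ph] = sum(x[ch, c, ph] for c in range(7)) / 7
        assert np.allclose(mean_envelope(x), loop, atol=1e-12)
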