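"""NNMF factorization tests: VAF arithmetic, planted-factor recovery,
module-count selection, restart monotonicity and temporal-module similarity."""

from __future__ import annotations

import numpy as np
import pytest

from emgmap.nnmf import (
    classify_modules,
    concatenate_tasks,
    fit_nnmf,
    module_similarity,
    select_module_count,
    subtract_baseline,
    vaf,
)


class TestConcatenate:
    def test_single_task_identity(self, rng):
        m = np.abs(rng.standard_normal((5, 500)))
        out, blocks = concatenate_tasks({"a": m})
        assert np.array_equal(out, m)
        assert blocks == {"a": (0, 500)}

    def test_fourteen_tasks_width(self, rng):
        envs = {f"t{i}": np.abs(rng.standard_normal((6, 500))) for i in range(14)}
        out, blocks = concatenate_tasks(envs)
        assert out.shape == (6, 7000)

    def test_block_roundtrip_bit_exact(self, rng):
        envs = {k: np.abs(rng.standard_normal((4, 100 + 50 * i)))
                for i, k in enumerate("abc")}
        out, blocks = concatenate_tasks(envs)
        for k, (s, e) in blocks.items():
            assert np.array_equal(out[:, s:e], envs[k])

    def test_mismatched_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="channel"):
            concatenate_tasks({
                "a": np.ones((4, 10)), "b": np.ones((5, 10)),
            })


class TestVaf:
    def test_perfect_reconstruction(self, rng):
        A = np.abs(rng.standard_normal((6, 2)))
        S = np.abs(rng.standard_normal((2, 40)))
        assert vaf(A @ S, A, S) == pytest.approx(1.0, abs=1e-12)

    def test_zero_reconstruction(self):
        M = np.ones((3, 4))
        assert vaf(M, np.zeros((3, 1)), np.zeros((1, 4))) == 0.0

    def test_hand_arithmetic(self):
        # M=[[1,2],[3,4]], AS=[[1,2],[3,0]]: SSE=16, SST=30
        M = np.array([[1.0, 2.0], [3.0, 4.0]])
        A = np.array([[1.0], [3.0]])
        S = np.array([[1.0, 2.0]])
        AS = A @ S
        AS[1, 1] = 0.0  # shape the reconstruction by hand
        sse = np.sum((M - AS) ** 2)
        assert sse == 16.0
        assert 1 - sse / np.sum(M**2) == pytest.approx(1 - 16 / 30)

    def test_zero_sst_rejected(self):
        with pytest.raises(ValueError):
            vaf(np.zeros((2, 2)), np.ones((2, 1)), np.ones((1, 2)))


class TestFitNnmf:
    def test_rank1_exact(self, rng):
        a = np.abs(rng.standard_normal(8)) + 0.1
        s = np.abs(rng.standard_normal(60)) + 0.1
        dec = fit_nnmf(np.outer(a, s), 1, n_restarts=5, seed=0)
        assert dec.sse / dec.sst < 1e-6

    def test_planted_rank3_recovered(self, rng):
        A0 = np.abs(rng.standard_normal((10, 3)))
        S0 = np.abs(rng.standard_normal((3, 200)))
        dec = fit_nnmf(A0 @ S0, 3, n_restarts=10, seed=0)
        assert dec.vaf > 0.999

    def test_channel_permutation_equivariance(self, rng):
        M = np.abs(rng.standard_normal((8, 120))) + 0.05
        perm = rng.permutation(8)
        dec = fit_nnmf(M, 2, n_restarts=10, seed=3)
        dec_p = fit_nnmf(M[perm], 2, n_restarts=10, seed=3)
        # same reconstruction quality; modules may swap, so compare via S match
        assert dec_p.sse == pytest.approx(dec.sse, rel=1e-6)
        links = module_similarity(dec.S, dec_p.S, threshold=0.99)
        assert len({i for i, _, _ in links}) == 2

    def test_nonnegativity_and_unit_max_modules(self, rng):
        M = np.abs(rng.standard_normal((8, 120)))
        dec = fit_nnmf(M, 3, n_restarts=5, seed=1)
        assert (dec.A >= 0).all() and (dec.S >= 0).all()
        assert np.allclose(dec.S.max(axis=1), 1.0)
        assert ((dec.A @ dec.S) >= 0).all()

    def test_deterministic_given_seed(self, rng):
        M = np.abs(rng.standard_normal((6, 80)))
        a = fit_nnmf(M, 2, n_restarts=5, seed=7)
        b = fit_nnmf(M, 2, n_restarts=5, seed=7)
        assert np.array_equal(a.A, b.A) and np.array_equal(a.S, b.S)

    def test_best_of_restarts_monotone(self, rng):
        # more restarts on the same seed sequence cannot worsen the best SSE
        M = np.abs(rng.standard_normal((10, 100)))
        sses = [fit_nnmf(M, 3, n_restarts=n, seed=5).sse for n in (1, 5, 15)]
        assert sses[0] >= sses[1] >= sses[2]

    def test_bad_inputs_rejected(self, rng):
        M = np.abs(rng.standard_normal((4, 30)))
        with pytest.raises(ValueError):
            fit_nnmf(M, 0, n_restarts=1)
        with pytest.raises(ValueError):
            fit_nnmf(M, 5, n_restarts=1)
        with pytest.raises(ValueError):
            fit_nnmf(-M, 2, n_restarts=1)
        M0 = M.copy()
        M0[2] = 0.0
        with pytest.raises(ValueError, match="zero"):
            fit_nnmf(M0, 2, n_restarts=1)


class TestSelectModuleCount:
    def test_planted_three_modules(self, rng):
        # three well-separated nonnegative factors: VAF jumps at N=3
        A0 = np.zeros((12, 3))
        A0[0:4, 0] = rng.uniform(0.5, 1, 4)
        A0[4:8, 1] = rng.uniform(0.5, 1, 4)
        A0[8:12, 2] = rng.uniform(0.5, 1, 4)
        t = np.linspace(0, 1, 300)
        S0 = np.vstack([
            np.exp(-((t - c) ** 2) / 0.01) for c in (0.2, 0.5, 0.8)
        ])
        M = A0 @ S0 + 0.01 * np.abs(rng.standard_normal((12, 300)))
        n_star, curve, _ = select_module_count(M, range(1, 7), n_restarts=5, seed=2)
        assert n_star == 3
        assert curve[3] >= 0.9 > curve[2]

    def test_vaf_monotone_in_n(self, rng):
        M = np.abs(rng.standard_normal((10, 150)))
        _, curve, _ = select_module_count(M, range(1, 7), n_restarts=5, seed=4)
        vals = [curve[n] for n in range(1, 7)]
        assert all(b >= a - 1e-6 for a, b in zip(vals, vals[1:]))

    def test_first_qualifying_count_wins(self, rng):
        a = np.abs(rng.standard_normal(8)) + 0.1
        s = np.abs(rng.standard_normal(50)) + 0.1
        n_star, _, _ = select_module_count(np.outer(a, s), range(1, 4),
                                           n_restarts=3, seed=0)
        assert n_star == 1

    def test_warns_when_threshold_unreachable(self, rng):
        M = np.abs(rng.standard_normal((10, 200)))
        with pytest.warns(UserWarning, match="arg-max"):
            select_module_count(M, range(1, 3), vaf_threshold=0.999999,
                                n_restarts=2, seed=0)


class TestModuleSimilarity:
    def test_superset_links_all(self, rng):
        S = np.abs(rng.standard_normal((3, 200)))
        S1 = np.vstack([S, np.abs(rng.standard_normal((1, 200)))])
        links = module_similarity(S, S1)
        linked_sources = {i for i, j, r in links if r > 0.999}
        assert linked_sources == {0, 1, 2}

    def test_orthogonal_noise_unlinked(self, rng):
        for _ in range(20):
            a = rng.standard_normal((2, 500))
            b = rng.standard_normal((2, 500))
            assert module_similarity(np.abs(a), np.abs(b)) == []

    def test_preserved_plus_new_module(self, rng):
        t = np.linspace(0, 1, 500)
        s1 = np.exp(-((t - 0.3) ** 2) / 0.01)
        s2 = np.exp(-((t - 0.7) ** 2) / 0.01)
        s3 = np.exp(-((t - 0.5) ** 2) / 0.002)
        links = module_similarity(np.vstack([s1, s2]), np.vstack([s1, s2, s3]))
        assert len(links) == 2
        assert {(i, j) for i, j, _ in links} == {(0, 0), (1, 1)}

    def test_constant_module_excluded_with_warning(self, rng):
        S = np.vstack([np.ones(100), rng.standard_normal(100)])
        with pytest.warns(UserWarning, match="constant"):
            links = module_similarity(S, S)
        assert all(i != 0 for i, _, _ in links)


class TestBaselineAndClassification:
    def test_baseline_subtraction_removes_offset(self, rng):
        sig = np.abs(rng.standard_normal((4, 500)))
        out = subtract_baseline(sig + 3.0)
        assert np.percentile(out, 5, axis=1) == pytest.approx(
            np.zeros(4), abs=0.02
        )
        assert (out == 0).any(axis=1).all()  # the floor was actually removed
        assert (out >= 0).all()

    def test_classify_by_peak_phase(self):
        t = np.linspace(0, 1, 500)
        ext = np.exp(-((t - 0.7) ** 2) / 0.01)
        flex = np.exp(-((t - 0.2) ** 2) / 0.01)
        S = np.vstack([flex, ext])
        labels = classify_modules(S)
        assert labels == {"flexor": 0, "extensor": 1}
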