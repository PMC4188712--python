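"""Motor-module extraction by non-negative matrix factorization.

The concatenated mean envelopes ``M`` (channels x tasks*500) are factorized
as ``M ~ A @ S`` with spatial coefficient maps ``A`` (channels x N, one map
per module over the electrode grid) and temporal modules ``S`` (N x time,
one activation time course per module).  Reconstruction quality is the
variance accounted for, VAF = 1 - SSE/SST with uncentered SST = sum(M^2),
and the module count is the smallest N whose VAF reaches 0.90.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import NMF

__all__ = [
    "ModuleDecomposition",
    "concatenate_tasks",
    "subtract_baseline",
    "fit_nnmf",
    "vaf",
    "select_module_count",
    "module_similarity",
    "classify_modules",
]


@dataclass
class ModuleDecomposition:
    """Result of one best-of-restarts factorization at a fixed module count.

    Rows of ``S`` are normalized to unit maximum with the scale pushed into
    ``A``, so map weights are comparable across conditions.
    """

    M: np.ndarray
    A: np.ndarray  # channels x N spatial coefficients
    S: np.ndarray  # N x time temporal modules
    n_modules: int
    sse: float
    sst: float
    n_restarts: int
    best_seed: int
    task_blocks: dict[str, tuple[int, int]] = field(default_factory=dict)
    channel_ids: np.ndarray | None = None  # rows of M in grid channel order

    @property
    def vaf(self) -> float:
        return 1.0 - self.sse / self.sst

    @property
    def residual(self) -> np.ndarray:
        return self.M - self.A @ self.S

    def task_map(self, module: int, task: str | None = None) -> np.ndarray:
        """Spatial coefficient vector of one module (task blocks share A)."""
        return self.A[:, module]


def concatenate_tasks(
    mean_envs: dict[str, np.ndarray],
) -> tuple[np.ndarray, dict[str, tuple[int, int]]]:
    """Horizontally concatenate per-task mean envelopes in a fixed order.

    Tasks are concatenated in the (insertion) order of the dict; the
    returned block table maps task name to its ``[start, end)`` column range
    so per-task segments can be sliced back bit-exactly.
    """
    if not mean_envs:
        raise ValueError("no tasks to concatenate")
    shapes = {v.shape[0] for v in mean_envs.values()}
    if len(shapes) != 1:
        raise ValueError("tasks have mismatched channel sets")
    blocks: dict[str, tuple[int, int]] = {}
    cols = 0
    parts = []
    for name, env in mean_envs.items():
        blocks[name] = (cols, cols + env.shape[1])
        cols += env.shape[1]
        parts.append(env)
    return np.concatenate(parts, axis=1), blocks


def subtract_baseline(mean_env: np.ndarray, percentile: float = 5.0) -> np.ndarray:
    """Remove the per-channel envelope baseline (noise floor of the chain).

    Subtracts each channel's ``percentile``-th envelope value and clips at
    zero: the additive noise floor of a monopolar chain raises every channel
    by a temporally flat offset that is not muscle activity and would
    otherwise appear as a spurious flat component in the factorization.
    """
    base = np.percentile(mean_env, percentile, axis=1, keepdims=True)
    return np.clip(mean_env - base, 0.0, None)


def vaf(M: np.ndarray, A: np.ndarray, S: np.ndarray) -> float:
    """Variance accounted for: 1 - SSE/SST with SST = sum(M^2) (uncentered)."""
    M = np.asarray(M, dtype=float)
    sst = float(np.sum(M**2))
    if sst == 0:
        raise ValueError("SST is zero")
    sse = float(np.sum((M - A @ S) ** 2))
    return 1.0 - sse / sst


def fit_nnmf(
    M: np.ndarray,
    n_modules: int,
    n_restarts: int = 100,
    seed: int = 0,
    max_iter: int = 400,
    task_blocks: dict[str, tuple[int, int]] | None = None,
    channel_ids: np.ndarray | None = None,
) -> ModuleDecomposition:
    """Best-of-restarts NMF of the concatenated mean envelopes.

    ``n_restarts`` random nonnegative initializations (coordinate-descent
    minimization of the Frobenius loss); the restart with the lowest SSE is
    kept.  One master seed spawns the restart seeds, so the result is
    deterministic given ``seed``.
    """
    M = np.asarray(M, dtype=float)
    if (M < 0).any():
        raise ValueError("M must be nonnegative")
    if not 1 <= n_modules <= min(M.shape):
        raise ValueError(f"module count {n_modules} out of range for shape {M.shape}")
    if (M.max(axis=1) == 0).any():
        raise ValueError("M contains all-zero channel rows; drop them first")
    restart_seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)
    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    for rs in restart_seeds:
        model = NMF(
            n_components=n_modules,
            init="random",
            solver="cd",
            max_iter=max_iter,
            random_state=int(rs),
            tol=1e-5,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings per restart
            A = model.fit_transform(M)
        S = model.components_
        sse = float(np.sum((M - A @ S) ** 2))
        if best is None or sse < best[0]:
            best = (sse, A, S, int(rs))
    sse, A, S, best_seed = best
    return _finalize(M, A, S, sse, n_modules, n_restarts, best_seed,
                     task_blocks, channel_ids)


def _finalize(M, A, S, sse, n_modules, n_restarts, best_seed,
              task_blocks, channel_ids) -> ModuleDecomposition:
    # fix scale indeterminacy: unit-max temporal modules
    A, S = A.copy(), S.copy()
    peaks = S.max(axis=1)
    peaks[peaks == 0] = 1.0
    S = S / peaks[:, None]
    A = A * peaks[None, :]
    return ModuleDecomposition(
        M=M,
        A=A,
        S=S,
        n_modules=n_modules,
        sse=sse,
        sst=float(np.sum(M**2)),
        n_restarts=n_restarts,
        best_seed=best_seed,
        task_blocks=task_blocks or {},
        channel_ids=channel_ids,
    )


def _warm_start_fit(
    M: np.ndarray, prev: ModuleDecomposition, max_iter: int = 400
) -> tuple[float, np.ndarray, np.ndarray]:
    """One extra candidate for N+1 modules: the N-module solution padded
    with a near-zero module.  Guarantees the best (N+1)-fit is at least as
    good as the best N-fit, making the VAF curve monotone by construction.
    """
    eps = 1e-6 * max(M.max(), 1e-30)
    W0 = np.hstack([np.maximum(prev.A, eps), np.full((M.shape[0], 1), eps)])
    H0 = np.vstack([np.maximum(prev.S, eps), np.full((1, M.shape[1]), eps)])
    model = NMF(
        n_components=prev.n_modules + 1, init="custom", solver="cd",
        max_iter=max_iter, tol=1e-5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        A = model.fit_transform(M, W=W0, H=H0)
    S = model.components_
    return float(np.sum((M - A @ S) ** 2)), A, S


def select_module_count(
    M: np.ndarray,
    n_range: range = range(1, 11),
    vaf_threshold: float = 0.90,
    n_restarts: int = 100,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, dict[int, float], dict[int, ModuleDecomposition]]:
    """Smallest module count whose VAF reaches the threshold.

    Returns ``(n_star, vaf_curve, decompositions)``.  If no count in the
    range qualifies, the arg-max of the VAF curve is returned with a warning.
    """
    curve: dict[int, float] = {}
    decs: dict[int, ModuleDecomposition] = {}
    prev: ModuleDecomposition | None = None
    for n in n_range:
        dec = fit_nnmf(M, n, n_restarts=n_restarts, seed=seed, **fit_kwargs)
        if prev is not None and prev.n_modules == n - 1:
            sse_w, A_w, S_w = _warm_start_fit(M, prev)
            if sse_w < dec.sse:
                dec = _finalize(M, A_w, S_w, sse_w, n, n_restarts, -1,
                                dec.task_blocks, dec.channel_ids)
        curve[n] = dec.vaf
        decs[n] = dec
        prev = dec
    qualifying = [n for n, v in curve.items() if v >= vaf_threshold]
    if qualifying:
        n_star = min(qualifying)
    else:
        n_star = max(curve, key=curve.get)
        warnings.warn(
            f"no module count reached VAF {vaf_threshold}; using arg-max {n_star}",
            stacklevel=2,
        )
    return n_star, curve, decs


def module_similarity(
    S_a: np.ndarray, S_b: np.ndarray, threshold: float = 0.7
) -> list[tuple[int, int, float]]:
    """Pearson links between two temporal-module sets sharing the time axis.

    Returns ``(i, j, r)`` for every pair with ``r > threshold``; constant
    (zero-variance) modules are excluded with a warning.  Used to show that
    the set with N modules is essentially preserved in the set with N+1, and
    to match modules across conditions.
    """
    S_a, S_b = np.asarray(S_a, float), np.asarray(S_b, float)
    if S_a.shape[1] != S_b.shape[1]:
        raise ValueError("module sets must share the time axis")
    links = []
    for i, si in enumerate(S_a):
        if si.std() == 0:
            warnings.warn(f"module {i} in first set is constant; excluded",
                          stacklevel=2)
            continue
        for j, sj in enumerate(S_b):
            if sj.std() == 0:
                continue
            r = float(np.corrcoef(si, sj)[0, 1])
            if r > threshold:
                links.append((i, j, r))
    return links


def classify_modules(S: np.ndarray, A: np.ndarray | None = None) -> dict[str, int]:
    """Label modules by activation timing over the normalized cycle.

    The module peaking in the second half of the cycle is the extensor
    module (extension follows flexion within each cycle); the one peaking in
    the first half is the flexor module.  When several modules share a half,
    the one carrying the most spatial weight (column sum of ``A``, or the
    temporal energy of ``S`` if no maps are given) wins.  Returns a
    label -> module-index map with keys ``extensor``/``flexor`` where
    identifiable.
    """
    T = S.shape[1]
    if T % 500 == 0:  # concatenated 500-point cycles: phase within the cycle
        peaks = (S.argmax(axis=1) % 500) / 500
    else:
        peaks = S.argmax(axis=1) / T
    strength = (
        np.abs(A).sum(axis=0) if A is not None else np.sum(S**2, axis=1)
    )
    out: dict[str, int] = {}
    second = [i for i, p in enumerate(peaks) if p >= 0.5]
    first = [i for i, p in enumerate(peaks) if p < 0.5]
    if second:
        out["extensor"] = max(second, key=lambda i: strength[i])
    if first:
        out["flexor"] = max(first, key=lambda i: strength[i])
    return out
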