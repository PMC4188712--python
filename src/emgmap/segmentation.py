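"""Segmentation of spatial coefficient maps into activity clusters.

Each module's coefficient map over the electrode grid is segmented in two
steps: watershed on the inverted, histogram-equalized map separates areas of
different amplitude; within each area, electrodes whose coefficient reaches
70% of the area maximum form the activity cluster.  Clusters are summarized
by their center of gravity (COG, in IED units), pairwise overlap (normalized
to the smaller and to the larger cluster), inter-condition COG shifts, and
the module weight at the barycenter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.measure import label as sk_label
from skimage.segmentation import watershed as sk_watershed

from .grid import GridLayout

__all__ = [
    "CoefficientMap",
    "ActivityCluster",
    "segment_map",
    "cog",
    "overlap",
    "cog_shift",
    "barycenter_weight",
    "weight_ratio",
    "cog_position_test",
]


@dataclass
class CoefficientMap:
    """Nonnegative module-coefficient map over the grid.

    ``values[x-1, y-1]`` is the coefficient of electrode (x, y); masked
    (bad) cells are excluded from equalization, segmentation and statistics.
    """

    values: np.ndarray  # (n_cols, n_rows)
    grid: GridLayout
    mask: np.ndarray | None = None  # True = bad/excluded

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_cols, self.grid.n_rows):
            raise ValueError("map shape must be (n_cols, n_rows)")
        if (self.values < 0).any():
            raise ValueError("coefficient map must be nonnegative")
        if self.mask is None:
            self.mask = np.zeros_like(self.values, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @classmethod
    def from_channels(
        cls, values: np.ndarray, grid: GridLayout, bad_mask: np.ndarray | None = None
    ) -> "CoefficientMap":
        m = grid.to_grid(values)
        mask = grid.to_grid(bad_mask).astype(bool) if bad_mask is not None else None
        return cls(values=m, grid=grid, mask=mask)


@dataclass
class ActivityCluster:
    """4-connected electrode subset where one module is mostly represented."""

    electrodes: list[tuple[int, int]]  # (x_el, y_el), 1-based
    weights: np.ndarray  # coefficient per member electrode
    grid: GridLayout
    cog: tuple[float, float] = field(init=False)
    total_weight: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.electrodes:
            raise ValueError("cluster must contain at least one electrode")
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")
        self.total_weight = float(self.weights.sum())
        self.cog = cog(self)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes)

    def electrode_set(self) -> set[tuple[int, int]]:
        return set(self.electrodes)


def _equalize(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Rank-based histogram equalization to [0, 1] over unmasked cells.

    Ties share their mean rank; masked cells are set to 0.
    """
    out = np.zeros_like(values, dtype=float)
    good = ~mask
    v = values[good]
    if v.size == 1:
        out[good] = 1.0
        return out
    ranks = stats.rankdata(v, method="average")
    out[good] = (ranks - 1) / (v.size - 1)
    return out


def segment_map(
    cmap: CoefficientMap,
    threshold: float = 0.70,
    noise_floor: float = 0.10,
) -> list[ActivityCluster]:
    """Two-step segmentation of a coefficient map into activity clusters.

    Step 1: marker-free watershed (4-connectivity) on the inverted
    histogram-equalized map yields catchment regions around local maxima.
    Step 2: within each region, electrodes with coefficient >= ``threshold``
    times the regional maximum form the cluster (the connected component
    containing the regional maximum, to keep clusters 4-connected).  Regions
    whose maximum is below ``noise_floor`` times the global maximum are
    discarded as noise.  An all-zero map yields an empty list with a warning.
    """
    vals = np.where(cmap.mask, 0.0, cmap.values)
    if vals.max() <= 0:
        warnings.warn("all-zero coefficient map: no clusters", stacklevel=2)
        return []
    eq = _equalize(cmap.values, cmap.mask)
    inverted = 1.0 - eq
    regions = sk_watershed(inverted, connectivity=1, mask=~cmap.mask)
    global_max = vals.max()
    clusters: list[ActivityCluster] = []
    for region_id in np.unique(regions):
        if region_id == 0:
            continue
        in_region = regions == region_id
        rmax = vals[in_region].max()
        if rmax < noise_floor * global_max or rmax <= 0:
            continue
        keep = in_region & (vals >= threshold * rmax)
        # keep the 4-connected component containing the regional maximum
        comp = sk_label(keep, connectivity=1)
        peak_idx = np.unravel_index(np.argmax(np.where(in_region, vals, -1)), vals.shape)
        comp_id = comp[peak_idx]
        cells = np.argwhere(comp == comp_id)
        electrodes = [(int(x) + 1, int(y) + 1) for x, y in cells]
        weights = np.array([vals[x - 1, y - 1] for x, y in electrodes])
        clusters.append(ActivityCluster(electrodes=electrodes, weights=weights,
                                        grid=cmap.grid))
    return clusters


def cog(cluster: ActivityCluster) -> tuple[float, float]:
    """Center of gravity of a cluster in continuous grid (IED) coordinates.

    ``xbar = sum(c_el * x_el) / A`` and ``ybar = sum(c_el * y_el) / A`` with
    ``c_el`` the member weights and ``A`` their sum.
    """
    w = np.asarray(cluster.weights, dtype=float)
    a = w.sum()
    if a <= 0:
        raise ValueError("zero total weight")
    xs = np.array([e[0] for e in cluster.electrodes], dtype=float)
    ys = np.array([e[1] for e in cluster.electrodes], dtype=float)
    return float((w * xs).sum() / a), float((w * ys).sum() / a)


def overlap(cl_a: ActivityCluster, cl_b: ActivityCluster) -> tuple[float, float]:
    """Percentage overlap of two clusters under both normalizations.

    Returns ``(100*i/min(|a|,|b|), 100*i/max(|a|,|b|))`` with ``i`` the
    number of shared electrodes: the first measures inclusion of the smaller
    area in the bigger one, the second the area common to both.
    """
    ia = cl_a.electrode_set()
    ib = cl_b.electrode_set()
    i = len(ia & ib)
    return 100.0 * i / min(len(ia), len(ib)), 100.0 * i / max(len(ia), len(ib))


def cog_shift(
    cl_cond1: ActivityCluster,
    cl_cond2: ActivityCluster,
    axis: str = "x",
) -> float:
    """COG displacement between two conditions, in IED units.

    ``axis='x'`` gives the ulnar--radial component ``|x1 - x2|``, ``'y'``
    the proximal--distal component, ``'euclidean'`` the planar distance.
    The clusters must belong to the same (temporally matched) module, which
    is the caller's responsibility (see pipeline.match_modules).
    """
    x1, y1 = cl_cond1.cog
    x2, y2 = cl_cond2.cog
    if axis == "x":
        return abs(x1 - x2)
    if axis == "y":
        return abs(y1 - y2)
    if axis == "euclidean":
        return float(np.hypot(x1 - x2, y1 - y2))
    raise ValueError(f"unknown axis {axis!r}")


def _fill_masked(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked cells by their nearest unmasked value (for interpolation)."""
    if not mask.any():
        return values
    _, (ix, iy) = ndimage.distance_transform_edt(mask, return_indices=True)
    return values[ix, iy]


def barycenter_weight(cmap: CoefficientMap, cog_xy: tuple[float, float]) -> float:
    """Bilinear interpolation of the coefficient map at the COG location."""
    x, y = cog_xy
    if not (1 <= x <= cmap.grid.n_cols and 1 <= y <= cmap.grid.n_rows):
        raise ValueError(f"COG {cog_xy} outside the grid")
    vals = _fill_masked(cmap.values, cmap.mask)
    x0 = max(1, min(int(np.floor(x)), cmap.grid.n_cols - 1))
    y0 = max(1, min(int(np.floor(y)), cmap.grid.n_rows - 1))
    fx, fy = x - x0, y - y0
    v00 = vals[x0 - 1, y0 - 1]
    v10 = vals[x0, y0 - 1]
    v01 = vals[x0 - 1, y0]
    v11 = vals[x0, y0]
    return float(
        v00 * (1 - fx) * (1 - fy)
        + v10 * fx * (1 - fy)
        + v01 * (1 - fx) * fy
        + v11 * fx * fy
    )


def weight_ratio(
    map_prone: CoefficientMap,
    cog_prone: tuple[float, float],
    map_neutral: CoefficientMap,
    cog_neutral: tuple[float, float],
) -> float:
    """Prone/neutral ratio of the module weight at each condition's barycenter."""
    w_n = barycenter_weight(map_neutral, cog_neutral)
    if w_n < 1e-9:
        raise ValueError("neutral barycenter weight is ~0; ratio undefined")
    return barycenter_weight(map_prone, cog_prone) / w_n


def cog_position_test(
    cogs_cond1: np.ndarray,
    cogs_cond2: np.ndarray,
    axis: str = "x",
) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired COG coordinates.

    ``cogs_cond*`` are (n, 2) arrays of per-subject COGs; the test is run on
    the chosen coordinate with the exact null distribution for n <= 25.
    All-zero differences return p = 1 with a warning.
    """
    c1 = np.atleast_2d(np.asarray(cogs_cond1, dtype=float))
    c2 = np.atleast_2d(np.asarray(cogs_cond2, dtype=float))
    if c1.shape != c2.shape:
        raise ValueError("paired samples must have equal shapes")
    if c1.shape[0] < 5:
        raise ValueError("need at least 5 pairs")
    col = {"x": 0, "y": 1}[axis]
    diffs = c1[:, col] - c2[:, col]
    if np.allclose(diffs, 0):
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    method = "exact" if diffs.size <= 25 else "auto"
    return float(stats.wilcoxon(diffs, alternative="two-sided", method=method).pvalue)
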