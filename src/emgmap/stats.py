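"""Group comparisons: one-way ANOVA with Student-Newman-Keuls post-hoc.

Used to compare joint-angle reconstruction quality (r^2) between electrode
subsets.  The SNK procedure tests ordered subsets of group means stepwise
against the studentized range, with the usual blocking rule (a range that is
not significant blocks all sub-ranges it contains).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sp_stats


@lru_cache(maxsize=256)
def _q_crit(alpha: float, span: int, df: int) -> float:
    return float(sp_stats.studentized_range.ppf(1 - alpha, span, df))

__all__ = ["AnovaSnkResult", "anova_snk"]


@dataclass
class AnovaSnkResult:
    f_stat: float
    p_value: float
    group_means: dict[str, float]
    significant_pairs: list[tuple[str, str]]
    alpha: float

    def pair_significant(self, a: str, b: str) -> bool:
        return (a, b) in self.significant_pairs or (b, a) in self.significant_pairs


def anova_snk(groups: dict[str, np.ndarray], alpha: float = 0.05) -> AnovaSnkResult:
    """One-way ANOVA followed by the SNK stepwise post-hoc.

    ``groups`` maps label -> sample; the SNK comparison of the pair spanning
    ``r`` ordered means uses the critical studentized range
    ``q(1-alpha, r, df_error)`` with the pooled error variance (harmonic
    mean of the pair's sizes for unbalanced groups).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if np.ptp([s.mean() for s in samples]) == 0:
        f_stat, p_value = 0.0, 1.0  # no between-group variation at all
    else:
        f_stat, p_value = sp_stats.f_oneway(*samples)

    n_total = sum(s.size for s in samples)
    k = len(samples)
    df_err = n_total - k
    means = np.array([s.mean() for s in samples])
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / df_err

    order = np.argsort(means)[::-1]  # descending
    sig: list[tuple[str, str]] = []
    # stepwise: examine spans from widest to narrowest; blocked spans are skipped
    blocked: set[tuple[int, int]] = set()
    for span in range(k, 1, -1):
        for start in range(0, k - span + 1):
            end = start + span - 1
            if (start, end) in blocked:
                continue
            i, j = order[start], order[end]
            n_h = 2.0 / (1.0 / samples[i].size + 1.0 / samples[j].size)
            se = np.sqrt(mse / n_h)
            if se == 0:
                significant = means[i] != means[j]
            else:
                q = (means[i] - means[j]) / se
                significant = q > _q_crit(alpha, span, df_err)
            if significant:
                sig.append((labels[i], labels[j]))
            else:
                for s2 in range(start, end + 1):
                    for e2 in range(s2 + 1, end + 1):
                        blocked.add((s2, e2))
    return AnovaSnkResult(
        f_stat=float(f_stat),
        p_value=float(p_value),
        group_means={k_: float(s.mean()) for k_, s in zip(labels, samples)},
        significant_pairs=sig,
        alpha=alpha,
    )
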