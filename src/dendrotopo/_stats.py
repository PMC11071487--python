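"""Small statistical helpers not provided by scipy.

Currently: Dunn's post-hoc test (rank-based multiple comparison after
Kruskal-Wallis) with Bonferroni adjustment, including the tie correction.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats

__all__ = ["dunn_bonferroni"]


def dunn_bonferroni(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's z-test p-values for all group pairs, Bonferroni-adjusted.

    ``groups`` maps group name to 1-D sample.  Returns
    ``{(name_a, name_b): adjusted p}`` with p capped at 1.
    """
    names = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    ties = float(np.sum(counts ** 3 - counts))
    tie_corr = ties / (12.0 * (n_total - 1)) if n_total > 1 else 0.0

    mean_ranks = {}
    start = 0
    for name, s in zip(names, samples):
        mean_ranks[name] = ranks[start:start + s.size].mean()
        start += s.size

    m = len(names) * (len(names) - 1) // 2
    out = {}
    sizes = {name: s.size for name, s in zip(names, samples)}
    for a, b in itertools.combinations(names, 2):
        na, nb = sizes[a], sizes[b]
        se = math.sqrt((n_total * (n_total + 1) / 12.0 - tie_corr)
                       * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        out[(a, b)] = min(1.0, p * m)
    return out
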