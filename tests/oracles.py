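"""Independent brute-force oracles for the exact nonparametric tests.

These enumerate the full permutation nulls directly (sign assignments,
group labelings, within-block orderings) and are deliberately written
without reusing any package internals, so they can certify the package's
exact modes.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def _two_sided(p_le: float, p_ge: float) -> float:
    return min(1.0, 2.0 * min(p_le, p_ge))


def brute_wilcoxon(x, y, alternative="two-sided") -> float:
    """Enumerate all 2^n sign assignments of the nonzero differences."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(ranks[np.array(signs, dtype=bool)].sum())
    ws = np.array(ws)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    p_le = np.mean(ws <= w_obs + 1e-12)
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(_two_sided(p_le, p_ge))


def brute_mannwhitney(g1, g2, alternative="two-sided") -> float:
    """Enumerate all C(n1+n2, n1) labelings of the pooled sample."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n1 = g1.size
    pooled = np.concatenate([g1, g2])
    ranks = rankdata(pooled)
    r_obs = ranks[:n1].sum()
    sums = np.array([ranks[list(c)].sum()
                     for c in itertools.combinations(range(pooled.size), n1)])
    p_ge = np.mean(sums >= r_obs - 1e-12)
    p_le = np.mean(sums <= r_obs + 1e-12)
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(_two_sided(p_le, p_ge))


def _friedman_chi2(ranks: np.ndarray) -> float:
    # tie-corrected chi-square form, written independently of the package
    n, k = ranks.shape
    rj = ranks.sum(axis=0)
    num = (k - 1) * (np.sum(rj ** 2) - n * n * k * (k + 1) ** 2 / 4.0)
    den = np.sum(ranks ** 2) - n * k * (k + 1) ** 2 / 4.0
    return 0.0 if den <= 0 else float(num / den)


def brute_friedman(blocks) -> float:
    """Enumerate all (k!)^n within-block orderings of the observed ranks."""
    blocks = np.asarray(blocks, dtype=float)
    ranks = np.vstack([rankdata(row) for row in blocks])
    n, k = ranks.shape
    obs = _friedman_chi2(ranks)
    perms = list(itertools.permutations(range(k)))
    hits = total = 0
    for assignment in itertools.product(range(len(perms)), repeat=n):
        permuted = np.vstack([ranks[i, list(perms[a])]
                              for i, a in enumerate(assignment)])
        if _friedman_chi2(permuted) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total
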