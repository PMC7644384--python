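"""Nonparametric test battery: Wilcoxon signed-rank, Mann–Whitney U,
Friedman, and Bonferroni post-hoc machinery.

All tests are rank-based with midrank tie handling. Small samples use exact
null distributions — computed by count-generating dynamic programming for
the signed-rank and U statistics and by within-block permutation for
Friedman — so that p-values are exact even with ties; larger samples use
the standard normal/chi-square approximations (with continuity and tie
corrections), matching conventional statistical packages.

Two-sided exact p-values follow the doubling convention
``min(1, 2 * min(P(T <= t), P(T >= t)))``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateError

#: Largest sample size handled by the exact signed-rank / U distributions.
EXACT_N_WILCOXON = 12
EXACT_N_MANNWHITNEY = 12
#: Exact Friedman permutation bounds (subjects, conditions).
EXACT_FRIEDMAN = (6, 4)


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p: float
    n: int
    method: str = "exact"  # "exact" | "approx"
    extra: dict = field(default_factory=dict)
    posthoc: list[dict] | None = None


def _two_sided(p_le: float, p_ge: float) -> float:
    return min(1.0, 2.0 * min(p_le, p_ge))


def _signed_rank_counts(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of 2*W+ over all sign assignments.

    ``ranks2`` are doubled midranks (integers). Returns counts[s] = number
    of sign vectors with positive-rank sum s (on the doubled scale).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_matched(x, y, alternative: str = "two-sided",
                     exact_n: int = EXACT_N_WILCOXON) -> StatResult:
    """Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped; ties get midranks. Exact p (all 2^n sign
    assignments, via the count-distribution recursion) for n <= ``exact_n``,
    otherwise normal approximation with tie correction and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateError("all paired differences are zero")
    if n < 5:
        raise DegenerateError(f"only {n} nonzero differences; need >= 5")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    if n <= exact_n:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_counts(ranks2)
        total = counts.sum()
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        method = "exact"
    else:
        tie_sizes = np.array([np.sum(ranks == r) for r in np.unique(ranks)])
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_sizes ** 3 - tie_sizes) / 48.0
        sd = math.sqrt(var)
        p_le = sps.norm.cdf((w_plus - mean + 0.5) / sd)
        p_ge = sps.norm.sf((w_plus - mean - 0.5) / sd)
        method = "approx"
    if alternative == "two-sided":
        p = _two_sided(p_le, p_ge)
    elif alternative == "greater":  # x tends larger than y
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return StatResult("wilcoxon_matched", w_plus, float(min(p, 1.0)), n,
                      method=method, extra={"mean_w": mean})


def _u_counts(ranks2: np.ndarray, n1: int) -> dict[int, float]:
    """Distribution of the group-1 doubled rank sum over all labelings."""
    # DP over (#chosen, doubled rank sum) -> count
    counts = {(0, 0): 1.0}
    for r in ranks2.astype(int):
        new = dict(counts)
        for (k, s), c in counts.items():
            if k < n1:
                key = (k + 1, s + r)
                new[key] = new.get(key, 0.0) + c
        counts = new
    return {s: c for (k, s), c in counts.items() if k == n1}


def mann_whitney(g1, g2, alternative: str = "two-sided",
                 exact_n: int = EXACT_N_MANNWHITNEY) -> StatResult:
    """Mann–Whitney U test for two independent groups.

    Exact p (all C(n1+n2, n1) labelings, via subset-sum counting) when
    n1 + n2 <= ``exact_n``; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n1, n2 = g1.size, g2.size
    if n1 == 0 or n2 == 0:
        raise DegenerateError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    if n1 + n2 <= exact_n:
        ranks2 = np.rint(2 * ranks).astype(int)
        dist = _u_counts(ranks2, n1)
        total = sum(dist.values())
        s = int(round(2 * r1))
        p_le = sum(c for v, c in dist.items() if v <= s) / total
        p_ge = sum(c for v, c in dist.items() if v >= s) / total
        method = "exact"
    else:
        mean = n1 * n2 / 2.0
        N = n1 + n2
        tie_sizes = np.array([np.sum(ranks == r) for r in np.unique(ranks)])
        tie_term = np.sum(tie_sizes ** 3 - tie_sizes) / (N * (N - 1))
        var = n1 * n2 / 12.0 * (N + 1 - tie_term)
        sd = math.sqrt(var)
        p_le = sps.norm.cdf((u1 - mean + 0.5) / sd)
        p_ge = sps.norm.sf((u1 - mean - 0.5) / sd)
        method = "approx"
    if alternative == "two-sided":
        p = _two_sided(p_le, p_ge)
    elif alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return StatResult("mann_whitney", u1, float(min(p, 1.0)), n1 + n2,
                      method=method, extra={"n1": n1, "n2": n2})


def _friedman_stat(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square statistic from within-block ranks."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * float(np.sum(col_sums ** 2) - n * n * k * (k + 1) ** 2 / 4.0)
    den = float(np.sum(ranks ** 2) - n * k * (k + 1) ** 2 / 4.0)
    if den <= 0:
        return 0.0
    return num / den


def friedman(blocks, exact_bounds: tuple[int, int] = EXACT_FRIEDMAN) -> StatResult:
    """Friedman test on a subjects x conditions matrix.

    Rows containing missing cells (NaN) are dropped and counted in the
    result extras. Ties get midranks with the standard tie-corrected
    statistic. For small designs (<= 6 subjects, <= 4 conditions) the p is
    an exact within-block permutation p; otherwise chi-square with k-1 df.
    A fully tied design yields statistic 0, p = 1 (flagged degenerate).
    """
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2:
        raise ValueError("blocks must be a 2-D subjects x conditions matrix")
    keep = ~np.isnan(blocks).any(axis=1)
    dropped = int((~keep).sum())
    blocks = blocks[keep]
    n, k = blocks.shape
    if k < 3:
        raise ValueError("need >= 3 conditions")
    if n < 5:
        raise DegenerateError(f"only {n} complete subjects; need >= 5")
    ranks = np.vstack([sps.rankdata(row) for row in blocks])
    stat = _friedman_stat(ranks)
    degenerate = stat == 0.0 and np.all(ranks == ranks[:, :1])
    if n <= exact_bounds[0] and k <= exact_bounds[1]:
        perms = list(itertools.permutations(range(k)))
        count = 0
        total = 0
        for assignment in itertools.product(perms, repeat=n):
            permuted = np.vstack([ranks[i, list(pr)] for i, pr in enumerate(assignment)])
            if _friedman_stat(permuted) >= stat - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "exact"
    else:
        p = float(sps.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
        method = "approx"
    return StatResult("friedman", stat, p, n, method=method,
                      extra={"k": k, "dropped_subjects": dropped,
                             "degenerate": bool(degenerate)})


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    m = m if m is not None else p.size
    return np.minimum(1.0, m * p)


def posthoc_pairs(blocks, alpha: float = 0.05,
                  labels: list[str] | None = None) -> list[dict]:
    """All pairwise Wilcoxon matched tests with Bonferroni adjustment.

    Intended after a significant Friedman omnibus on the same matrix; the
    multiplier m is the number of condition pairs.
    """
    blocks = np.asarray(blocks, dtype=float)
    keep = ~np.isnan(blocks).any(axis=1)
    blocks = blocks[keep]
    k = blocks.shape[1]
    labels = labels if labels is not None else [f"c{j}" for j in range(k)]
    pairs = list(itertools.combinations(range(k), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        try:
            res = wilcoxon_matched(blocks[:, i], blocks[:, j])
            raw = res.p
            stat = res.statistic
        except DegenerateError:
            raw, stat = 1.0, float("nan")
        adj = float(min(1.0, m * raw))
        out.append({"pair": (labels[i], labels[j]), "statistic": stat,
                    "raw_p": raw, "adjusted_p": adj,
                    "significant": adj < alpha,
                    "median_diff": float(np.median(blocks[:, i] - blocks[:, j]))})
    return out
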