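"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (enumeration,
closed-form textbook formulas, memoized recursion) and shares no code with
the package.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb, sqrt

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import t as _t


def fisher_enum_two_sided(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


def yates_formula(table) -> tuple[float, float]:
    """Yates-corrected chi-square by the textbook formula, cell by cell."""
    t = [[float(v) for v in row] for row in table]
    total = sum(sum(row) for row in t)
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = sum(t[i]) * (t[0][j] + t[1][j]) / total
            adj = abs(t[i][j] - e) - 0.5
            if adj < 0:
                adj = 0.0
            stat += adj * adj / e
    return stat, float(_chi2.sf(stat, 1))


def ols_closed_form(x, y) -> dict:
    """OLS slope/intercept/R^2/slope-p from the summation formulas."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    syy = ((y - y.mean()) ** 2).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    ss_res = syy - slope * sxy
    r2 = 1.0 - ss_res / syy if syy > 0 else 0.0
    se = sqrt(ss_res / (n - 2) / sxx)
    t_stat = slope / se
    p = 2.0 * float(_t.sf(abs(t_stat), n - 2))
    return {"slope": slope, "intercept": intercept, "r_squared": r2, "p_value": p}


def welch_t(a, b) -> tuple[float, float]:
    """Welch two-sample t from the textbook formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t_stat = (a.mean() - b.mean()) / sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t_stat, 2.0 * float(_t.sf(abs(t_stat), df))


def paired_log10_t(a, b) -> tuple[float, float]:
    """Paired t on log10 ratios from the textbook formula."""
    d = np.log10(np.asarray(a, float)) - np.log10(np.asarray(b, float))
    n = len(d)
    t_stat = d.mean() / (d.std(ddof=1) / sqrt(n))
    return t_stat, 2.0 * float(_t.sf(abs(t_stat), n - 1))


def semi_global_score(
    read: str,
    consensus: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
) -> float:
    """Optimal semi-global score by memoized recursion over (i, j, last-op).

    Consensus end gaps are free: the alignment may start at any consensus
    offset and stops as soon as the read is consumed. A gap of length g
    costs gap_open + (g-1)*gap_extend.
    """
    n, m = len(read), len(consensus)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, last: str) -> float:
        if i == n:
            return 0.0  # trailing consensus gap is free
        best = -float("inf")
        if j < m:
            s = match if read[i] == consensus[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
            cost = gap_extend if last == "X" else gap_open
            best = max(best, cost + rec(i, j + 1, "X"))
        cost = gap_extend if last == "Y" else gap_open
        best = max(best, cost + rec(i + 1, j, "Y"))
        return best

    result = max(rec(0, j0, "M") for j0 in range(m + 1))
    rec.cache_clear()
    return result


def sliding_dinucleotide_counts(seq: str) -> tuple[int, int]:
    """CG and TG counts by an explicit window scan."""
    n_cg = n_tg = 0
    for i in range(len(seq) - 1):
        w = seq[i : i + 2]
        if w == "CG":
            n_cg += 1
        elif w == "TG":
            n_tg += 1
    return n_cg, n_tg


def brute_force_gene_labels(sites, genes, distance: int):
    """Genic/proximal/intergenic by an all-pairs distance scan."""
    labels = []
    for _, site in sites.iterrows():
        pos = int(site["pos"])
        best = None
        for g in genes:
            if g.chrom != site["chrom"]:
                continue
            if g.start <= pos < g.end:
                best = 0
                break
            d = g.start - pos if pos < g.start else pos - (g.end - 1)
            best = d if best is None else min(best, d)
        if best is None:
            labels.append("intergenic")
        elif best == 0:
            labels.append("genic")
        elif best <= distance:
            labels.append("proximal")
        else:
            labels.append("intergenic")
    return labels
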