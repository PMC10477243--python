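"""Independent brute-force oracles used to validate the implementations.

Everything here is written from first principles (definitions, not the
package's code paths) and deliberately favours clarity over speed.
"""

from __future__ import annotations

import math

import numpy as np


def bh_brute_force(p_values):
    """O(m^2) Benjamini-Hochberg step-up straight from the definition:
    padj_i = min over j with p_(j) >= p_(i) of m*p_(j)/j, capped at 1."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank_i, i in enumerate(order, start=1):
        best = math.inf
        for rank_j, j in enumerate(order, start=1):
            if rank_j >= rank_i:
                best = min(best, m * p[j] / rank_j)
        adj[i] = min(best, 1.0)
    return adj


def count_intron_brute(reads, intron_start, intron_end, min_overhang):
    """Interval-membership re-derivation of the spliced/unspliced rule.

    reads: list of block tuples [(s0,e0), (s1,e1), ...].
    """
    spliced = 0
    unspliced = 0
    for blocks in reads:
        is_spliced = False
        for a, b in zip(blocks, blocks[1:]):
            gap = (a[1], b[0])
            if gap == (intron_start, intron_end):
                if (a[1] - a[0]) >= min_overhang and (b[1] - b[0]) >= min_overhang:
                    is_spliced = True
        if is_spliced:
            spliced += 1
            continue
        crosses = False
        for s, e in blocks:
            for boundary in (intron_start, intron_end):
                if s + min_overhang <= boundary <= e - min_overhang:
                    crosses = True
        internal = all(s >= intron_start and e <= intron_end for s, e in blocks)
        if crosses or internal:
            unspliced += 1
    return spliced, unspliced


def count_junction_brute(reads, junction, min_overhang):
    """Reads with a gap exactly equal to ``junction`` with enough overhang."""
    count = 0
    for blocks in reads:
        for a, b in zip(blocks, blocks[1:]):
            if (a[1], b[0]) == junction and (a[1] - a[0]) >= min_overhang and (
                b[1] - b[0]
            ) >= min_overhang:
                count += 1
                break
    return count


def welch_brute(a, b):
    """Welch statistic, Welch-Satterthwaite df, and two-sided p by formula."""
    from scipy import stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va = a.var(ddof=1) / len(a)
    vb = b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def fisher_meta_closed_form(p1, p2):
    """Chi-square(4) survival at x = -2(ln p1 + ln p2): e^(-x/2) (1 + x/2)."""
    x = -2.0 * (math.log(p1) + math.log(p2))
    return math.exp(-x / 2.0) * (1.0 + x / 2.0)


def bound_ligand_numeric(n_mt, xt, kd):
    """Bound concentration from the quadratic Kd*B = (nMt - B)(Xt - B) via
    a numeric root-finder, independent of the closed form."""
    from scipy import optimize

    def f(b):
        return kd * b - (n_mt - b) * (xt - b)

    hi = min(n_mt, xt)
    if hi == 0:
        return 0.0
    return optimize.brentq(f, 0.0, hi, xtol=1e-18, rtol=1e-15)


def random_read_blocks(rng, lo=0, hi=1000, max_blocks=3, min_len=1, max_len=120):
    """A random strictly-increasing block tuple for oracle comparisons."""
    n_blocks = int(rng.integers(1, max_blocks + 1))
    blocks = []
    cursor = int(rng.integers(lo, hi))
    for _ in range(n_blocks):
        length = int(rng.integers(min_len, max_len))
        blocks.append((cursor, cursor + length))
        cursor += length + int(rng.integers(1, 200))
    return tuple(blocks)
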