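"""Independent brute-force oracles used to freeze expected values.

Everything here deliberately avoids the code paths it checks: grid
maximization instead of the closed-form MLE, direct step-up arithmetic
instead of the BH wrapper, full enumeration instead of scipy's exact
tests, Monte-Carlo permutation instead of the hypergeometric sum.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def grid_mle(beta_bs: float, n_bs: float, beta_ox: float, n_ox: float, step: float = 1e-4):
    """Maximize the joint binomial log-likelihood over the (m, h) lattice.

    Exhaustive maximization over q = m + h and m <= q on a ``step``
    lattice, exploiting that the log-likelihood separates into f(q) + g(m);
    the running maximum over m reproduces the full 2-D lattice optimum
    exactly. Returns (m, h) at the lattice maximum.
    """
    x_bs = round(beta_bs * n_bs)
    x_ox = round(beta_ox * n_ox)
    grid = np.arange(0.0, 1.0 + step / 2, step)

    def loglik(x, n, p):
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = x * np.log(p) + (n - x) * np.log1p(-p)
        ll = np.where((p == 0) & (x == 0), 0.0, ll)
        ll = np.where((p == 1) & (x == n), 0.0, ll)
        ll = np.where((p == 0) & (x > 0), -np.inf, ll)
        ll = np.where((p == 1) & (x < n), -np.inf, ll)
        return ll

    f = loglik(x_bs, n_bs, grid)        # BS channel, parameter q = m + h
    g = loglik(x_ox, n_ox, grid)        # oxBS channel, parameter m
    total = f + np.maximum.accumulate(g)
    q_idx = int(np.argmax(total))
    m_idx = int(np.argmax(g[: q_idx + 1]))
    return grid[m_idx], grid[q_idx] - grid[m_idx]


def bh_stepup(p):
    """Benjamini-Hochberg adjusted p-values by the direct definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def mannwhitney_exact(a, b):
    """Exact two-sided rank-sum p by enumerating all group labelings."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)

    def u_stat(group_a_idx):
        group_a = [pooled[i] for i in group_a_idx]
        group_b = [pooled[i] for i in range(len(pooled)) if i not in set(group_a_idx)]
        return sum(1 for x in group_a for y in group_b if x > y) + \
            0.5 * sum(1 for x in group_a for y in group_b if x == y)

    observed = u_stat(range(n_a))
    us = [u_stat(comb) for comb in itertools.combinations(range(len(pooled)), n_a)]
    total = len(us)
    lower = sum(1 for u in us if u <= observed + 1e-12) / total
    upper = sum(1 for u in us if u >= observed - 1e-12) / total
    return observed, min(1.0, 2.0 * min(lower, upper))


def hypergeom_upper_tail(k, universe, n_a, n_b):
    """P[X >= k] for X ~ Hypergeometric(universe, n_a, n_b), exact sum."""
    total = math.comb(universe, n_b)
    upper = min(n_a, n_b)
    return sum(
        math.comb(n_a, j) * math.comb(universe - n_a, n_b - j) for j in range(k, upper + 1)
    ) / total


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher exact p by enumerating tables with fixed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (math.comb(row1, x) * math.comb(n - row1, col1 - x)) / math.comb(n, col1)

    p_obs = prob(a)
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def overlap_permutation_p(k, universe, n_a, n_b, n_draws=100_000, seed=0):
    """Monte-Carlo estimate of P[|A&B| >= k] for random B of fixed size."""
    rng = np.random.default_rng(seed)
    hits = 0
    items = np.arange(universe)
    a_set = set(range(n_a))
    for _ in range(n_draws):
        draw = rng.choice(items, size=n_b, replace=False)
        if len(a_set.intersection(draw.tolist())) >= k:
            hits += 1
    return hits / n_draws
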