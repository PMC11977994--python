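"""Independent oracles used by the test suite.

These deliberately avoid the package's computational paths: the Fisher
oracle enumerates all tables with fixed margins using exact integer
binomial coefficients and solves the estimating equations by plain
bisection; the similarity oracle enumerates common ancestors by
explicitly walking parent edges.
"""

from __future__ import annotations

import math

import numpy as np

P_TIE_TOL = 1.0 + 1e-7


def fisher_oracle_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by explicit enumeration of one table's margins."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    total = sum(weights)
    probs = [w / total for w in weights]
    p_obs = probs[a - lo]
    return min(1.0, sum(p for p in probs if p <= p_obs * P_TIE_TOL))


def _support_grids(tables: np.ndarray):
    a, b, c, d = tables.T
    r1, r2, c1 = a + b, c + d, a + c
    lo = np.maximum(0, c1 - r2)
    hi = np.minimum(r1, c1)
    width = int((hi - lo).max()) + 1
    ks = lo[:, None] + np.arange(width)[None, :]
    valid = ks <= hi[:, None]
    # exact integer binomial products, evaluated per table
    logw = np.full(ks.shape, -np.inf)
    for i in range(tables.shape[0]):
        for j in range(width):
            if valid[i, j]:
                k = int(ks[i, j])
                w = math.comb(int(r1[i]), k) * math.comb(int(r2[i]), int(c1[i]) - k)
                logw[i, j] = math.log(w)
    return a, lo, hi, np.where(valid, ks, lo[:, None]), valid, logw


def _cond_pmf(logw, ks, valid, t):
    logits = np.where(valid, logw + ks * t[:, None], -np.inf)
    logits = logits - logits.max(axis=1, keepdims=True)
    z = np.where(valid, np.exp(logits), 0.0)
    return z / z.sum(axis=1, keepdims=True)


def _bisect_rows(g, target, active, n, lo0=-60.0, hi0=60.0, iters=64, increasing=True):
    lo = np.full(n, lo0)
    hi = np.full(n, hi0)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        v = g(mid)
        right = (v < target) if increasing else (v > target)
        lo = np.where(right & active, mid, lo)
        hi = np.where(~right & active, mid, hi)
    return 0.5 * (lo + hi)


def fisher_oracle(tables, alpha: float = 0.05):
    """Batch oracle: p, conditional-MLE OR and exact CI for 2x2 tables.

    ``tables`` is an (n, 4) array of (a, b, c, d) rows with positive
    margins.  Returns dict of arrays mirroring the quantities under test.
    """
    tables = np.asarray(tables, dtype=np.int64)
    a, lo, hi, ks, valid, logw = _support_grids(tables)
    n = tables.shape[0]
    kf = ks.astype(float)

    pmf0 = _cond_pmf(logw, kf, valid, np.zeros(n))
    # sort-and-cumsum construction of the two-sided p
    order = np.argsort(pmf0, axis=1)
    sorted_p = np.take_along_axis(pmf0, order, axis=1)
    csum = np.cumsum(sorted_p, axis=1)
    p_obs = pmf0[np.arange(n), a - lo]
    idx = (sorted_p <= (p_obs * P_TIE_TOL)[:, None]).sum(axis=1) - 1
    p = np.minimum(1.0, csum[np.arange(n), idx])

    at_lo, at_hi = a == lo, a == hi

    def mean_at(t):
        return (_cond_pmf(logw, kf, valid, t) * kf).sum(axis=1)

    def tail_ge_at(t):
        pm = _cond_pmf(logw, kf, valid, t)
        return np.where(kf >= a[:, None], pm, 0.0).sum(axis=1)

    def tail_le_at(t):
        pm = _cond_pmf(logw, kf, valid, t)
        return np.where(kf <= a[:, None], pm, 0.0).sum(axis=1)

    interior = ~(at_lo | at_hi)
    t_hat = _bisect_rows(mean_at, a.astype(float), interior, n)
    or_cmle = np.where(interior, np.exp(t_hat), np.nan)
    or_cmle = np.where(at_lo & ~at_hi, 0.0, or_cmle)
    or_cmle = np.where(at_hi & ~at_lo, np.inf, or_cmle)

    half = alpha / 2.0
    t_lo = _bisect_rows(tail_ge_at, np.full(n, half), ~at_lo, n)
    ci_low = np.where(~at_lo, np.exp(t_lo), 0.0)
    t_hi = _bisect_rows(tail_le_at, np.full(n, half), ~at_hi, n, increasing=False)
    ci_high = np.where(~at_hi, np.exp(t_hi), np.inf)
    return {"p": p, "or_cmle": or_cmle, "ci_low": ci_low, "ci_high": ci_high}


def ancestors_by_walk(term: str, parents_of: dict[str, set[str]]) -> set[str]:
    """Ancestors-or-self by explicit breadth-first parent walking."""
    seen = {term}
    frontier = [term]
    while frontier:
        nxt = []
        for t in frontier:
            for p in parents_of.get(t, ()):
                if p not in seen:
                    seen.add(p)
                    nxt.append(p)
        frontier = nxt
    return seen


def resnik_oracle(a: str, b: str, ic: dict[str, float], edges) -> float:
    parents_of: dict[str, set[str]] = {}
    for child, parent in edges:
        parents_of.setdefault(child, set()).add(parent)
    common = ancestors_by_walk(a, parents_of) & ancestors_by_walk(b, parents_of)
    vals = [ic[t] for t in common if t in ic]
    return max(vals) if vals else 0.0


def lin_oracle(a: str, b: str, ic: dict[str, float], edges, roots) -> float:
    mica = resnik_oracle(a, b, ic, edges)
    denom = ic[a] + ic[b]
    if denom == 0:
        return 1.0 if (a == b and a in roots) else 0.0
    return min(1.0, max(0.0, 2 * mica / denom))


def random_dag(rng: np.random.Generator, n_terms: int):
    """Random layered DAG edge list for property tests (multiple parents)."""
    terms = [f"N{i}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.3)
        choices = rng.choice(i, size=min(n_parents, i), replace=False)
        for j in choices:
            edges.append((terms[i], terms[j]))
    return terms, edges
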