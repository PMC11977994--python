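"""Vectorized Fisher exact test machinery.

A 2x2 table ``[[a, b], [c, d]]`` conditioned on its margins follows a
noncentral hypergeometric distribution in the first cell ``a`` with odds
parameter psi.  This module computes, for batches of tables at once:

* the two-sided Fisher exact p-value (total probability of tables, under
  psi = 1, no more probable than the observed one);
* the conditional maximum-likelihood estimate of psi (the odds ratio
  reported by R's ``fisher.test``);
* the exact confidence interval obtained by inverting the conditional
  tail probabilities at alpha/2 per side.

Everything is computed on a padded ``(batch, support)`` grid with a fixed
number of bisection iterations, so cost is a handful of dense numpy passes
regardless of batch size.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

# relative tolerance for "no more probable than observed", matching the
# convention of R's fisher.test and scipy
_P_REL_TOL = 1.0 + 1e-7

_SOLVE_ITER = 40
_LOG_PSI_BOUND = 60.0  # psi bracketed in [e^-60, e^60]


def _log_binom(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


class _Grid:
    """Padded support grid for a batch of tables with fixed margins."""

    def __init__(self, a, b, c, d):
        a, b, c, d = (np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
        if a.shape != b.shape or b.shape != c.shape or c.shape != d.shape:
            raise ValueError("cell arrays must share a shape")
        if np.any((a < 0) | (b < 0) | (c < 0) | (d < 0)):
            raise ValueError("negative cell count")
        r1, r2 = a + b, c + d
        c1 = a + c
        if np.any((r1 == 0) | (r2 == 0) | (c1 == 0) | (b + d == 0)):
            raise ValueError("Fisher test undefined for a table with an empty margin")
        self.a = a
        self.lo = np.maximum(0, c1 - r2)
        self.hi = np.minimum(r1, c1)
        width = int(np.max(self.hi - self.lo)) + 1
        k = self.lo[:, None] + np.arange(width)[None, :]
        self.valid = k <= self.hi[:, None]
        k = np.where(self.valid, k, self.lo[:, None])
        self.k = k.astype(np.float64)
        # log weights of the (central) hypergeometric kernel
        logw = _log_binom(r1[:, None].astype(float), self.k) + _log_binom(
            r2[:, None].astype(float), c1[:, None].astype(float) - self.k
        )
        self.logw = np.where(self.valid, logw, -np.inf)
        self.obs = (a - self.lo)[:, None] == (self.k - self.lo[:, None])

    def pmf(self, log_psi: np.ndarray) -> np.ndarray:
        """Conditional pmf over the support at odds exp(log_psi) (per row)."""
        logits = self.logw + self.k * log_psi[:, None]
        logits -= logits.max(axis=1, keepdims=True)
        z = np.exp(logits, where=np.isfinite(logits), out=np.zeros_like(logits))
        return z / z.sum(axis=1, keepdims=True)

    def mean(self, log_psi: np.ndarray):
        """Conditional mean and its derivative (= variance) w.r.t. log psi."""
        p = self.pmf(log_psi)
        m = (p * self.k).sum(axis=1)
        v = (p * self.k * self.k).sum(axis=1) - m * m
        return m, v

    def tail_ge(self, log_psi: np.ndarray):
        """log P(X >= a) and its derivative w.r.t. log psi (increasing)."""
        p = self.pmf(log_psi)
        sel = self.k >= self.a[:, None]
        g = np.where(sel, p, 0.0).sum(axis=1)
        m = (p * self.k).sum(axis=1)
        m_sel = np.where(sel, p * self.k, 0.0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log(g), m_sel / g - m

    def tail_le(self, log_psi: np.ndarray):
        """log P(X <= a) and its derivative w.r.t. log psi (decreasing)."""
        p = self.pmf(log_psi)
        sel = self.k <= self.a[:, None]
        g = np.where(sel, p, 0.0).sum(axis=1)
        m = (p * self.k).sum(axis=1)
        m_sel = np.where(sel, p * self.k, 0.0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log(g), m_sel / g - m


def _solve(func, target, rows, t0, increasing: bool) -> np.ndarray:
    """Solve func(log_psi) = target per row.

    Safeguarded Newton: each step falls back to bisection of the maintained
    bracket whenever the Newton update leaves it, so the fixed iteration
    count guarantees convergence for every row.
    """
    lo = np.full_like(t0, -_LOG_PSI_BOUND)
    hi = np.full_like(t0, _LOG_PSI_BOUND)
    t = np.clip(t0, lo + 1.0, hi - 1.0)
    for _ in range(_SOLVE_ITER):
        val, dval = func(t)
        resid = val - target
        below = resid < 0 if increasing else resid > 0
        lo = np.where(below & rows, t, lo)
        hi = np.where(~below & rows, t, hi)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = t - resid / dval
        mid = 0.5 * (lo + hi)
        ok = np.isfinite(step) & (step > lo) & (step < hi)
        t_next = np.where(ok, step, mid)
        # an exactly-zero residual is a solved row: keep it (the Newton
        # step would land on the bracket edge and trigger a midpoint jump)
        t_next = np.where(resid == 0.0, t, t_next)
        done = (~rows) | (np.abs(t_next - t) < 1e-11) | (hi - lo < 1e-10)
        t = t_next
        if done.all():
            break
    return t


def fisher_batch(a, b, c, d, alpha: float = 0.05):
    """Exact Fisher results for a batch of 2x2 tables ``[[a, b], [c, d]]``.

    Returns a dict of arrays: ``p`` (two-sided), ``or_cmle`` (conditional
    MLE odds ratio; 0, +inf or NaN at the support edges), ``ci_low``,
    ``ci_high`` (exact ``1 - alpha`` interval), ``or_sample``.
    """
    g = _Grid(a, b, c, d)
    n_rows = g.a.shape[0]

    # two-sided p at psi = 1
    pmf0 = g.pmf(np.zeros(n_rows))
    p_obs = np.where(g.obs, pmf0, np.nan)
    p_obs = np.nansum(p_obs, axis=1)
    small = pmf0 <= (p_obs * _P_REL_TOL)[:, None]
    p = np.where(small & g.valid, pmf0, 0.0).sum(axis=1)
    p = np.minimum(p, 1.0)

    at_lo = g.a == g.lo
    at_hi = g.a == g.hi
    degenerate = at_lo & at_hi  # single-point support

    af, bf, cf, df = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    # continuity-corrected sample log-OR as the Newton starting point
    t0 = np.log((af + 0.5) * (df + 0.5)) - np.log((bf + 0.5) * (cf + 0.5))

    interior = ~(at_lo | at_hi)
    log_or = _solve(g.mean, g.a.astype(float), interior, t0, increasing=True)
    or_cmle = np.exp(log_or)
    or_cmle = np.where(at_lo & ~degenerate, 0.0, or_cmle)
    or_cmle = np.where(at_hi & ~degenerate, np.inf, or_cmle)
    or_cmle = np.where(degenerate, np.nan, or_cmle)

    log_half = np.log(alpha / 2.0)
    target = np.full(n_rows, log_half)
    # lower bound: psi with P(X >= a) = alpha/2 (tail increasing in psi)
    need_low = ~at_lo
    log_lo = _solve(g.tail_ge, target, need_low, t0 - 2.0, increasing=True)
    ci_low = np.where(need_low, np.exp(log_lo), 0.0)
    # upper bound: psi with P(X <= a) = alpha/2 (tail decreasing in psi)
    need_high = ~at_hi
    log_hi = _solve(g.tail_le, target, need_high, t0 + 2.0, increasing=False)
    ci_high = np.where(need_high, np.exp(log_hi), np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        or_sample = (af * df) / (bf * cf)

    return {
        "p": p,
        "or_cmle": or_cmle,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "or_sample": or_sample,
    }
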