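"""Brute-force fine-grid posterior integration, independent of the package.

Integrates the joint density of (delta, lambda) on a fixed uniform grid
(default: lambda step 1e-3 over [-9, 0] intersected with the model's lambda
floor, delta step 1e-3 over [-3, 3]) with the trapezoid rule, using SciPy's
binomial pmf and Gaussian pdf directly.  Used as the reference for the
adaptive per-gene integration in ``asc.posterior``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import binom, norm

LN10 = math.log(10.0)


def _lattice_logpmf(x, N, lo, n_vals, step):
    """Binomial log-pmf at proportions 10**(lo + k*step), k = 0..n_vals-1."""
    y = lo + step * np.arange(n_vals)
    pi = np.power(10.0, np.minimum(y, 0.0))
    with np.errstate(divide="ignore"):
        lp = binom.logpmf(x, N, pi)
    return np.where(y > 0.0, -np.inf, lp)


def oracle_delta_marginal(
    x1,
    x2,
    N1,
    N2,
    alpha,
    tau,
    lam_lo=-9.0,
    lam_step=1e-3,
    d_lo=-3.0,
    d_hi=3.0,
    d_step=1e-3,
    chunk=400,
):
    """Return (delta_grid, normalized density) by exhaustive 2-D integration.

    The lambda domain is [max(lam_lo, floor), 0] where floor is the model's
    hard lower bound log10(0.25/(N1+N2)); the prior tilt is exp(-alpha*lam)
    and the delta prior N(0, tau^2).  lam_step must equal 2*(delta half-step)
    lattice-compatible spacing; with both steps 1e-3 the evaluation points
    of lambda +/- delta/2 lie on a lattice of spacing 5e-4, so the binomial
    pmf is evaluated once per lattice point and indexed.
    """
    floor = math.log10(0.25 / (N1 + N2))
    lo = max(lam_lo, floor)
    lam = np.arange(lo, 0.0 + lam_step / 2.0, lam_step)
    delta = np.arange(d_lo, d_hi + d_step / 2.0, d_step)
    nl, nd = len(lam), len(delta)
    half = d_step / 2.0
    assert abs(lam_step - 2.0 * half) < 1e-12, "steps must be lattice-compatible"
    # u = lam_i + delta_j/2 = (lam[0] + delta[0]/2) + (2i + j) * half
    n_u = 2 * (nl - 1) + (nd - 1) + 1
    lp1 = _lattice_logpmf(x1, N1, lam[0] + delta[0] / 2.0, n_u, half)
    # v = lam_i - delta_j/2 = (lam[0] - delta[-1]/2) + (2i + (nd-1-j)) * half
    lp2 = _lattice_logpmf(x2, N2, lam[0] - delta[-1] / 2.0, n_u, half)
    log_prior_d = norm.logpdf(delta, 0.0, tau)
    j = np.arange(nd)
    jrev = nd - 1 - j
    # accumulate the log of the lambda-integral for each delta, trapezoid weights
    wl = np.full(nl, lam_step)
    wl[0] = wl[-1] = lam_step / 2.0
    m_best = np.full(nd, -np.inf)
    acc = np.zeros(nd)
    for start in range(0, nl, chunk):
        idx = np.arange(start, min(start + chunk, nl))
        base = 2 * idx[:, None]
        L = lp1[base + j[None, :]] + lp2[base + jrev[None, :]]
        L += log_prior_d[None, :]
        L += (-alpha * lam[idx])[:, None]
        m_chunk = np.max(L, axis=0)
        m_chunk = np.where(np.isfinite(m_chunk), m_chunk, -np.inf)
        with np.errstate(under="ignore", invalid="ignore"):
            contrib = np.where(
                np.isfinite(m_chunk)[None, :], np.exp(L - m_chunk[None, :]), 0.0
            )
            s_chunk = wl[idx] @ contrib
        # merge running (m_best, acc) with the chunk's (m_chunk, s_chunk)
        m_new = np.maximum(m_best, m_chunk)
        with np.errstate(under="ignore", invalid="ignore"):
            acc = np.where(
                np.isfinite(m_new),
                np.where(np.isfinite(m_best), acc * np.exp(m_best - m_new), 0.0)
                + np.where(np.isfinite(m_chunk), s_chunk * np.exp(m_chunk - m_new), 0.0),
                0.0,
            )
        m_best = m_new
    offset = np.max(m_best[np.isfinite(m_best)])
    with np.errstate(under="ignore"):
        marg = np.where(np.isfinite(m_best), acc * np.exp(m_best - offset), 0.0)
    z = np.trapezoid(marg, delta)
    return delta, marg / z


def oracle_summary(x1, x2, N1, N2, alpha, tau, delta0=None, **kw):
    """Posterior mean of delta and (optionally) P(|delta| > delta0)."""
    d, g = oracle_delta_marginal(x1, x2, N1, N2, alpha, tau, **kw)
    delta_hat = float(np.trapezoid(g * d, d))
    if delta0 is None:
        return delta_hat
    inner = _interval_mass(d, g, -delta0, delta0)
    return delta_hat, float(min(max(1.0 - inner, 0.0), 1.0))


def _interval_mass(d, g, a, b):
    """Trapezoid integral of g over [a, b] with interpolated end points."""
    a = max(a, d[0])
    b = min(b, d[-1])
    if b <= a:
        return 0.0
    ga, gb = np.interp([a, b], d, g)
    ia = int(np.searchsorted(d, a, side="right"))
    ib = int(np.searchsorted(d, b, side="left"))
    x = np.concatenate(([a], d[ia:ib], [b]))
    y = np.concatenate(([ga], g[ia:ib], [gb]))
    return float(np.trapezoid(y, x))
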