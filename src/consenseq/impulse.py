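"""The impulse expression model and its negative-binomial likelihood fit.

The impulse curve is a product of two logistic transitions,

    f(t) = (1/h1) * [h0 + (h1-h0)*sigma(beta*(t-t1))]
                  * [h2 + (h1-h2)*sigma(-beta*(t-t2))]

with strictly positive levels h0 (initial), h1 (peak/transition) and h2
(terminal), transition times t1 <= t2 and slope beta > 0. It represents
monotone trajectories (t2 outside the observed window) as well as transient
ones (onset and offset inside it).

Per-gene fits maximize the negative-binomial log-likelihood of counts with
mean f(t) * library_offset and a fixed, externally supplied dispersion.
Differential dynamics between a treated and a control arm are tested by a
likelihood-ratio test of one shared curve against separate per-arm curves.
The reference chi-square degrees of freedom equal the number of additional
identifiable mean dimensions — the number of (condition, timepoint) cells
in the alternative minus the number of timepoint cells in the null — rather
than the raw parameter-count difference, because with few distinct
timepoints the six-parameter curve is overparameterized and the raw count
would make the test badly conservative.

Optimization is deterministic: Nelder-Mead refinement of a fixed set of
data-driven starts (cell-mean levels with midpoint transition times at two
slopes, plus a flat curve; alternative fits additionally start from the
null solution, which guarantees the alternative log-likelihood is never
below the null).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats

__all__ = ["ImpulseParams", "evaluate_impulse", "fit_impulse_curve", "fit_impulse_nb"]

# bounds on theta = (log h0, log h1, log h2, t1, t2, log beta)
_LO = np.array([-9.2, -9.2, -9.2, -5.0, -5.0, math.log(0.05)])
_HI = np.array([20.7, 20.7, 20.7, 20.0, 20.0, math.log(20.0)])


@dataclass
class ImpulseParams:
    h0: float
    h1: float
    h2: float
    t1: float
    t2: float
    beta: float

    def __post_init__(self) -> None:
        if min(self.h0, self.h1, self.h2) <= 0:
            raise ValueError("impulse levels must be strictly positive")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.t1 > self.t2:  # canonical ordering: onset before offset
            self.t1, self.t2 = self.t2, self.t1

    def as_theta(self) -> np.ndarray:
        return np.array([math.log(self.h0), math.log(self.h1), math.log(self.h2),
                         self.t1, self.t2, math.log(self.beta)])

    @classmethod
    def from_theta(cls, th: np.ndarray) -> "ImpulseParams":
        return cls(math.exp(th[0]), math.exp(th[1]), math.exp(th[2]),
                   float(th[3]), float(th[4]), math.exp(th[5]))


def _sigma(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def evaluate_impulse(params, t) -> np.ndarray:
    """Evaluate the impulse mean curve at times ``t`` (hours).

    ``params`` may be an :class:`ImpulseParams`, a mapping with keys
    h0/h1/h2/t1/t2/beta, or a 6-vector in that order.
    """
    if isinstance(params, ImpulseParams):
        h0, h1, h2, t1, t2, beta = params.h0, params.h1, params.h2, params.t1, params.t2, params.beta
    elif isinstance(params, dict):
        h0, h1, h2, t1, t2, beta = (params[k] for k in ("h0", "h1", "h2", "t1", "t2", "beta"))
    else:
        h0, h1, h2, t1, t2, beta = params
    if min(h0, h1, h2) <= 0:
        raise ValueError("impulse levels must be strictly positive")
    t = np.asarray(t, dtype=float)
    s1 = _sigma(beta * (t - t1))
    s2 = _sigma(-beta * (t - t2))
    return (h0 + (h1 - h0) * s1) * (h2 + (h1 - h2) * s2) / h1


# ---------------------------------------------------------------------------
# numba core

@njit(fastmath=False)
def _nll(th, y, t, off, phi, lo, hi):
    pen = 0.0
    h = np.empty(6)
    for i in range(6):
        v = th[i]
        if v < lo[i]:
            pen += (lo[i] - v) ** 2
            v = lo[i]
        elif v > hi[i]:
            pen += (v - hi[i]) ** 2
            v = hi[i]
        h[i] = v
    if h[3] > h[4]:  # soft ordering t1 <= t2
        pen += (h[3] - h[4]) ** 2
        mid = 0.5 * (h[3] + h[4])
        h[3] = mid
        h[4] = mid
    h0 = math.exp(h[0]); h1 = math.exp(h[1]); h2 = math.exp(h[2])
    t1 = h[3]; t2 = h[4]; beta = math.exp(h[5])
    total = 1e4 * pen
    use_pois = phi < 1e-12
    r = 0.0 if use_pois else 1.0 / phi
    for s in range(y.shape[0]):
        x1 = beta * (t[s] - t1)
        if x1 > 60.0:
            x1 = 60.0
        elif x1 < -60.0:
            x1 = -60.0
        s1 = 1.0 / (1.0 + math.exp(-x1))
        x2 = beta * (t2 - t[s])
        if x2 > 60.0:
            x2 = 60.0
        elif x2 < -60.0:
            x2 = -60.0
        s2 = 1.0 / (1.0 + math.exp(-x2))
        f = (h0 + (h1 - h0) * s1) * (h2 + (h1 - h2) * s2) / h1
        mu = f * off[s]
        if mu < 1e-10:
            mu = 1e-10
        ys = y[s]
        if use_pois:
            ll = ys * math.log(mu) - mu - math.lgamma(ys + 1.0)
        else:
            ll = (math.lgamma(ys + r) - math.lgamma(r) - math.lgamma(ys + 1.0)
                  + r * math.log(r / (r + mu)) + ys * math.log(mu / (r + mu)) if ys > 0
                  else r * math.log(r / (r + mu)))
        total -= ll
    return total


@njit(fastmath=False)
def _nelder_mead(y, t, off, phi, x0, step, lo, hi, maxiter, ftol):
    n = 6
    sim = np.empty((n + 1, n))
    fv = np.empty(n + 1)
    sim[0] = x0
    fv[0] = _nll(x0, y, t, off, phi, lo, hi)
    for i in range(n):
        x = x0.copy()
        x[i] += step[i]
        sim[i + 1] = x
        fv[i + 1] = _nll(x, y, t, off, phi, lo, hi)
    for _ in range(maxiter):
        order = np.argsort(fv)
        sim = sim[order]
        fv = fv[order]
        if fv[n] - fv[0] <= ftol * (abs(fv[0]) + 1e-9):
            break
        centroid = np.zeros(n)
        for i in range(n):
            centroid += sim[i]
        centroid /= n
        xr = centroid + (centroid - sim[n])
        fr = _nll(xr, y, t, off, phi, lo, hi)
        if fr < fv[0]:
            xe = centroid + 2.0 * (centroid - sim[n])
            fe = _nll(xe, y, t, off, phi, lo, hi)
            if fe < fr:
                sim[n] = xe
                fv[n] = fe
            else:
                sim[n] = xr
                fv[n] = fr
        elif fr < fv[n - 1]:
            sim[n] = xr
            fv[n] = fr
        else:
            if fr < fv[n]:
                xc = centroid + 0.5 * (xr - centroid)
            else:
                xc = centroid + 0.5 * (sim[n] - centroid)
            fc = _nll(xc, y, t, off, phi, lo, hi)
            if fc < min(fr, fv[n]):
                sim[n] = xc
                fv[n] = fc
            else:  # shrink toward best
                for i in range(1, n + 1):
                    sim[i] = sim[0] + 0.5 * (sim[i] - sim[0])
                    fv[i] = _nll(sim[i], y, t, off, phi, lo, hi)
    best = int(np.argmin(fv))
    return sim[best], fv[best]


@njit(fastmath=False)
def _fit_multistart(y, t, off, phi, inits, maxiter, ftol):
    best_th = inits[0].copy()
    best_f = np.inf
    step = np.array([0.3, 0.3, 0.3, 1.0, 1.0, 0.4])
    for k in range(inits.shape[0]):
        th, f = _nelder_mead(y, t, off, phi, inits[k], step, _LO, _HI, maxiter, ftol)
        f0 = _nll(inits[k], y, t, off, phi, _LO, _HI)
        if f0 < f:  # never accept a step that worsened the start
            th, f = inits[k].copy(), f0
        if f < best_f:
            best_f = f
            best_th = th
    return best_th, best_f


# ---------------------------------------------------------------------------
# python drivers

def _cell_means(y, t, off):
    """Mean CPM-scale level per distinct timepoint (offset-corrected)."""
    ts = np.unique(t)
    m = np.empty(ts.size)
    for i, tv in enumerate(ts):
        sel = t == tv
        m[i] = np.sum(y[sel]) / np.sum(off[sel])
    return ts, np.maximum(m, 1e-2)


def _build_inits(y, t, off, extra=None):
    ts, m = _cell_means(y, t, off)
    logm = np.log(m)
    flat = float(np.log(max(np.sum(y) / np.sum(off), 1e-2)))
    if ts.size == 1:
        cands = [np.array([flat, flat, flat, ts[0], ts[0] + 1.0, 0.0])]
    else:
        mids = 0.5 * (ts[:-1] + ts[1:])
        t1 = mids[0]
        t2 = mids[-1] if mids.size > 1 else mids[0] + 3.0
        first, peak, last = logm[0], logm[np.argmax(np.abs(logm - flat))], logm[-1]
        cands = []
        for lb in (math.log(1.0), math.log(3.0)):
            cands.append(np.array([first, logm[min(1, ts.size - 1)], last, t1, t2, lb]))
            cands.append(np.array([first, peak, last, t1, t2, lb]))
        cands.append(np.array([flat, flat, flat, t1, t2, 0.0]))
    if extra is not None:
        cands.extend(extra)
    return np.array(cands)


def fit_impulse_curve(y, t, offsets=None, dispersion=0.0, maxiter=300, ftol=1e-10):
    """Maximum-likelihood impulse fit to one gene's counts.

    Parameters
    ----------
    y : array of counts
    t : array of times (hours), same length
    offsets : multiplicative library offsets (library size / 1e6 puts the
        curve on the CPM scale); defaults to 1
    dispersion : fixed NB dispersion (0 = Poisson)

    Returns ``(ImpulseParams, log_likelihood)``.
    """
    y = np.asarray(y, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    off = np.ones_like(t) if offsets is None else np.asarray(offsets, dtype=np.float64)
    inits = _build_inits(y, t, off)
    th, f = _fit_multistart(y, t, off, float(dispersion), inits, maxiter, ftol)
    return ImpulseParams.from_theta(th), -float(f)


@dataclass
class ImpulseFit:
    """Result of the shared-vs-separate impulse likelihood-ratio test."""

    null_params: ImpulseParams
    alt_params: dict
    ll_null: float
    ll_alt: float
    statistic: float
    df: int
    p_value: float
    converged: bool = True


def fit_impulse_nb(y, t, condition, offsets=None, dispersion=0.0,
                   maxiter=300, ftol=1e-10) -> ImpulseFit:
    """Likelihood-ratio test of condition-dependent impulse dynamics.

    Null: one impulse curve for all samples. Alternative: an independent
    curve per condition. ``condition`` is a vector of labels; the test is
    symmetric in them. The alternative fit for each condition is seeded with
    the null solution, so ``ll_alt >= ll_null`` always.
    """
    y = np.asarray(y, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    off = np.ones_like(t) if offsets is None else np.asarray(offsets, dtype=np.float64)
    cond = np.asarray(condition)
    phi = float(dispersion)
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    labels = np.unique(cond)
    if labels.size < 2:
        raise ValueError("need at least two conditions")
    treated_times = [np.unique(t[cond == lab]).size for lab in labels]
    if max(treated_times) < 3:
        raise ValueError("need >=3 distinct timepoints in at least one arm")

    th0, f0 = _fit_multistart(y, t, off, phi, _build_inits(y, t, off), maxiter, ftol)
    ll_alt = 0.0
    alt = {}
    for lab in labels:
        sel = cond == lab
        inits = _build_inits(y[sel], t[sel], off[sel], extra=[th0])
        th, f = _fit_multistart(y[sel], t[sel], off[sel], phi, inits, maxiter, ftol)
        alt[lab] = ImpulseParams.from_theta(th)
        ll_alt += -f
    ll_null = -f0
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    n_cells_alt = sum(np.unique(t[cond == lab]).size for lab in labels)
    # identifiable extra mean dimensions, capped by the parameter count
    df = min(int(n_cells_alt - np.unique(t).size), 6 * (labels.size - 1))
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return ImpulseFit(ImpulseParams.from_theta(th0), alt, ll_null, ll_alt, stat, df, p)
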