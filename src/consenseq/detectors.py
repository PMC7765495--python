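"""Four independent per-gene time-course differential-expression tests.

All four compare an inhibitor arm against its time-matched DMSO control:

``pairwise_nb``
    Per-timepoint negative-binomial Wald tests of the treated/control mean
    difference on the log scale (variance from the shrunk dispersion and the
    pooled mean), combined across timepoints by the Sidak minimum-p
    transform, which is exactly uniform under independent null timepoints.
``impulse_lrt``
    Likelihood-ratio test of one shared impulse curve against separate
    per-arm curves under an NB likelihood (see :mod:`consenseq.impulse`).
``spline_f``
    Gaussian working model on log2(CPM + pc) with a natural-cubic-spline
    time basis; condition-dependent terms enter through interaction columns
    that vanish at t = 0 h (both arms coincide pre-treatment), and are
    tested with an empirical-Bayes moderated F statistic in the style of
    limma's variance squeezing.
``poly_twostage``
    Two-stage polynomial regression: a global F test of the full
    degree-d polynomial-in-time x condition model against an intercept-only
    model, followed by backward elimination of non-significant terms for the
    genes that pass stage one.

Untreated anchor samples at 0 h serve as the shared pre-treatment baseline
for the regression detectors and are excluded from the two count-based
contrasts; untreated 9 h anchors are solvent-effect controls and never
enter the tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .dispersion import estimate_dispersions
from .impulse import fit_impulse_nb
from .preprocess import CountMatrix, SampleSheet, ValidationError, cpm

DETECTOR_NAMES = ("pairwise_nb", "impulse_lrt", "spline_f", "poly_twostage")

__all__ = [
    "DETECTOR_NAMES",
    "adjust_pvalues",
    "detect_pairwise_nb",
    "detect_impulse",
    "detect_spline",
    "detect_polynomial",
    "run_detectors",
    "combine_results",
    "natural_spline_basis",
]


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(np.isnan(p)):
        raise ValidationError("NaN p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values outside [0,1]")
    if method.lower() not in ("bh", "fdr_bh"):
        raise ValidationError(f"unsupported adjustment {method!r}")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _result(gene_ids, statistic, p_raw, name, **extra) -> pd.DataFrame:
    p_raw = np.clip(np.asarray(p_raw, dtype=float), 0.0, 1.0)
    out = pd.DataFrame(
        {"statistic": statistic, "p_raw": p_raw, "p_adj": adjust_pvalues(p_raw), "detector": name},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    for k, v in extra.items():
        out[k] = v
    return out


def _contrast_samples(sheet: SampleSheet, treatment: str):
    """Treated and DMSO sample lists per nonzero timepoint."""
    times = [t for t in sheet.timepoints(treatment) if t != 0]
    groups = {}
    for t in times:
        trt, ctl = sheet.samples(treatment, t), sheet.samples("DMSO", t)
        if not trt or not ctl:
            raise ValidationError(f"missing treated or DMSO group at {t} h")
        groups[t] = (trt, ctl)
    return times, groups


# ---------------------------------------------------------------------------
# quasi-likelihood moderation shared by the count-based tests

def _ql_variance(matrix: CountMatrix, phi: np.ndarray, cells: list[list[str]]):
    """Quasi-dispersion per gene: Pearson X^2 of the saturated cell-means NB
    fit divided by its residual df, then empirical-Bayes squeezed across
    genes. Scaling Wald/LRT statistics by this variance and referencing an F
    distribution with the squeezed prior df in the denominator absorbs both
    small-sample anti-conservatism and dispersion-estimation noise (the
    quasi-likelihood F idiom of count-based DE tools)."""
    libs = matrix.lib_sizes
    x2 = np.zeros(matrix.counts.shape[0])
    d_res = 0
    for cell in cells:
        off = (libs[cell] / 1e6).to_numpy()
        y = matrix.counts[cell].to_numpy(dtype=float)
        m = y.sum(axis=1) / off.sum()
        mu = m[:, None] * off[None, :]
        denom = np.maximum(mu + phi[:, None] * mu ** 2, 1e-12)
        x2 += ((y - mu) ** 2 / denom).sum(axis=1)
        d_res += len(cell) - 1
    s2 = x2 / d_res
    s2_post, d0 = _squeeze_var(s2, d_res)
    return np.maximum(s2_post, 1e-8), d0, d_res


# ---------------------------------------------------------------------------
# pairwise NB Wald

def detect_pairwise_nb(matrix: CountMatrix, sheet: SampleSheet, treatment: str,
                       dispersions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-timepoint moderated NB Wald tests combined over timepoints.

    The squared Wald statistic is scaled by the quasi-dispersion and
    referenced against F(1, d0 + d_res); per-timepoint p-values combine by
    the Sidak minimum-p transform (exactly uniform under independent null
    timepoints)."""
    sheet.validate_against(matrix)
    if dispersions is None:
        dispersions = estimate_dispersions(matrix, sheet)
    phi = dispersions.loc[matrix.gene_ids, "phi_shrunk"].to_numpy()
    times, groups = _contrast_samples(sheet, treatment)
    x = cpm(matrix)
    libs = matrix.lib_sizes
    delta = 0.5e6 / float(np.exp(np.mean(np.log(libs))))  # half a count, CPM scale
    s2, d0, d_res = _ql_variance(matrix, phi, [g for t in times for g in groups[t]])
    df_den = min(d0 + d_res, 1e8)

    pmin = np.ones(matrix.counts.shape[0])
    zmax = np.zeros_like(pmin)
    for t in times:
        trt, ctl = groups[t]
        mT = x[trt].mean(axis=1).to_numpy()
        mC = x[ctl].mean(axis=1).to_numpy()
        pooled = x[trt + ctl].mean(axis=1).to_numpy() + delta
        d = np.log(mT + delta) - np.log(mC + delta)
        se2 = np.zeros_like(d)
        for grp in (trt, ctl):
            rel = sum(1e6 / (libs[s] * pooled) + phi for s in grp) / len(grp) ** 2
            se2 += rel
        z2 = d ** 2 / se2 / s2
        p = stats.f.sf(z2, 1, df_den)
        pmin = np.minimum(pmin, p)
        zmax = np.maximum(zmax, np.sqrt(z2))
    p_gene = 1.0 - (1.0 - pmin) ** len(times)
    return _result(matrix.gene_ids, zmax, p_gene, "pairwise_nb")


# ---------------------------------------------------------------------------
# impulse LRT

def detect_impulse(matrix: CountMatrix, sheet: SampleSheet, treatment: str,
                   dispersions: pd.DataFrame | None = None,
                   maxiter: int = 300) -> pd.DataFrame:
    """Shared-vs-separate impulse-curve NB likelihood-ratio test per gene,
    moderated by the quasi-dispersion: F = (LRT/df)/s2 against
    F(df, d0 + d_res)."""
    sheet.validate_against(matrix)
    if dispersions is None:
        dispersions = estimate_dispersions(matrix, sheet)
    phi = dispersions.loc[matrix.gene_ids, "phi_shrunk"].to_numpy()
    times, groups = _contrast_samples(sheet, treatment)
    samples, cond = [], []
    for t in times:
        trt, ctl = groups[t]
        samples += trt + ctl
        cond += ["case"] * len(trt) + ["control"] * len(ctl)
    cond = np.array(cond)
    tvec = sheet.table.loc[samples, "timepoint_h"].to_numpy(dtype=float)
    off = (matrix.lib_sizes[samples] / 1e6).to_numpy()
    counts = matrix.counts[samples].to_numpy(dtype=float)
    s2, d0, d_res = _ql_variance(matrix, phi, [g for t in times for g in groups[t]])
    df_den = min(d0 + d_res, 1e8)

    stat = np.empty(counts.shape[0])
    p = np.empty_like(stat)
    for i in range(counts.shape[0]):
        fit = fit_impulse_nb(counts[i], tvec, cond, off, phi[i], maxiter=maxiter)
        stat[i] = fit.statistic
        F = (fit.statistic / fit.df) / s2[i] if fit.df > 0 else 0.0
        p[i] = stats.f.sf(F, fit.df, df_den) if fit.df > 0 else 1.0
    return _result(matrix.gene_ids, stat, p, "impulse_lrt")


# ---------------------------------------------------------------------------
# spline moderated F

def natural_spline_basis(x, knots) -> np.ndarray:
    """Natural cubic spline basis (K knots -> K-1 columns, no intercept)."""
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    K = knots.size
    if K < 2:
        raise ValidationError("need at least two knots")

    def d(k, v):
        return (np.maximum(v - knots[k], 0) ** 3 - np.maximum(v - knots[-1], 0) ** 3) / (knots[-1] - knots[k])

    cols = [x]
    for k in range(K - 2):
        cols.append(d(k, x) - d(K - 2, x))
    return np.column_stack(cols)


def _regression_design(matrix: CountMatrix, sheet: SampleSheet, treatment: str,
                       pseudocount: float):
    """Samples, log2-CPM responses, times, condition indicator for the
    regression detectors (treated + DMSO arms, plus untreated 0 h anchors
    as shared baseline when present)."""
    times, groups = _contrast_samples(sheet, treatment)
    samples, cond = [], []
    for t in times:
        trt, ctl = groups[t]
        samples += trt + ctl
        cond += [1.0] * len(trt) + [0.0] * len(ctl)
    base = sheet.samples("untreated", 0)
    samples += base
    cond += [0.0] * len(base)
    y = np.log2(cpm(matrix)[samples].to_numpy() + pseudocount)
    tvec = sheet.table.loc[samples, "timepoint_h"].to_numpy(dtype=float)
    return samples, y, tvec, np.array(cond)


def _ols_rss(X, Y):
    """Residual sums of squares of Y (genes x samples) on design X."""
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    return np.sum(resid ** 2, axis=0), beta


def _trigamma_inverse(y: float) -> float:
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)

def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of residual variances (Smyth-style moment
    matching of a scaled inverse-chi-square prior on log variances).
    Returns (posterior variances, prior df)."""
    ok = s2 > 1e-12
    if ok.sum() < 2:
        return s2, np.inf
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0, s0 = np.inf, float(np.exp(np.mean(e)))
    if np.isinf(d0):
        post = np.full_like(s2, s0)
    else:
        post = (d0 * s0 + df * s2) / (d0 + df)
    return post, d0


def detect_spline(matrix: CountMatrix, sheet: SampleSheet, treatment: str,
                  df: int = 3, pseudocount: float = 0.5) -> pd.DataFrame:
    """Moderated F test of condition-dependent spline coefficients."""
    sheet.validate_against(matrix)
    samples, Y, tvec, cond = _regression_design(matrix, sheet, treatment, pseudocount)
    utimes = np.unique(tvec)
    if df >= utimes.size:
        raise ValidationError(f"spline df={df} requires more than {df} distinct timepoints")
    knots = np.quantile(utimes, np.linspace(0, 1, df + 1))
    B = natural_spline_basis(tvec, knots)
    B0 = natural_spline_basis(np.array([0.0]), knots)
    inter = cond[:, None] * (B - B0)  # vanishes at t=0: arms equal pre-treatment
    X_full = np.column_stack([np.ones_like(tvec), B, inter])
    X_null = np.column_stack([np.ones_like(tvec), B])
    k = inter.shape[1]
    rss1, _ = _ols_rss(X_full, Y)
    rss0, _ = _ols_rss(X_null, Y)
    df_res = Y.shape[1] - np.linalg.matrix_rank(X_full)
    s2 = rss1 / df_res
    s2_post, d0 = _squeeze_var(s2, df_res)
    df_total = df_res + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(s2_post > 0, (rss0 - rss1) / k / np.where(s2_post > 0, s2_post, 1.0), 0.0)
    F = np.where((rss0 - rss1) <= 1e-12, 0.0, F)
    p = stats.f.sf(F, k, min(df_total, 1e8))
    return _result(matrix.gene_ids, F, p, "spline_f")


# ---------------------------------------------------------------------------
# two-stage polynomial

def detect_polynomial(matrix: CountMatrix, sheet: SampleSheet, treatment: str,
                      degree: int = 2, alpha_stage1: float = 0.05,
                      elim_alpha: float = 0.05, pseudocount: float = 0.5) -> pd.DataFrame:
    """Two-stage polynomial regression (global F, then backward elimination)."""
    sheet.validate_against(matrix)
    samples, Y, tvec, cond = _regression_design(matrix, sheet, treatment, pseudocount)
    utimes = np.unique(tvec)
    if degree >= utimes.size:
        raise ValidationError(f"degree={degree} requires more than {degree} distinct timepoints")
    ts = tvec / max(utimes.max(), 1.0)  # scaled time for conditioning
    names, cols = [], []
    for d in range(1, degree + 1):
        names.append(f"time^{d}")
        cols.append(ts ** d)
    for d in range(1, degree + 1):
        names.append(f"cond:time^{d}")
        cols.append(cond * ts ** d)
    X_full = np.column_stack([np.ones_like(ts)] + cols)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValidationError("collinear polynomial design (duplicate timepoints collapse)")
    n = Y.shape[1]
    k = X_full.shape[1] - 1
    df_res = n - X_full.shape[1]
    rss1, _ = _ols_rss(X_full, Y)
    ybar = Y.mean(axis=1, keepdims=True)
    rss0 = np.sum((Y - ybar) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / k) / (rss1 / df_res)
    F = np.where(np.isfinite(F), F, np.inf)
    F = np.where((rss0 - rss1) <= 1e-12, 0.0, F)
    p1 = stats.f.sf(F, k, df_res)

    selected = np.array([""] * Y.shape[0], dtype=object)
    passing = np.where(p1 < alpha_stage1)[0]
    for i in passing:
        selected[i] = ";".join(_backward_eliminate(X_full, names, Y[i], elim_alpha))
    return _result(matrix.gene_ids, F, p1, "poly_twostage", selected_terms=selected)


def _backward_eliminate(X_full, names, y, alpha):
    keep = list(range(1, X_full.shape[1]))  # non-intercept columns
    while keep:
        X = X_full[:, [0] + keep]
        n, q = X.shape
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dfres = n - q
        s2 = resid @ resid / dfres if dfres > 0 else 0.0
        if s2 <= 1e-300:
            break
        XtX_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.maximum(np.diag(XtX_inv) * s2, 1e-300))
        tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), dfres)
        worst = int(np.argmax(pvals[1:])) + 1
        if pvals[worst] <= alpha:
            break
        keep.pop(worst - 1)
    return [names[j - 1] for j in keep]


# ---------------------------------------------------------------------------
# orchestration

def run_detectors(matrix: CountMatrix, sheet: SampleSheet, treatment: str,
                  dispersions: pd.DataFrame | None = None,
                  spline_df: int = 3, poly_degree: int = 2,
                  pseudocount: float = 0.5,
                  impulse_maxiter: int = 300) -> dict[str, pd.DataFrame]:
    """Run all four detectors for one inhibitor arm; returns name -> table."""
    if dispersions is None:
        dispersions = estimate_dispersions(matrix, sheet)
    return {
        "pairwise_nb": detect_pairwise_nb(matrix, sheet, treatment, dispersions),
        "impulse_lrt": detect_impulse(matrix, sheet, treatment, dispersions, maxiter=impulse_maxiter),
        "spline_f": detect_spline(matrix, sheet, treatment, df=spline_df, pseudocount=pseudocount),
        "poly_twostage": detect_polynomial(matrix, sheet, treatment, degree=poly_degree,
                                           pseudocount=pseudocount),
    }


def combine_results(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Wide table joining every detector's statistic / p_raw / p_adj."""
    parts = []
    for name, tab in results.items():
        parts.append(tab[["statistic", "p_raw", "p_adj"]].add_prefix(f"{name}_"))
    return pd.concat(parts, axis=1)
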