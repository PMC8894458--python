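"""Differential testing with precision weights and moderated statistics.

Counts are transformed to log2-CPM with a half-count offset,
``log2((count + 0.5) / (libsize + 1) * 1e6)``. A mean-variance trend is
fitted by LOWESS to (average log2-count, sqrt residual SD) across features;
each observation receives a precision weight equal to the predicted
standard deviation at its fitted value raised to the -4 (so weight ~ 1/var
on the quarter-root-SD scale, the voom construction). Per-feature weighted
least squares then yields coefficients and residual variances; variances
are shrunk toward a common prior by empirical Bayes — the prior degrees of
freedom d0 and prior variance s0^2 are estimated by method of moments on
log residual variances via digamma/trigamma identities, and the posterior
variance is (d0*s0^2 + d*s^2)/(d0 + d). Moderated t statistics carry
d0 + d degrees of freedom; p-values are two-sided and Benjamini-Hochberg
adjusted.

Significance calls use strict inequalities: adjusted p < alpha and
log2 fold change > lfc_threshold (or |log2FC| > threshold two-sided).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from pseudoex.quantify import CountMatrix, ExonBin

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEParams:
    lfc_threshold: float = 1.0
    alpha: float = 0.01
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")


@dataclass
class DEResult:
    feature_id: str
    mean_expr: float  # mean log2-CPM
    log2fc: float  # contrast condition minus reference
    t: float
    p: float
    adj_p: float = np.nan
    significant: bool = False
    direction: str = ""


def logcpm_transform(counts: CountMatrix) -> pd.DataFrame:
    """log2((count + 0.5) / (libsize + 1) * 1e6); finite everywhere."""
    lib = counts.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return np.log2((counts.counts + 0.5) / (lib + 1.0) * 1e6)


def build_design(conditions: list[str], reference: str) -> np.ndarray:
    """Two-column design: intercept and treatment indicator vs reference."""
    uniq = sorted(set(conditions))
    if reference not in uniq:
        raise ValueError(f"reference condition {reference!r} not present")
    X = np.column_stack(
        [np.ones(len(conditions)), [0.0 if c == reference else 1.0 for c in conditions]]
    )
    return X


def mean_variance_weights(
    logcpm: pd.DataFrame,
    design: np.ndarray,
    span: float = 0.5,
    iterations: int = 3,
) -> pd.DataFrame:
    """Per-observation precision weights from a LOWESS mean-variance trend.

    For each feature an OLS fit against ``design`` gives fitted values and a
    residual SD; the trend is LOWESS of sqrt(SD) on the feature's average
    log2-CPM (span 0.5, 3 robustness iterations). Weights are the trend
    prediction at each observation's fitted value, raised to the -4, and
    interpolated monotonically between fitted trend points. Features with
    zero residual degrees of freedom are excluded from trend fitting but
    still receive weights.
    """
    Y = logcpm.to_numpy(dtype=float)
    n_features, n_samples = Y.shape
    p = design.shape[1]
    df_resid = n_samples - p
    if df_resid < 1:
        raise ValueError("need >= 1 residual degree of freedom")
    groups = design[:, 1] if p > 1 else np.zeros(n_samples)
    for g in np.unique(groups):
        if (groups == g).sum() < 2:
            raise ValueError("need >= 2 samples per group")

    pinv = np.linalg.pinv(design)
    beta = Y @ pinv.T
    fitted = beta @ design.T
    resid = Y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / df_resid)

    sx = Y.mean(axis=1)
    sy = np.sqrt(sigma)  # quarter-root variance scale
    ok = sigma > 0
    if ok.sum() < 2:
        # degenerate: flat trend at the pooled SD
        level = max(float(np.sqrt(sigma.mean())), 1e-6)
        trend_x = np.array([sx.min() - 1, sx.max() + 1])
        trend_y = np.array([level, level])
    else:
        smooth = lowess(sy[ok], sx[ok], frac=span, it=iterations, return_sorted=True)
        trend_x, idx = np.unique(smooth[:, 0], return_index=True)
        trend_y = smooth[idx, 1]
    trend_y = np.clip(trend_y, 1e-6, None)
    pred = np.interp(fitted, trend_x, trend_y)
    weights = pred**-4.0
    return pd.DataFrame(weights, index=logcpm.index, columns=logcpm.columns)


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_prior(
    s2: np.ndarray, df: float, d0: float | None = None
) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) by method of moments on log variances.

    Uses the scaled-F model for residual variances: log s^2 has mean
    log s0^2 + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2) and excess
    variance trigamma(d0/2) beyond trigamma(d/2). A non-finite or
    non-positive moment estimate falls back to d0 = inf (fully pooled).
    When ``d0`` is supplied only s0^2 is estimated, conditioned on it.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    if d0 is None:
        evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
        if not np.isfinite(evar) or evar <= 0:
            return np.inf, float(np.exp(emean))
        d0 = 2.0 * _trigamma_inverse(evar)
    if not np.isfinite(d0):
        return np.inf, float(np.exp(emean))
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def weighted_moderated_fit(
    logcpm: pd.DataFrame,
    weights: pd.DataFrame,
    design: np.ndarray,
    contrast_index: int = 1,
    prior_df: float | None = None,
) -> list[DEResult]:
    """Per-feature weighted least squares with moderated t statistics.

    ``contrast_index`` selects the design coefficient reported as log2FC.
    ``prior_df`` overrides the estimated prior degrees of freedom (0 forces
    ordinary weighted t; inf forces full pooling).
    """
    Y = logcpm.to_numpy(dtype=float)
    W = weights.to_numpy(dtype=float)
    if not np.all(np.isfinite(Y)):
        bad = logcpm.index[~np.isfinite(Y).all(axis=1)].tolist()
        raise ValueError(f"non-finite log-expression for features {bad[:10]}")
    if not np.all(np.isfinite(W)) or (W <= 0).any():
        bad = weights.index[~(np.isfinite(W) & (W > 0)).all(axis=1)].tolist()
        raise ValueError(f"invalid weights for features {bad[:10]}")
    n_features, n_samples = Y.shape
    p = design.shape[1]
    if np.linalg.matrix_rank(design) < p:
        raise ValueError("design matrix is not full rank")
    df = n_samples - p
    if df < 1:
        raise ValueError("no residual degrees of freedom")

    beta = np.empty((n_features, p))
    s2 = np.empty(n_features)
    unscaled = np.empty(n_features)  # sqrt of [ (X'WX)^-1 ]_cc
    for i in range(n_features):
        w = W[i]
        Xw = design * w[:, None]
        XtWX = design.T @ Xw
        XtWXinv = np.linalg.inv(XtWX)
        b = XtWXinv @ (Xw.T @ Y[i])
        r = Y[i] - design @ b
        beta[i] = b
        s2[i] = float(w @ r**2) / df
        unscaled[i] = np.sqrt(XtWXinv[contrast_index, contrast_index])

    if prior_df is None:
        d0, s02 = estimate_prior(s2, df)
        if not np.isfinite(d0):
            logger.info("prior-df estimation degenerate; pooling variances fully")
    elif prior_df == 0:
        d0, s02 = 0.0, 0.0  # s02 unused at d0 = 0
    elif np.isinf(prior_df):
        d0, s02 = np.inf, float(np.mean(s2))
    else:
        d0 = prior_df
        _, s02 = estimate_prior(s2, df, d0=prior_df)

    if d0 == 0:
        post_var = s2.copy()
        total_df = float(df)
    elif np.isinf(d0):
        post_var = np.full(n_features, s02)
        total_df = np.inf
    else:
        post_var = (d0 * s02 + df * s2) / (d0 + df)
        total_df = d0 + df

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[:, contrast_index] / (np.sqrt(post_var) * unscaled)
    tstat = np.where(np.isfinite(tstat), tstat, 0.0)
    if np.isinf(total_df):
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(tstat), total_df)
    pvals = np.clip(pvals, 0.0, 1.0)

    mean_expr = Y.mean(axis=1)
    return [
        DEResult(
            feature_id=str(fid),
            mean_expr=float(mean_expr[i]),
            log2fc=float(beta[i, contrast_index]),
            t=float(tstat[i]),
            p=float(pvals[i]),
        )
        for i, fid in enumerate(logcpm.index)
    ]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order restored to input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def adjust_results(results: list[DEResult]) -> list[DEResult]:
    adj = bh_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.adj_p = float(a)
    return results


def call_events(
    results: list[DEResult], params: DEParams | None = None, direction: str = "up"
) -> set[str]:
    """Significant features at adj p < alpha and log2FC beyond threshold.

    ``direction='up'`` requires log2FC > threshold; ``'any'`` requires
    |log2FC| > threshold. Both inequalities are strict.
    """
    params = params or DEParams()
    called = set()
    for r in results:
        if not np.isfinite(r.adj_p) or r.adj_p >= params.alpha:
            r.significant = False
            continue
        fc_ok = (
            r.log2fc > params.lfc_threshold
            if direction == "up"
            else abs(r.log2fc) > params.lfc_threshold
        )
        r.significant = fc_ok
        r.direction = "up" if r.log2fc > 0 else "down"
        if fc_ok:
            called.add(r.feature_id)
    return called


def classify_washout(
    pre_results: list[DEResult],
    post_results: list[DEResult],
    params: DEParams | None = None,
    direction: str = "up",
) -> dict[str, str]:
    """Label each feature reversible / persistent / absent.

    Significant before and after washout -> persistent; significant before
    only -> reversible; not significant before -> absent.
    """
    pre_ids = [r.feature_id for r in pre_results]
    post_ids = {r.feature_id for r in post_results}
    if set(pre_ids) != post_ids:
        raise ValueError("pre and post result sets must share feature ids")
    sig_pre = call_events(pre_results, params, direction)
    sig_post = call_events(post_results, params, direction)
    labels = {}
    for fid in pre_ids:
        if fid in sig_pre:
            labels[fid] = "persistent" if fid in sig_post else "reversible"
        else:
            labels[fid] = "absent"
    return labels


def exon_profile(
    bins: list[ExonBin],
    counts: CountMatrix,
    size_factors: pd.Series,
    conditions: list[str],
    treated: str,
    control: str,
) -> tuple[pd.DataFrame, float]:
    """Per-exon-bin log2 fold-change profile for one gene, plus its median.

    Counts are scaled by per-sample size factors; each bin's log2FC is
    log2((mean normalized treated + 0.5) / (mean normalized control + 0.5)).
    Rows are ordered by rank (5'->3').
    """
    if not bins:
        raise ValueError("gene has no exon bins")
    cond = np.asarray(conditions)
    norm = counts.counts / size_factors.reindex(counts.counts.columns).to_numpy()
    rows = []
    for b in sorted(bins, key=lambda b: b.rank):
        if b.id not in norm.index:
            raise ValueError(f"bin {b.id} not quantified")
        vals = norm.loc[b.id]
        m_t = float(vals[cond == treated].mean())
        m_c = float(vals[cond == control].mean())
        rows.append((b.rank, np.log2((m_t + 0.5) / (m_c + 0.5))))
    df = pd.DataFrame(rows, columns=["rank", "log2fc"])
    return df, float(df["log2fc"].median())


def differential_inclusion(
    counts: CountMatrix,
    conditions: list[str],
    treated: str,
    control: str,
    params: DEParams | None = None,
    direction: str = "up",
    prior_df: float | None = None,
) -> list[DEResult]:
    """End-to-end contrast: logCPM, voom weights, moderated fit, BH.

    Samples not in {treated, control} are dropped; features with all-zero
    counts across the used samples are excluded before transformation.
    """
    params = params or DEParams()
    mask = [c in (treated, control) for c in conditions]
    sub = CountMatrix(
        counts.counts.loc[:, mask],
        counts.library_sizes[mask],
        feature_lengths=counts.feature_lengths,
        meta=dict(counts.meta),
    )
    used_conditions = [c for c in conditions if c in (treated, control)]
    nonzero = sub.counts.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("excluding %d all-zero features", n_dropped)
    sub.counts = sub.counts.loc[nonzero]
    logcpm = logcpm_transform(sub)
    design = build_design(used_conditions, reference=control)
    weights = mean_variance_weights(logcpm, design)
    results = weighted_moderated_fit(logcpm, weights, design, prior_df=prior_df)
    adjust_results(results)
    call_events(results, params, direction)
    return results


def results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "mean_expr": [r.mean_expr for r in results],
            "log2fc": [r.log2fc for r in results],
            "t": [r.t for r in results],
            "p": [r.p for r in results],
            "adj_p": [r.adj_p for r in results],
            "significant": [r.significant for r in results],
        }
    )
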