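"""Moderated differential-abundance statistics from aggregated moments.

The estimation path mirrors the limma/DEqMS workflow for label-based and
label-free proteomics, but is organised around *sufficient statistics*
(per-protein ``X'X``, ``X'Y`` and residual sums of squares) so the same code
serves both the pooled reference analysis and the federated engine, where
those moments arrive as secure sums of client-local blocks.

Missing intensities are handled by a per-protein design mask: cohorts with
no observed value for a protein drop out of its model, and if the reference
cohort itself is unobserved the lowest-indexed observed cohort becomes that
protein's reference (its indicator column is masked to keep the reduced
design full rank).  This reproduces the NA-handling of ordinary pooled
least squares row-deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, special
from scipy import stats as sps

__all__ = [
    "DesignStructure",
    "DesignMask",
    "build_design_mask",
    "local_moments",
    "solve_global_lm",
    "residual_sse",
    "fit_contrast",
    "trigamma_inverse",
    "fit_f_dist",
    "moderate",
    "bh_adjust",
    "count_adjust",
    "ModerationResult",
]


@dataclass(frozen=True)
class DesignStructure:
    """Metadata tying global design columns to their roles.

    ``cohort_of_col`` maps a design-column index to the cohort it indicates;
    the reference cohort has no column (limma-style reference coding).
    """

    columns: tuple[str, ...]
    class_cols: tuple[int, int]
    cohort_of_col: dict[int, int] = field(default_factory=dict)
    n_cohorts: int = 1
    reference_cohort: int = 0

    @property
    def n_columns(self) -> int:
        return len(self.columns)


@dataclass
class DesignMask:
    """Per-protein estimability of each design column.

    ``active[p, c]`` is True when column ``c`` enters protein ``p``'s model;
    ``reference[p]`` records the (possibly switched) reference cohort.
    """

    active: np.ndarray          # (n_proteins, n_columns) bool
    reference: np.ndarray       # (n_proteins,) int
    n_obs: np.ndarray           # (n_proteins,) effective sample count m_p
    n_params: np.ndarray        # (n_proteins,) effective |v|_p

    @property
    def df_residual(self) -> np.ndarray:
        return self.n_obs - self.n_params


def build_design_mask(
    obs_per_cohort: np.ndarray,
    support_counts: np.ndarray,
    structure: DesignStructure,
) -> DesignMask:
    """Derive the per-protein design mask from aggregated observation counts.

    Parameters
    ----------
    obs_per_cohort
        (n_proteins, n_cohorts) integer counts of observed samples.
    support_counts
        (n_proteins, n_columns) counts of observed samples with a nonzero
        entry in each design column.
    """
    obs = np.asarray(obs_per_cohort)
    sup = np.asarray(support_counts)
    n, v = sup.shape
    if np.any(obs.sum(axis=1) == 0):
        bad = int(np.argmax(obs.sum(axis=1) == 0))
        raise ValueError(
            f"protein index {bad} has no observations in any cohort; "
            "it should have been removed by the missing-value filter"
        )
    active = sup > 0
    reference = np.full(n, structure.reference_cohort, dtype=int)
    col_of_cohort = {coh: col for col, coh in structure.cohort_of_col.items()}
    ref = structure.reference_cohort
    switched = obs[:, ref] == 0 if structure.n_cohorts > 1 else np.zeros(n, bool)
    for p in np.flatnonzero(switched):
        new_ref = int(np.flatnonzero(obs[p] > 0)[0])
        reference[p] = new_ref
        if new_ref in col_of_cohort:
            active[p, col_of_cohort[new_ref]] = False
    n_obs = obs.sum(axis=1)
    return DesignMask(
        active=active,
        reference=reference,
        n_obs=n_obs,
        n_params=active.sum(axis=1),
    )


def local_moments(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-protein ``X'X`` and ``X'Y`` over this block's observed samples.

    ``Y`` is (n_proteins, n_samples) with NaN for missing; ``X`` is
    (n_samples, n_columns).  Rows with missing intensity simply do not
    contribute, so summing these blocks over any partition of the samples
    reproduces the pooled moments.  Returns dense blocks that expose no
    per-sample values.
    """
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    obs = np.isfinite(Y).astype(float)
    yf = np.where(np.isfinite(Y), Y, 0.0)
    xty = (obs * yf) @ X
    cross = (X[:, :, None] * X[:, None, :]).reshape(X.shape[0], -1)
    xtx = (obs @ cross).reshape(Y.shape[0], X.shape[1], X.shape[1])
    return xtx, xty


def solve_global_lm(
    xtx: np.ndarray,
    xty: np.ndarray,
    mask: DesignMask,
    rank_tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Masked per-protein least squares from aggregated moment blocks.

    Returns ``(beta, stdev_unscaled, cov_unscaled, singular)`` where masked
    coefficients are NaN, ``cov_unscaled[p]`` holds (X'X)^-1 on the active
    submatrix (NaN elsewhere), and ``singular`` flags proteins whose active
    submatrix is rank deficient beyond the mask (excluded downstream).
    """
    n, v = xty.shape
    beta = np.full((n, v), np.nan)
    stdev = np.full((n, v), np.nan)
    cov = np.full((n, v, v), np.nan)
    singular = np.zeros(n, dtype=bool)
    for p in range(n):
        idx = np.flatnonzero(mask.active[p])
        if idx.size == 0:
            singular[p] = True
            continue
        a = xtx[p][np.ix_(idx, idx)]
        tol = rank_tol * max(np.max(np.diag(a)), 1.0)
        try:
            c, low = linalg.cho_factor(a, lower=True, check_finite=False)
        except linalg.LinAlgError:
            singular[p] = True
            continue
        if np.min(np.diag(c)) ** 2 <= tol:
            singular[p] = True
            continue
        ainv = linalg.cho_solve((c, low), np.eye(idx.size), check_finite=False)
        b = ainv @ xty[p, idx]
        beta[p, idx] = b
        stdev[p, idx] = np.sqrt(np.diag(ainv))
        cov[p][np.ix_(idx, idx)] = ainv
    return beta, stdev, cov, singular


def residual_sse(Y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Per-protein sum of squared residuals over this block's observed cells.

    Masked (NaN) coefficients contribute zero to the fitted values, which is
    exactly the reduced per-protein model implied by the design mask.
    """
    bz = np.where(np.isfinite(beta), beta, 0.0)
    fitted = bz @ np.asarray(X, float).T
    resid = np.asarray(Y, float) - fitted
    return np.nansum(resid**2, axis=1)


def pooled_sigma(sse: np.ndarray, df_residual: np.ndarray) -> np.ndarray:
    """Residual standard deviation; NaN where df <= 0."""
    df = np.asarray(df_residual, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(df > 0, sse / df, np.nan)
    return np.sqrt(np.maximum(s2, 0.0))


def fit_contrast(
    beta: np.ndarray,
    cov_unscaled: np.ndarray,
    mask: DesignMask,
    K: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a contrast vector to per-protein coefficients.

    Follows the covariance route of limma's ``contrasts.fit``: the unscaled
    covariance is reduced to a correlation matrix, Cholesky-decomposed, and
    the factor maps the contrast into the unscaled standard deviation
    ``sqrt(K' (X'X)^-1 K)``.  Proteins whose contrast touches a masked
    coefficient get NaN.
    """
    K = np.asarray(K, float)
    n = beta.shape[0]
    beta_c = np.full(n, np.nan)
    stdev_c = np.full(n, np.nan)
    nz = np.flatnonzero(K)
    for p in range(n):
        if not mask.active[p, nz].all():
            continue
        idx = np.flatnonzero(mask.active[p])
        U = cov_unscaled[p][np.ix_(idx, idx)]
        u = np.sqrt(np.diag(U))
        corr = U / np.outer(u, u)
        try:
            R = linalg.cholesky(corr, lower=False, check_finite=False)
        except linalg.LinAlgError:
            continue
        ks = K[idx]
        a = R @ (u * ks)
        beta_c[p] = beta[p, idx] @ ks
        stdev_c[p] = math.sqrt(float(a @ a))
    return beta_c, stdev_c


def trigamma_inverse(y: float) -> float:
    """Solve ``trigamma(x) = y`` by monotone Newton iteration."""
    if not np.isfinite(y) or y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            return x
    return x


def fit_f_dist(sigma2: np.ndarray, df_residual: np.ndarray) -> tuple[float, float]:
    """Fit the scaled-F prior for the residual variances.

    Method of moments on ``z = log(s^2)``: the mean and variance of ``z``
    are matched to the log-F distribution via digamma/trigamma identities,
    and the prior degrees of freedom are recovered by inverting the
    trigamma function.  When the observed spread of ``z`` is no larger than
    the sampling spread implied by the residual df, the prior df is
    infinite and every posterior variance collapses to the prior.
    """
    s2 = np.asarray(sigma2, float)
    df = np.asarray(df_residual, float)
    ok = np.isfinite(s2) & (s2 > -1e-15) & np.isfinite(df) & (df > 1e-15)
    if ok.sum() < 2:
        raise ValueError("insufficient features to fit the variance prior")
    x = np.maximum(s2[ok], 0.0)
    m = float(np.median(x))
    if m == 0.0:
        m = 1.0
    x = np.maximum(x, 1e-5 * m)  # offset exact zeros away from log singularity
    z = np.log(x)
    half = df[ok] / 2.0
    e = z - special.digamma(half) + np.log(half)
    emean = float(e.mean())
    evar = float(np.sum((e - emean) ** 2) / (e.size - 1))
    evar -= float(np.mean(special.polygamma(1, half)))
    if evar > 0:
        df_prior = 2.0 * trigamma_inverse(evar)
        s2_prior = math.exp(
            emean + float(special.digamma(df_prior / 2.0)) - math.log(df_prior / 2.0)
        )
    else:
        # no excess spread beyond sampling noise: completely shared variance
        df_prior = math.inf
        s2_prior = float(np.mean(x))
    return df_prior, s2_prior


def _squeeze_var(
    sigma2: np.ndarray, df: np.ndarray, df_prior: float, s2_prior: float
) -> np.ndarray:
    if math.isinf(df_prior):
        return np.where(np.isfinite(sigma2), s2_prior, np.nan)
    with np.errstate(invalid="ignore"):
        return (df * sigma2 + df_prior * s2_prior) / (df + df_prior)


def _t_sf(x: np.ndarray, df: np.ndarray) -> np.ndarray:
    out = np.full_like(x, np.nan, dtype=float)
    fin = np.isfinite(x) & np.isfinite(df)
    out[fin] = sps.t.sf(x[fin], df[fin])
    inf_df = np.isfinite(x) & np.isinf(df)
    out[inf_df] = sps.norm.sf(x[inf_df])
    return out


def _t_isf(q: float, df: np.ndarray) -> np.ndarray:
    df = np.asarray(df, float)
    out = np.full(df.shape, np.nan)
    fin = np.isfinite(df)
    out[fin] = sps.t.isf(q, df[fin])
    out[np.isinf(df)] = sps.norm.isf(q)
    return out


def _var_prior_mixture(
    t: np.ndarray,
    stdev_c: np.ndarray,
    df_total: np.ndarray,
    proportion: float,
    v0_lim: tuple[float, float] = (0.1**2, 4.0**2),
) -> float:
    """Estimate the unscaled variance of true log fold changes.

    Matches the largest |t| statistics against their expected quantiles in a
    two-component mixture where a fraction ``proportion`` of proteins carry a
    coefficient variance inflated by v0 (Smyth-style target-quantile method).
    Used only for the log-odds (B) column.
    """
    ok = np.isfinite(t) & np.isfinite(stdev_c) & np.isfinite(df_total)
    if not ok.any():
        return float("nan")
    tt = np.abs(t[ok])
    v1 = stdev_c[ok] ** 2
    df = df_total[ok]
    n = tt.size
    ntarget = int(np.ceil(proportion / 2.0 * n))
    if ntarget < 1:
        return float("nan")
    p = max(ntarget / n, proportion)
    maxdf = float(np.max(df[np.isfinite(df)])) if np.isfinite(df).any() else math.inf
    low = df < maxdf
    if low.any():
        tail = np.clip(_t_sf(tt[low], df[low]), 1e-300, 1.0)
        conv = np.array([float(sps.t.isf(q, maxdf)) for q in tail])
        tt = tt.copy()
        tt[low] = conv
    order = np.argsort(-tt)[:ntarget]
    tt, v1 = tt[order], v1[order]
    p0 = 2.0 * _t_sf(tt, np.full(ntarget, maxdf))
    r = np.arange(1, ntarget + 1)
    ptarget = ((r - 0.5) / n - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        qtarget = np.array([float(sps.t.isf(q / 2.0, maxdf)) for q in ptarget[pos]])
        v0[pos] = v1[pos] * ((tt[pos] / qtarget) ** 2 - 1.0)
    v0 = np.clip(v0, v0_lim[0], v0_lim[1])
    return float(np.mean(v0))


@dataclass
class ModerationResult:
    """Per-protein moderated statistics for one contrast."""

    logfc: np.ndarray
    stdev_c: np.ndarray
    sigma: np.ndarray
    df_residual: np.ndarray
    df_prior: float
    s2_prior: float
    s2_post: np.ndarray
    t: np.ndarray
    p: np.ndarray
    adj_p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    lods: np.ndarray


def moderate(
    beta_c: np.ndarray,
    stdev_c: np.ndarray,
    sigma2: np.ndarray,
    df_residual: np.ndarray,
    df_prior: float,
    s2_prior: float,
    p_de: float = 0.01,
    conf_level: float = 0.95,
) -> ModerationResult:
    """Empirical-Bayes moderated t statistics for a fitted contrast.

    The posterior variance is the df-weighted average of the residual and
    prior variances; t uses ``df_residual + df_prior`` degrees of freedom.
    The B column is the log posterior odds of differential abundance with
    prior proportion ``p_de``; it is reported for ranking only.
    """
    sigma2 = np.asarray(sigma2, float)
    df = np.asarray(df_residual, float)
    usable = np.isfinite(beta_c) & np.isfinite(stdev_c) & np.isfinite(sigma2) & (df > 0)
    s2_post = np.where(usable, _squeeze_var(sigma2, df, df_prior, s2_prior), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(usable, beta_c / (stdev_c * np.sqrt(s2_post)), np.nan)
    df_total = np.where(usable, df + df_prior, np.nan)
    p = 2.0 * _t_sf(np.abs(t), df_total)
    adj = bh_adjust(p)
    margin = _t_isf((1.0 - conf_level) / 2.0, df_total) * stdev_c * np.sqrt(s2_post)
    # coefficient-scale limits for the mixture prior, relative to the
    # typical residual variance
    scale = s2_prior if s2_prior > 0 else 1.0
    v0 = _var_prior_mixture(
        t, stdev_c, df_total, p_de, (0.1**2 / scale, 4.0**2 / scale)
    )
    if not np.isfinite(v0):
        v0 = 1.0 / s2_prior
    v1 = stdev_c**2
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (v1 + v0) / v1
        kernel = np.where(
            np.isinf(df_total),
            t**2 * (1.0 - 1.0 / r) / 2.0,
            (1.0 + df_total) / 2.0 * np.log((t**2 + df_total) / (t**2 / r + df_total)),
        )
        lods = math.log(p_de / (1.0 - p_de)) - np.log(r) / 2.0 + kernel
    return ModerationResult(
        logfc=beta_c,
        stdev_c=stdev_c,
        sigma=np.sqrt(sigma2),
        df_residual=df,
        df_prior=df_prior,
        s2_prior=s2_prior,
        s2_post=s2_post,
        t=t,
        p=p,
        adj_p=adj,
        ci_low=beta_c - margin,
        ci_high=beta_c + margin,
        lods=lods,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs stay NaN and do not
    count toward the denominator."""
    p = np.asarray(p, float)
    if np.any((p[np.isfinite(p)] < 0) | (p[np.isfinite(p)] > 1)):
        raise ValueError("p values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return out
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.clip(u, 0.0, 1.0) ** 3, 0.0, None) ** 3
    return w


def loess_trend(x: np.ndarray, y: np.ndarray, span: float = 0.75) -> np.ndarray:
    """Local quadratic tricube-weighted regression evaluated at each x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    q = max(int(math.ceil(span * n)), 4)
    q = min(q, n)
    pred = np.empty(n)
    uniq = np.unique(x)
    cache: dict[float, float] = {}
    for x0 in uniq:
        d = np.abs(x - x0)
        dq = np.partition(d, q - 1)[q - 1]
        if dq == 0:
            sel = d == 0
            cache[x0] = float(np.mean(y[sel]))
            continue
        w = _tricube(d / dq)
        sel = w > 0
        xs = x[sel] - x0
        basis = np.column_stack([np.ones(xs.size), xs, xs**2])
        wsel = w[sel]
        wb = basis * wsel[:, None]
        coef, *_ = np.linalg.lstsq(wb.T @ basis, wb.T @ y[sel], rcond=None)
        cache[x0] = float(coef[0])
    for i in range(n):
        pred[i] = cache[x[i]]
    return pred


@dataclass
class CountAdjustResult:
    """Peptide-count-adjusted moderated statistics."""

    sca_t: np.ndarray
    sca_p: np.ndarray
    sca_adj_p: np.ndarray
    sca_df_prior: float
    sca_s2_prior: np.ndarray
    count: np.ndarray


def count_adjust(
    beta_c: np.ndarray,
    stdev_c: np.ndarray,
    sigma2: np.ndarray,
    df_residual: np.ndarray,
    min_count: np.ndarray,
    base: ModerationResult,
    span: float = 0.75,
    min_distinct_for_loess: int = 10,
) -> CountAdjustResult:
    """Re-moderate with a peptide-count-dependent prior variance.

    ``log(sigma^2)`` is regressed on ``log2(min precursor count)`` with a
    smooth trend; each protein's prior variance is read off the trend and
    the prior df re-estimated from the residual spread around it by the same
    log-F moment method used globally.  Proteins with well-supported
    quantification (high counts) typically receive smaller prior variances
    and hence tighter moderated statistics.

    Proteins lacking a count keep their count-free moderated statistics
    (their sca fields are NaN).  If every protein shares one count the
    trend is flat and the count-free moderation is returned unchanged.
    """
    sigma2 = np.asarray(sigma2, float)
    df = np.asarray(df_residual, float)
    cnt = np.asarray(min_count, float)
    n = sigma2.size
    usable = (
        np.isfinite(beta_c)
        & np.isfinite(stdev_c)
        & np.isfinite(sigma2)
        & (sigma2 > 0)
        & (df > 0)
        & np.isfinite(cnt)
        & (cnt >= 1)
    )
    sca_t = np.full(n, np.nan)
    sca_p = np.full(n, np.nan)
    s02 = np.full(n, np.nan)
    if usable.sum() < 2:
        return CountAdjustResult(sca_t, sca_p, bh_adjust(sca_p), np.nan, s02, cnt)

    x = np.log2(cnt[usable])
    logvar = np.log(sigma2[usable])
    distinct = np.unique(x)
    if distinct.size == 1:
        # flat trend: count carries no information, keep global moderation
        sca_t[usable] = base.t[usable]
        sca_p[usable] = base.p[usable]
        s02[usable] = base.s2_prior
        return CountAdjustResult(
            sca_t, sca_p, bh_adjust(sca_p), base.df_prior, s02, cnt
        )
    if distinct.size >= min_distinct_for_loess:
        ypred = loess_trend(x, logvar, span=span)
    else:
        ypred = np.empty_like(logvar)
        for val in distinct:
            sel = x == val
            ypred[sel] = np.mean(logvar[sel])

    half = df[usable] / 2.0
    eg = logvar - special.digamma(half) + np.log(half)
    egpred = ypred - special.digamma(half) + np.log(half)
    myfct = (eg - egpred) ** 2 - special.polygamma(1, half)
    mean_myfct = float(np.mean(myfct))
    d0 = 2.0 * trigamma_inverse(mean_myfct) if mean_myfct > 0 else math.inf
    if math.isinf(d0):
        prior = np.exp(egpred)
        post = prior
        df_tot = np.full(usable.sum(), np.inf)
    else:
        prior = np.exp(egpred + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
        post = (d0 * prior + df[usable] * sigma2[usable]) / (d0 + df[usable])
        df_tot = d0 + df[usable]
    s02[usable] = prior
    with np.errstate(invalid="ignore", divide="ignore"):
        tvals = beta_c[usable] / (stdev_c[usable] * np.sqrt(post))
    sca_t[usable] = tvals
    sca_p[usable] = 2.0 * _t_sf(np.abs(tvals), df_tot)
    return CountAdjustResult(sca_t, sca_p, bh_adjust(sca_p), d0, s02, cnt)
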