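"""Mass-univariate linear mixed models and associated inference.

At every channel(-frequency)-timepoint a random-intercept linear mixed
model is fitted by maximum likelihood:

``y = X beta + sum_k Z_k gamma_k + eps``,  ``gamma_k ~ N(0, s_k I)``,
``eps ~ N(0, s_e I)``

with one grouping factor (subject) for condition comparisons, or two
crossed grouping factors (subject and condition) for correlation maps.
The profiled marginal likelihood is maximised over log-variances; fixed
effects and their covariance follow by generalised least squares.

Inference per coefficient uses the Satterthwaite approximation for the
denominator degrees of freedom: ``df = 2 g^2 / (grad_g' A grad_g)`` where
``g(theta) = Var(c' beta_hat)`` and ``A`` is the inverse expected Fisher
information of the variance parameters.  p-values are corrected with the
Benjamini–Yekutieli FDR (valid under arbitrary dependence) and surviving
points must additionally form clusters of at least three consecutive
timepoints at a channel or three channels at a timepoint.

Variance explained by the fixed effects is summarised by the marginal R²:
``sigma_f^2 / (sigma_f^2 + sum_k sigma_k^2 + sigma_eps^2)`` with
``sigma_f^2`` the variance of the fitted fixed-effect predictions; for
single-predictor correlation maps it is signed by the focal coefficient.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LMMFit",
    "StatMap",
    "fit_lmm",
    "marginal_r2",
    "satterthwaite_p",
    "by_fdr",
    "cluster_filter",
    "mass_univariate_r2",
    "mass_univariate_conditions",
    "exgauss_fit",
    "exgauss_mu",
    "condition_design",
]

_VAR_FLOOR_FRAC = 1e-8  # variance floor, as a fraction of var(y)


@dataclass
class LMMFit:
    """Maximum-likelihood fit of a random-intercept mixed model."""

    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    cov_beta: np.ndarray
    var_components: dict  # grouping name -> variance
    sigma2_resid: float
    sigma2_fixed: float  # variance of fitted fixed-effect predictions
    loglik: float
    column_names: list
    converged: bool
    # internals for Satterthwaite / R2
    _X: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _Z: list = field(repr=False, default=None)  # list of (name, indicator matrix)

    def coef_index(self, name) -> int:
        if isinstance(name, (int, np.integer)):
            return int(name)
        return self.column_names.index(name)


def _build_indicator(codes: np.ndarray) -> np.ndarray:
    codes = np.asarray(codes)
    _, inv = np.unique(codes, return_inverse=True)
    z = np.zeros((codes.size, inv.max() + 1))
    z[np.arange(codes.size), inv] = 1.0
    return z


class _MarginalModel:
    """Marginal covariance machinery for random-intercept models.

    ``V = s_e I + sum_k s_k Z_k Z_k'`` is never formed; everything goes
    through the Woodbury identity, so per-evaluation cost scales with the
    total number of random-effect levels (q), not the number of rows (n).
    """

    def __init__(self, y, X, Zs):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.Zs = Zs  # list of (name, indicator matrix)
        self.n, self.p = self.X.shape
        self.qs = [z.shape[1] for _, z in Zs]
        self.Zall = (np.hstack([z for _, z in Zs]) if Zs
                     else np.zeros((self.n, 0)))
        self.ZtZ = self.Zall.T @ self.Zall
        self.ZtX = self.Zall.T @ self.X
        self.Zty = self.Zall.T @ self.y
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    def _col_scale(self, theta):
        if not self.qs:
            return np.zeros(0)
        return np.concatenate(
            [np.full(q, s) for q, s in zip(self.qs, theta[:-1])]
        )

    def _cap(self, theta):
        """Cholesky of the capacitance K = I + U Z'Z U / s_e, U = diag sqrt."""
        s_e = theta[-1]
        u = np.sqrt(self._col_scale(theta))
        K = np.eye(u.size) + (u[:, None] * self.ZtZ * u[None, :]) / s_e
        return s_e, u, cho_factor(K, lower=True)

    def neg2ll(self, theta):
        """-2 log marginal ML likelihood with beta profiled out."""
        try:
            s_e, u, cho = self._cap(theta)
        except np.linalg.LinAlgError:
            return np.inf, None
        a = u[:, None] * self.ZtX
        b = u * self.Zty
        XtViX = (self.XtX - a.T @ cho_solve(cho, a) / s_e) / s_e
        XtViy = (self.Xty - a.T @ cho_solve(cho, b) / s_e) / s_e
        ytViy = (self.yty - b @ cho_solve(cho, b) / s_e) / s_e
        logdet = self.n * np.log(s_e) + 2.0 * np.sum(np.log(np.diag(cho[0])))
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return np.inf, None
        quad = ytViy - 2 * beta @ XtViy + beta @ XtViX @ beta
        val = logdet + quad + self.n * np.log(2 * np.pi)
        return val, (beta, XtViX)

    def vinv_mat(self, theta, M):
        """V^{-1} M for a tall matrix M (n x m)."""
        s_e, u, cho = self._cap(theta)
        ZtM = self.Zall.T @ M
        inner = u[:, None] * cho_solve(cho, u[:, None] * ZtM)
        return (M - self.Zall @ inner / s_e) / s_e

    def fisher_info(self, theta):
        """Expected information of (s_1..s_K, s_e), all via q x q algebra."""
        s_e, u, cho = self._cap(theta)
        k = len(self.qs)
        info = np.empty((k + 1, k + 1))
        if k:
            VinvZ = self.vinv_mat(theta, self.Zall)  # n x q
            S = self.Zall.T @ VinvZ  # q x q, symmetric
            bounds = np.concatenate([[0], np.cumsum(self.qs)])
            for i in range(k):
                si, ei = bounds[i], bounds[i + 1]
                for j in range(i, k):
                    sj, ej = bounds[j], bounds[j + 1]
                    blk = S[si:ei, sj:ej]
                    info[i, j] = info[j, i] = 0.5 * np.sum(blk * blk)
                # cross term with the residual variance: tr(Vinv Zi Zi' Vinv)
                info[i, k] = info[k, i] = 0.5 * np.sum(VinvZ[:, si:ei] ** 2)
        # residual-residual: tr(Vinv^2) via the capacitance
        W = (u[:, None] * self.ZtZ * u[None, :]) / s_e
        T = cho_solve(cho, W)
        tr_b = np.trace(T)
        tr_b2 = np.sum(T * T.T)
        info[k, k] = 0.5 * (self.n - 2 * tr_b + tr_b2) / s_e**2
        return info


def fit_lmm(y, X, groups, column_names=None) -> LMMFit:
    """Fit a linear mixed model with random intercepts by ML.

    Parameters
    ----------
    y : array (n,)
    X : array (n, p) fixed-effects design (include the intercept column)
        or a DataFrame (column names taken from it).
    groups : dict name -> array (n,) of group codes
        One entry per random intercept factor; factors may be crossed.

    Raises
    ------
    ValueError if the design is rank-deficient (aliased columns listed).
    """
    if isinstance(X, pd.DataFrame):
        column_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if column_names is None:
        column_names = [f"x{j}" for j in range(p)]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, R = np.linalg.qr(X)
        aliased = [column_names[j] for j in range(p)
                   if abs(R[min(j, R.shape[0] - 1), j]) < 1e-10]
        raise ValueError(f"singular fixed-effects design; aliased columns: {aliased}")
    for name, codes in groups.items():
        if np.unique(codes).size < 2:
            raise ValueError(f"random factor {name!r} has fewer than 2 groups")

    Z = [(name, _build_indicator(codes)) for name, codes in groups.items()]
    model = _MarginalModel(y, X, Z)
    var_y = max(float(np.var(y)), 1e-12)
    k = len(Z)
    floor = np.log(var_y * _VAR_FLOOR_FRAC)

    def objective(log_theta):
        val, _ = model.neg2ll(np.exp(log_theta))
        return val

    # two starts: variance split equally, and residual-dominant (covers
    # degenerate perfect-fit responses where the surface is ill-conditioned)
    bounds = [(floor, np.log(var_y * 1e4) + 1)] * (k + 1)
    starts = [np.log(np.full(k + 1, var_y / (k + 1))),
              np.array([floor] * k + [np.log(var_y)])]
    res = min(
        (optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
         for x0 in starts),
        key=lambda r: r.fun,
    )
    theta = np.exp(res.x)
    # treat variances at the floor as zero
    theta[theta <= var_y * _VAR_FLOOR_FRAC * 10] = 0.0
    theta[-1] = max(theta[-1], var_y * _VAR_FLOOR_FRAC * 10)

    val, aux = model.neg2ll(theta)
    if aux is None:
        raise RuntimeError("mixed-model likelihood not evaluable at optimum")
    beta, XtViX = aux
    cov_beta = np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))
    fitted = X @ beta
    sigma2_fixed = float(np.var(fitted, ddof=1)) if n > 1 else 0.0
    return LMMFit(
        beta=beta,
        se=se,
        tvalues=beta / se,
        cov_beta=cov_beta,
        var_components={name: float(s) for (name, _), s in zip(Z, theta[:-1])},
        sigma2_resid=float(theta[-1]),
        sigma2_fixed=sigma2_fixed,
        loglik=-0.5 * val,
        column_names=column_names,
        converged=bool(res.success),
        _X=X, _y=y, _Z=Z,
    )


def marginal_r2(fit: LMMFit, focal=None) -> float:
    """Signed marginal R²: fixed-effect variance share, signed by the focal beta.

    ``focal`` names the focal predictor (defaults to the last non-intercept
    column), whose coefficient sign is attached to the magnitude.
    """
    total = fit.sigma2_fixed + sum(fit.var_components.values()) + fit.sigma2_resid
    if total <= 0:
        return 0.0
    magnitude = fit.sigma2_fixed / total
    if focal is None:
        non_icpt = [j for j, nm in enumerate(fit.column_names) if nm != "Intercept"]
        focal = non_icpt[-1] if non_icpt else 0
    sign = np.sign(fit.beta[fit.coef_index(focal)])
    return float(magnitude * (sign if sign != 0 else 0.0))


def satterthwaite_p(fit: LMMFit, coefficient) -> tuple:
    """Satterthwaite-approximated (df, two-sided p) for one coefficient.

    Differentiates ``g(theta) = Var(c' beta_hat)`` analytically with respect
    to the variance parameters and uses the inverse expected Fisher
    information as their sampling covariance.  Returns (nan, nan) with a
    warning if the df estimate is non-positive.
    """
    j = fit.coef_index(coefficient)
    model = _MarginalModel(fit._y, fit._X, fit._Z)
    theta = np.array(list(fit.var_components.values()) + [fit.sigma2_resid])

    info = model.fisher_info(theta)
    Vinv_X = model.vinv_mat(theta, model.X)
    A = fit.cov_beta
    g = A[j, j]

    # dg/dtheta_k = [A X' Vinv G_k Vinv X A]_jj with G_k = Z_k Z_k' (or I)
    grads = []
    for _, z in fit._Z:
        ztvx = z.T @ Vinv_X
        grads.append(float((A @ (ztvx.T @ ztvx) @ A)[j, j]))
    grads.append(float((A @ (Vinv_X.T @ Vinv_X) @ A)[j, j]))
    grads = np.array(grads)

    # parameters estimated at (effectively) zero variance sit on the
    # boundary and carry no usable curvature; treat them as fixed
    active = theta > 0
    info_a = info[np.ix_(active, active)]
    grads_a = grads[active]
    try:
        cov_theta = np.linalg.inv(info_a)
    except np.linalg.LinAlgError:
        cov_theta = np.linalg.pinv(info_a)
    denom = float(grads_a @ cov_theta @ grads_a)
    if denom <= 0 or g <= 0:
        warnings.warn("non-positive Satterthwaite df estimate; result flagged")
        return float("nan"), float("nan")
    df = 2.0 * g**2 / denom
    t = fit.tvalues[j]
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(df), float(p)


def by_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Yekutieli step-up significance mask.

    Missing (NaN) entries are excluded from the number of tests and are
    False in the output.
    """
    p = np.asarray(p_values, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if not np.any(ok):
        return mask
    rejected, *_ = multipletests(p[ok], alpha=q, method="fdr_by")
    mask[ok] = rejected
    return mask


def cluster_filter(mask: np.ndarray, min_extent: int = 3) -> np.ndarray:
    """Cluster rule over a (channel, time) or (channel, frequency, time) mask.

    A significant point survives iff it lies in a run of >= ``min_extent``
    consecutive significant timepoints at its channel (same frequency), or
    >= ``min_extent`` channels are simultaneously significant at its
    timepoint (same frequency).  The output is a subset of the input.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 2:
        return _cluster_filter_2d(mask, min_extent)
    if mask.ndim == 3:
        out = np.empty_like(mask)
        for f in range(mask.shape[1]):
            out[:, f, :] = _cluster_filter_2d(mask[:, f, :], min_extent)
        return out
    raise ValueError("mask must be (channels, time) or (channels, freq, time)")


def _cluster_filter_2d(mask: np.ndarray, min_extent: int) -> np.ndarray:
    keep = np.zeros_like(mask)
    # temporal runs per channel
    for ch in range(mask.shape[0]):
        row = mask[ch]
        run = 0
        for t in range(row.size + 1):
            if t < row.size and row[t]:
                run += 1
            else:
                if run >= min_extent:
                    keep[ch, t - run : t] = True
                run = 0
    # simultaneous channels per timepoint
    counts = mask.sum(axis=0)
    keep |= mask & (counts >= min_extent)[None, :]
    return keep


@dataclass
class StatMap:
    """Mass-univariate mixed-model outputs on a map of points."""

    coef: np.ndarray
    r2_signed: np.ndarray
    p: np.ndarray
    df: np.ndarray
    fdr_significant: np.ndarray
    cluster_significant: np.ndarray
    term: str
    q: float = 0.05


def _point_iter(shape):
    return itertools.product(*(range(s) for s in shape))


def mass_univariate_r2(dependent_map, predictor_map, q: float = 0.05,
                       min_extent: int = 3) -> StatMap:
    """Signed marginal R² between two maps, point by point.

    Both maps have shape (subject, condition, *points).  At each point a
    mixed model ``dep ~ 1 + pred + (1|subject) + (1|condition)`` is fitted
    (crossed random intercepts); rows with missing values are dropped and
    points whose fit fails or whose predictor is constant are flagged NaN.
    """
    dep = np.asarray(dependent_map, dtype=float)
    pred = np.asarray(predictor_map, dtype=float)
    if dep.shape != pred.shape:
        raise ValueError("maps must share shape (subject, condition, ...points)")
    S, C = dep.shape[:2]
    pts = dep.shape[2:]
    subj = np.repeat(np.arange(S), C)
    cond = np.tile(np.arange(C), S)

    r2 = np.full(pts, np.nan)
    coef = np.full(pts, np.nan)
    pvals = np.full(pts, np.nan)
    dfs = np.full(pts, np.nan)
    for ix in _point_iter(pts):
        yv = dep[(slice(None), slice(None)) + ix].ravel()
        xv = pred[(slice(None), slice(None)) + ix].ravel()
        ok = np.isfinite(yv) & np.isfinite(xv)
        if ok.sum() < 4 or np.ptp(xv[ok]) == 0:
            continue
        X = np.column_stack([np.ones(ok.sum()), xv[ok] - xv[ok].mean()])
        try:
            fit = fit_lmm(yv[ok], X, {"subject": subj[ok], "condition": cond[ok]},
                          column_names=["Intercept", "pred"])
            df, p = satterthwaite_p(fit, "pred")
        except (ValueError, RuntimeError):
            continue
        r2[ix] = marginal_r2(fit, "pred")
        coef[ix] = fit.beta[1]
        pvals[ix] = p
        dfs[ix] = df
    fdr = by_fdr(pvals, q)
    cluster = cluster_filter(fdr, min_extent) if fdr.ndim in (2, 3) else fdr
    return StatMap(coef=coef, r2_signed=r2, p=pvals, df=dfs,
                   fdr_significant=fdr, cluster_significant=cluster,
                   term="pred", q=q)


def condition_design(labels, rt_mu=None):
    """Sum-coded full-factorial design for (modality, load, stimulus) labels.

    Returns a DataFrame with an intercept, one +/-1 column per non-degenerate
    two-level factor, all interactions among them, and (optionally) a
    mean-centred ``rt`` column.  Factors with a single level are dropped.
    """
    labels = [tuple(l) for l in labels]
    names = ["modality", "nback", "stimulus"]
    cols = {}
    for i, name in enumerate(names):
        levels = sorted({l[i] for l in labels})
        if len(levels) == 1:
            continue
        if len(levels) > 2:
            raise ValueError(f"factor {name!r} has more than two levels")
        cols[name] = np.array([1.0 if l[i] == levels[1] else -1.0 for l in labels])
    design = {"Intercept": np.ones(len(labels))}
    design.update(cols)
    factor_names = list(cols)
    for r in (2, 3):
        for combo in itertools.combinations(factor_names, r):
            design[":".join(combo)] = np.prod([cols[c] for c in combo], axis=0)
    df = pd.DataFrame(design)
    if rt_mu is not None:
        rt = np.asarray(rt_mu, dtype=float)
        df["rt"] = rt - np.nanmean(rt)
    return df


def mass_univariate_conditions(maps, condition_labels, rt_mu=None,
                               q: float = 0.05, min_extent: int = 3) -> dict:
    """Condition comparisons at every point of a parameter map.

    ``maps`` has shape (subject, condition, *points); at each point the
    model ``y ~ 1 + modality*nback*stimulus + rt + (1|subject)`` is fitted
    (degenerate factors dropped), Satterthwaite p-values are computed per
    term, corrected by BY-FDR across the point map, and the cluster rule is
    applied.  Returns a dict term -> StatMap.
    """
    maps = np.asarray(maps, dtype=float)
    S, C = maps.shape[:2]
    pts = maps.shape[2:]
    if rt_mu is not None and not np.any(np.isfinite(rt_mu)):
        warnings.warn("reaction-time summaries all missing; rt term dropped")
        rt_mu = None
    base = condition_design(condition_labels)  # per-condition rows
    terms = [c for c in base.columns if c != "Intercept"]
    if rt_mu is not None:
        terms.append("rt")

    subj = np.repeat(np.arange(S), C)
    Xcond = pd.concat([base] * S, ignore_index=True)
    if rt_mu is not None:
        rt = np.asarray(rt_mu, dtype=float).reshape(S * C)
        Xcond["rt"] = rt - np.nanmean(rt)

    results = {t: {"coef": np.full(pts, np.nan), "p": np.full(pts, np.nan),
                   "df": np.full(pts, np.nan), "r2": np.full(pts, np.nan)}
               for t in terms}
    for ix in _point_iter(pts):
        yv = maps[(slice(None), slice(None)) + ix].ravel()
        ok = np.isfinite(yv) & Xcond.notna().all(axis=1).to_numpy()
        if ok.sum() < len(base.columns) + 2:
            continue
        try:
            fit = fit_lmm(yv[ok], Xcond[ok], {"subject": subj[ok]})
        except (ValueError, RuntimeError):
            continue
        for t in terms:
            try:
                df, p = satterthwaite_p(fit, t)
            except (ValueError, RuntimeError):
                continue
            results[t]["coef"][ix] = fit.beta[fit.coef_index(t)]
            results[t]["p"][ix] = p
            results[t]["df"][ix] = df
            results[t]["r2"][ix] = marginal_r2(fit, t)

    out = {}
    for t in terms:
        p = results[t]["p"]
        fdr = by_fdr(p, q)
        cluster = cluster_filter(fdr, min_extent) if p.ndim in (2, 3) else fdr
        out[t] = StatMap(coef=results[t]["coef"], r2_signed=results[t]["r2"],
                         p=p, df=results[t]["df"], fdr_significant=fdr,
                         cluster_significant=cluster, term=t, q=q)
    return out


# ---------------------------------------------------------------------------
# reaction-time summaries
# ---------------------------------------------------------------------------

def _exgauss_nll(params, rts):
    mu, log_sigma, log_tau = params
    sigma, tau = np.exp(log_sigma), np.exp(log_tau)
    k = tau / sigma
    return -np.sum(stats.exponnorm.logpdf(rts, k, loc=mu, scale=sigma))


def exgauss_fit(rts) -> tuple:
    """Maximum-likelihood ex-Gaussian parameters (mu, sigma, tau).

    Starting values come from the method of moments
    (``tau ~ sd * (skew/2)^(1/3)``); the likelihood is minimised with
    Nelder-Mead on (mu, log sigma, log tau).
    """
    rts = np.asarray(rts, dtype=float)
    m, s = rts.mean(), rts.std(ddof=1)
    skew = float(stats.skew(rts))
    tau0 = s * (max(skew, 0.01) / 2.0) ** (1.0 / 3.0)
    tau0 = min(max(tau0, 1e-3), s * 2)
    sigma0 = np.sqrt(max(s**2 - tau0**2, (0.1 * s) ** 2))
    mu0 = m - tau0
    res = optimize.minimize(
        _exgauss_nll, [mu0, np.log(sigma0), np.log(tau0)], args=(rts,),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
    )
    mu, log_sigma, log_tau = res.x
    return float(mu), float(np.exp(log_sigma)), float(np.exp(log_tau))


def exgauss_mu(rts, min_rt: float = 0.2, z_max: float = 3.0,
               min_n: int = 10):
    """Cell-level reaction-time summary: ex-Gaussian mu after outlier filters.

    Reaction times with a within-cell z-score above ``z_max`` or below
    ``min_rt`` seconds are removed before fitting.  Returns
    ``(mu, sigma, tau)``; all NaN (flagged missing) if fewer than ``min_n``
    values survive.
    """
    rts = np.asarray(rts, dtype=float)
    rts = rts[np.isfinite(rts)]
    if rts.size:
        z = (rts - rts.mean()) / rts.std(ddof=1) if rts.std(ddof=1) > 0 else 0 * rts
        rts = rts[(z <= z_max) & (rts >= min_rt)]
    if rts.size < min_n:
        return float("nan"), float("nan"), float("nan")
    return exgauss_fit(rts)
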