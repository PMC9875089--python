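"""Random-intercept linear mixed models with Satterthwaite F-tests.

The models fitted here have the form

    y = X beta + sum_k Z_k b_k + e,   b_k ~ N(0, s2_k I),  e ~ N(0, s2 I)

with one or more crossed random intercepts (``animal_id``, ``batch``) and a
fixed-effects design built from sum-to-zero-coded factors, so that the
marginal (Type III) F-test of each term is meaningful in an unbalanced
design.  Estimation maximises the REML profile likelihood over the variance
ratios; denominator degrees of freedom for each F-test use the Satterthwaite
approximation (per-contrast moment matching, with the usual eigencontrast
combination for multi-df terms), which yields the fractional denominator
dfs familiar from mixed-model ANOVA tables.  Effect sizes are reported as
partial eta squared computed from F and its degrees of freedom, which keeps
the measure well defined for fractional denominator df.

Tukey HSD post-hoc comparisons operate on estimated marginal means: each
factor level's prediction averaged over a balanced grid of the other
factors, compared pairwise with studentized-range-adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import linalg, optimize, stats

from .transforms import apply_transform

__all__ = [
    "LmmSpec",
    "LmmResult",
    "ConvergenceError",
    "fit_lmm",
    "tukey_posthoc",
    "residual_diagnostics",
    "eta_p2_from_f",
    "genotype_behavior_spec",
    "session_consistency_spec",
]

_BOUNDARY_TOL = 1e-6   # variance ratio below this counts as a zero component
_ZERO_RSS_TOL = 1e-10  # relative residual SS below this is a noiseless fit


class ConvergenceError(RuntimeError):
    """REML optimisation failed to converge."""


@dataclass(frozen=True)
class LmmSpec:
    """Specification of one mixed model.

    ``fixed`` is a patsy right-hand-side formula over columns of the data
    (factors should be sum-coded, e.g. ``C(genotype, Sum)``); ``random`` is
    a list of column names, each contributing one random intercept per
    level; ``transform`` names a registered monotone response transform.
    """

    response: str
    fixed: str
    random: tuple[str, ...] = ()
    transform: str = "identity"
    factors: tuple[str, ...] = ()   # data columns treated as factors (for EMM grids)
    covariates: tuple[str, ...] = ()


def genotype_behavior_spec(response: str, transform: str = "identity") -> LmmSpec:
    """The genotype x behavior model for session-1 LI or |LI|.

    Fixed effects: genotype, behavior and their interaction (sum-to-zero
    coded); random intercepts for batch and animal identity (each animal
    contributes up to four behaviors).
    """
    return LmmSpec(
        response=response,
        fixed="C(genotype, Sum) * C(behavior, Sum)",
        random=("batch", "animal_id"),
        transform=transform,
        factors=("genotype", "behavior"),
    )


def session_consistency_spec(response: str, baseline: str,
                             transform: str = "identity") -> LmmSpec:
    """Per-behavior temporal-consistency model.

    Session-2 measure regressed on the session-1 measure, genotype and
    their interaction, with a batch random intercept.
    """
    return LmmSpec(
        response=response,
        fixed=f"{baseline} * C(genotype, Sum)",
        random=("batch",),
        transform=transform,
        factors=("genotype",),
        covariates=(baseline,),
    )


@dataclass
class LmmResult:
    """Fitted model: ANOVA table, estimates, variance components, internals."""

    spec: LmmSpec
    anova: pd.DataFrame            # term, F, df_num, df_den, p, eta_p2
    params: pd.Series              # fixed-effect estimates
    cov_params: np.ndarray
    vcomp: dict[str, float]        # random-intercept variances (natural scale)
    scale: float                   # residual variance
    resid: np.ndarray              # conditional residuals (BLUPs subtracted)
    fitted: np.ndarray
    n_obs: int
    df_resid: float
    converged: bool
    loglike: float
    warnings: list[str] = field(default_factory=list)
    # internals used by post-hocs / Satterthwaite
    _design_info: object = None
    _data: pd.DataFrame | None = None
    _X: np.ndarray | None = None
    _Zs: list | None = None
    _y: np.ndarray | None = None
    _theta: np.ndarray | None = None     # (s2_resid, s2_k ...) incl. zeroed comps
    _theta_free: np.ndarray | None = None  # indices of non-boundary params
    _noiseless: bool = False


# ---------------------------------------------------------------------------
# REML engine
# ---------------------------------------------------------------------------

def _random_design(data: pd.DataFrame, column: str) -> np.ndarray:
    codes, _ = pd.factorize(data[column], sort=True)
    z = np.zeros((len(data), codes.max() + 1))
    z[np.arange(len(data)), codes] = 1.0
    return z


def _profiled_reml(loggam: np.ndarray, Gs: list[np.ndarray], X: np.ndarray,
                   y: np.ndarray) -> float:
    """-2 REML profile log-likelihood over variance ratios gamma_k."""
    n, p = X.shape
    v0 = np.eye(n)
    for lg, G in zip(loggam, Gs):
        v0 += np.exp(lg) * G
    try:
        c, low = linalg.cho_factor(v0, check_finite=False)
    except linalg.LinAlgError:
        return 1e12
    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    wx = linalg.cho_solve((c, low), X, check_finite=False)
    wy = linalg.cho_solve((c, low), y, check_finite=False)
    xtwx = X.T @ wx
    sign, logdet_x = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(xtwx, X.T @ wy)
    r = y - X @ beta
    rss = float(r @ linalg.cho_solve((c, low), r, check_finite=False))
    if rss <= 0:
        return 1e12
    return logdet_v + logdet_x + (n - p) * np.log(rss)


def _reml_loglike_natural(theta: np.ndarray, Gs: list[np.ndarray],
                          X: np.ndarray, y: np.ndarray) -> float:
    """REML log-likelihood at natural variances theta = (s2, s2_1, ...)."""
    n, p = X.shape
    v = theta[0] * np.eye(n)
    for t, G in zip(theta[1:], Gs):
        v += t * G
    c, low = linalg.cho_factor(v, check_finite=False)
    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    wx = linalg.cho_solve((c, low), X, check_finite=False)
    wy = linalg.cho_solve((c, low), y, check_finite=False)
    xtwx = X.T @ wx
    _, logdet_x = np.linalg.slogdet(xtwx)
    beta = np.linalg.solve(xtwx, X.T @ wy)
    r = y - X @ beta
    rss = float(r @ linalg.cho_solve((c, low), r, check_finite=False))
    return -0.5 * (logdet_v + logdet_x + rss)


def _cov_beta(theta: np.ndarray, Gs: list[np.ndarray], X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    v = theta[0] * np.eye(n)
    for t, G in zip(theta[1:], Gs):
        v += t * G
    c, low = linalg.cho_factor(v, check_finite=False)
    wx = linalg.cho_solve((c, low), X, check_finite=False)
    return np.linalg.inv(X.T @ wx)


def fit_lmm(data: pd.DataFrame, spec: LmmSpec) -> LmmResult:
    """Fit a random-intercept LMM by REML and build its Type III ANOVA table.

    The response is transformed per ``spec.transform`` before fitting.
    Random grouping columns with fewer than two levels are dropped with a
    warning; a variance ratio driven to the boundary is reported as a zero
    component with a singular-fit warning.  Failure of the optimiser raises
    :class:`ConvergenceError` rather than silently falling back.
    """
    notes: list[str] = []
    df = data.reset_index(drop=True).copy()
    yvals = apply_transform(spec.transform, df[spec.response].to_numpy())
    if not np.all(np.isfinite(yvals)):
        raise ValueError(f"non-finite response values after transform {spec.transform!r}")
    df["__response"] = yvals

    ymat, X = patsy.dmatrices("__response ~ " + spec.fixed, df, return_type="matrix")
    design_info = X.design_info
    X = np.asarray(X, dtype=float)
    y = np.asarray(ymat, dtype=float).ravel()
    n, p = X.shape

    random_cols = []
    for col in spec.random:
        if df[col].nunique() < 2:
            msg = f"random intercept {col!r} has < 2 levels; dropped"
            warnings.warn(msg, stacklevel=2)
            notes.append(msg)
        else:
            random_cols.append(col)
    Zs = [_random_design(df, col) for col in random_cols]
    Gs = [Z @ Z.T for Z in Zs]

    # Noiseless short-circuit: OLS already interpolates the data.
    beta_ols, rss_ols = np.linalg.lstsq(X, y, rcond=None)[:2]
    rss_ols = float(rss_ols[0]) if len(rss_ols) else float(((y - X @ beta_ols) ** 2).sum())
    noiseless = rss_ols <= _ZERO_RSS_TOL * max(1.0, float(y @ y))

    if noiseless:
        notes.append("residual variance is (numerically) zero; F-tests undefined")
        beta = beta_ols
        gam = np.zeros(len(Gs))
        sigma2 = 0.0
        cbeta = np.full((p, p), np.nan)
        converged = True
        loglike = np.nan
    elif not Gs:
        beta = beta_ols
        gam = np.zeros(0)
        sigma2 = rss_ols / (n - p)
        cbeta = sigma2 * np.linalg.inv(X.T @ X)
        converged = True
        loglike = _reml_loglike_natural(np.array([sigma2]), [], X, y)
    else:
        obj = lambda lg: _profiled_reml(lg, Gs, X, y)
        res = optimize.minimize(
            obj, np.full(len(Gs), -1.0), method="L-BFGS-B",
            bounds=[(-16.0, 12.0)] * len(Gs),
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
        )
        if not res.success and "ROUNDING" not in str(res.message).upper():
            # L-BFGS-B line searches can stall on near-flat boundary profiles;
            # polish with a derivative-free restart before giving up
            res2 = optimize.minimize(
                obj, np.clip(res.x, -16.0, 12.0), method="Nelder-Mead",
                options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-12},
            )
            if res2.fun <= res.fun:
                res = res2
                res.x = np.clip(res.x, -16.0, 12.0)
            if not res.success:
                raise ConvergenceError(f"REML optimisation failed: {res.message}")
        gam = np.exp(res.x)
        at_boundary = res.x <= -16.0 + 1e-6
        gam[gam < _BOUNDARY_TOL] = 0.0
        for col, boundary, g in zip(random_cols, at_boundary, gam):
            if boundary or g == 0.0:
                msg = f"random intercept {col!r}: variance estimated at zero (singular fit)"
                notes.append(msg)
        v0 = np.eye(n)
        for g, G in zip(gam, Gs):
            v0 += g * G
        c, low = linalg.cho_factor(v0, check_finite=False)
        wx = linalg.cho_solve((c, low), X, check_finite=False)
        wy = linalg.cho_solve((c, low), y, check_finite=False)
        xtwx = X.T @ wx
        beta = np.linalg.solve(xtwx, X.T @ wy)
        r = y - X @ beta
        sigma2 = float(r @ linalg.cho_solve((c, low), r, check_finite=False)) / (n - p)
        cbeta = sigma2 * np.linalg.inv(xtwx)
        converged = True
        theta_full = np.concatenate([[sigma2], gam * sigma2])
        loglike = _reml_loglike_natural(theta_full, Gs, X, y)

    vcomp = {col: float(g * sigma2) for col, g in zip(random_cols, gam)}
    theta = np.concatenate([[sigma2], gam * sigma2]) if not noiseless else np.concatenate([[0.0], np.zeros(len(Gs))])
    free = np.concatenate([[True], gam > 0]) if not noiseless else np.zeros(1 + len(Gs), bool)

    # conditional residuals: subtract BLUPs of the random intercepts
    if not noiseless and Gs and gam.sum() > 0:
        v0 = np.eye(n)
        for g, G in zip(gam, Gs):
            v0 += g * G
        r_marg = y - X @ beta
        w_r = np.linalg.solve(v0, r_marg)
        cond = r_marg.copy()
        for g, Z in zip(gam, Zs):
            cond -= g * (Z @ (Z.T @ w_r))
        resid = cond
        fitted = y - cond
    else:
        resid = y - X @ beta
        fitted = X @ beta

    result = LmmResult(
        spec=spec,
        anova=pd.DataFrame(),
        params=pd.Series(beta, index=design_info.column_names),
        cov_params=cbeta,
        vcomp=vcomp,
        scale=float(sigma2),
        resid=resid,
        fitted=fitted,
        n_obs=n,
        df_resid=float(n - p),
        converged=converged,
        loglike=float(loglike) if np.isfinite(np.atleast_1d(loglike)).all() else np.nan,
        warnings=notes,
        _design_info=design_info,
        _data=df,
        _X=X,
        _Zs=Zs,
        _y=y,
        _theta=theta,
        _theta_free=np.flatnonzero(free),
        _noiseless=noiseless,
    )
    result.anova = _anova_table(result)
    return result


# ---------------------------------------------------------------------------
# Satterthwaite denominator degrees of freedom
# ---------------------------------------------------------------------------

def _satterthwaite_machinery(result: LmmResult):
    """Precompute perturbed cov(beta) matrices and the REML information.

    Returns a closure ``df_for(ell)`` giving the Satterthwaite df of the
    scalar contrast ``ell' beta``.  For an OLS-limit fit (no free variance
    components beyond the residual) the df is exactly ``n - p``.
    """
    theta = result._theta
    free = result._theta_free
    X, y = result._X, result._y
    Gs = [Z @ Z.T for Z in result._Zs]
    n_resid = result.df_resid

    if result._noiseless:
        return lambda ell: np.nan

    if len(free) <= 1:
        # only the residual variance is free: exact chi-square, df = n - p
        return lambda ell: n_resid

    steps = np.array([1e-4 * max(theta[i], 0.05 * theta[0]) for i in free])
    cov_plus, cov_minus = [], []
    for i, h in zip(free, steps):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] = max(tm[i] - h, 1e-12 * theta[0])
        cov_plus.append(_cov_beta(tp, Gs, X))
        cov_minus.append(_cov_beta(tm, Gs, X))
    actual_steps = np.array(
        [theta[i] + h - max(theta[i] - h, 1e-12 * theta[0]) for i, h in zip(free, steps)]
    )

    # observed REML information on the free variance parameters
    d = len(free)
    ll0 = _reml_loglike_natural(theta, Gs, X, y)
    H = np.zeros((d, d))
    ll_p = np.zeros(d)
    ll_m = np.zeros(d)
    for a in range(d):
        tp, tm = theta.copy(), theta.copy()
        tp[free[a]] += steps[a]
        tm[free[a]] = max(tm[free[a]] - steps[a], 1e-12 * theta[0])
        ll_p[a] = _reml_loglike_natural(tp, Gs, X, y)
        ll_m[a] = _reml_loglike_natural(tm, Gs, X, y)
        H[a, a] = (ll_p[a] - 2 * ll0 + ll_m[a]) / ((actual_steps[a] / 2) ** 2)
    for a in range(d):
        for b in range(a + 1, d):
            tpp, tmm = theta.copy(), theta.copy()
            tpp[free[a]] += steps[a]; tpp[free[b]] += steps[b]
            tmm[free[a]] = max(tmm[free[a]] - steps[a], 1e-12 * theta[0])
            tmm[free[b]] = max(tmm[free[b]] - steps[b], 1e-12 * theta[0])
            llpp = _reml_loglike_natural(tpp, Gs, X, y)
            llmm = _reml_loglike_natural(tmm, Gs, X, y)
            ha = actual_steps[a] / 2
            hb = actual_steps[b] / 2
            H[a, b] = H[b, a] = (
                llpp - ll_p[a] - ll_p[b] + 2 * ll0 - ll_m[a] - ll_m[b] + llmm
            ) / (2 * ha * hb)
    try:
        acov = np.linalg.pinv(-H)
    except np.linalg.LinAlgError:
        acov = None

    cbeta = result.cov_params

    def df_for(ell: np.ndarray) -> float:
        f0 = float(ell @ cbeta @ ell)
        if acov is None or f0 <= 0:
            return n_resid
        g = np.array(
            [
                (ell @ cp @ ell - ell @ cm @ ell) / h
                for cp, cm, h in zip(cov_plus, cov_minus, actual_steps)
            ]
        )
        denom = float(g @ acov @ g)
        if denom <= 0 or not np.isfinite(denom):
            return n_resid
        df = 2.0 * f0 * f0 / denom
        if not np.isfinite(df) or df < 1.0:
            return n_resid
        return df

    return df_for


def _term_f_test(result: LmmResult, L: np.ndarray, df_for: Callable) -> tuple:
    """Type III F statistic and Satterthwaite denominator df for L beta = 0.

    Multi-df terms use the eigencontrast decomposition of L cov(beta) L':
    each eigen-direction is a 1-df contrast with its own Satterthwaite df,
    combined through E = sum nu_i/(nu_i - 2), ddf = 2E/(E - q).
    """
    beta = result.params.to_numpy()
    q = L.shape[0]
    M = L @ result.cov_params @ L.T
    Lb = L @ beta
    try:
        F = float(Lb @ np.linalg.solve(M, Lb)) / q
    except np.linalg.LinAlgError:
        return np.nan, np.nan
    if result._noiseless:
        return F, np.nan
    eigval, eigvec = np.linalg.eigh(M)
    nus = []
    for j in range(q):
        if eigval[j] <= 1e-12 * eigval.max():
            continue
        ell = L.T @ eigvec[:, j]
        nus.append(df_for(ell))
    if q == 1:
        return F, nus[0] if nus else result.df_resid
    good = [nu for nu in nus if nu > 2.0]
    if not good:
        return F, result.df_resid
    E = sum(nu / (nu - 2.0) for nu in good)
    if E <= q:
        return F, result.df_resid
    return F, 2.0 * E / (E - q)


def _anova_table(result: LmmResult) -> pd.DataFrame:
    di = result._design_info
    df_for = _satterthwaite_machinery(result)
    rows = []
    p_cols = len(di.column_names)
    for term in di.term_names:
        if term == "Intercept":
            continue
        sl = di.term_name_slices[term]
        idx = np.arange(p_cols)[sl]
        L = np.zeros((len(idx), p_cols))
        L[np.arange(len(idx)), idx] = 1.0
        F, ddf = _term_f_test(result, L, df_for)
        if np.isfinite(F) and np.isfinite(ddf):
            p = float(stats.f.sf(F, len(idx), ddf))
            eta = eta_p2_from_f(F, len(idx), ddf)
        else:
            p, eta = np.nan, np.nan
        rows.append(
            {"term": term, "F": F, "df_num": len(idx), "df_den": ddf,
             "p": p, "eta_p2": eta}
        )
    return pd.DataFrame(rows)


def eta_p2_from_f(F: float, df_num: int, df_den: float) -> float:
    """Partial eta squared from an F statistic: F*q / (F*q + ddf)."""
    if F < 0 or df_num <= 0 or df_den <= 0:
        raise ValueError("F must be >= 0 and degrees of freedom positive")
    return float(F * df_num / (F * df_num + df_den))


# ---------------------------------------------------------------------------
# Estimated marginal means and Tukey HSD
# ---------------------------------------------------------------------------

def _reference_grid(result: LmmResult) -> pd.DataFrame:
    spec, df = result.spec, result._data
    levels = {f: sorted(df[f].dropna().unique(), key=str) for f in spec.factors}
    grid = pd.MultiIndex.from_product(levels.values(), names=levels.keys()).to_frame(index=False)
    for cov in spec.covariates:
        grid[cov] = df[cov].mean()
    return grid


def estimated_marginal_means(result: LmmResult, factor: str) -> pd.DataFrame:
    """EMMs for ``factor``: predictions averaged over the balanced grid."""
    if factor not in result.spec.factors:
        raise ValueError(f"{factor!r} is not a factor of this model")
    grid = _reference_grid(result)
    (mat,) = patsy.build_design_matrices([result._design_info], grid)
    mat = np.asarray(mat, dtype=float)
    beta = result.params.to_numpy()
    rows = []
    for level in sorted(grid[factor].unique(), key=str):
        ell = mat[(grid[factor] == level).to_numpy()].mean(axis=0)
        se = float(np.sqrt(ell @ result.cov_params @ ell)) if not result._noiseless else np.nan
        rows.append({"level": level, "emmean": float(ell @ beta), "se": se,
                     "_ell": ell})
    return pd.DataFrame(rows)


def tukey_posthoc(result: LmmResult, factor: str) -> pd.DataFrame:
    """All pairwise EMM contrasts for ``factor`` with Tukey HSD adjustment.

    The studentized-range adjustment uses k = number of levels and the
    Satterthwaite df of each individual contrast.  With two levels the
    adjusted p reduces to the unadjusted t-test p.
    """
    emm = estimated_marginal_means(result, factor)
    k = len(emm)
    if k < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    df_for = _satterthwaite_machinery(result)
    beta = result.params.to_numpy()
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            ell = emm["_ell"].iloc[i] - emm["_ell"].iloc[j]
            est = float(ell @ beta)
            if result._noiseless:
                rows.append({"contrast": f"{emm['level'].iloc[i]} - {emm['level'].iloc[j]}",
                             "estimate": est, "se": np.nan, "df": np.nan,
                             "t": np.nan, "p_tukey": np.nan})
                continue
            se = float(np.sqrt(ell @ result.cov_params @ ell))
            nu = df_for(ell)
            t = est / se if se > 0 else np.inf
            p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, nu))
            rows.append({"contrast": f"{emm['level'].iloc[i]} - {emm['level'].iloc[j]}",
                         "estimate": est, "se": se, "df": nu, "t": t,
                         "p_tukey": min(1.0, p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Residual diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagnosticsReport:
    shapiro_stat: float
    shapiro_p: float
    variance_ratio: float        # max/min residual variance across design cells
    heteroscedastic: bool
    degenerate: bool
    recommend_transform: bool


def residual_diagnostics(result: LmmResult, variance_ratio_flag: float = 4.0) -> DiagnosticsReport:
    """Shapiro-Wilk normality test and a grouped-variance homoscedasticity flag.

    Residual variances are compared across the cells of the model's factors
    (cells with < 3 residuals are skipped); a max/min ratio above
    ``variance_ratio_flag`` raises the heteroscedasticity flag.  A
    Shapiro-Wilk p <= 0.05 yields a recommendation to transform the
    response.  Constant residuals are reported as degenerate rather than
    tested.
    """
    r = np.asarray(result.resid, dtype=float)
    if len(r) < 3:
        raise ValueError("diagnostics require at least 3 residuals")
    if np.ptp(r) == 0:
        return DiagnosticsReport(np.nan, np.nan, np.nan, False, True, False)
    stat, p = stats.shapiro(r)
    ratio = np.nan
    hetero = False
    if result.spec.factors and result._data is not None:
        cells = pd.Series(r).groupby(
            [result._data[f] for f in result.spec.factors], observed=True
        )
        variances = [v for _, g in cells if len(g) >= 3 for v in [float(np.var(g, ddof=1))]]
        variances = [v for v in variances if v > 0]
        if len(variances) >= 2:
            ratio = max(variances) / min(variances)
            hetero = ratio > variance_ratio_flag
    return DiagnosticsReport(
        shapiro_stat=float(stat),
        shapiro_p=float(p),
        variance_ratio=float(ratio) if np.isfinite(ratio) else np.nan,
        heteroscedastic=hetero,
        degenerate=False,
        recommend_transform=bool(p <= 0.05),
    )
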