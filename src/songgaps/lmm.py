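"""Linear mixed models with crossed/nested random intercepts, fitted by
restricted maximum likelihood (REML).

Implements exactly the model family the coupling analyses need:

    y = X beta + sum_k Z_k u_k + eps,     u_k ~ N(0, s2_k I),  eps ~ N(0, s2_e I)

with a handful of random-intercept factors (bird, sequence-within-bird).
Variance components are *unbounded*: the REML criterion is optimised over
variance ratios ``gamma_k = s2_k / s2_e`` without a positivity constraint,
subject only to the marginal covariance ``V`` staying positive definite, so
small negative component estimates are representable (as in JMP-style REML).
Denominator degrees of freedom for t/F tests use the Satterthwaite
approximation, computed from finite-difference derivatives of the
fixed-effect covariance and the observed REML information.  Multi-degree
contrasts use the eigenvalue-averaged Satterthwaite df, and pairwise
comparisons of least-squares means use the studentized range
(Tukey-Kramer for unbalanced designs).

Problem sizes here are a few hundred rows, so all linear algebra is dense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import f as f_dist
from scipy.stats import studentized_range, t as t_dist

__all__ = ["MixedModelResult", "fit_lmm", "ls_means", "tukey_pairs"]


@dataclass
class MixedModelResult:
    """Fitted mixed model.

    ``fe_params``/``fe_se`` are the fixed-effect estimates and standard
    errors (indexed by ``fe_names``); ``vcomps`` maps each random factor
    (plus ``"residual"``) to its variance estimate, possibly negative;
    ``df_satt``, ``tvalues``, ``fvalues`` and ``pvalues`` are per-coefficient
    Satterthwaite t/F statistics (``F = t^2`` with 1 numerator df).
    ``resid`` holds conditional residuals (observed minus fixed plus BLUP
    random effects).
    """

    fe_names: list[str]
    fe_params: np.ndarray
    fe_se: np.ndarray
    cov_fe: np.ndarray
    vcomps: dict[str, float]
    df_satt: np.ndarray
    tvalues: np.ndarray
    fvalues: np.ndarray
    pvalues: np.ndarray
    resid: np.ndarray
    resid_marginal: np.ndarray
    fitted: np.ndarray
    nobs: int
    loglike_reml: float
    converged: bool
    negative_components: bool
    _internals: dict = field(default_factory=dict, repr=False)

    def coef(self, name: str) -> dict:
        i = self.fe_names.index(name)
        return {
            "estimate": float(self.fe_params[i]),
            "se": float(self.fe_se[i]),
            "F": float(self.fvalues[i]),
            "df_num": 1.0,
            "df_den": float(self.df_satt[i]),
            "p": float(self.pvalues[i]),
        }

    def contrast(self, l: np.ndarray) -> dict:
        """t-test of the scalar contrast ``l @ beta`` with Satterthwaite df."""
        est, se, df = _contrast_stats(self, np.asarray(l, dtype=float))
        t = est / se if se > 0 else np.inf
        return {
            "estimate": est,
            "se": se,
            "t": t,
            "df": df,
            "p": float(2.0 * t_dist.sf(abs(t), df)),
        }

    def ftest(self, L: np.ndarray) -> dict:
        """Omnibus F test of the multi-row contrast ``L @ beta = 0``."""
        return _ftest(self, np.atleast_2d(np.asarray(L, dtype=float)))


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def _indicator(codes: np.ndarray) -> np.ndarray:
    levels, inv = np.unique(codes, return_inverse=True)
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), inv] = 1.0
    return Z


def _profiled_neg2_reml(gamma, Gs, X, y, n, p):
    V0 = np.eye(n)
    for g, G in zip(gamma, Gs):
        V0 += g * G
    try:
        c, low = cho_factor(V0, lower=True)
    except np.linalg.LinAlgError:
        return 1e12, None
    logdet_V0 = 2.0 * np.sum(np.log(np.diag(c)))
    ViX = cho_solve((c, low), X)
    Viy = cho_solve((c, low), y)
    XtViX = X.T @ ViX
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e12, None
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    r = y - X @ beta
    q = float(r @ cho_solve((c, low), r))
    if q <= 0:
        q = 1e-300
    sigma2 = q / (n - p)
    neg2 = (
        (n - p) * (1.0 + np.log(2.0 * np.pi * sigma2))
        + logdet_V0
        + logdet_XtViX
    )
    return neg2, (beta, sigma2, (c, low), XtViX)


def _full_neg2_reml(theta, Zs_G, X, y, n, p):
    """-2 REML log-likelihood at raw variances theta = (vc..., resid)."""
    V = theta[-1] * np.eye(n)
    for th, G in zip(theta[:-1], Zs_G):
        V += th * G
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return 1e12
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    ViX = cho_solve((c, low), X)
    XtViX = X.T @ ViX
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(XtViX, ViX.T @ y)
    r = y - X @ beta
    q = float(r @ cho_solve((c, low), r))
    return logdet_V + logdet_XtViX + q + (n - p) * np.log(2.0 * np.pi)


def _cov_fe_at(theta, Gs, X, n):
    V = theta[-1] * np.eye(n)
    for th, G in zip(theta[:-1], Gs):
        V += th * G
    c, low = cho_factor(V, lower=True)
    XtViX = X.T @ cho_solve((c, low), X)
    return np.linalg.inv(XtViX)


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    factors: dict[str, np.ndarray],
    fe_names: list[str] | None = None,
    allow_negative: bool = True,
) -> MixedModelResult:
    """Fit the random-intercept mixed model by REML.

    Parameters
    ----------
    y, X
        Response vector and fixed-effect design (include the intercept
        column explicitly).
    factors
        Mapping of factor name to a length-n array of group codes; each
        contributes one random-intercept variance component.  Nesting is
        expressed through the codes themselves (e.g. sequence ids prefixed
        with the bird id).
    allow_negative
        If True (default), variance ratios are unconstrained apart from
        positive-definiteness of ``V``; if False they are bounded at zero.

    Raises
    ------
    ValueError
        If the design is rank deficient (e.g. a constant predictor column
        alongside the intercept); the offending column is named.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if fe_names is None:
        fe_names = [f"x{j}" for j in range(p)]
    if n <= p:
        raise ValueError(f"too few rows ({n}) for {p} fixed effects")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify a dependent column for the error message
        for j in range(p):
            keep = [k for k in range(p) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                raise ValueError(
                    f"fixed-effect design is singular: column {fe_names[j]!r} "
                    "is collinear (constant predictor?)"
                )
        raise ValueError("fixed-effect design is singular")

    names = list(factors)
    Zs = [_indicator(np.asarray(factors[k])) for k in names]
    Gs = [Z @ Z.T for Z in Zs]
    K = len(Gs)

    if K == 0:
        return _ols_result(y, X, fe_names)

    def objective(gamma):
        if not allow_negative and (np.asarray(gamma) < 0).any():
            return 1e12
        return _profiled_neg2_reml(gamma, Gs, X, y, n, p)[0]

    best = None
    for start in ([0.5] * K, [0.05] * K):
        res = optimize.minimize(
            objective,
            np.asarray(start, dtype=float),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 3000},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and best.fun < 1e11:
            # two starts only guard against a poor local basin; stop early
            # when the first converged cleanly at a plausible optimum
            break
    gamma = best.x
    neg2, aux = _profiled_neg2_reml(gamma, Gs, X, y, n, p)
    if aux is None:
        raise RuntimeError("REML optimisation ended at a non-PD covariance")
    beta, sigma2, chol_V0, XtViX = aux
    theta = np.append(gamma * sigma2, sigma2)
    cov_fe = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_fe))

    # BLUPs -> conditional residuals
    r_marg = y - X @ beta
    Vir = cho_solve(chol_V0, r_marg) / sigma2
    resid = r_marg.copy()
    for g, Z in zip(gamma, Zs):
        u = (g * sigma2) * (Z.T @ Vir)
        resid -= Z @ u

    internals = {
        "theta": theta,
        "Gs": Gs,
        "X": X,
        "y": y,
        "n": n,
        "p": p,
        "sigma2": sigma2,
    }
    result = MixedModelResult(
        fe_names=list(fe_names),
        fe_params=beta,
        fe_se=se,
        cov_fe=cov_fe,
        vcomps={**{k: float(th) for k, th in zip(names, theta[:-1])},
                "residual": float(sigma2)},
        df_satt=np.zeros(p),
        tvalues=np.zeros(p),
        fvalues=np.zeros(p),
        pvalues=np.zeros(p),
        resid=resid,
        resid_marginal=r_marg,
        fitted=y - resid,
        nobs=n,
        loglike_reml=-0.5 * neg2,
        converged=bool(best.success),
        negative_components=bool((theta[:-1] < 0).any()),
        _internals=internals,
    )
    _attach_cov_theta(result)
    for j in range(p):
        l = np.zeros(p)
        l[j] = 1.0
        _est, se_j, df_j = _contrast_stats(result, l)
        result.df_satt[j] = df_j
        result.tvalues[j] = beta[j] / se_j if se_j > 0 else np.inf
        result.fvalues[j] = result.tvalues[j] ** 2
        result.pvalues[j] = 2.0 * t_dist.sf(abs(result.tvalues[j]), df_j)
    return result


def _ols_result(y, X, fe_names):
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    sigma2 = float(r @ r) / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = np.where(se > 0, beta / se, np.inf)
    df = float(n - p)
    pv = 2.0 * t_dist.sf(np.abs(t), df)
    return MixedModelResult(
        fe_names=list(fe_names), fe_params=beta, fe_se=se, cov_fe=cov,
        vcomps={"residual": sigma2}, df_satt=np.full(p, df), tvalues=t,
        fvalues=t**2, pvalues=pv, resid=r, resid_marginal=r, fitted=y - r,
        nobs=n, loglike_reml=np.nan, converged=True, negative_components=False,
        _internals={"theta": np.array([sigma2]), "Gs": [], "X": X, "y": y,
                    "n": n, "p": p, "sigma2": sigma2},
    )


# --------------------------------------------------------------------------
# Satterthwaite machinery
# --------------------------------------------------------------------------


def _attach_cov_theta(result: MixedModelResult) -> None:
    """Observed-information covariance of the variance components, by
    central finite differences of the full (unprofiled) -2 REML criterion."""
    it = result._internals
    theta, Gs, X, y, n, p = (
        it["theta"], it["Gs"], it["X"], it["y"], it["n"], it["p"],
    )
    m = len(theta)
    scale = max(it["sigma2"], 1e-12)
    h = np.maximum(np.abs(theta), 0.05 * scale) * 1e-3

    def f(th):
        return _full_neg2_reml(th, Gs, X, y, n, p)

    H = np.zeros((m, m))
    f0 = f(theta)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            if i == j:
                val = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                val = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4.0 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    # Cov(theta) = inverse REML information = 2 * H^{-1}
    try:
        cov_theta = 2.0 * np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        cov_theta = np.full((m, m), np.nan)
    it["cov_theta"] = cov_theta
    it["h_theta"] = h


def _contrast_stats(result: MixedModelResult, l: np.ndarray):
    it = result._internals
    est = float(l @ result.fe_params)
    var = float(l @ result.cov_fe @ l)
    se = np.sqrt(max(var, 0.0))
    n, p = it["n"], it["p"]
    if not it["Gs"] or "cov_theta" not in it:
        return est, se, float(n - p)
    theta, Gs, X = it["theta"], it["Gs"], it["X"]
    h = it["h_theta"]
    m = len(theta)
    grad = np.zeros(m)
    for i in range(m):
        ei = np.zeros(m); ei[i] = h[i]
        try:
            cp = float(l @ _cov_fe_at(theta + ei, Gs, X, n) @ l)
            cm = float(l @ _cov_fe_at(theta - ei, Gs, X, n) @ l)
        except np.linalg.LinAlgError:
            return est, se, float(n - p)
        grad[i] = (cp - cm) / (2.0 * h[i])
    denom = float(grad @ it["cov_theta"] @ grad)
    if denom <= 0 or not np.isfinite(denom) or var <= 0:
        return est, se, float(n - p)
    df = 2.0 * var**2 / denom
    return est, se, float(np.clip(df, 1.0, n - p))


def _ftest(result: MixedModelResult, L: np.ndarray) -> dict:
    beta = result.fe_params
    C = result.cov_fe
    q = L.shape[0]
    M = L @ C @ L.T
    Minv = np.linalg.pinv(M)
    F = float(beta @ L.T @ Minv @ L @ beta) / q
    # eigenvalue-averaged multi-df Satterthwaite denominator
    vals, vecs = np.linalg.eigh(M)
    keep = vals > max(vals.max(), 0) * 1e-10
    nu = []
    for lam, v in zip(vals[keep], vecs[:, keep].T):
        contrast = v @ L
        _e, _s, df_i = _contrast_stats(result, contrast)
        nu.append(df_i)
    nu = np.asarray(nu)
    good = nu > 2.0
    if good.any():
        E = float(np.sum(nu[good] / (nu[good] - 2.0)))
        df_den = 2.0 * E / (E - q) if E > q else float(result.nobs - len(beta))
    else:
        df_den = float(result.nobs - len(beta))
    df_den = float(np.clip(df_den, 1.0, result.nobs - len(beta)))
    return {
        "F": F,
        "df_num": float(q),
        "df_den": df_den,
        "p": float(f_dist.sf(F, q, df_den)),
    }


# --------------------------------------------------------------------------
# least-squares means and Tukey-Kramer comparisons
# --------------------------------------------------------------------------


def ls_means(
    result: MixedModelResult, levels: list[str], contrast_rows: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Least-squares means for a categorical fixed factor.

    ``contrast_rows[level]`` is the fixed-design row vector producing that
    level's adjusted mean.
    """
    rows = []
    for lev in levels:
        l = contrast_rows[lev]
        est, se, df = _contrast_stats(result, np.asarray(l, dtype=float))
        rows.append({"level": lev, "lsmean": est, "se": se, "df": df})
    return pd.DataFrame(rows)


def tukey_pairs(
    result: MixedModelResult, levels: list[str], contrast_rows: dict[str, np.ndarray]
) -> pd.DataFrame:
    """All pairwise LS-mean differences with Tukey-Kramer adjusted p-values
    (studentized range on Satterthwaite df; family-wise alpha applies across
    the ``k = len(levels)`` means)."""
    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            l = np.asarray(contrast_rows[levels[i]], dtype=float) - np.asarray(
                contrast_rows[levels[j]], dtype=float
            )
            est, se, df = _contrast_stats(result, l)
            if se <= 0:
                continue
            qstat = np.sqrt(2.0) * abs(est) / se
            p = float(studentized_range.sf(qstat, k, df))
            rows.append(
                {
                    "level_a": levels[i],
                    "level_b": levels[j],
                    "difference": est,
                    "se": se,
                    "df": df,
                    "q": qstat,
                    "p_tukey": min(max(p, 0.0), 1.0),
                }
            )
    return pd.DataFrame(rows)
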