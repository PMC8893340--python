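"""Linear mixed models with Satterthwaite degrees of freedom.

Estimation is restricted maximum likelihood via
:class:`statsmodels.regression.mixed_linear_model.MixedLM`, restricted to
the structure both revision models share: a per-group random intercept
plus independent random slopes (a diagonal random-effect covariance),

    y_g = X_g beta + Z_g b_g + e_g,   b_g ~ N(0, diag(d)),  e_g ~ N(0, s2 I).

On top of the REML variance estimates this module computes, per fixed
effect, the generalised-least-squares covariance, Wald F statistics
(numerator df 1), and denominator degrees of freedom by the Satterthwaite
approximation: df_j = 2 Var(beta_j)^2 / Var_hat(Var(beta_j)), with the
variance of the variance obtained from the delta method using the
numerical gradient of Var(beta_j) with respect to the variance parameters
and the inverse observed information of the restricted log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MixedFit", "fit_mixed", "restricted_loglik"]


@dataclass
class MixedFit:
    """Fitted mixed model: per-term inference plus variance components.

    ``terms`` has one row per fixed effect with columns
    estimate / se / ci_low / ci_high / fstat / df_num / df_den / p.
    """

    terms: pd.DataFrame
    random_variances: dict
    residual_var: float
    loglike: float
    bic: float
    n_obs: int
    n_groups: int
    reml: bool = True
    singular: bool = False
    simplified: bool = False

    def to_dict(self) -> dict:
        return {
            "terms": self.terms.reset_index().to_dict(orient="records"),
            "random_variances": {k: float(v) for k, v in self.random_variances.items()},
            "residual_var": float(self.residual_var),
            "loglike": float(self.loglike),
            "bic": float(self.bic),
            "n_obs": int(self.n_obs),
            "n_groups": int(self.n_groups),
            "reml": self.reml,
            "singular": self.singular,
            "simplified": self.simplified,
        }


def _blocks(X, Z, y, groups):
    out = []
    for g in pd.unique(groups):
        m = np.asarray(groups) == g
        out.append((X[m], Z[m], y[m]))
    return out


def _v_chol(Zg, theta):
    """Cholesky of V_g = s2 I + Z diag(d) Z'."""
    s2, d = theta[0], theta[1:]
    V = (Zg * d) @ Zg.T
    V[np.diag_indices_from(V)] += s2
    return np.linalg.cholesky(V)


def _gls(blocks, theta):
    """Profiled GLS at variance parameters theta: returns (beta, C, quad, logdetV, logdetM)."""
    p = blocks[0][0].shape[1]
    M = np.zeros((p, p))
    v = np.zeros(p)
    logdetV = 0.0
    solves = []
    for Xg, Zg, yg in blocks:
        L = _v_chol(Zg, theta)
        logdetV += 2.0 * np.log(np.diag(L)).sum()
        Xs = np.linalg.solve(L, Xg)
        ys = np.linalg.solve(L, yg)
        M += Xs.T @ Xs
        v += Xs.T @ ys
        solves.append((Xs, ys))
    C = np.linalg.inv(M)
    beta = C @ v
    quad = 0.0
    for Xs, ys in solves:
        r = ys - Xs @ beta
        quad += r @ r
    sign, logdetM = np.linalg.slogdet(M)
    return beta, C, quad, logdetV, logdetM


def restricted_loglik(theta, blocks):
    """REML log-likelihood (up to an additive constant) at variance parameters theta."""
    if np.any(np.asarray(theta) < 0):
        return -np.inf
    try:
        _, _, quad, logdetV, logdetM = _gls(blocks, np.asarray(theta, float))
    except np.linalg.LinAlgError:
        return -np.inf
    return -0.5 * (logdetV + logdetM + quad)


def _satterthwaite_all(blocks, theta):
    """Denominator df for every fixed effect at the REML estimate theta.

    The observed information of the restricted log-likelihood is shared
    across coefficients; only the gradient of each Var(beta_j) differs.
    """
    theta = np.asarray(theta, float)
    k = theta.size
    p = blocks[0][0].shape[1]
    h = 1e-3 * np.maximum(theta, 1e-4)

    def cdiag(t):
        return np.diag(_gls(blocks, t)[1]).copy()

    grads = np.zeros((p, k))
    for i in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h[i]
        tm[i] = max(tm[i] - h[i], 0.0)
        grads[:, i] = (cdiag(tp) - cdiag(tm)) / (tp[i] - tm[i])

    H = np.zeros((k, k))
    f0 = restricted_loglik(theta, blocks)
    for i in range(k):
        for l in range(i, k):
            if i == l:
                tp, tm = theta.copy(), theta.copy()
                tp[i] += h[i]
                tm[i] = max(tm[i] - h[i], 0.0)
                fp = restricted_loglik(tp, blocks)
                fm = restricted_loglik(tm, blocks)
                # non-uniform step second difference
                a, b = tp[i] - theta[i], theta[i] - tm[i]
                H[i, i] = 2.0 * (b * fp - (a + b) * f0 + a * fm) / (a * b * (a + b))
            else:
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[i] += h[i]; tpp[l] += h[l]
                tpm[i] += h[i]; tpm[l] = max(tpm[l] - h[l], 0.0)
                tmp[i] = max(tmp[i] - h[i], 0.0); tmp[l] += h[l]
                tmm[i] = max(tmm[i] - h[i], 0.0); tmm[l] = max(tmm[l] - h[l], 0.0)
                di = tpp[i] - tmp[i]
                dl = tpp[l] - tpm[l]
                H[i, l] = H[l, i] = (
                    restricted_loglik(tpp, blocks)
                    - restricted_loglik(tpm, blocks)
                    - restricted_loglik(tmp, blocks)
                    + restricted_loglik(tmm, blocks)
                ) / (di * dl)
    try:
        A = np.linalg.pinv(-H)
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)
    cjj = cdiag(theta)
    out = np.full(p, np.nan)
    for j in range(p):
        denom = grads[j] @ A @ grads[j]
        if denom > 0:
            out[j] = 2.0 * cjj[j] ** 2 / denom
    return out


def fit_mixed(
    data: pd.DataFrame,
    response: str,
    fixed: list,
    random_slopes: list,
    group: str,
    reml: bool = True,
    dof: str = "satterthwaite",
) -> MixedFit:
    """Fit a mixed model with random intercept plus independent random slopes.

    Parameters
    ----------
    fixed : list of term specs; each is a tuple of column names whose
        product forms the regressor (the empty tuple is the intercept).
    random_slopes : column names whose per-group slopes get independent
        random deviations (the random intercept is always included).
    dof : "satterthwaite" or "residual" (cheap fallback used by bulk
        simulation loops; denominator df = n_obs - n_fixed).

    A non-positive-definite or non-converged fit triggers one refit with
    the random slopes dropped (random intercept only); the result is then
    flagged ``simplified``.
    """
    import statsmodels.formula.api as smf

    d = pd.DataFrame({"y": np.asarray(data[response], float)})
    names = []
    for term in fixed:
        if not term:
            continue
        name = ":".join(term)
        col = np.ones(len(data))
        for c in term:
            col = col * np.asarray(data[c], float)
        d[f"f{len(names)}"] = col
        names.append(name)
    slope_cols = {}
    for i, s in enumerate(random_slopes):
        d[f"s{i}"] = np.asarray(data[s], float)
        slope_cols[f"s{i}"] = s
    d["grp"] = np.asarray(data[group])

    fixed_rhs = " + ".join(f"f{i}" for i in range(len(names))) or "1"

    def _run(slopes: dict):
        vc = {k: f"0 + {k}" for k in slopes}
        model = smf.mixedlm(
            f"y ~ {fixed_rhs}", d, groups=d["grp"], re_formula="1", vc_formula=vc or None
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=reml, method="lbfgs", maxiter=200)
        return res

    simplified = False
    res = _run(slope_cols)
    ok = res.converged and np.all(np.isfinite(res.bse_fe))
    if not ok:
        warnings.warn(
            "mixed model did not converge with the full random structure; "
            "refitting with a random intercept only",
            stacklevel=2,
        )
        simplified = True
        slope_cols = {}
        res = _run(slope_cols)

    s2 = float(res.scale)
    var_int = float(np.asarray(res.cov_re)[0, 0])
    vcomp = [float(v) for v in np.atleast_1d(res.vcomp)] if len(slope_cols) else []
    theta = np.array([s2, var_int] + vcomp)
    singular = bool(np.any(theta[1:] < 1e-8 * max(s2, 1e-12)))

    # rebuild designs for the GLS covariance and Satterthwaite layer
    X = np.column_stack(
        [np.ones(len(d))] + [np.asarray(d[f"f{i}"], float) for i in range(len(names))]
    )
    Z = np.column_stack(
        [np.ones(len(d))] + [np.asarray(d[k], float) for k in slope_cols]
    )
    blocks = _blocks(X, Z, np.asarray(d["y"], float), d["grp"])
    beta, C, _, _, _ = _gls(blocks, theta)
    se = np.sqrt(np.diag(C))

    n, p = len(d), X.shape[1]
    term_names = ["intercept"] + names
    if dof == "satterthwaite":
        df_den = _satterthwaite_all(blocks, theta)
        df_den = np.where(np.isfinite(df_den), np.clip(df_den, 1.0, n - p), n - p)
    else:
        df_den = np.full(p, float(n - p))
    fstat = (beta / se) ** 2
    pvals = stats.f.sf(fstat, 1.0, df_den)
    tcrit = stats.t.ppf(0.975, df_den)
    terms = pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "ci_low": beta - tcrit * se,
            "ci_high": beta + tcrit * se,
            "fstat": fstat,
            "df_num": 1.0,
            "df_den": df_den,
            "p": pvals,
        },
        index=pd.Index(term_names, name="term"),
    )
    llf = float(res.llf)
    k_params = p + theta.size
    bic = -2.0 * llf + k_params * np.log(n)
    random_variances = {"intercept": var_int}
    random_variances.update({slope_cols[k]: v for k, v in zip(slope_cols, vcomp)})
    return MixedFit(
        terms=terms,
        random_variances=random_variances,
        residual_var=s2,
        loglike=llf,
        bic=bic,
        n_obs=n,
        n_groups=int(d["grp"].nunique()),
        reml=reml,
        singular=singular,
        simplified=simplified,
    )
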