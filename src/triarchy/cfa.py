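"""Confirmatory factor analysis of the candidate executive-function models.

Twelve latent-variable models are compared on the 9-task score table: five
correlated-factors models (the full three-factor "I+U+S" model, the three
two-factor mergers "S/I+U", "U/I+S", "S/U+I", and the one-factor "G" model)
and seven bifactor models in which a common factor loads on all nine tasks
and orthogonal domain-specific factors load on task triads ("C+I+U+S" down
to "C+I", "C+S", "C+U").

Estimation is maximum likelihood on the multivariate-normal model
Sigma(theta) = Lambda Phi Lambda' + Theta with factor variances fixed at 1.
With incomplete rows the likelihood is full-information (FIML): rows are
grouped by missingness pattern and each pattern contributes the likelihood
of its observed sub-vector.  chi^2 = 2(l_sat - l_model) against a saturated
model (EM-estimated under missingness); CFI/RMSEA/SRMR/AIC/BIC and nested
chi^2-difference tests follow the conventional definitions; factor scores
use the regression (Thurstone) method per missingness pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

INHIBITING = ["antisaccade", "ssrt", "stroop"]
UPDATING = ["keep_track", "letter_3back", "spatial_2back"]
SHIFTING = ["number_letter", "color_shape", "category_switch"]
INDICATORS = INHIBITING + UPDATING + SHIFTING


@dataclass
class ModelSpec:
    """Loading pattern and factor covariance structure of one candidate model.

    `factors` maps each factor name to the indicators it loads on.
    `orthogonal` factors (bifactor specs) have an identity factor-correlation
    matrix; otherwise all pairwise factor correlations are free.
    """

    name: str
    factors: dict[str, list[str]]
    orthogonal: bool = False
    indicators: list[str] = field(default_factory=lambda: list(INDICATORS))

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def n_free_loadings(self) -> int:
        return sum(len(v) for v in self.factors.values())

    @property
    def n_free_correlations(self) -> int:
        if self.orthogonal:
            return 0
        k = self.n_factors
        return k * (k - 1) // 2

    def loading_pattern(self) -> np.ndarray:
        """Boolean p x k matrix of free loadings."""
        p = len(self.indicators)
        pat = np.zeros((p, self.n_factors), dtype=bool)
        for f, (name, inds) in enumerate(self.factors.items()):
            for ind in inds:
                pat[self.indicators.index(ind), f] = True
        return pat


def model_library() -> dict[str, ModelSpec]:
    """The 12 candidate models, keyed by their conventional names."""
    lib = {}

    def corr(name, factors):
        lib[name] = ModelSpec(name=name, factors=factors, orthogonal=False)

    def bifactor(name, specifics):
        factors = {"C": list(INDICATORS)}
        factors.update(specifics)
        lib[name] = ModelSpec(name=name, factors=factors, orthogonal=True)

    corr("I+U+S", {"I": INHIBITING, "U": UPDATING, "S": SHIFTING})
    corr("S/I+U", {"S/I": SHIFTING + INHIBITING, "U": UPDATING})
    corr("U/I+S", {"U/I": UPDATING + INHIBITING, "S": SHIFTING})
    corr("S/U+I", {"S/U": SHIFTING + UPDATING, "I": INHIBITING})
    corr("G", {"G": list(INDICATORS)})
    bifactor("C+I+U+S", {"I": INHIBITING, "U": UPDATING, "S": SHIFTING})
    bifactor("C+I+S", {"I": INHIBITING, "S": SHIFTING})
    bifactor("C+I+U", {"I": INHIBITING, "U": UPDATING})
    bifactor("C+U+S", {"U": UPDATING, "S": SHIFTING})
    bifactor("C+I", {"I": INHIBITING})
    bifactor("C+S", {"S": SHIFTING})
    bifactor("C+U", {"U": UPDATING})
    return lib


def model_degrees_of_freedom(spec: ModelSpec) -> int:
    """df = p(p+1)/2 - q; q = free loadings + residual variances + factor correlations."""
    p = len(spec.indicators)
    moments = p * (p + 1) // 2
    q = spec.n_free_loadings + p + spec.n_free_correlations
    df = moments - q
    if df < 0:
        raise ValueError(f"model {spec.name} is not identified (df={df})")
    return df


# ---------------------------------------------------------------------------
# likelihood machinery


def _pattern_stats(X: np.ndarray):
    """Group rows by missingness pattern; per-pattern (obs idx, n, mean, scatter)."""
    obs = ~np.isnan(X)
    keys = obs @ (1 << np.arange(X.shape[1]))
    out = []
    for key in np.unique(keys):
        rows = X[keys == key]
        idx = np.flatnonzero(obs[np.argmax(keys == key)])
        if idx.size == 0:
            continue
        sub = rows[:, idx]
        m = sub.mean(axis=0)
        d = sub - m
        S = d.T @ d / len(sub)
        out.append((idx, len(sub), m, S))
    return out


def _mvn_loglik_patterns(patterns, mu: np.ndarray, sigma: np.ndarray) -> float:
    ll = 0.0
    c = np.log(2 * np.pi)
    for idx, n_g, m_g, S_g in patterns:
        sub = sigma[np.ix_(idx, idx)]
        sign, logdet = np.linalg.slogdet(sub)
        if sign <= 0:
            return -np.inf
        inv = np.linalg.inv(sub)
        diff = m_g - mu[idx]
        ll += -0.5 * n_g * (len(idx) * c + logdet + np.trace(S_g @ inv) + diff @ inv @ diff)
    return ll


def saturated_loglik(X: np.ndarray, tol: float = 1e-8, max_iter: int = 500):
    """ML (FIML) fit of an unrestricted MVN: returns (logL, mu, Sigma).

    Complete data has the closed form (sample mean, ML covariance); with
    missing entries an EM algorithm for the multivariate normal is run to
    convergence in the observed-data log-likelihood.
    """
    n, p = X.shape
    complete = ~np.isnan(X).any()
    if complete:
        mu = X.mean(axis=0)
        S = np.cov(X, rowvar=False, ddof=0)
        sign, logdet = np.linalg.slogdet(S)
        ll = -0.5 * n * (p * np.log(2 * np.pi) + logdet + p)
        return ll, mu, S

    patterns = _pattern_stats(X)
    # EM initialisation from available-case moments
    mu = np.nanmean(X, axis=0)
    S = np.diag(np.nanvar(X, axis=0))
    ll_old = -np.inf
    for _ in range(max_iter):
        # E-step: accumulate expected sufficient statistics
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        obs_mask = ~np.isnan(X)
        keys = obs_mask @ (1 << np.arange(p))
        for key in np.unique(keys):
            rows = X[keys == key]
            o = np.flatnonzero(obs_mask[np.argmax(keys == key)])
            m = np.setdiff1d(np.arange(p), o)
            n_g = len(rows)
            if o.size == 0:
                sum_x += n_g * mu
                sum_xx += n_g * (S + np.outer(mu, mu))
                continue
            xo = rows[:, o]
            if m.size == 0:
                sum_x[o] += xo.sum(axis=0)
                sum_xx[np.ix_(o, o)] += xo.T @ xo
                continue
            Soo_inv = np.linalg.inv(S[np.ix_(o, o)])
            reg = S[np.ix_(m, o)] @ Soo_inv
            xm = mu[m] + (xo - mu[o]) @ reg.T
            cond = S[np.ix_(m, m)] - reg @ S[np.ix_(o, m)]
            full = np.empty((n_g, p))
            full[:, o] = xo
            full[:, m] = xm
            sum_x += full.sum(axis=0)
            sum_xx += full.T @ full
            sum_xx[np.ix_(m, m)] += n_g * cond
        mu = sum_x / n
        S = sum_xx / n - np.outer(mu, mu)
        ll = _mvn_loglik_patterns(patterns, mu, S)
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return ll, mu, S


def independence_loglik(X: np.ndarray) -> tuple[float, int]:
    """FIML logL and parameter count of the independence (diagonal Sigma) model.

    The likelihood factorizes over variables, so each variable's ML solution
    is the mean/variance of its observed entries.
    """
    ll = 0.0
    p = X.shape[1]
    for j in range(p):
        x = X[:, j]
        x = x[~np.isnan(x)]
        v = x.var(ddof=0)
        ll += -0.5 * len(x) * (np.log(2 * np.pi) + np.log(v) + 1.0)
    return ll, p  # p free variances (means saturated, excluded from q)


@dataclass
class CFAFit:
    spec: ModelSpec
    loadings: pd.DataFrame  # p x k, zeros where fixed
    factor_corr: pd.DataFrame  # k x k
    residual_var: pd.Series
    mu: np.ndarray
    loglik: float
    loglik_saturated: float
    chisq: float
    df: int
    n_used: int
    n_params: int
    converged: bool
    missing: str
    loading_se: pd.DataFrame | None = None
    loading_p: pd.DataFrame | None = None
    warnings: list = field(default_factory=list)

    def implied_sigma(self) -> np.ndarray:
        L = self.loadings.to_numpy()
        P = self.factor_corr.to_numpy()
        return L @ P @ L.T + np.diag(self.residual_var.to_numpy())


def _unpack(theta, spec: ModelSpec, pat: np.ndarray, estimate_mu: bool, p: int):
    nl = spec.n_free_loadings
    L = np.zeros(pat.shape)
    L[pat] = theta[:nl]
    th = np.exp(theta[nl : nl + p])
    k = spec.n_factors
    P = np.eye(k)
    pos = nl + p
    if not spec.orthogonal and k > 1:
        iu = np.triu_indices(k, 1)
        vals = np.tanh(theta[pos : pos + len(iu[0])])
        P[iu] = vals
        P[(iu[1], iu[0])] = vals
        pos += len(iu[0])
    mu = theta[pos : pos + p] if estimate_mu else None
    return L, P, th, mu


def fit_cfa(
    scores: pd.DataFrame,
    spec: ModelSpec,
    missing: str = "fiml",
    max_iter: int = 500,
    tol: float = 1e-8,
    compute_se: bool = True,
) -> CFAFit:
    """Fit one candidate model by (FI)ML.

    `missing` is "fiml" (use all rows with >= 1 observed indicator) or
    "listwise" (complete cases only).  Parameters are optimized on an
    unconstrained scale (log residual variances, atanh factor correlations)
    by L-BFGS; standard errors come from the inverse numerical Hessian.
    """
    X = scores[spec.indicators].to_numpy(float)
    if missing == "listwise":
        X = X[~np.isnan(X).any(axis=1)]
    elif missing == "fiml":
        X = X[~np.isnan(X).all(axis=1)]
    else:
        raise ValueError(f"unknown missing-data handling: {missing!r}")
    n, p = X.shape
    if n < p:
        raise ValueError("too few usable rows")
    pat = spec.loading_pattern()
    has_missing = bool(np.isnan(X).any())

    ll_sat, mu_sat, S_sat = saturated_loglik(X)

    if has_missing:
        patterns = _pattern_stats(X)

        def negll(theta):
            L, P, th, mu = _unpack(theta, spec, pat, True, p)
            sigma = L @ P @ L.T + np.diag(th)
            ll = _mvn_loglik_patterns(patterns, mu, sigma)
            return np.inf if not np.isfinite(ll) else -ll

    else:
        xbar = X.mean(axis=0)
        S = np.cov(X, rowvar=False, ddof=0)
        const = p * np.log(2 * np.pi)

        def negll(theta):
            L, P, th, _ = _unpack(theta, spec, pat, False, p)
            sigma = L @ P @ L.T + np.diag(th)
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                return np.inf
            inv = np.linalg.inv(sigma)
            return 0.5 * n * (const + logdet + np.trace(S @ inv))

    # fixed default starts
    nl = spec.n_free_loadings
    col_var = np.nanvar(X, axis=0)
    theta0 = np.concatenate(
        [
            np.full(nl, 0.5),
            np.log(np.maximum(0.5 * col_var, 1e-3)),
            np.full(spec.n_free_correlations, np.arctanh(0.2)),
            np.nanmean(X, axis=0) if has_missing else np.empty(0),
        ]
    )
    # Heywood guard: residual variances bounded below at 1e-6 * column variance
    bounds = (
        [(None, None)] * nl
        + [(np.log(1e-6 * max(v, 1e-12)), None) for v in col_var]
        + [(None, None)] * (len(theta0) - nl - p)
    )
    res = optimize.minimize(
        negll, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": tol},
    )
    warnings = []
    if not res.success:
        warnings.append(f"optimizer: {res.message}")
    L, P, th, mu = _unpack(res.x, spec, pat, has_missing, p)
    if mu is None:
        mu = X.mean(axis=0)
    at_floor = th <= 1.01e-6 * col_var
    if at_floor.any():
        warnings.append(f"Heywood: {int(at_floor.sum())} residual variance(s) at boundary")

    ll_model = -res.fun
    chisq = max(2.0 * (ll_sat - ll_model), 0.0)
    q = spec.n_free_loadings + p + spec.n_free_correlations
    df = p * (p + 1) // 2 - q

    factors = list(spec.factors)
    fit = CFAFit(
        spec=spec,
        loadings=pd.DataFrame(L, index=spec.indicators, columns=factors),
        factor_corr=pd.DataFrame(P, index=factors, columns=factors),
        residual_var=pd.Series(th, index=spec.indicators),
        mu=mu,
        loglik=ll_model,
        loglik_saturated=ll_sat,
        chisq=chisq,
        df=df,
        n_used=n,
        n_params=q,
        converged=bool(res.success),
        missing=missing,
        warnings=warnings,
    )
    if compute_se:
        se = _loading_se(negll, res.x, nl)
        se_mat = np.full(pat.shape, np.nan)
        se_mat[pat] = se
        z = np.where(se_mat > 0, L / se_mat, np.nan)
        fit.loading_se = pd.DataFrame(se_mat, index=spec.indicators, columns=factors)
        fit.loading_p = pd.DataFrame(
            2 * stats.norm.sf(np.abs(z)), index=spec.indicators, columns=factors
        )
    return fit


def _loading_se(negll, theta_hat, n_loadings, step=1e-4):
    """Wald SEs of the free loadings from the inverse numerical Hessian."""
    k = len(theta_hat)
    H = np.zeros((k, k))
    f0 = negll(theta_hat)
    steps = step * np.maximum(1.0, np.abs(theta_hat))
    fp = np.empty(k)
    fm = np.empty(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = steps[i]
        fp[i] = negll(theta_hat + e)
        fm[i] = negll(theta_hat - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / steps[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = negll(theta_hat + ei + ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / (steps[i] * steps[j])
    try:
        cov = np.linalg.inv(H)
        var = np.clip(np.diag(cov)[:n_loadings], 0, None)
        return np.sqrt(var)
    except np.linalg.LinAlgError:
        return np.full(n_loadings, np.nan)


@dataclass
class FitIndices:
    cfi: float
    rmsea: float | None
    srmr: float
    aic: float
    bic: float
    chisq: float
    df: int
    chisq_baseline: float
    df_baseline: int


def fit_indices(fit: CFAFit, scores: pd.DataFrame) -> FitIndices:
    """CFI, RMSEA, SRMR, AIC, BIC for a fitted model.

    The baseline is the independence model (diagonal Sigma, free variances)
    under the same missing-data handling; SRMR compares sample (saturated
    under FIML) and implied correlations over the off-diagonal lower
    triangle.
    """
    X = scores[fit.spec.indicators].to_numpy(float)
    if fit.missing == "listwise":
        X = X[~np.isnan(X).any(axis=1)]
    else:
        X = X[~np.isnan(X).all(axis=1)]
    n = fit.n_used
    ll_base, q_base = independence_loglik(X)
    chisq_b = max(2.0 * (fit.loglik_saturated - ll_base), 0.0)
    p = len(fit.spec.indicators)
    df_b = p * (p + 1) // 2 - p

    num = max(fit.chisq - fit.df, 0.0)
    den = max(chisq_b - df_b, num)
    cfi = 1.0 - num / den if den > 0 else 1.0
    rmsea = float(np.sqrt(num / (fit.df * n))) if fit.df > 0 else None

    _, _, S_sat = saturated_loglik(X)
    sd = np.sqrt(np.diag(S_sat))
    R_sample = S_sat / np.outer(sd, sd)
    sig = fit.implied_sigma()
    sdi = np.sqrt(np.diag(sig))
    R_implied = sig / np.outer(sdi, sdi)
    il = np.tril_indices(p, -1)
    srmr = float(np.sqrt(np.mean((R_sample[il] - R_implied[il]) ** 2)))

    aic = -2 * fit.loglik + 2 * fit.n_params
    bic = -2 * fit.loglik + fit.n_params * np.log(n)
    return FitIndices(
        cfi=float(cfi), rmsea=rmsea, srmr=srmr, aic=float(aic), bic=float(bic),
        chisq=fit.chisq, df=fit.df, chisq_baseline=chisq_b, df_baseline=df_b,
    )


def chisq_diff_test(fit_restricted: CFAFit, fit_full: CFAFit):
    """Nested chi^2-difference test: (delta chi^2, delta df, one-sided p)."""
    d_chi = fit_restricted.chisq - fit_full.chisq
    d_df = fit_restricted.df - fit_full.df
    warn = None
    if d_chi < 0:
        warn = "negative chi^2 difference treated as 0 (estimation noise)"
        d_chi = 0.0
    if d_df < 0:
        raise ValueError("models are not nested (delta df < 0)")
    if d_df == 0:
        p = 1.0 if d_chi < 1e-8 else 0.0  # identical structures
    else:
        p = float(stats.chi2.sf(d_chi, d_df))
    return d_chi, d_df, p, warn


def factor_scores(fit: CFAFit, scores: pd.DataFrame) -> pd.DataFrame:
    """Regression (Thurstone) factor scores, per missingness pattern.

    F_hat = Phi Lambda' Sigma^-1 (x - mu) evaluated on each subject's
    observed sub-vector.  Subjects with no observed indicators get missing
    scores.
    """
    X = scores[fit.spec.indicators].to_numpy(float)
    L = fit.loadings.to_numpy()
    P = fit.factor_corr.to_numpy()
    sigma = fit.implied_sigma()
    out = np.full((len(X), fit.spec.n_factors), np.nan)
    obs_mask = ~np.isnan(X)
    keys = obs_mask @ (1 << np.arange(X.shape[1]))
    for key in np.unique(keys):
        sel = keys == key
        idx = np.flatnonzero(obs_mask[np.argmax(sel)])
        if idx.size == 0:
            continue
        W = P @ L[idx].T @ np.linalg.inv(sigma[np.ix_(idx, idx)])
        out[sel] = (X[np.ix_(sel, idx)] - fit.mu[idx]) @ W.T
    return pd.DataFrame(out, index=scores.index, columns=list(fit.spec.factors))


def pairwise_correlations(scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation table (reporting utility)."""
    return scores.corr(method="pearson", min_periods=2)
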