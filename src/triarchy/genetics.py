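"""Genotype QC, GRM construction, ancestry PCA, and REML variance components.

The genetic analyses follow the GREML tradition: a genetic relationship
matrix (GRM) over standardized SNP dosages enters a linear mixed model
y = Xb + g + e with g ~ N(0, sigma_g^2 A), giving SNP heritability
h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).  A bivariate model with a shared
GRM yields the genetic correlation r_g; a joint two-GRM model over a SNP
set and its complement yields partitioned heritability and enrichment folds.

Estimation is AI-REML (EM warm-up iterations followed by average-information
updates).  Single-GRM and bivariate models exploit the GRM eigenbasis, where
every iteration is O(n); the general multi-GRM model uses dense solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

VAR_FLOOR_FRAC = 1e-6  # variance components clamped at this fraction of Var(y)


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Dosage matrix (n subjects x m SNPs, {0,1,2} with NaN missing) + metadata."""

    dosages: np.ndarray
    variants: pd.DataFrame  # columns: snp, chrom, bp, a1, a2
    subjects: list

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[np.asarray(idx)].reset_index(drop=True),
            subjects=list(self.subjects),
        )

    def subset_subjects(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[np.asarray(idx)],
            variants=self.variants.copy(),
            subjects=[self.subjects[i] for i in np.asarray(idx)],
        )


@dataclass
class QCReport:
    n_snps_in: int
    n_removed_maf: int
    n_removed_miss: int
    n_removed_hwe: int
    n_subjects_removed: int
    kept_snps: np.ndarray
    kept_subjects: np.ndarray


def allele_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Per-SNP frequency of the counted allele, ignoring missing dosages."""
    return np.nanmean(dosages, axis=0) / 2.0


def hwe_chisq_p(dosages: np.ndarray) -> np.ndarray:
    """1-df chi-square Hardy-Weinberg test per SNP on genotype counts."""
    m = dosages.shape[1]
    pvals = np.ones(m)
    for j in range(m):
        x = dosages[:, j]
        x = x[~np.isnan(x)]
        n = len(x)
        if n == 0:
            continue
        counts = np.array([(x == 0).sum(), (x == 1).sum(), (x == 2).sum()], float)
        p = (2 * counts[2] + counts[1]) / (2 * n)
        if p in (0.0, 1.0):
            continue
        exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        chi2 = float(np.sum((counts - exp) ** 2 / exp))
        pvals[j] = stats.chi2.sf(chi2, 1)
    return pvals


def qc_genotypes(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
    hwe_p_min: float = 1e-6,
    subject_miss_max: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Standard GWAS QC: drop SNPs by MAF / missingness / HWE, then subjects."""
    X = geno.dosages
    freq = allele_frequencies(X)
    maf = np.minimum(freq, 1 - freq)
    miss = np.isnan(X).mean(axis=0)
    bad_maf = maf < maf_min
    bad_miss = miss > miss_max
    hwe = hwe_chisq_p(X)
    bad_hwe = hwe < hwe_p_min
    keep_snp = ~(bad_maf | bad_miss | bad_hwe)
    if not keep_snp.any():
        raise ValueError("QC removed every SNP")
    sub_miss = np.isnan(X[:, keep_snp]).mean(axis=1)
    keep_subj = sub_miss <= subject_miss_max
    report = QCReport(
        n_snps_in=geno.n_snps,
        n_removed_maf=int(bad_maf.sum()),
        n_removed_miss=int((bad_miss & ~bad_maf).sum()),
        n_removed_hwe=int((bad_hwe & ~bad_maf & ~bad_miss).sum()),
        n_subjects_removed=int((~keep_subj).sum()),
        kept_snps=np.flatnonzero(keep_snp),
        kept_subjects=np.flatnonzero(keep_subj),
    )
    out = geno.subset_snps(report.kept_snps).subset_subjects(report.kept_subjects)
    return out, report


def standardized_dosages(dosages: np.ndarray) -> np.ndarray:
    """(x - 2p)/sqrt(2p(1-p)) with missing dosages mean-imputed; monomorphic SNPs dropped."""
    X = np.asarray(dosages, float).copy()
    p = allele_frequencies(X)
    ok = (p > 0) & (p < 1)
    X = X[:, ok]
    p = p[ok]
    mean = 2 * p
    inds = np.where(np.isnan(X))
    X[inds] = mean[inds[1]]
    return (X - mean) / np.sqrt(2 * p * (1 - p))


def compute_grm(geno: "GenotypeMatrix | np.ndarray") -> np.ndarray:
    """GRM A_jk = (1/m) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2p_i(1-p_i))."""
    dos = geno.dosages if isinstance(geno, GenotypeMatrix) else np.asarray(geno, float)
    W = standardized_dosages(dos)
    m = W.shape[1]
    if m == 0:
        raise ValueError("no polymorphic SNPs")
    return W @ W.T / m


def prune_related(grm: np.ndarray, cutoff: float = 0.05, seed=0) -> np.ndarray:
    """Indices of subjects kept after greedy relatedness pruning.

    While any off-diagonal exceeds the cutoff, one member of the
    most-related pair is removed at random (seeded).
    """
    rng = np.random.default_rng(seed)
    n = grm.shape[0]
    active = np.ones(n, dtype=bool)
    A = grm.copy()
    np.fill_diagonal(A, -np.inf)
    while True:
        sub = np.where(np.outer(active, active), A, -np.inf)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= cutoff:
            break
        active[rng.choice([i, j])] = False
    return np.flatnonzero(active)


def grm_pca(grm: np.ndarray, k: int = 10) -> pd.DataFrame:
    """Top-k ancestry principal components from the GRM eigendecomposition.

    PCs are ordered by descending eigenvalue; each PC's sign is fixed so its
    largest-magnitude entry is positive.
    """
    n = grm.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of subjects")
    vals, vecs = np.linalg.eigh(grm)
    order = np.argsort(vals)[::-1][:k]
    V = vecs[:, order]
    for c in range(k):
        imax = np.argmax(np.abs(V[:, c]))
        if V[imax, c] < 0:
            V[:, c] = -V[:, c]
    return pd.DataFrame(V, columns=[f"PC{i+1}" for i in range(k)])


# ---------------------------------------------------------------------------
# REML


@dataclass
class VCResult:
    variance_components: np.ndarray  # genetic component(s) then residual
    se_components: np.ndarray
    h2: float
    h2_se: float
    loglik: float
    loglik_history: list
    converged: bool
    lrt_p: float | None = None
    rg: float | None = None
    rg_se: float | None = None
    h2_per_grm: np.ndarray | None = None
    h2_per_grm_se: np.ndarray | None = None
    warnings: list = field(default_factory=list)


def _design(n: int, covariates) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effects design")
    return X


def reml_loglik_null(y: np.ndarray, X: np.ndarray) -> float:
    """Restricted logL of the covariates-only (no genetic component) model."""
    n, c = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    s2 = rss / (n - c)
    _, logdet_xx = np.linalg.slogdet(X.T @ X / s2)
    return -0.5 * (n * np.log(s2) + logdet_xx + rss / s2)


def reml_loglik_dense(y, A_list, X, s) -> float:
    """Restricted log-likelihood at variance components s (residual last).

    Convention: -0.5 [ log|V| + log|X'V^-1 X| + y'Py ], constants dropped.
    """
    n = len(y)
    V = s[-1] * np.eye(n)
    for k, A in enumerate(A_list):
        V += s[k] * A
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vinv_y = np.linalg.solve(V, y)
    Vinv_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vinv_X
    _, logdet_x = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vinv_y)
    yPy = float(y @ Vinv_y - (X.T @ Vinv_y) @ beta)
    return -0.5 * (logdet_v + logdet_x + yPy)


def _ai_reml_dense(y, A_list, X, max_iter=100, tol=1e-6, n_em=3):
    """Average-information REML for V = sum_k s_k A_k + s_e I (dense solves).

    EM warm-up iterations are followed by AI (quasi-Newton) updates with
    step-halving back toward the last accepted point whenever a proposal
    makes V singular or decreases the restricted likelihood.
    """
    n = len(y)
    n_comp = len(A_list) + 1
    vary = float(np.var(y))
    floor = VAR_FLOOR_FRAC * vary
    s = np.full(n_comp, vary / n_comp)
    s_acc = s.copy()
    ll_acc = None
    history: list[float] = []
    converged = False
    AIinv = np.eye(n_comp)
    it = 0
    while it < max_iter:
        it += 1
        V = s[-1] * np.eye(n)
        for k, A in enumerate(A_list):
            V += s[k] * A
        try:
            Vinv = np.linalg.inv(V)
            ok = np.isfinite(Vinv).all()
        except np.linalg.LinAlgError:
            ok = False
        if not ok:
            s = 0.5 * (s + s_acc)
            continue
        VX = Vinv @ X
        XtViX_inv = np.linalg.inv(X.T @ VX)
        P = Vinv - VX @ XtViX_inv @ VX.T
        Py = P @ y
        _, logdet_v = np.linalg.slogdet(V)
        _, logdet_x = np.linalg.slogdet(X.T @ VX)
        ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
        if ll_acc is not None and ll < ll_acc - 1e-8 and len(history) > n_em:
            s = 0.5 * (s + s_acc)
            continue
        if ll_acc is not None and abs(ll - ll_acc) < tol:
            history.append(ll)
            converged = True
            break
        history.append(ll)
        ll_acc = ll
        s_acc = s.copy()
        APy = [A @ Py for A in A_list] + [Py]
        tr_PA = [float(np.sum(P * A)) for A in A_list] + [float(np.trace(P))]
        grad_em = np.array([(Py @ APy[k] - tr_PA[k]) / n for k in range(n_comp)])
        if len(history) <= n_em:
            s_new = s + s**2 * grad_em
        else:
            PAPy = [P @ v for v in APy]
            AI = 0.5 * np.array([[APy[j] @ PAPy[k] for k in range(n_comp)] for j in range(n_comp)])
            grad = np.array([-0.5 * (tr_PA[k] - Py @ APy[k]) for k in range(n_comp)])
            try:
                AIinv = np.linalg.inv(AI)
                s_new = s + AIinv @ grad
            except np.linalg.LinAlgError:
                s_new = s + s**2 * grad_em
        s = np.maximum(s_new, floor)
    se = np.sqrt(np.clip(np.diag(AIinv), 0, None))
    if not history:
        raise np.linalg.LinAlgError("REML could not evaluate the likelihood")
    return s_acc, se, AIinv, history, converged


def _ai_reml_eigen(d, yt, Xt, max_iter=100, tol=1e-6, n_em=3):
    """AI-REML for a single GRM in its eigenbasis (V diagonal, O(n)/iteration)."""
    n = len(yt)
    vary = float(np.var(yt))
    floor = VAR_FLOOR_FRAC * vary
    s = np.array([vary / 2, vary / 2])
    history: list[float] = []
    converged = False
    AIinv = np.eye(2)
    ones = np.ones(n)
    for it in range(max_iter):
        v = s[0] * d + s[1]
        w = 1.0 / v
        XtW = Xt * w[:, None]
        XtViX = Xt.T @ XtW
        XtViX_inv = np.linalg.inv(XtViX)
        beta = XtViX_inv @ (XtW.T @ yt)
        resid = yt - Xt @ beta
        Py = w * resid
        _, logdet_x = np.linalg.slogdet(XtViX)
        ll = -0.5 * (float(np.sum(np.log(v))) + logdet_x + float(resid @ Py))
        if history and abs(ll - history[-1]) < tol:
            history.append(ll)
            converged = True
            break
        history.append(ll)

        def trace_PA(dd):
            M = XtW.T @ (XtW * dd[:, None])
            return float(np.sum(dd * w) - np.trace(XtViX_inv @ M))

        def P_mul(z):
            return w * z - XtW @ (XtViX_inv @ (XtW.T @ z))

        APy = [d * Py, Py]
        tr_PA = [trace_PA(d), trace_PA(ones)]
        grad_em = np.array([(Py @ APy[k] - tr_PA[k]) / n for k in range(2)])
        if it < n_em:
            s_new = s + s**2 * grad_em
        else:
            PAPy = [P_mul(u) for u in APy]
            AI = 0.5 * np.array([[APy[j] @ PAPy[k] for k in range(2)] for j in range(2)])
            grad = np.array([-0.5 * (tr_PA[k] - Py @ APy[k]) for k in range(2)])
            try:
                AIinv = np.linalg.inv(AI)
                s_new = s + AIinv @ grad
            except np.linalg.LinAlgError:
                s_new = s + s**2 * grad_em
        s = np.maximum(s_new, floor)
    se = np.sqrt(np.clip(np.diag(AIinv), 0, None))
    return s, se, AIinv, history, converged


def _h2_delta(s, cov, idx):
    total = float(np.sum(s))
    h2 = float(s[idx] / total)
    g = np.full(len(s), -s[idx] / total**2)
    g[idx] += 1.0 / total
    se = float(np.sqrt(max(g @ cov @ g, 0.0)))
    return h2, se


def reml_variance_components(
    y,
    grms,
    covariates=None,
    max_iter: int = 100,
    tol: float = 1e-6,
    eigen=None,
) -> VCResult:
    """AI-REML variance components for one trait and one or more GRMs.

    Returns per-GRM heritabilities and the total, SEs from the inverse AI
    matrix (delta method for ratios), and — for single-GRM models — an LRT
    p-value against the no-genetic-component model using the boundary
    mixture 0.5*chi2_0 + 0.5*chi2_1.

    ``eigen=(values, vectors)`` may pass a precomputed eigendecomposition of
    a single GRM to amortize repeated fits on the same relatedness structure.
    """
    if isinstance(grms, np.ndarray) and grms.ndim == 2:
        grms = [grms]
    grms = list(grms)
    y = np.asarray(y, float)
    n = len(y)
    X = _design(n, covariates)
    if len(grms) == 1:
        if eigen is None:
            d, U = np.linalg.eigh(grms[0])
        else:
            d, U = eigen
        yt = U.T @ y
        Xt = U.T @ X
        s, se, cov, history, converged = _ai_reml_eigen(d, yt, Xt, max_iter, tol)
    else:
        s, se, cov, history, converged = _ai_reml_dense(y, grms, X, max_iter, tol)
    n_g = len(s) - 1
    h2_per = np.empty(n_g)
    h2_se_per = np.empty(n_g)
    for k in range(n_g):
        h2_per[k], h2_se_per[k] = _h2_delta(s, cov, k)
    total = float(np.sum(s))
    h2 = float(np.sum(s[:-1]) / total)
    g = np.full(len(s), -np.sum(s[:-1]) / total**2)
    g[:-1] += 1.0 / total
    h2_se = float(np.sqrt(max(g @ cov @ g, 0.0)))

    lrt_p = None
    if len(grms) == 1:
        # LRT needs matching constants: evaluate both under the dense convention
        ll_alt = history[-1]
        v = s[0] * _eig_d(grms[0], eigen) + s[1]
        # recompute null on the same scale
        ll_null = _reml_loglik_null_matched(y, X)
        lrt = max(2.0 * (ll_alt - ll_null), 0.0)
        lrt_p = float(0.5 * stats.chi2.sf(lrt, 1)) if lrt > 0 else 1.0
    return VCResult(
        variance_components=s,
        se_components=se,
        h2=h2,
        h2_se=h2_se,
        loglik=history[-1],
        loglik_history=history,
        converged=converged,
        lrt_p=lrt_p,
        h2_per_grm=h2_per,
        h2_per_grm_se=h2_se_per,
    )


def _eig_d(grm, eigen):
    return eigen[0] if eigen is not None else np.linalg.eigvalsh(grm)


def _reml_loglik_null_matched(y, X):
    """Null REML logL under the same -0.5(log|V|+log|X'V^-1X|+y'Py) convention."""
    n, c = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    s2 = rss / (n - c)
    _, logdet_xx = np.linalg.slogdet(X.T @ X)
    return -0.5 * (n * np.log(s2) + (logdet_xx - c * np.log(s2)) + rss / s2)


# ---------------------------------------------------------------------------
# bivariate REML (shared GRM, 2x2 blocks in the eigenbasis)


def reml_bivariate(y1, y2, grm, covariates=None, eigen=None) -> VCResult:
    """Bivariate GREML: genetic correlation r_g of two traits sharing a GRM.

    The stacked 2n-observation model V = G (x) A + R (x) I block-diagonalizes
    in the GRM eigenbasis into n 2x2 blocks d_i G + R, making each restricted
    likelihood evaluation O(n).  G and R are parameterized with log variances
    and atanh correlations; the likelihood is maximized by quasi-Newton, and
    the r_g standard error comes from the inverse numerical Hessian by the
    delta method.
    """
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    n = len(y1)
    X = _design(n, covariates)
    if eigen is None:
        d, U = np.linalg.eigh(grm)
    else:
        d, U = eigen
    t1 = U.T @ y1
    t2 = U.T @ y2
    Xt = U.T @ X

    def negll(theta):
        g1, g2, e1, e2 = np.exp(theta[[0, 1, 3, 4]])
        rg = np.tanh(theta[2])
        re = np.tanh(theta[5])
        g12 = rg * np.sqrt(g1 * g2)
        e12 = re * np.sqrt(e1 * e2)
        a = d * g1 + e1
        b = d * g12 + e12
        cc = d * g2 + e2
        det = a * cc - b**2
        if np.any(det <= 0) or np.any(a <= 0):
            return np.inf
        ia, ib, ic = cc / det, -b / det, a / det

        def wsum(wgt):
            return Xt.T @ (Xt * wgt[:, None])

        XtViX = np.block([[wsum(ia), wsum(ib)], [wsum(ib), wsum(ic)]])
        r1 = Xt.T @ (ia * t1 + ib * t2)
        r2 = Xt.T @ (ib * t1 + ic * t2)
        XtViy = np.concatenate([r1, r2])
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return np.inf
        yViy = float(t1 @ (ia * t1 + ib * t2) + t2 @ (ib * t1 + ic * t2))
        yPy = yViy - float(XtViy @ beta)
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        return 0.5 * (float(np.sum(np.log(det))) + logdet_x + yPy)

    v1 = float(np.var(y1))
    v2 = float(np.var(y2))
    r0 = float(np.clip(np.corrcoef(y1, y2)[0, 1], -0.9, 0.9))
    theta0 = np.array(
        [np.log(v1 / 2), np.log(v2 / 2), np.arctanh(r0), np.log(v1 / 2), np.log(v2 / 2), np.arctanh(r0)]
    )
    bounds = [(-20.0, 10.0), (-20.0, 10.0), (-6.0, 6.0), (-20.0, 10.0), (-20.0, 10.0), (-6.0, 6.0)]
    res = optimize.minimize(negll, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500})
    th = res.x
    g1, g2, e1, e2 = np.exp(th[[0, 1, 3, 4]])
    rg = float(np.tanh(th[2]))
    warnings = []
    h2_1 = g1 / (g1 + e1)
    h2_2 = g2 / (g2 + e2)
    if min(h2_1, h2_2) < 1e-3:
        warnings.append("a trait's h2 is at the boundary; r_g unstable")
    rg_se = None
    try:
        H = _numeric_hessian(negll, th)
        cov = np.linalg.inv(H)
        rg_se = float(np.sqrt(max(cov[2, 2], 0.0)) * (1 - rg**2))
    except np.linalg.LinAlgError:
        pass
    s = np.array([g1, g2, rg * np.sqrt(g1 * g2), e1, e2])
    return VCResult(
        variance_components=s,
        se_components=np.full(s.shape, np.nan),
        h2=float(h2_1),
        h2_se=np.nan,
        loglik=-float(res.fun),
        loglik_history=[-float(res.fun)],
        converged=bool(res.success),
        rg=rg,
        rg_se=rg_se,
        warnings=warnings,
    )


def _numeric_hessian(f, x, step=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    steps = step * np.maximum(1.0, np.abs(x))
    fp = np.empty(k)
    fm = np.empty(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = steps[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / steps[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = steps[i]
            ej[j] = steps[j]
            H[i, j] = H[j, i] = (f(x + ei + ej) - fp[i] - fp[j] + f0) / (steps[i] * steps[j])
    return H


# ---------------------------------------------------------------------------
# partitioned heritability


@dataclass
class PartitionResult:
    h2_set: float
    h2_set_se: float
    h2_control: float
    h2_total: float
    h2_set_expected: float
    fold: float
    z: float
    p: float
    vc: VCResult
    warnings: list = field(default_factory=list)


def partition_enrichment(y, set_mask, geno, covariates=None) -> PartitionResult:
    """Partitioned-heritability enrichment of a SNP set.

    Two GRMs (set / control complement) enter a joint REML; the enrichment
    fold is h2_set over its expectation h2_total * (|set|/m), with a
    one-sided z-test of h2_set against that expectation.
    """
    dos = geno.dosages if isinstance(geno, GenotypeMatrix) else np.asarray(geno, float)
    set_mask = np.asarray(set_mask, bool)
    m = dos.shape[1]
    n_set = int(set_mask.sum())
    if n_set == 0 or n_set == m:
        raise ValueError("SNP set must be a non-empty proper subset")
    warnings = []
    if n_set < 50:
        warnings.append("fewer than 50 SNPs in the set; GRM_set is unstable")
    A_set = compute_grm(dos[:, set_mask])
    A_ctl = compute_grm(dos[:, ~set_mask])
    vc = reml_variance_components(y, [A_set, A_ctl], covariates=covariates)
    h2_set, h2_set_se = float(vc.h2_per_grm[0]), float(vc.h2_per_grm_se[0])
    h2_ctl = float(vc.h2_per_grm[1])
    h2_total = h2_set + h2_ctl
    expected = h2_total * n_set / m
    fold = h2_set / expected if expected > 0 else np.nan
    z = (h2_set - expected) / h2_set_se if h2_set_se > 0 else np.nan
    p = float(stats.norm.sf(z)) if np.isfinite(z) else np.nan
    return PartitionResult(
        h2_set=h2_set,
        h2_set_se=h2_set_se,
        h2_control=h2_ctl,
        h2_total=h2_total,
        h2_set_expected=float(expected),
        fold=float(fold),
        z=float(z),
        p=p,
        vc=vc,
        warnings=warnings,
    )
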