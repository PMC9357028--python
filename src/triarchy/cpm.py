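"""Connectome-based predictive modelling (CPM) of factor scores.

CPM predicts a behavioral score from functional-connectivity edges with a
cross-validated, threshold-based pipeline: within each training fold, edges
whose partial correlation with the score (controlling for scanner and head
motion) reaches p <= p_thresh are selected; unit-weighted sums of the
positive- and negative-correlated selections summarize each subject; a
linear regression on the two sums predicts held-out subjects.  Prediction
accuracy is the Pearson r between predicted and observed scores over the
concatenated held-out folds, averaged over many random fold splits, with a
permutation test (shuffling the score across subjects) for inference.
Edges selected in nearly every fold x split iteration are the component's
"contributing edges".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _residualize(M: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    """Residualize the columns of M on covariates C (with intercept)."""
    if C is None:
        return M - M.mean(axis=0)
    X = np.column_stack([np.ones(len(M)), C])
    beta, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ beta


def select_edges(
    edges_train: np.ndarray,
    y_train: np.ndarray,
    covariates: np.ndarray | None = None,
    p_thresh: float = 0.05,
):
    """Partial-correlation edge screening on the training set.

    Both the edges and the score are residualized on the covariates, the
    Pearson correlation of the residuals gives the partial r, and a
    two-sided t-test with n-2-q degrees of freedom gives p.  Returns
    (positive mask, negative mask, r, p); zero-variance edges are excluded
    from both masks with p = 1.
    """
    n, n_edges = edges_train.shape
    q = 0 if covariates is None else np.atleast_2d(covariates.T).shape[0]
    E = _residualize(edges_train, covariates)
    yr = _residualize(y_train[:, None], covariates)[:, 0]
    se = E.std(axis=0)
    sy = yr.std()
    ok = (se > 1e-12) & (sy > 1e-12)
    r = np.zeros(n_edges)
    r[ok] = (E[:, ok].T @ yr) / (n * se[ok] * sy)
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    dof = n - 2 - q
    t = r * np.sqrt(dof / (1 - r**2))
    p = np.ones(n_edges)
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), dof)
    sel = ok & (p <= p_thresh)
    return sel & (r > 0), sel & (r < 0), r, p


def summarize_edges(edges: np.ndarray, pos_mask: np.ndarray, neg_mask: np.ndarray):
    """Unit-weighted sums of edge values within each selection mask."""
    return edges[:, pos_mask].sum(axis=1), edges[:, neg_mask].sum(axis=1)


def _zscore(E: np.ndarray) -> np.ndarray:
    sd = E.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return (E - E.mean(axis=0)) / sd


@dataclass
class CPMResult:
    r_per_split: np.ndarray
    mean_r: float
    selection_counts: np.ndarray  # per candidate edge, over folds x splits
    total_iterations: int
    p_permutation: float | None = None
    n_empty_folds: int = 0
    edge_subset: np.ndarray | None = None
    warnings: list = field(default_factory=list)


def run_cpm(
    edges: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    k: int = 10,
    n_splits: int = 100,
    p_thresh: float = 0.05,
    edge_subset: np.ndarray | None = None,
    seed=0,
) -> CPMResult:
    """k-fold cross-validated CPM over `n_splits` random fold assignments.

    Per fold, edges are standardized within the training and test sets
    separately; per split, accuracy is the Pearson r between observed scores
    and the concatenated held-out predictions.  `edge_subset` (indices)
    restricts the candidate edges, e.g. to edges incident to a node set.
    A fold whose screening selects nothing falls back to an intercept-only
    prediction.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float)
    n = len(y)
    if edge_subset is not None:
        cand = edges[:, np.asarray(edge_subset)]
    else:
        cand = edges
    n_edges = cand.shape[1]
    counts = np.zeros(n_edges, dtype=np.int64)
    r_split = np.empty(n_splits)
    n_empty = 0
    for s in range(n_splits):
        order = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[order] = np.arange(n) % k
        yhat = np.empty(n)
        for f in range(k):
            test = fold_of == f
            train = ~test
            E_tr = _zscore(cand[train])
            E_te = _zscore(cand[test])
            pos, neg, _, _ = select_edges(E_tr, y[train], None if covariates is None else covariates[train], p_thresh)
            counts += pos
            counts += neg
            if not pos.any() and not neg.any():
                yhat[test] = y[train].mean()
                n_empty += 1
                continue
            ps_tr, ns_tr = summarize_edges(E_tr, pos, neg)
            ps_te, ns_te = summarize_edges(E_te, pos, neg)
            X_tr = np.column_stack([np.ones(train.sum()), ps_tr, ns_tr])
            beta, *_ = np.linalg.lstsq(X_tr, y[train], rcond=None)
            X_te = np.column_stack([np.ones(test.sum()), ps_te, ns_te])
            yhat[test] = X_te @ beta
        sd = yhat.std()
        r_split[s] = np.corrcoef(yhat, y)[0, 1] if sd > 1e-12 else 0.0
    return CPMResult(
        r_per_split=r_split,
        mean_r=float(r_split.mean()),
        selection_counts=counts,
        total_iterations=k * n_splits,
        n_empty_folds=n_empty,
        edge_subset=None if edge_subset is None else np.asarray(edge_subset),
    )


def cpm_permutation_test(
    edges: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 1000,
    seed=0,
    observed: CPMResult | None = None,
    **cpm_kwargs,
) -> tuple[float, CPMResult, np.ndarray]:
    """One-sided permutation p for CPM accuracy.

    The factor score is shuffled across subjects (covariates stay attached
    to their subjects) and the full cross-validation pipeline is rerun per
    permutation; p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    warn = []
    if n_perm < 100:
        warn.append("n_perm < 100 gives coarse p-value resolution")
    rng = np.random.default_rng(seed)
    if observed is None:
        observed = run_cpm(edges, y, covariates, seed=rng.integers(2**31), **cpm_kwargs)
    null_r = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        res = run_cpm(edges, y_perm, covariates, seed=rng.integers(2**31), **cpm_kwargs)
        null_r[b] = res.mean_r
    p = float((1 + np.sum(null_r >= observed.mean_r)) / (1 + n_perm))
    observed.p_permutation = p
    observed.warnings.extend(warn)
    return p, observed, null_r


def contributing_edges(
    selection_counts: np.ndarray, total_iterations: int, threshold: float = 0.95
) -> np.ndarray:
    """Mask of edges selected in at least `threshold` of all CV iterations."""
    return np.asarray(selection_counts) >= threshold * total_iterations


def fdr_bh(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjustment; NaN p-values are excluded.

    Returns (adjusted p, rejected-at-alpha) aligned with the input, NaN
    where the input was NaN.
    """
    p = np.asarray(p_values, float)
    ok = ~np.isnan(p)
    adj = np.full(p.shape, np.nan)
    rej = np.zeros(p.shape, dtype=bool)
    if ok.any():
        r, a, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        adj[ok] = a
        rej[ok] = r
    return adj, rej
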