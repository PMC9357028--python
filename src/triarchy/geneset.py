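"""GWAS scan, SNP-to-gene mapping, and MAGENTA-style gene-set enrichment.

The gene-set analysis asks whether a candidate set of genes (e.g. genes with
enhanced expression in a brain region) carries more trait association than
chance.  Each gene is scored by the best (minimum) p-value among the SNPs
mapped into its flanked boundary window; scores are corrected for gene-level
confounds (gene length, SNP count) by regressing -log10(best p) on the
confounds and ranking the residuals; enrichment of a candidate set is the
count of its genes above a percentile cutoff of the corrected scores,
referenced to random same-size gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def gwas_scan(y: np.ndarray, dosages: np.ndarray, covariates: np.ndarray | None = None) -> pd.DataFrame:
    """Per-SNP additive association scan: OLS of y on dosage + covariates.

    Returns a frame with beta, SE and the two-sided Wald p per SNP.
    Monomorphic SNPs are skipped (NaN row).  The scan is vectorized by
    residualizing y and all dosage columns on the covariates
    (Frisch-Waugh-Lovell), so each SNP costs O(n).
    """
    y = np.asarray(y, float)
    n = len(y)
    X = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    q = X.shape[1]
    G = np.asarray(dosages, float)
    # mean-impute missing dosages
    col_mean = np.nanmean(G, axis=0)
    inds = np.where(np.isnan(G))
    if inds[0].size:
        G = G.copy()
        G[inds] = col_mean[inds[1]]
    coef_y, *_ = np.linalg.lstsq(X, y, rcond=None)
    ry = y - X @ coef_y
    coef_g, *_ = np.linalg.lstsq(X, G, rcond=None)
    RG = G - X @ coef_g
    ss = np.sum(RG**2, axis=0)
    poly = ss > 1e-12
    beta = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    beta[poly] = (RG[:, poly].T @ ry) / ss[poly]
    dof = n - q - 1
    rss = np.sum(ry**2) - beta[poly] ** 2 * ss[poly]
    se[poly] = np.sqrt(np.maximum(rss / dof, 0.0) / ss[poly])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return pd.DataFrame({"beta": beta, "se": se, "p": p})


def map_snps_to_genes(variants: pd.DataFrame, genes: pd.DataFrame, flank_kb: float = 35.0) -> dict[str, np.ndarray]:
    """Map SNPs into flanked gene windows; multi-assignment allowed.

    `variants` has 1-based bp in columns (chrom, bp); `genes` carries BED
    0-based half-open (chrom, start, end, gene).  A SNP at 1-based position
    b maps to a gene iff start - flank <= b-1 < end + flank in 0-based
    coordinates.  Returns gene -> array of variant row indices; genes with
    no SNPs are absent.
    """
    flank = int(round(flank_kb * 1000))
    out: dict[str, np.ndarray] = {}
    for chrom, gsub in genes.groupby("chrom"):
        vsub = variants[variants["chrom"] == chrom]
        if vsub.empty:
            continue
        pos0 = vsub["bp"].to_numpy() - 1  # to 0-based
        vidx = vsub.index.to_numpy()
        order = np.argsort(pos0)
        pos_sorted = pos0[order]
        for _, g in gsub.iterrows():
            lo = np.searchsorted(pos_sorted, g["start"] - flank, side="left")
            hi = np.searchsorted(pos_sorted, g["end"] + flank, side="left")
            if hi > lo:
                out[g["gene"]] = np.sort(vidx[order[lo:hi]])
    return out


def gene_scores(gwas: pd.DataFrame, mapping: dict[str, np.ndarray], genes: pd.DataFrame) -> pd.DataFrame:
    """Best-SNP gene scores: raw score = min p over the gene's mapped SNPs."""
    if not mapping:
        raise ValueError("empty SNP-to-gene mapping")
    glen = genes.set_index("gene")
    rows = []
    pvals = gwas["p"].to_numpy()
    for gene, idx in mapping.items():
        ps = pvals[idx]
        ps = ps[~np.isnan(ps)]
        if ps.size == 0:
            continue
        rows.append(
            {
                "gene": gene,
                "n_snps": len(idx),
                "raw_score": float(ps.min()),
                "length_kb": float(glen.loc[gene, "end"] - glen.loc[gene, "start"]) / 1000.0,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def correct_gene_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Confound-correct gene scores by OLS on gene length and SNP count.

    -log10(raw score) is regressed on the confounds; the corrected score is
    the residual, with percentile ranks recomputed from it.  Degenerate
    confounds fall back to the raw ranking with a warning column.
    """
    out = table.copy()
    y = -np.log10(np.clip(out["raw_score"].to_numpy(), 1e-300, 1.0))
    C = out[["length_kb", "n_snps"]].to_numpy(float)
    X = np.column_stack([np.ones(len(out)), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        out["corrected_score"] = y
        out["corrected_degenerate"] = True
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        out["corrected_score"] = y - X @ beta
        out["corrected_degenerate"] = False
    out["percentile"] = out["corrected_score"].rank(pct=True) * 100
    return out


@dataclass
class MagentaResult:
    cutoff_percentile: float
    observed: int
    expected: float
    set_size: int
    p_value: float
    null_counts: np.ndarray


def magenta_test(
    candidate_genes,
    corrected: pd.DataFrame,
    cutoff_percentile: float = 75,
    n_perm: int = 10_000,
    seed=0,
    size_matched: bool = False,
) -> MagentaResult:
    """Permutation enrichment of a candidate gene set above a score cutoff.

    The cutoff is the given percentile of all corrected scores; observed is
    the number of candidate genes above it; the null compares against
    `n_perm` random gene sets of identical size drawn from all scored genes
    (optionally size-matched on SNP count by sampling within SNP-count
    deciles).  One-sided p with the +1 correction.
    """
    cand = [g for g in candidate_genes if g in corrected.index]
    if not cand:
        raise ValueError("no candidate gene overlaps the scored genes")
    scores = corrected["corrected_score"].to_numpy()
    thresh = np.percentile(scores, cutoff_percentile)
    above = scores > thresh
    cand_idx = corrected.index.get_indexer(cand)
    observed = int(above[cand_idx].sum())
    k = len(cand)
    expected = k * (1 - cutoff_percentile / 100.0)
    rng = np.random.default_rng(seed)
    n_genes = len(corrected)
    if size_matched:
        deciles = pd.qcut(corrected["n_snps"], 10, labels=False, duplicates="drop").to_numpy()
        cand_bins = deciles[cand_idx]
        pools = {b: np.flatnonzero(deciles == b) for b in np.unique(deciles)}
        null = np.empty(n_perm, dtype=int)
        for i in range(n_perm):
            tot = 0
            for b, cnt in zip(*np.unique(cand_bins, return_counts=True)):
                pick = rng.choice(pools[b], size=cnt, replace=False)
                tot += int(above[pick].sum())
            null[i] = tot
    else:
        null = np.array([int(above[rng.choice(n_genes, k, replace=False)].sum()) for i in range(n_perm)])
    p = float((1 + np.sum(null >= observed)) / (1 + n_perm))
    return MagentaResult(
        cutoff_percentile=float(cutoff_percentile),
        observed=observed,
        expected=float(expected),
        set_size=k,
        p_value=p,
        null_counts=null,
    )


def select_enhanced_genes(expression: pd.DataFrame, target_region: str, top_k: int = 1000) -> list[str]:
    """Top-k genes by expression fold change in a target region.

    Fold change = log(mean expression in the target region) - log(mean over
    all other regions); ties break by gene id.  Expression must be strictly
    positive.
    """
    if target_region not in expression.columns:
        raise ValueError(f"region {target_region!r} not in expression columns")
    if (expression.to_numpy() <= 0).any():
        raise ValueError("expression must be strictly positive for log fold change")
    target = np.log(expression[target_region])
    others = expression.drop(columns=[target_region])
    fold = target - np.log(others.mean(axis=1))
    ranked = fold.sort_values(ascending=False, kind="stable")
    # deterministic tie-break by gene id
    df = pd.DataFrame({"fold": fold})
    df["gene"] = df.index
    df = df.sort_values(["fold", "gene"], ascending=[False, True], kind="stable")
    return list(df.index[: min(top_k, len(df))])
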