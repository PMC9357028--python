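"""Synthetic cohorts with planted gene-brain-behavior ground truth.

The generator emulates the study design the analysis chain expects: nine
task scores driven by a configurable latent factor model with MCAR
missingness; 264-node functional connectomes with a planted set of
informative edges; biallelic SNP genotypes in linkage equilibrium with
additive effects producing target SNP heritability and genetic correlation;
a toy gene annotation whose flanked windows partition the SNPs; gene sets;
a gene x region expression matrix with region-enhanced genes; and a
mediation wiring Z -> M -> Y calibrated so the true proportion of variance
mediated equals a target exactly.

Everything planted is recorded in ``CohortDataset.truth`` so each
downstream estimator can be checked against a closed-form oracle, and the
same seed always reproduces byte-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cfa
from .genetics import GenotypeMatrix
from .mediation import pvm_from_truth
from .overlap import n_edges as edge_count

DEFAULT_COMMON_LOADINGS = {
    "antisaccade": 0.50, "ssrt": 0.45, "stroop": 0.40,
    "keep_track": 0.60, "letter_3back": 0.65, "spatial_2back": 0.55,
    "number_letter": 0.50, "color_shape": 0.55, "category_switch": 0.60,
}
DEFAULT_SHIFTING_LOADINGS = {"number_letter": 0.50, "color_shape": 0.55, "category_switch": 0.45}


@dataclass
class CohortConfig:
    """Study conditions of a synthetic cohort.

    Defaults mirror the desk-scale study: 870 subjects, a true bifactor
    "C+S" latent model, 264-node connectomes with 100 informative edges per
    predictable component at effect size b = 0.5, 5,000 linkage-equilibrium
    SNPs, 500 genes, heritability 0.62 for the common and 0.19 for the
    shifting-specific component, genetic correlation -0.06, and a true
    mediated proportion PVM = 0.19 for the common pathway.
    """

    n_subjects: int = 870
    seed: int = 0
    model_name: str = "C+S"
    loadings: dict = field(default_factory=lambda: {
        "C": dict(DEFAULT_COMMON_LOADINGS), "S": dict(DEFAULT_SHIFTING_LOADINGS),
    })
    factor_corr: dict = field(default_factory=dict)  # (f1,f2) -> rho for correlated models
    missing_rate: float = 0.05
    covariate_effects: dict = field(default_factory=lambda: {"age": 0.02, "sex": 0.1})
    n_nodes: int = 264
    n_informative_edges: int = 100
    edge_effect: float = 0.5  # b, correlation-scale slope of edge on component score
    batch_effect: float = 0.2  # site shift on edges
    fd_effect: float = 0.3  # motion-nuisance slope on edges
    n_snps: int = 5000
    maf_range: tuple = (0.05, 0.5)
    n_causal: int = 100
    target_h2: dict = field(default_factory=lambda: {"C": 0.62, "S": 0.19})
    target_rg: float = -0.06
    target_pvm: float = 0.19
    n_genes: int = 500
    n_regions: int = 8
    enhanced_fraction: float = 0.1
    expression_log_fold: float = 3.0

    def validate(self):
        for name, v in [("missing_rate", self.missing_rate), ("enhanced_fraction", self.enhanced_fraction)]:
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0,1]")
        for t, h2 in self.target_h2.items():
            if not 0 < h2 < 1:
                raise ValueError(f"target_h2[{t}] must lie in (0,1)")
        if not -1 <= self.target_rg <= 1:
            raise ValueError("target_rg must lie in [-1,1]")
        if not 0 <= self.target_pvm <= 1:
            raise ValueError("target_pvm must lie in [0,1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not np.isfinite(self.edge_effect):
            raise ValueError("edge effect must be finite")


# ---------------------------------------------------------------------------
# trials


def simulate_trials(task_kind: str, n_subjects: int, n_trials: int, ability=0.0, seed=0,
                    staircase_step: float = 50.0) -> pd.DataFrame:
    """Trial tables for one task family.

    generic_rt: shifted log-normal RTs whose location falls with ability and
    logistic accuracy rising with ability.  stop_signal: 25% No-go trials
    with a 1-up/1-down staircase on the stop-signal delay converging to ~50%
    stop failure under a race model.  nback: one-third match trials with
    ability-dependent hit and false-alarm rates.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if task_kind not in ("generic_rt", "stop_signal", "nback"):
        raise ValueError(f"unknown task kind: {task_kind!r}")
    rng = np.random.default_rng(seed)
    ability = np.broadcast_to(np.asarray(ability, float), (n_subjects,))
    rows = []
    for s in range(n_subjects):
        a = ability[s]
        if task_kind == "generic_rt":
            rt = 100.0 + rng.lognormal(mean=6.0 - 0.3 * a, sigma=0.35, size=n_trials)
            p_correct = 1.0 / (1.0 + np.exp(-(2.0 + a)))
            correct = rng.random(n_trials) < p_correct
            for t in range(n_trials):
                rows.append((s, task_kind, t, "go", rt[t], bool(correct[t]), np.nan))
        elif task_kind == "stop_signal":
            ssrt_true = 250.0 * np.exp(-0.2 * a)
            ssd = 200.0
            is_stop = rng.random(n_trials) < 0.25
            for t in range(n_trials):
                go_rt = 100.0 + rng.lognormal(mean=6.0 - 0.3 * a, sigma=0.35)
                if not is_stop[t]:
                    correct = rng.random() < 1.0 / (1.0 + np.exp(-(2.0 + a)))
                    rows.append((s, task_kind, t, "go", go_rt, bool(correct), np.nan))
                else:
                    failed = go_rt < ssd + ssrt_true  # go process wins the race
                    rows.append((s, task_kind, t, "nogo", go_rt if failed else np.nan, not failed, ssd))
                    ssd = max(ssd - staircase_step, 0.0) if failed else ssd + staircase_step
        else:  # nback
            is_match = rng.random(n_trials) < 1.0 / 3.0
            p_hit = 1.0 / (1.0 + np.exp(-(0.8 + a)))
            p_fa = 1.0 / (1.0 + np.exp(-(-0.8 - a)))
            for t in range(n_trials):
                rt = 100.0 + rng.lognormal(mean=6.2 - 0.3 * a, sigma=0.35)
                if is_match[t]:
                    rows.append((s, task_kind, t, "match", rt, bool(rng.random() < p_hit), np.nan))
                else:
                    rows.append((s, task_kind, t, "nonmatch", rt, bool(rng.random() >= p_fa), np.nan))
    return pd.DataFrame(rows, columns=["subject", "task", "trial", "condition", "rt_ms", "correct", "ssd_ms"])


# ---------------------------------------------------------------------------
# latent factors and task scores


def _model_matrices(config: CohortConfig):
    spec = cfa.model_library()[config.model_name]
    factors = list(spec.factors)
    p = len(spec.indicators)
    L = np.zeros((p, len(factors)))
    for f, fname in enumerate(factors):
        for ind, lam in config.loadings.get(fname, {}).items():
            L[spec.indicators.index(ind), f] = lam
    k = len(factors)
    Phi = np.eye(k)
    if not spec.orthogonal:
        for (f1, f2), rho in config.factor_corr.items():
            i, j = factors.index(f1), factors.index(f2)
            Phi[i, j] = Phi[j, i] = rho
    Theta = 1.0 - np.diag(L @ Phi @ L.T)
    sigma = L @ Phi @ L.T + np.diag(Theta)
    if np.min(np.linalg.eigvalsh(sigma)) <= 0 or np.min(Theta) <= 0:
        raise ValueError("implied covariance is not positive definite")
    return spec, L, Phi, Theta


def simulate_task_scores(config: CohortConfig, factors: np.ndarray, rng: np.random.Generator):
    """Task scores Lambda f + covariate effects + residual noise, MCAR-masked.

    `factors` are the (already generated) latent component scores, one
    column per factor of the configured model.
    """
    spec, L, Phi, Theta = _model_matrices(config)
    n = len(factors)
    age = rng.uniform(17, 31, n)
    sex = rng.integers(0, 2, n).astype(float)
    site = rng.integers(0, 2, n).astype(float)
    fd = rng.lognormal(-2.3, 0.4, n)
    covariates = pd.DataFrame({"age": age, "sex": sex, "site": site, "fd": fd})
    eps = rng.standard_normal((n, len(spec.indicators))) * np.sqrt(Theta)
    X = factors @ L.T + eps
    X += config.covariate_effects.get("age", 0.0) * (age - age.mean())[:, None]
    X += config.covariate_effects.get("sex", 0.0) * (sex - sex.mean())[:, None]
    if config.missing_rate > 0:
        mask = rng.random(X.shape) < config.missing_rate
        X = np.where(mask, np.nan, X)
    scores = pd.DataFrame(X, columns=spec.indicators)
    return scores, covariates


def draw_factors(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent factor scores per the configured model (no genetic wiring)."""
    spec, L, Phi, Theta = _model_matrices(config)
    chol = np.linalg.cholesky(Phi)
    return rng.standard_normal((config.n_subjects, len(spec.factors))) @ chol.T


# ---------------------------------------------------------------------------
# connectome


def simulate_connectome(
    n: int,
    n_nodes: int,
    informative_edges: dict[str, np.ndarray],
    b: float,
    component_scores: dict[str, np.ndarray],
    site: np.ndarray | None = None,
    fd: np.ndarray | None = None,
    batch_effect: float = 0.0,
    fd_effect: float = 0.0,
    seed=0,
    base_mean: float = 0.3,
) -> np.ndarray:
    """Subject x edge Fisher-z connectivity with planted informative edges.

    Every edge is Gaussian noise around `base_mean`; each informative edge
    of a component adds b times that component's score; site adds a batch
    shift and framewise displacement a motion nuisance on all edges.
    """
    if not np.isfinite(b):
        raise ValueError("edge effect b must be finite")
    E = edge_count(n_nodes)
    for comp, idx in informative_edges.items():
        if np.max(idx, initial=-1) >= E:
            raise ValueError(f"edge index out of range for component {comp!r}")
    rng = np.random.default_rng(seed)
    edges = base_mean + rng.standard_normal((n, E))
    for comp, idx in informative_edges.items():
        if comp in component_scores and len(idx):
            edges[:, np.asarray(idx)] += b * np.asarray(component_scores[comp], float)[:, None]
    if site is not None and batch_effect:
        edges += batch_effect * np.asarray(site, float)[:, None]
    if fd is not None and fd_effect:
        edges += fd_effect * (np.asarray(fd, float) - np.mean(fd))[:, None]
    return edges


def default_parcellation(n_nodes: int = 264, n_networks: int = 8) -> pd.DataFrame:
    """A deterministic toy parcellation: nodes assigned to networks round-robin."""
    nets = ["FPN", "CON", "DMN", "SAN", "DAN", "VAN", "Somato", "Subcor"][:n_networks]
    return pd.DataFrame(
        {
            "node": np.arange(n_nodes),
            "name": [f"node_{i:03d}" for i in range(n_nodes)],
            "network": [nets[i % len(nets)] for i in range(n_nodes)],
        }
    )


# ---------------------------------------------------------------------------
# genotypes, annotation, expression


def simulate_genotypes_and_annotations(
    n: int,
    m: int,
    maf_range=(0.05, 0.5),
    n_genes: int = 500,
    flank_max_kb: float = 50.0,
    seed=0,
):
    """Genotypes in linkage equilibrium plus a toy gene annotation.

    Dosages are Binomial(2, p_i) with p_i uniform on the MAF range.  Genes
    tile a toy chromosome with inter-gene gaps wider than twice the largest
    flank, so +/-flank windows never overlap neighboring genes and every
    in-gene SNP maps to exactly one gene.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(float)

    snps_per_gene = max(m // n_genes, 1)
    gap = int(2 * flank_max_kb * 1000) + 10_000
    body = snps_per_gene * 1000
    stride = body + gap
    positions = np.empty(m, dtype=int)
    gene_rows = []
    for g in range(n_genes):
        start = 10_000 + g * stride
        gene_rows.append({"chrom": "1", "start": start, "end": start + body, "gene": f"G{g:04d}"})
        lo_i = g * snps_per_gene
        hi_i = min((g + 1) * snps_per_gene, m)
        k = hi_i - lo_i
        if k > 0:
            positions[lo_i:hi_i] = start + np.arange(k) * 1000 + 1  # 1-based, inside the body
    extra = m - n_genes * snps_per_gene
    if extra > 0:
        far = 10_000 + n_genes * stride + int(2 * flank_max_kb * 1000)
        positions[n_genes * snps_per_gene:] = far + np.arange(extra) * 200_000
    variants = pd.DataFrame(
        {
            "snp": [f"rs{i:06d}" for i in range(m)],
            "chrom": "1",
            "bp": positions,
            "a1": "A",
            "a2": "G",
            "maf": p,
        }
    )
    genes = pd.DataFrame(gene_rows)
    geno = GenotypeMatrix(dosages=dosages, variants=variants, subjects=[f"S{i:04d}" for i in range(n)])
    snp_gene = np.full(m, -1)
    snp_gene[: n_genes * snps_per_gene] = np.repeat(np.arange(n_genes), snps_per_gene)[: n_genes * snps_per_gene]
    return geno, genes, snp_gene


def planted_trait(W_causal: np.ndarray, h2: float, rng: np.random.Generator,
                  exact: bool = True) -> np.ndarray:
    """A trait y = g + e with genetic variance h2 from standardized causal dosages.

    With ``exact=True`` (the generator's bookkeeping convention) the genetic
    and environmental parts are rescaled to exact sample variances h2 and
    1 - h2, so the generative variance ratio equals the target by
    construction rather than only in expectation.
    """
    n, mc = W_causal.shape
    u = rng.standard_normal(mc)
    g = W_causal @ (u / np.linalg.norm(u) * np.sqrt(h2 / np.mean(np.sum(W_causal**2, 1) / mc)))
    e = rng.standard_normal(n)
    if exact:
        g = (g - g.mean()) / g.std() * np.sqrt(h2)
        e = (e - e.mean()) / e.std() * np.sqrt(1.0 - h2)
    else:
        e *= np.sqrt(1.0 - h2)
    return g + e


def planted_trait_pair(W_causal: np.ndarray, h2_1: float, h2_2: float, rg: float,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two traits whose realized genetic values correlate at exactly rg.

    Both genetic components are rescaled to exact sample variances and the
    second is orthogonalized/recombined so the sample correlation of the two
    genetic values equals rg by construction.
    """
    n, mc = W_causal.shape
    g1 = W_causal @ rng.standard_normal(mc)
    g2 = W_causal @ rng.standard_normal(mc)
    g1 = (g1 - g1.mean()) / g1.std()
    resid = g2 - (g2 @ g1 / (g1 @ g1)) * g1
    resid = (resid - resid.mean()) / resid.std()
    g2 = rg * g1 + np.sqrt(max(1 - rg**2, 0.0)) * resid
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    y1 = g1 * np.sqrt(h2_1) + (e1 - e1.mean()) / e1.std() * np.sqrt(1 - h2_1)
    y2 = g2 * np.sqrt(h2_2) + (e2 - e2.mean()) / e2.std() * np.sqrt(1 - h2_2)
    return y1, y2


def correlated_effects(m_causal: int, h2_1: float, h2_2: float, rg: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Standardized-scale causal effect vectors with ||u_t||^2 = h2_t and corr rg."""
    u1 = rng.standard_normal(m_causal)
    raw = rng.standard_normal(m_causal)
    u1h = u1 / np.linalg.norm(u1)
    orth = raw - (raw @ u1h) * u1h
    orth /= np.linalg.norm(orth)
    u2 = rg * u1h + np.sqrt(max(1 - rg**2, 0.0)) * orth
    return u1h * np.sqrt(h2_1), u2 * np.sqrt(h2_2)


def simulate_expression(n_genes: int, n_regions: int, enhanced_gene_idx, target_region: int = 0,
                        log_fold: float = 3.0, seed=0) -> pd.DataFrame:
    """Log-normal gene x region expression with region-enhanced genes.

    Enhanced genes' log expression in the target region is shifted by
    `log_fold`; all other entries share the same baseline distribution.
    """
    if log_fold < 0:
        raise ValueError("log_fold must be non-negative")
    rng = np.random.default_rng(seed)
    logx = rng.normal(2.0, 0.5, size=(n_genes, n_regions))
    enhanced = np.asarray(enhanced_gene_idx, dtype=int)
    logx[enhanced, target_region] += log_fold
    return pd.DataFrame(
        np.exp(logx),
        index=[f"G{g:04d}" for g in range(n_genes)],
        columns=[f"region_{r}" for r in range(n_regions)],
    )


# ---------------------------------------------------------------------------
# the full cohort


@dataclass
class CohortDataset:
    config: CohortConfig
    scores: pd.DataFrame
    covariates: pd.DataFrame
    factors: pd.DataFrame
    edges: np.ndarray
    parcellation: pd.DataFrame
    genotypes: GenotypeMatrix
    genes: pd.DataFrame
    gene_sets: dict[str, list[str]]
    expression: pd.DataFrame
    truth: dict


def simulate_cohort(config: CohortConfig) -> CohortDataset:
    """Generate one coherent cohort with a planted gene-brain-behavior pathway.

    The first factor of the configured model (the "common" component in
    bifactor models) is generated through the mediation wiring
    M = Z B + eta,  f1 = M gamma + Z beta + eps, with (B, gamma, beta)
    rescaled so that (i) the exposure-attributable variance of f1 equals its
    target heritability and (ii) the true PVM equals config.target_pvm to
    1e-6.  The mediator columns are that component's informative edges.
    Remaining factors get direct additive genetics (causal effects
    correlated with the first factor's total effect at target_rg) and
    additive edge effects of size b on their own informative-edge sets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    spec, L, Phi, Theta = _model_matrices(config)
    factors_names = list(spec.factors)

    geno, genes, snp_gene = simulate_genotypes_and_annotations(
        n, config.n_snps, config.maf_range, config.n_genes, seed=rng.integers(2**31)
    )
    # causal SNPs drawn inside gene bodies so the causal gene set is well defined
    in_gene = np.flatnonzero(snp_gene >= 0)
    causal = np.sort(rng.choice(in_gene, size=config.n_causal, replace=False))
    p_maf = geno.variants["maf"].to_numpy()
    W = (geno.dosages - 2 * p_maf) / np.sqrt(2 * p_maf * (1 - p_maf))
    Z = W[:, causal]

    # mediation wiring for the first ("common") component
    E = edge_count(config.n_nodes)
    all_edges = rng.permutation(E)
    informative = {}
    pos = 0
    for fname in factors_names:
        informative[fname] = np.sort(all_edges[pos : pos + config.n_informative_edges])
        pos += config.n_informative_edges

    h2_1 = config.target_h2.get(factors_names[0], 0.6)
    p_med = config.n_informative_edges
    q = config.n_causal
    B, gamma, beta = _calibrated_mediation(q, p_med, h2_1, config.target_pvm, rng)
    vte, vie, pvm = pvm_from_truth(B, gamma, beta, 1.0)

    eta_sd = np.sqrt(np.maximum(1.0 - np.sum(B**2, axis=0), 1e-3))
    M = Z @ B + rng.standard_normal((n, p_med)) * eta_sd
    resid_var = 1.0 - vte - float(gamma @ (np.diag(eta_sd**2) @ gamma))
    resid_var = max(resid_var, 0.05)
    f1 = M @ gamma + Z @ beta + rng.standard_normal(n) * np.sqrt(resid_var)

    # remaining factors: direct additive genetics + independent environment
    factors = np.empty((n, len(factors_names)))
    factors[:, 0] = f1
    total1 = B @ gamma + beta
    for j, fname in enumerate(factors_names[1:], start=1):
        h2_j = config.target_h2.get(fname, 0.2)
        u1, uj = correlated_effects(q, h2_1, h2_j, config.target_rg, rng)
        # align the shared direction with the realized total effect of f1
        uj = _align_effect(uj, total1, config.target_rg, h2_j)
        factors[:, j] = Z @ uj + rng.standard_normal(n) * np.sqrt(max(1 - h2_j, 1e-3))

    scores, covariates = simulate_task_scores(config, factors, rng)

    comp_scores = {fname: factors[:, j] for j, fname in enumerate(factors_names)}
    edges = simulate_connectome(
        n,
        config.n_nodes,
        {f: informative[f] for f in factors_names[1:]},
        config.edge_effect,
        comp_scores,
        site=covariates["site"].to_numpy(),
        fd=covariates["fd"].to_numpy(),
        batch_effect=config.batch_effect,
        fd_effect=config.fd_effect,
        seed=rng.integers(2**31),
    )
    # the first component's informative edges ARE the mediators
    edges[:, informative[factors_names[0]]] = M + 0.3

    causal_genes = sorted({f"G{g:04d}" for g in snp_gene[causal] if g >= 0})
    n_enh = max(int(config.enhanced_fraction * config.n_genes), len(causal_genes))
    enhanced_idx = sorted({int(g) for g in snp_gene[causal] if g >= 0})
    if len(enhanced_idx) < n_enh:
        others = np.setdiff1d(np.arange(config.n_genes), enhanced_idx)
        pad = rng.choice(others, size=n_enh - len(enhanced_idx), replace=False)
        enhanced_idx = sorted(set(enhanced_idx) | set(int(x) for x in pad))
    expression = simulate_expression(
        config.n_genes, config.n_regions, enhanced_idx, 0, config.expression_log_fold,
        seed=rng.integers(2**31),
    )
    enhanced_genes = [f"G{g:04d}" for g in enhanced_idx]
    gene_sets = {
        "causal_set": causal_genes,
        "enhanced_region_0": enhanced_genes,
        "random_control": sorted(
            rng.choice(genes["gene"].to_numpy(), size=len(causal_genes), replace=False)
        ),
    }

    truth = {
        "model_name": config.model_name,
        "loadings": config.loadings,
        "factor_names": factors_names,
        "informative_edges": {k: np.asarray(v) for k, v in informative.items()},
        "causal_snps": causal,
        "B": B,
        "gamma": gamma,
        "beta": beta,
        "var_z": 1.0,
        "vte": vte,
        "vie": vie,
        "pvm": pvm,
        "target_h2": dict(config.target_h2),
        "target_rg": config.target_rg,
        "enhanced_genes": enhanced_genes,
        "causal_genes": causal_genes,
        "factors": factors,
    }
    return CohortDataset(
        config=config,
        scores=scores,
        covariates=covariates,
        factors=pd.DataFrame(factors, columns=factors_names),
        edges=edges,
        parcellation=default_parcellation(config.n_nodes),
        genotypes=geno,
        genes=genes,
        gene_sets=gene_sets,
        expression=expression,
        truth=truth,
    )


def _calibrated_mediation(q: int, p: int, vte_target: float, pvm_target: float, rng):
    """Draw (B, gamma, beta) with exact VTE and PVM under Var(Z) = I.

    beta is decomposed orthogonally to B gamma, so VTE = |B gamma|^2 +
    |beta|^2 and the targets are hit by rescaling: |B gamma|^2 = PVM * VTE,
    |beta|^2 = (1-PVM) * VTE.  PVM = 0 forces gamma = 0; PVM = 1 forces
    beta = 0.
    """
    B = rng.standard_normal((q, p)) * np.sqrt(0.5 / q)  # mediator exposure-variance ~ 0.5
    gamma = rng.standard_normal(p)
    v = B @ gamma
    nv = np.linalg.norm(v)
    if pvm_target == 0.0:
        gamma = np.zeros(p)
        v = np.zeros(q)
    else:
        scale = np.sqrt(pvm_target * vte_target) / nv
        gamma = gamma * scale
        v = v * scale
    if pvm_target == 1.0:
        beta = np.zeros(q)
    else:
        raw = rng.standard_normal(q)
        if nv > 0:
            vh = (B @ (gamma if pvm_target > 0 else rng.standard_normal(p)))
            nh = np.linalg.norm(vh)
            if nh > 0:
                raw = raw - (raw @ vh / nh**2) * vh
        beta = raw / np.linalg.norm(raw) * np.sqrt((1.0 - pvm_target) * vte_target)
    return B, gamma, beta


def _align_effect(uj: np.ndarray, total1: np.ndarray, rg: float, h2_j: float) -> np.ndarray:
    """Rotate a causal-effect vector so corr(u_j, total1) = rg with |u_j|^2 = h2_j."""
    t = total1 / np.linalg.norm(total1)
    raw = uj - (uj @ t) * t
    nr = np.linalg.norm(raw)
    if nr < 1e-12:
        return t * np.sqrt(h2_j) * np.sign(rg if rg != 0 else 1.0)
    orth = raw / nr
    return (rg * t + np.sqrt(max(1 - rg**2, 0.0)) * orth) * np.sqrt(h2_j)
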