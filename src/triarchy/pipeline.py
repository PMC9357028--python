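"""End-to-end orchestration of the synthetic gene-brain-behavior study.

One config drives the full analysis sequence on a simulated cohort:
behavioral residualization -> CFA model comparison -> factor scores ->
connectome-based prediction with permutation inference and FDR ->
contributing edges, Dice overlap, node ranking, network enrichment ->
GRM / heritability / genetic correlation / partitioned enrichment ->
expression-based gene-set selection and MAGENTA -> high-dimensional
mediation.  Every stage's output lands in the report (and, when an output
directory is given, in flat files) so stages can be inspected in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, cfa, cpm, geneset, genetics, mediation, overlap, simulate
from .io import _TruthEncoder, write_cohort

log = logging.getLogger("triarchy")

NESTED_PAIRS = [("U/I+S", "I+U+S"), ("C+S", "C+U+S"), ("C+S", "C+I+S")]


@dataclass
class StudyConfig:
    cohort: simulate.CohortConfig = field(default_factory=simulate.CohortConfig)
    models: list = field(default_factory=lambda: ["I+U+S", "U/I+S", "C+I+S", "C+U+S", "C+S"])
    score_model: str | None = None  # defaults to the cohort's generating model
    cpm_folds: int = 10
    cpm_splits: int = 20
    cpm_p_thresh: float = 0.05
    cpm_perms: int = 100
    contributing_threshold: float = 0.95
    dice_perms: int = 10_000
    flank_kb: float = 35.0
    magenta_cutoff: float = 75.0
    magenta_perms: int = 2000
    mediation_perms: int = 199
    seed: int = 0
    outdir: str | None = None


@dataclass
class StudyReport:
    model_fits: pd.DataFrame
    nested_tests: pd.DataFrame
    cpm: pd.DataFrame
    dice: dict
    node_ranking: dict
    network_enrichment: dict
    heritability: pd.DataFrame
    genetic_correlation: pd.DataFrame
    partition: dict
    magenta: dict
    mediation: dict
    runtimes: dict

    def to_json(self, path):
        payload = {
            "model_fits": self.model_fits.to_dict("records"),
            "nested_tests": self.nested_tests.to_dict("records"),
            "cpm": self.cpm.to_dict("records"),
            "dice": self.dice,
            "heritability": self.heritability.to_dict("records"),
            "genetic_correlation": self.genetic_correlation.to_dict("records"),
            "partition": self.partition,
            "magenta": self.magenta,
            "mediation": self.mediation,
            "runtimes": self.runtimes,
        }
        Path(path).write_text(json.dumps(payload, cls=_TruthEncoder, indent=1))


def normalize_within_subject(edges: np.ndarray) -> np.ndarray:
    """Z-score connectivity across edges within each participant."""
    mu = edges.mean(axis=1, keepdims=True)
    sd = edges.std(axis=1, keepdims=True)
    sd[sd < 1e-12] = 1.0
    return (edges - mu) / sd


def run_full_study(config: StudyConfig) -> StudyReport:
    t_all = time.time()
    runtimes = {}
    rng = np.random.default_rng(config.seed)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- cohort -----------------------------------------------------------
    t0 = time.time()
    config.cohort.seed = int(rng.integers(2**31))
    cohort = simulate.simulate_cohort(config.cohort)
    runtimes["simulate"] = time.time() - t0
    if outdir:
        write_cohort(cohort, outdir / "cohort")

    # --- behavior: residualize scores on age and sex ----------------------
    t0 = time.time()
    scores = behavior.residualize_scores(cohort.scores, cohort.covariates[["age", "sex"]])
    runtimes["behavior"] = time.time() - t0

    # --- CFA model comparison ---------------------------------------------
    t0 = time.time()
    lib = cfa.model_library()
    fits = {}
    rows = []
    for name in config.models:
        fit = cfa.fit_cfa(scores, lib[name], missing="fiml", compute_se=False)
        fi = cfa.fit_indices(fit, scores)
        fits[name] = fit
        rows.append(
            {
                "model": name, "chisq": fit.chisq, "df": fit.df, "cfi": fi.cfi,
                "rmsea": fi.rmsea, "srmr": fi.srmr, "aic": fi.aic, "bic": fi.bic,
                "converged": fit.converged,
                "good_fit": fi.cfi > 0.95 and (fi.rmsea or 0) < 0.05 and fi.srmr < 0.05,
            }
        )
    model_fits = pd.DataFrame(rows)
    nrows = []
    for restricted, full in NESTED_PAIRS:
        if restricted in fits and full in fits:
            d_chi, d_df, p, _ = cfa.chisq_diff_test(fits[restricted], fits[full])
            nrows.append({"restricted": restricted, "full": full,
                          "chisq_diff": d_chi, "df_diff": d_df, "p": p})
    nested = pd.DataFrame(nrows)
    runtimes["cfa"] = time.time() - t0

    # --- factor scores from the scoring model -----------------------------
    score_model = config.score_model or config.cohort.model_name
    fscores = cfa.factor_scores(fits[score_model], scores)
    components = list(fscores.columns)

    # --- CPM per component -------------------------------------------------
    t0 = time.time()
    edges_norm = normalize_within_subject(cohort.edges)
    covars = cohort.covariates[["site", "fd"]].to_numpy()
    cpm_rows = []
    cpm_results = {}
    for comp in components:
        y = fscores[comp].to_numpy()
        ok = ~np.isnan(y)
        p_val, res, _ = cpm.cpm_permutation_test(
            edges_norm[ok], y[ok], covars[ok], n_perm=config.cpm_perms,
            seed=int(rng.integers(2**31)),
            k=config.cpm_folds, n_splits=config.cpm_splits, p_thresh=config.cpm_p_thresh,
        )
        cpm_results[comp] = res
        cpm_rows.append({"component": comp, "mean_r": res.mean_r, "p_permutation": p_val})
    cpm_table = pd.DataFrame(cpm_rows)
    adj, rej = cpm.fdr_bh(cpm_table["p_permutation"].to_numpy())
    cpm_table["p_fdr"] = adj
    cpm_table["significant"] = rej
    runtimes["cpm"] = time.time() - t0

    # --- overlap statistics -------------------------------------------------
    t0 = time.time()
    masks = {
        comp: cpm.contributing_edges(
            cpm_results[comp].selection_counts,
            cpm_results[comp].total_iterations,
            config.contributing_threshold,
        )
        for comp in components
    }
    dice_out = {}
    for i, c1 in enumerate(components):
        for c2 in components[i + 1:]:
            obs = overlap.dice_coefficient(masks[c1], masks[c2])
            dr = overlap.dice_permutation_test(
                int(masks[c1].sum()), int(masks[c2].sum()), masks[c1].size, obs,
                n_perm=config.dice_perms, seed=int(rng.integers(2**31)),
            )
            dice_out[f"{c1}|{c2}"] = {"dice": dr.observed, "p": dr.p_value}
    ranking = {}
    enrichment = {}
    for comp in components:
        rk = overlap.rank_nodes(masks[comp], cohort.parcellation, top_k=10)
        ranking[comp] = rk
        if rk["n_contributing"].iloc[0] > 0:
            enrichment[comp] = overlap.network_enrichment(
                masks[comp], int(rk["node"].iloc[0]), cohort.parcellation
            )
    runtimes["overlap"] = time.time() - t0

    # --- genetics ----------------------------------------------------------
    t0 = time.time()
    geno_qc, qc_report = genetics.qc_genotypes(cohort.genotypes)
    grm = genetics.compute_grm(geno_qc)
    kept = genetics.prune_related(grm, seed=int(rng.integers(2**31)))
    pcs = genetics.grm_pca(grm[np.ix_(kept, kept)], k=min(10, len(kept) - 1))
    d, U = np.linalg.eigh(grm[np.ix_(kept, kept)])
    gcov = np.column_stack(
        [cohort.covariates.iloc[kept][["age", "sex", "site"]].to_numpy(), pcs.to_numpy()]
    )
    h_rows = []
    for comp in components:
        y = fscores[comp].to_numpy()[kept]
        ok = ~np.isnan(y)
        vc = genetics.reml_variance_components(y[ok], [grm[np.ix_(kept, kept)][np.ix_(ok, ok)]],
                                               covariates=gcov[ok])
        h_rows.append({"component": comp, "h2": vc.h2, "se": vc.h2_se, "p": vc.lrt_p})
    herit = pd.DataFrame(h_rows)
    rg_rows = []
    for i, c1 in enumerate(components):
        for c2 in components[i + 1:]:
            y1 = fscores[c1].to_numpy()[kept]
            y2 = fscores[c2].to_numpy()[kept]
            ok = ~np.isnan(y1) & ~np.isnan(y2)
            bv = genetics.reml_bivariate(y1[ok], y2[ok], grm[np.ix_(kept, kept)][np.ix_(ok, ok)],
                                         covariates=gcov[ok])
            rg_rows.append({"pair": f"{c1}|{c2}", "rg": bv.rg, "se": bv.rg_se})
    rg_table = pd.DataFrame(rg_rows)
    set_mask = np.zeros(geno_qc.n_snps, dtype=bool)
    causal_ids = set(cohort.genotypes.variants["snp"].iloc[cohort.truth["causal_snps"]])
    set_mask[[i for i, s in enumerate(geno_qc.variants["snp"]) if s in causal_ids]] = True
    y0 = fscores[components[0]].to_numpy()[kept]
    ok0 = ~np.isnan(y0)
    part = None
    if 0 < set_mask.sum() < geno_qc.n_snps:
        pr = genetics.partition_enrichment(y0[ok0], set_mask, geno_qc.subset_subjects(kept).dosages[ok0],
                                           covariates=gcov[ok0])
        part = {"fold": pr.fold, "h2_set": pr.h2_set, "h2_total": pr.h2_total, "z": pr.z, "p": pr.p}
    runtimes["genetics"] = time.time() - t0

    # --- gene sets / MAGENTA ------------------------------------------------
    t0 = time.time()
    enhanced = geneset.select_enhanced_genes(
        cohort.expression, "region_0", top_k=len(cohort.truth["enhanced_genes"])
    )
    magenta_out = {}
    for comp in components:
        y = fscores[comp].to_numpy()[kept]
        ok = ~np.isnan(y)
        gwas = geneset.gwas_scan(y[ok], geno_qc.subset_subjects(kept).dosages[ok], covariates=gcov[ok])
        gwas[["chrom", "bp"]] = geno_qc.variants[["chrom", "bp"]]
        mapping = geneset.map_snps_to_genes(geno_qc.variants, cohort.genes, config.flank_kb)
        table = geneset.correct_gene_scores(geneset.gene_scores(gwas, mapping, cohort.genes))
        mg = geneset.magenta_test(enhanced, table, config.magenta_cutoff,
                                  n_perm=config.magenta_perms, seed=int(rng.integers(2**31)))
        magenta_out[comp] = {"observed": mg.observed, "expected": mg.expected, "p": mg.p_value}
    runtimes["geneset"] = time.time() - t0

    # --- mediation -----------------------------------------------------------
    t0 = time.time()
    comp0 = components[0]
    mask0 = masks[comp0]
    med_edges = cohort.edges[:, mask0] if mask0.sum() >= 5 else cohort.edges[
        :, cohort.truth["informative_edges"][comp0]
    ]
    W = genetics.standardized_dosages(cohort.genotypes.dosages[:, cohort.truth["causal_snps"]])
    Y = fscores[comp0].to_numpy()
    okm = ~np.isnan(Y)
    Ym = Y[okm] - np.nanmean(Y[okm])
    Mm = med_edges[okm] - med_edges[okm].mean(0)
    Zm = W[okm] - W[okm].mean(0)
    p_med, med_res, _ = mediation.mediation_permutation_test(
        Ym, Mm, Zm, n_perm=config.mediation_perms, seed=int(rng.integers(2**31))
    )
    med_out = {
        "component": comp0, "vte": med_res.vte, "vie": med_res.vie, "vde": med_res.vde,
        "pvm": med_res.pvm, "p_permutation": p_med, "true_pvm": cohort.truth["pvm"],
    }
    runtimes["mediation"] = time.time() - t0
    runtimes["total"] = time.time() - t_all

    report = StudyReport(
        model_fits=model_fits,
        nested_tests=nested,
        cpm=cpm_table,
        dice=dice_out,
        node_ranking={k: v.to_dict("records") for k, v in ranking.items()},
        network_enrichment={k: v.to_dict("records") for k, v in enrichment.items()},
        heritability=herit,
        genetic_correlation=rg_table,
        partition=part,
        magenta=magenta_out,
        mediation=med_out,
        runtimes=runtimes,
    )
    if outdir:
        report.to_json(outdir / "report.json")
    return report
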