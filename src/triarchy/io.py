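"""Readers and writers for the genetics and cohort file formats.

PLINK .bed/.bim/.fam are handled with a hand-written codec for the v1.00
SNP-major binary layout (magic bytes 0x6c 0x1b 0x01, two bits per genotype:
00 = two copies of A1, 10 = one copy, 11 = zero copies, 01 = missing).
The GRM writer follows the GCTA binary dialect (float32 lower triangle,
row-wise, with .id and .N.bin companions).  Gene sets use GMT, gene
boundaries use BED (0-based half-open), and everything tabular is TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import GenotypeMatrix

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> dosage of A1; 1 codes missing
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write .bed (SNP-major v1.00), .bim and .fam files."""
    prefix = Path(prefix)
    n, m = geno.n_subjects, geno.n_snps
    dos = geno.dosages
    n_bytes = (n + 3) // 4
    codes = np.full((m, n), 3, dtype=np.uint8)  # 3 = dosage 0
    codes[np.isnan(dos).T] = 1
    codes[(dos == 1).T] = 2
    codes[(dos == 2).T] = 0
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    for k in range(4):
        idx = np.arange(k, n, 4)
        packed[:, idx // 4] |= codes[:, idx] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    v = geno.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "snp": v["snp"],
            "cm": 0,
            "bp": v["bp"],
            "a1": v["a1"],
            "a2": v["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": geno.subjects,
            "iid": geno.subjects,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a .bed/.bim/.fam trio into a GenotypeMatrix."""
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"])
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "bp", "a1", "a2"], dtype={"chrom": str})
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK v1.00 .bed file")
    n_bytes = (n + 3) // 4
    body = raw[3:].reshape(m, n_bytes)
    codes = np.empty((m, n), dtype=np.uint8)
    for k in range(4):
        idx = np.arange(k, n, 4)
        codes[:, idx] = (body[:, idx // 4] >> (2 * k)) & 0b11
    dos = _CODE_TO_DOSAGE[codes].T
    variants = bim[["snp", "chrom", "bp", "a1", "a2"]].copy()
    return GenotypeMatrix(dosages=dos, variants=variants, subjects=list(fam["iid"]))


def write_grm_gcta(grm: np.ndarray, n_snps: int, ids: list, prefix: str | Path) -> None:
    """Write a GRM in the GCTA binary dialect (.grm.bin/.grm.N.bin/.grm.id)."""
    prefix = Path(prefix)
    n = grm.shape[0]
    il = np.tril_indices(n)
    grm[il].astype("<f4").tofile(f"{prefix}.grm.bin")
    np.full(len(il[0]), n_snps, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    pd.DataFrame({"fid": ids, "iid": ids}).to_csv(f"{prefix}.grm.id", sep="\t", header=False, index=False)


def read_grm_gcta(prefix: str | Path) -> tuple[np.ndarray, list]:
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None)[1].tolist()
    n = len(ids)
    vals = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    grm = np.zeros((n, n))
    il = np.tril_indices(n)
    grm[il] = vals
    grm = grm + grm.T - np.diag(np.diag(grm))
    return grm, ids


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, name] + list(members)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                out[parts[0]] = parts[2:]
    return out


def write_bed_genes(genes: pd.DataFrame, path: str | Path) -> None:
    genes[["chrom", "start", "end", "gene"]].to_csv(path, sep="\t", header=False, index=False)


def read_bed_genes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "gene"],
                       dtype={"chrom": str})


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic GT dosages from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gt = var.gt_types.astype(float)  # 0=hom ref,1=het,2=hom alt(cyvcf2:3),3=missing(cyvcf2:2)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        dosages.append(dos)
        rows.append({"snp": var.ID or f"{var.CHROM}:{var.POS}", "chrom": str(var.CHROM),
                     "bp": var.POS, "a1": var.ALT[0], "a2": var.REF})
    return GenotypeMatrix(
        dosages=np.array(dosages).T if dosages else np.empty((len(subjects), 0)),
        variants=pd.DataFrame(rows),
        subjects=subjects,
    )


class _TruthEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return super().default(o)


def write_cohort(dataset, outdir: str | Path) -> None:
    """Write every cohort block as flat files (TSV / PLINK / GMT / BED / npy)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.scores.to_csv(out / "scores.tsv", sep="\t", index_label="subject")
    dataset.covariates.to_csv(out / "covariates.tsv", sep="\t", index_label="subject")
    dataset.factors.to_csv(out / "factors_true.tsv", sep="\t", index_label="subject")
    np.save(out / "edges.npy", dataset.edges)
    dataset.parcellation.to_csv(out / "parcellation.tsv", sep="\t", index=False)
    write_plink(dataset.genotypes, out / "genotypes")
    write_bed_genes(dataset.genes, out / "genes.bed")
    write_gmt(dataset.gene_sets, out / "gene_sets.gmt")
    dataset.expression.to_csv(out / "expression.tsv", sep="\t", index_label="gene")
    with open(out / "truth.json", "w") as fh:
        json.dump(dataset.truth, fh, cls=_TruthEncoder, indent=1)
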