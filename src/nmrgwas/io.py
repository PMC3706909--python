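"""Readers and writers for the pipeline's text artifacts.

All tabular artifacts are tab-separated text; the spectra matrix carries
a ppm header with at least 4 decimals, the binned matrix a JSON sidecar
with bin metadata and provenance flags.  Genotypes round-trip either as a
dosage TSV with a SNP-metadata sidecar or as an uncompressed VCF (GT
field; missing genotypes as ./.).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import BinnedSpectraMatrix
from .synth import GenotypeSet, MetaboliteSet, TruthTable

__all__ = [
    "write_spectra_tsv", "read_spectra_tsv",
    "write_dosage_tsv", "read_dosage_tsv",
    "write_vcf", "read_vcf",
    "write_covariates_tsv", "read_covariates_tsv",
    "write_metabolites_tsv", "read_metabolites_tsv",
    "write_truth_tsv",
    "write_binned", "read_binned",
]


# ----------------------------------------------------------------- spectra

def write_spectra_tsv(path, grid: np.ndarray, spectra: np.ndarray,
                      subjects: list[str]) -> None:
    header = "subject\t" + "\t".join(f"{x:.4f}" for x in grid)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for sid, row in zip(subjects, spectra):
            fh.write(sid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_spectra_tsv(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    grid = np.array([float(c) for c in df.columns])
    return grid, df.to_numpy(dtype=float), [str(s) for s in df.index]


# --------------------------------------------------------------- genotypes

def write_dosage_tsv(path, genotypes: GenotypeSet, meta_path=None) -> None:
    df = pd.DataFrame(genotypes.dosage, index=genotypes.subjects,
                      columns=genotypes.snps["id"])
    df.index.name = "subject"
    df.to_csv(path, sep="\t", na_rep="NA")
    if meta_path is None:
        meta_path = str(path) + ".meta.tsv"
    genotypes.snps.to_csv(meta_path, sep="\t", index=False)


def read_dosage_tsv(path, meta_path=None) -> GenotypeSet:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    if meta_path is None:
        meta_path = str(path) + ".meta.tsv"
    snps = pd.read_csv(meta_path, sep="\t")
    return GenotypeSet(subjects=[str(s) for s in df.index], snps=snps,
                       dosage=df.to_numpy(dtype=float))


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(path, genotypes: GenotypeSet) -> None:
    """Plain-text VCFv4.2 with GT; ALT is the minor (counted) allele."""
    snps = genotypes.snps
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.subjects) + "\n")
        for j in range(len(snps)):
            row = snps.iloc[j]
            gts = [("./." if not np.isfinite(d) else _GT_CODE[float(d)])
                   for d in genotypes.dosage[:, j]]
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t"
                     f"{row['allele_a']}\t{row['allele_b']}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def read_vcf(path) -> GenotypeSet:
    """Read a VCF (via cyvcf2) into a minor-allele-oriented GenotypeSet."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        # gt_types: 0=hom ref, 1=het, 3=hom alt, 2=unknown
        codes = np.asarray(var.gt_types, dtype=float)
        d = np.where(codes == 0, 0.0,
                     np.where(codes == 1, 1.0,
                              np.where(codes == 3, 2.0, np.nan)))
        obs = d[np.isfinite(d)]
        call_rate = obs.size / len(subjects) if subjects else 0.0
        freq_alt = float(obs.mean() / 2.0) if obs.size else 0.0
        a, b = var.REF, (var.ALT[0] if var.ALT else ".")
        if freq_alt > 0.5:
            d = 2.0 - d
            a, b = b, a
            freq_alt = 1.0 - freq_alt
        cols.append(d)
        rows.append(dict(id=var.ID or f"{var.CHROM}:{var.POS}", chrom=str(var.CHROM),
                         pos=int(var.POS), allele_a=a, allele_b=b,
                         maf=freq_alt, call_rate=call_rate))
    dosage = np.column_stack(cols) if cols else np.empty((len(subjects), 0))
    return GenotypeSet(subjects=subjects, snps=pd.DataFrame(
        rows, columns=["id", "chrom", "pos", "allele_a", "allele_b",
                       "maf", "call_rate"]), dosage=dosage)


# -------------------------------------------------------------- covariates

def write_covariates_tsv(path, covariates: pd.DataFrame) -> None:
    covariates[["subject", "age", "sex"]].to_csv(path, sep="\t", index=False)


def read_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------- metabolites

def write_metabolites_tsv(path, mset: MetaboliteSet, meta_path=None) -> None:
    df = pd.DataFrame(mset.values, index=mset.subjects, columns=mset.names)
    df.index.name = "subject"
    df.to_csv(path, sep="\t", na_rep="NA")
    if meta_path is None:
        meta_path = str(path) + ".meta.tsv"
    mset.meta.to_csv(meta_path, sep="\t", index=False)


def read_metabolites_tsv(path, meta_path=None) -> MetaboliteSet:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    if meta_path is None:
        meta_path = str(path) + ".meta.tsv"
    meta = pd.read_csv(meta_path, sep="\t")
    return MetaboliteSet(subjects=[str(s) for s in df.index], meta=meta,
                         values=df.to_numpy(dtype=float))


def write_truth_tsv(path, truth: TruthTable) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ binned matrix

def write_binned(path, binned: BinnedSpectraMatrix, sidecar=None) -> None:
    df = pd.DataFrame(binned.values, index=binned.subjects,
                      columns=[f"{x:.3f}" for x in binned.labels])
    df.index.name = "subject"
    df.to_csv(path, sep="\t", na_rep="NA")
    meta = {
        "left": [float(x) for x in binned.bins["left"]],
        "right": [float(x) for x in binned.bins["right"]],
        "label": [float(x) for x in binned.labels],
        "excluded": [bool(x) for x in binned.excluded],
        "log_transformed": binned.log_transformed,
        "outliers_removed": binned.outliers_removed,
        "water_masked": binned.water_masked,
    }
    sidecar = Path(str(path) + ".json" if sidecar is None else sidecar)
    sidecar.write_text(json.dumps(meta))


def read_binned(path, sidecar=None) -> BinnedSpectraMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    sidecar = Path(str(path) + ".json" if sidecar is None else sidecar)
    meta = json.loads(sidecar.read_text())
    bins = pd.DataFrame({"left": meta["left"], "right": meta["right"],
                         "label": meta["label"]})
    return BinnedSpectraMatrix(
        subjects=[str(s) for s in df.index], bins=bins,
        values=df.to_numpy(dtype=float),
        excluded=np.array(meta["excluded"], dtype=bool),
        log_transformed=meta["log_transformed"],
        outliers_removed=meta["outliers_removed"],
        water_masked=meta["water_masked"],
    )
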