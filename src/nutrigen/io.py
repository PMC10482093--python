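"""Readers and writers for the interchange formats.

Canonical tabular dialect: tab-separated, UTF-8, one header row, "." for
missing. Genotypes travel as PLINK ``.raw``-style additive-dosage text
(FID, IID, PAT, MAT, SEX, PHENOTYPE, then one ``SNP_ALLELE`` column per
variant, the suffix naming the counted allele) or as VCF (dosage from GT;
read through cyvcf2). PRS weights are a (snp, effect_allele, beta) TSV,
gene locations a (gene, chrom, start, end) TSV, gene sets GMT lines.
Missing genotype policy: per-SNP mean imputation with the count logged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("nutrigen")

MISSING = "."


# ------------------------------------------------------------------- TSVs

def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=MISSING)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=[MISSING],
                       keep_default_na=False)


def read_prs_weights(path) -> pd.DataFrame:
    """TSV with columns snp, effect_allele (A1), beta — GWAS summary layout."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    ren = {}
    for want, aliases in (("snp", ("snp", "id", "rsid")),
                          ("effect_allele", ("effect_allele", "a1", "ea")),
                          ("beta", ("beta", "effect", "b"))):
        for a in aliases:
            if a in cols:
                ren[cols[a]] = want
                break
        else:
            raise ValueError(f"PRS weight file missing a {want} column")
    df = df.rename(columns=ren)
    if df["snp"].duplicated().any():
        raise ValueError("duplicate SNP ids in PRS weight file")
    return df[["snp", "effect_allele", "beta"]]


def read_gene_locations(path) -> pd.DataFrame:
    """TSV with columns gene, chrom, start, end (1-based closed, GRCh37-style)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"gene", "chrom", "start", "end"}
    if not need.issubset(df.columns):
        raise ValueError(f"gene location file must have columns {sorted(need)}")
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line — name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs >=3 fields")
            name, _desc, *genes = parts
            sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ------------------------------------------------------------- PLINK .raw

def write_raw(dosages: pd.DataFrame, snp_info: pd.DataFrame, path,
              phenotype: pd.Series | None = None) -> None:
    """PLINK ``.raw``-style additive dosage text (space-separated)."""
    header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    snp_cols = [f"{snp}_{snp_info.loc[snp, 'a1']}" for snp in dosages.columns]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(" ".join(header + snp_cols) + "\n")
        pheno = (phenotype.reindex(dosages.index) + 1
                 if phenotype is not None else None)  # PLINK 1/2 coding
        for i, (iid, row) in enumerate(dosages.iterrows()):
            ph = "-9" if pheno is None else str(int(pheno.iloc[i]))
            vals = ["NA" if pd.isna(v) else str(int(v)) for v in row]
            fh.write(" ".join([str(iid), str(iid), "0", "0", "0", ph] + vals) + "\n")


def read_raw(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read ``.raw`` dosages; returns (dosages, snp_info with counted allele).

    Missing genotypes (NA) are mean-imputed per SNP; the imputation count
    is logged, never silent.
    """
    df = pd.read_csv(path, sep=r"\s+")
    fixed = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[: len(fixed)]) != fixed:
        raise ValueError(f"malformed .raw header in {path}")
    snp_cols = list(df.columns[len(fixed):])
    snps, a1 = [], []
    for c in snp_cols:
        if "_" not in c:
            raise ValueError(f"malformed SNP column {c!r} (expected SNP_ALLELE)")
        s, a = c.rsplit("_", 1)
        snps.append(s)
        a1.append(a)
    dos = df[snp_cols].astype(float)
    n_missing = int(dos.isna().sum().sum())
    if n_missing:
        logger.info("read_raw: mean-imputing %d missing genotypes", n_missing)
        dos = dos.fillna(dos.mean())
    dos.columns = snps
    dos.index = pd.Index(df["IID"].astype(str), name="iid")
    snp_info = pd.DataFrame({"snp": snps, "a1": a1}).set_index("snp")
    return dos, snp_info


# -------------------------------------------------------------------- VCF

def write_vcf(dosages: pd.DataFrame, snp_info: pd.DataFrame, path) -> None:
    """Minimal diploid GT-only VCF for the dosage matrix (REF=a2, ALT=a1,
    dosage counts ALT alleles)."""
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    samples = [str(s) for s in dosages.index]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(snp_info["chrom"].astype(str).unique(), key=str):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for snp in dosages.columns:
            info = snp_info.loc[snp]
            d = dosages[snp]
            gts = "\t".join("./." if pd.isna(v) else gt_of[int(v)] for v in d)
            fh.write(f"{info['chrom']}\t{int(info['pos'])}\t{snp}\t"
                     f"{info['a2']}\t{info['a1']}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dosage (ALT-allele count from GT) and SNP metadata via cyvcf2.

    Missing or mixed-ploidy genotypes are mean-imputed per SNP with the
    count logged; a variant with more than one ALT allele is an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps, chroms, pos, a1, a2, cols = [], [], [], [], [], []
    n_missing = 0
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multiallelic variant {var.ID} not supported")
        gts = np.array([g[:2] for g in var.genotypes], dtype=float)
        if (np.array([len(g) for g in var.genotypes]) < 3).any():
            raise ValueError(f"mixed ploidy at {var.ID}")
        d = np.where((gts < 0).any(axis=1), np.nan, gts.clip(0).sum(axis=1))
        miss = np.isnan(d)
        if miss.any():
            n_missing += int(miss.sum())
            d[miss] = np.nanmean(d) if not miss.all() else 0.0
        snps.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        pos.append(int(var.POS))
        a1.append(var.ALT[0])
        a2.append(var.REF)
        cols.append(d)
    if n_missing:
        logger.info("read_vcf: mean-imputed %d missing genotypes", n_missing)
    dosages = pd.DataFrame(np.column_stack(cols) if cols else np.empty((len(samples), 0)),
                           index=pd.Index(samples, name="iid"), columns=snps)
    snp_info = pd.DataFrame({"snp": snps, "chrom": chroms, "pos": pos,
                             "a1": a1, "a2": a2}).set_index("snp")
    return dosages, snp_info


def read_genotypes(path, format: str | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dispatch on ``format`` ('raw' or 'vcf'; inferred from the suffix)."""
    path = Path(path)
    fmt = format or ("vcf" if path.suffix == ".vcf" else "raw")
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "raw":
        return read_raw(path)
    raise ValueError(f"unknown genotype format {fmt!r}")
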