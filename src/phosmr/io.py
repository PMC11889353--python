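"""Readers and writers for the on-disk cohort formats.

Conventions: VCF 4.2 for genotypes (GT mapped to dosages 0/1/2, missing
recorded as NaN; biallelic autosomal SNPs only), tab-separated tables for
everything else.  Coordinates are 1-based inclusive at every interface.
Omics matrices are features x samples with a leading feature-id column
and a ``gene`` column mapping each feature to its host gene.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("phosmr")

NA_TOKENS = {"", "NA", "nan", "NaN"}
SEX_CHROMS = {"X", "Y", "chrX", "chrY"}

__all__ = [
    "read_genotypes",
    "read_genotypes_vcf",
    "read_genotypes_tsv",
    "write_genotypes_vcf",
    "write_genotypes_tsv",
    "read_matrix",
    "write_matrix",
    "read_covariates",
    "read_regions",
    "read_priors",
    "load_cohort",
    "write_run_report",
]


def read_genotypes_vcf(path, drop_sex_chroms: bool = True, strict: bool = False):
    """Read a VCF into (dosage matrix, SNP annotation, sample ids).

    GT fields map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2 (phased separators
    accepted); ``./.`` becomes NaN.  Non-biallelic or non-SNP records are
    skipped with a logged count (or raise in strict mode); sex-chromosome
    records are excluded by default.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ann = [], []
    skipped = {"non_biallelic": 0, "sex_chrom": 0, "half_missing": 0}
    for var in vcf:
        if len(var.ALT) != 1 or var.is_indel:
            if strict:
                raise ValueError(
                    f"non-biallelic SNP record at {var.CHROM}:{var.POS} in strict mode"
                )
            skipped["non_biallelic"] += 1
            continue
        if drop_sex_chroms and var.CHROM in SEX_CHROMS:
            skipped["sex_chrom"] += 1
            continue
        dosages = np.empty(len(samples))
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 and b < 0:
                dosages[i] = np.nan
            elif a < 0 or b < 0:
                raise ValueError(
                    f"half-missing genotype at {var.CHROM}:{var.POS} sample {samples[i]}"
                )
            elif max(a, b) > 1:
                raise ValueError(f"multi-allelic genotype at {var.CHROM}:{var.POS}")
            else:
                dosages[i] = a + b
        rows.append(dosages)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        ann.append({"id": vid, "chrom": var.CHROM, "pos": var.POS})
    for key, count in skipped.items():
        if count:
            logger.warning("read_genotypes_vcf: skipped %d %s records", count, key)
    G = np.array(rows).T if rows else np.empty((len(samples), 0))
    return G, pd.DataFrame(ann, columns=["id", "chrom", "pos"]), samples


def read_genotypes_tsv(path):
    """Read a dosage TSV (columns: snp_id, chrom, pos, then one per sample)."""
    df = pd.read_csv(path, sep="\t", na_values=list(NA_TOKENS), keep_default_na=False)
    required = ["snp_id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"dosage TSV must start with columns {required}")
    samples = list(df.columns[3:])
    G = df[samples].to_numpy(float).T
    ok = np.isnan(G) | np.isin(G, (0.0, 1.0, 2.0))
    if not ok.all():
        raise ValueError("dosage values must be 0/1/2 or missing")
    snps = df[required].rename(columns={"snp_id": "id"})
    return G, snps, samples


def read_genotypes(path, **kwargs):
    """Dispatch on extension: ``.vcf`` or a dosage ``.tsv``."""
    path = Path(path)
    if path.suffix == ".vcf":
        return read_genotypes_vcf(path, **kwargs)
    return read_genotypes_tsv(path)


def write_genotypes_vcf(path, genotypes, snps: pd.DataFrame, samples) -> None:
    """Write dosages as a minimal sorted VCF 4.2 (GT only)."""
    G = np.asarray(genotypes, dtype=float)
    order = np.lexsort((snps["pos"].to_numpy(), snps["chrom"].to_numpy()))
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(snps["chrom"].to_numpy()[order]):
            max_pos = int(snps.loc[snps["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1_000_000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j in order:
            row = snps.iloc[j]
            gts = "\t".join(
                gt_map.get(v, "./.") if np.isfinite(v) else "./." for v in G[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_genotypes_tsv(path, genotypes, snps: pd.DataFrame, samples) -> None:
    G = np.asarray(genotypes, dtype=float)
    out = snps.rename(columns={"id": "snp_id"}).copy()
    for i, s in enumerate(samples):
        col = G[i, :]
        out[s] = [("" if not np.isfinite(v) else str(int(v))) for v in col]
    out.to_csv(path, sep="\t", index=False)


def read_matrix(path):
    """Read an omics matrix TSV -> (features x samples frame, gene map)."""
    df = pd.read_csv(path, sep="\t", na_values=list(NA_TOKENS), keep_default_na=False)
    feature_col = df.columns[0]
    if "gene" not in df.columns:
        raise ValueError("omics matrix requires a 'gene' column")
    df = df.set_index(feature_col)
    df.index.name = None
    gene = df.pop("gene")
    gene.name = None
    return df.astype(float), gene


def write_matrix(path, matrix: pd.DataFrame, feature_col: str, gene: pd.Series) -> None:
    out = matrix.copy()
    out.insert(0, "gene", gene.reindex(out.index))
    out.rename_axis(feature_col).reset_index().to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


def read_covariates(path) -> pd.DataFrame:
    """Covariate TSV: sample_id column followed by numeric covariates."""
    df = pd.read_csv(path, sep="\t", na_values=list(NA_TOKENS), keep_default_na=False)
    if df.columns[0] != "sample_id":
        raise ValueError("covariates TSV must start with a sample_id column")
    return df.set_index("sample_id").astype(float)


def read_regions(path) -> pd.DataFrame:
    """Gene regions TSV (gene, chrom, start, end), 1-based inclusive."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"regions TSV requires columns {sorted(required)}")
    df = df.set_index("gene")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def read_priors(path) -> set:
    """Prior SNP list: TSV with a snp_id column (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t")
    col = "snp_id" if "snp_id" in df.columns else df.columns[0]
    return set(df[col].astype(str))


def load_cohort(
    genotypes_path,
    phospho_path,
    protein_path,
    covariates_path,
    regions_path,
    priors_path,
    **geno_kwargs,
):
    """Assemble a :class:`~phosmr.screen.CohortData` from files.

    Sample order follows the genotype file; omics and covariate samples
    are reconciled against it, with dropped samples logged.
    """
    from .screen import CohortData

    G, snps, samples = read_genotypes(genotypes_path, **geno_kwargs)
    phospho, phospho_gene = read_matrix(phospho_path)
    protein, protein_gene = read_matrix(protein_path)
    covariates = read_covariates(covariates_path)

    keep = [s for s in samples if s in phospho.columns and s in protein.columns and s in covariates.index]
    dropped = [s for s in samples if s not in keep]
    if dropped:
        logger.warning("load_cohort: dropping %d samples absent from some table", len(dropped))
        idx = [samples.index(s) for s in keep]
        G = G[idx, :]
    for name, m in (("phospho", phospho), ("protein", protein)):
        extra = set(m.columns) - set(keep)
        if extra:
            logger.warning("load_cohort: %s has %d unknown sample columns (dropped)", name, len(extra))
    phospho = phospho[keep]
    protein = protein[keep]
    covariates = covariates.loc[keep].reset_index(drop=True)

    return CohortData(
        genotypes=G,
        snps=snps,
        phospho=phospho,
        phospho_gene=phospho_gene,
        protein=protein,
        protein_gene=protein_gene,
        covariates=covariates,
        gene_regions=read_regions(regions_path),
        prior_snps=read_priors(priors_path),
        sample_ids=keep,
    )


def write_run_report(path, **fields) -> None:
    """JSON provenance report (package version, parameters, stage counts)."""
    from . import __version__

    payload = {"phosmr_version": __version__}
    payload.update(fields)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(json.dumps(payload, indent=2, default=_default))
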