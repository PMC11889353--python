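"""Synthetic multiomics cohort generator with planted causal links.

Emulates the statistical structure the screening pipeline assumes: genes
placed on synthetic chromosomes with non-overlapping cis windows, cis
SNPs in LD blocks driving each phosphosite, a prior list covering a
configurable fraction of the true instruments, planted phosphosite ->
protein causal effects, a shared latent confounder, covariates with
modest effects, and missing-completely-at-random omics values.

LD is generated by thresholding correlated latent Gaussians per allele
draw; the realized genotype correlation is somewhat below the latent
``ld_block_r``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .screen import CohortData

__all__ = ["FixtureSpec", "make_cohort", "write_fixture"]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic cohort.

    Defaults describe a strong-cis-pQTL regime: 200 samples, 12 genes on
    two chromosomes, six cis SNPs per gene of which three (the prior
    subset) drive the phosphosite with effects U(0.8, 1.2), eight planted
    links of effect 0.6, confounder loadings 0.75, 5% missing omics
    values.
    """

    n_samples: int = 200
    n_genes: int = 12
    snps_per_gene: int = 6
    n_causal_snps: int = 3  # per gene; these are the prior-eligible drivers
    ld_block_r: float = 0.3
    maf: float = 0.3
    n_causal_links: int = 8
    theta_causal: float = 0.6
    gamma_low: float = 0.8
    gamma_high: float = 1.2
    prior_coverage: float = 1.0
    missing_rate_omics: float = 0.05
    theta_ux: float = 0.75
    theta_uy: float = 0.75
    noise_sd: float = 1.0
    gene_length: int = 10_000
    gene_spacing: int = 2_600_000
    cis_window: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ld_block_r", "prior_coverage", "missing_rate_omics"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not np.isfinite(self.theta_causal):
            raise ValueError("theta_causal must be finite")
        if self.n_causal_snps > self.snps_per_gene:
            raise ValueError("n_causal_snps cannot exceed snps_per_gene")
        if self.n_causal_links > self.n_genes:
            raise ValueError("n_causal_links cannot exceed n_genes")
        if self.gene_spacing <= 2 * self.cis_window + self.gene_length:
            raise ValueError(
                "cis windows would overlap; increase gene_spacing beyond "
                f"{2 * self.cis_window + self.gene_length} bp"
            )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _latent_corr_for(target_r: float, maf: float) -> float:
    """Latent-Gaussian correlation whose thresholded alleles correlate ``target_r``.

    Thresholding attenuates correlation (the phi coefficient of a
    dichotomized bivariate normal is below its latent correlation), so the
    requested genotype-level r is mapped back through the tetrachoric
    relation numerically.
    """
    if target_r <= 0:
        return 0.0
    thr = stats.norm.ppf(maf)
    pq = maf * (1.0 - maf)

    def phi_coeff(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf([thr, thr], cov=[[1, rho], [rho, 1]])
        return (p11 - maf * maf) / pq

    from scipy.optimize import brentq

    if phi_coeff(0.999) <= target_r:
        return 0.999
    return float(brentq(lambda r: phi_coeff(r) - target_r, 0.0, 0.999, xtol=1e-6))


def _ld_block_genotypes(
    n: int, m: int, r: float, maf: float, rng: np.random.Generator
) -> np.ndarray:
    """Genotypes for one LD block via correlated latent Gaussians.

    Each of the two allele draws shares a block factor; latent values
    below the maf quantile carry the alternate allele.  The block-factor
    loading is tetrachorically corrected so the realized pairwise
    genotype correlation is approximately ``r``.
    """
    thr = stats.norm.ppf(maf)
    rho = _latent_corr_for(r, maf)
    g = np.zeros((n, m), dtype=np.int8)
    for _ in range(2):
        common = rng.normal(size=(n, 1))
        z = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * rng.normal(size=(n, m))
        g += z < thr
    return g


def make_cohort(spec: FixtureSpec) -> tuple[CohortData, pd.DataFrame]:
    """Generate a cohort and its planted-link truth table."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    genes = [f"G{k:02d}" for k in range(spec.n_genes)]

    # genome placement: genes alternate between two synthetic chromosomes,
    # spaced so that +/- cis_window windows never overlap
    regions, snp_rows, geno_blocks = [], [], []
    causal_cols: dict[str, list[int]] = {}
    col = 0
    for k, gene in enumerate(genes):
        chrom = f"chr{k % 2 + 1}"
        start = 1_500_000 + (k // 2) * spec.gene_spacing
        end = start + spec.gene_length - 1
        regions.append({"gene": gene, "chrom": chrom, "start": start, "end": end})
        block = _ld_block_genotypes(n, spec.snps_per_gene, spec.ld_block_r, spec.maf, rng)
        geno_blocks.append(block)
        positions = np.sort(
            rng.choice(np.arange(start - 50_000, end + 50_000), spec.snps_per_gene, replace=False)
        )
        cols = []
        for j in range(spec.snps_per_gene):
            snp_rows.append(
                {
                    "id": f"{chrom}:{positions[j]}",
                    "chrom": chrom,
                    "pos": int(positions[j]),
                    "gene": gene,
                }
            )
            cols.append(col)
            col += 1
        causal_cols[gene] = list(rng.choice(cols, spec.n_causal_snps, replace=False))

    G = np.concatenate(geno_blocks, axis=1)
    snps = pd.DataFrame(snp_rows)
    gene_regions = pd.DataFrame(regions).set_index("gene")

    # prior list: a prior_coverage fraction of each gene's true drivers
    prior: set[str] = set()
    for gene in genes:
        k = int(round(spec.prior_coverage * len(causal_cols[gene])))
        if k:
            chosen = rng.choice(causal_cols[gene], k, replace=False)
            prior.update(snps["id"].iloc[chosen])

    # covariates
    age = rng.normal(60, 10, size=n).round(1)
    sex = rng.integers(0, 2, size=n)
    smoking = rng.integers(0, 2, size=n)
    covariates = pd.DataFrame({"age": age, "sex": sex, "smoking": smoking})
    cov_shift = 0.01 * (age - 60) + 0.2 * sex + 0.2 * smoking

    U = rng.normal(size=n)

    # phosphosites: one per gene, driven by its causal cis SNPs
    site_ids = [f"{g}_pS{rng.integers(10, 999)}" for g in genes]
    phospho = np.empty((spec.n_genes, n))
    for k, gene in enumerate(genes):
        gamma = rng.uniform(spec.gamma_low, spec.gamma_high, size=spec.n_causal_snps)
        phospho[k] = (
            G[:, causal_cols[gene]] @ gamma
            + spec.theta_ux * U
            + cov_shift
            + rng.normal(0, spec.noise_sd, size=n)
        )

    # planted links: distinct target genes, never the site's own gene
    links = []
    targets = rng.permutation(spec.n_genes)
    sources = rng.permutation(spec.n_genes)
    si = 0
    for t in targets:
        if len(links) == spec.n_causal_links:
            break
        while sources[si % spec.n_genes] == t:
            si += 1
        links.append((sources[si % spec.n_genes], t))
        si += 1
    truth = pd.DataFrame(
        {
            "phosphosite": [site_ids[s] for s, _ in links],
            "protein": [genes[t] for _, t in links],
            "theta": spec.theta_causal,
        }
    )

    protein = np.empty((spec.n_genes, n))
    target_of = {t: s for s, t in links}
    for k in range(spec.n_genes):
        base = spec.theta_uy * U + cov_shift + rng.normal(0, spec.noise_sd, size=n)
        if k in target_of:
            base = base + spec.theta_causal * phospho[target_of[k]]
        protein[k] = base

    # MCAR missingness on both omics layers
    def _mask(m: np.ndarray) -> np.ndarray:
        out = m.copy()
        out[rng.random(m.shape) < spec.missing_rate_omics] = np.nan
        return out

    sample_ids = [f"S{i:03d}" for i in range(n)]
    phospho_df = pd.DataFrame(_mask(phospho), index=site_ids, columns=sample_ids)
    protein_df = pd.DataFrame(_mask(protein), index=genes, columns=sample_ids)

    cohort = CohortData(
        genotypes=G.astype(float),
        snps=snps,
        phospho=phospho_df,
        phospho_gene=pd.Series(genes, index=site_ids),
        protein=protein_df,
        protein_gene=pd.Series(genes, index=genes),
        covariates=covariates,
        gene_regions=gene_regions,
        prior_snps=prior,
        sample_ids=sample_ids,
    )
    return cohort, truth


def write_fixture(cohort: CohortData, truth: pd.DataFrame, out_dir: str | Path) -> dict:
    """Write a cohort to the on-disk formats the CLI consumes.

    Emits genotypes.vcf, phospho.tsv, protein.tsv, covariates.tsv,
    regions.tsv, prior_snps.tsv and truth.tsv; re-reading with
    :func:`phosmr.io.load_cohort` reproduces the in-memory objects.
    """
    from . import io as pio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "phospho": out / "phospho.tsv",
        "protein": out / "protein.tsv",
        "covariates": out / "covariates.tsv",
        "regions": out / "regions.tsv",
        "priors": out / "prior_snps.tsv",
        "truth": out / "truth.tsv",
    }
    pio.write_genotypes_vcf(paths["vcf"], cohort.genotypes, cohort.snps, cohort.sample_ids)
    pio.write_matrix(paths["phospho"], cohort.phospho, feature_col="phosphosite", gene=cohort.phospho_gene)
    pio.write_matrix(paths["protein"], cohort.protein, feature_col="protein", gene=cohort.protein_gene)
    cov = cohort.covariates.copy()
    cov.insert(0, "sample_id", cohort.sample_ids)
    cov.to_csv(paths["covariates"], sep="\t", index=False)
    cohort.gene_regions.reset_index().to_csv(paths["regions"], sep="\t", index=False)
    pd.DataFrame({"snp_id": sorted(cohort.prior_snps)}).to_csv(paths["priors"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
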