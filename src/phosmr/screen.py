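"""End-to-end cohort screening for phosphosite -> protein causal links.

Pipeline order, applied to a :class:`CohortData`:

1. drop phosphosites and proteins with missing-value fraction above 90%;
2. drop SNPs with variation rate below 10% or minor allele frequency at
   or below 0.01;
3. prefilter candidate (phosphosite, protein) pairs by Pearson
   correlation (p < 0.05);
4. per phosphosite, build the instrument set: cis SNPs (host gene plus/minus
   1 Mb) intersected with the prior phosphorylation-related SNP list,
   kept when the covariate-adjusted SNP-phosphosite regression gives
   p < 0.05, then greedily LD-pruned at r^2 > 0.2;
5. per surviving pair, covariate-adjusted SNP-protein regressions feed a
   fixed-effects IVW estimate;
6. BH adjustment across all tested pairs; links with adjusted p < 0.05
   are flagged significant.

Every stage logs its in/out counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import adjusted_regression, pearson_test
from .ivsel import cis_filter, filter_features, filter_snps, ld_prune
from .mr import MREstimate, bh_adjust, ivw

__all__ = ["CohortData", "ScreenParams", "screen", "export_network"]


@dataclass
class CohortData:
    """A small multiomics cohort ready for screening.

    All matrices share one ordered sample list.  ``genotypes`` is
    (samples x SNPs) with dosages 0/1/2 (NaN for missing); ``snps`` is an
    annotation frame with columns id, chrom, pos aligned to the genotype
    columns.  Omics matrices are features x samples, log-scale, NaN for
    missing; ``phospho_gene`` / ``protein_gene`` map feature ids to host
    gene ids; ``gene_regions`` maps gene ids to (chrom, start, end),
    1-based inclusive.
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    phospho: pd.DataFrame
    phospho_gene: pd.Series
    protein: pd.DataFrame
    protein_gene: pd.Series
    covariates: pd.DataFrame
    gene_regions: pd.DataFrame
    prior_snps: set = field(default_factory=set)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = np.asarray(self.genotypes).shape[0]
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match genotype rows")
        for name, m in (("phospho", self.phospho), ("protein", self.protein)):
            if list(m.columns) != list(self.sample_ids):
                raise ValueError(f"{name} columns must equal the shared sample list")
        if len(self.covariates) != n:
            raise ValueError("covariates must have one row per sample")
        g = np.asarray(self.genotypes, dtype=float)
        vals = g[np.isfinite(g)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype dosages must be 0/1/2 (or missing)")
        missing_genes = set(self.phospho_gene) - set(self.gene_regions.index)
        if missing_genes:
            raise ValueError(f"phosphosite host genes missing from gene_regions: {sorted(missing_genes)[:5]}")


@dataclass
class ScreenParams:
    """Thresholds of the screening pipeline (defaults as documented above)."""

    max_missing: float = 0.90
    variation_min: float = 0.10
    maf_min: float = 0.01
    prefilter_alpha: float = 0.05
    iv_alpha: float = 0.05
    r2_max: float = 0.2
    cis_window: int = 1_000_000
    link_alpha: float = 0.05
    min_complete: int = 10
    min_iv: int = 1
    restrict_same_gene_pairs: bool = False  # optionally only host-gene-matched pairs


def _site_instruments(
    cohort: CohortData,
    site: str,
    G: np.ndarray,
    snps: pd.DataFrame,
    covmat: np.ndarray,
    params: ScreenParams,
    log: dict,
):
    """Instrument ids for one phosphosite (steps 4a-4c)."""
    gene = cohort.phospho_gene[site]
    region = cohort.gene_regions.loc[gene]
    in_cis = cis_filter(
        snps["chrom"].to_numpy(),
        snps["pos"].to_numpy(),
        (region["chrom"], region["start"], region["end"]),
        window=params.cis_window,
    )
    cand = np.flatnonzero(in_cis & snps["id"].isin(cohort.prior_snps).to_numpy())
    log["iv_candidates"] += len(cand)
    if cand.size == 0:
        return []
    x = cohort.phospho.loc[site].to_numpy(float)
    keep, pvals = [], []
    for j in cand:
        mask = np.isfinite(G[:, j]) & np.isfinite(x)
        if mask.sum() < max(params.min_complete, covmat.shape[1] + 3):
            continue
        res = adjusted_regression(G[:, j], x, covmat)
        if not res.degenerate and res.pvalue < params.iv_alpha:
            keep.append(j)
            pvals.append(res.pvalue)
    log["iv_associated"] += len(keep)
    if not keep:
        return []
    kept_ids = ld_prune(
        G[:, keep],
        pvals,
        snp_ids=snps["id"].to_numpy()[keep],
        r2_max=params.r2_max,
    )
    log["iv_pruned"] += len(kept_ids)
    return kept_ids


def screen(
    cohort: CohortData, params: ScreenParams | None = None
) -> tuple[pd.DataFrame, dict]:
    """Run the full screening pipeline.

    Returns ``(links, stage_log)``: one row per tested pair with the IVW
    estimate, BH-adjusted p-value, instrument ids, and prefilter
    correlation; and a dict of per-stage in/out counts.
    """
    params = params or ScreenParams()
    log: dict = {}

    sites = filter_features(cohort.phospho, params.max_missing)
    prots = filter_features(cohort.protein, params.max_missing)
    log["phosphosites_in"] = cohort.phospho.shape[0]
    log["phosphosites_kept"] = len(sites)
    log["proteins_in"] = cohort.protein.shape[0]
    log["proteins_kept"] = len(prots)

    G = np.asarray(cohort.genotypes, dtype=float)
    snp_ids_kept = set(
        filter_snps(
            G,
            snp_ids=cohort.snps["id"].to_numpy(),
            maf_min=params.maf_min,
            variation_min=params.variation_min,
        )
    )
    keep_mask = cohort.snps["id"].isin(snp_ids_kept).to_numpy()
    G = G[:, keep_mask]
    snps = cohort.snps.loc[keep_mask].reset_index(drop=True)
    log["snps_in"] = cohort.snps.shape[0]
    log["snps_kept"] = int(keep_mask.sum())

    covmat = cohort.covariates.to_numpy(float)

    # step 3: Pearson prefilter over candidate pairs
    pairs = []
    for site in sites:
        for prot in prots:
            if (
                params.restrict_same_gene_pairs
                and cohort.phospho_gene[site] != cohort.protein_gene[prot]
            ):
                continue
            x = cohort.phospho.loc[site].to_numpy(float)
            y = cohort.protein.loc[prot].to_numpy(float)
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < max(params.min_complete, 4):
                continue
            try:
                r, p = pearson_test(x, y)
            except ValueError:
                continue
            if p < params.prefilter_alpha:
                pairs.append((site, prot, r, p))
    log["pairs_prefiltered"] = len(pairs)

    # step 4: per-phosphosite instrument sets (cached across proteins)
    iv_cache: dict[str, list] = {}
    iv_log = {"iv_candidates": 0, "iv_associated": 0, "iv_pruned": 0}
    for site in {s for s, *_ in pairs}:
        iv_cache[site] = _site_instruments(cohort, site, G, snps, covmat, params, iv_log)
    log.update(iv_log)

    # step 5: IVW per pair with instruments
    id_to_col = {s: j for j, s in enumerate(snps["id"])}
    rows = []
    for site, prot, r, pre_p in pairs:
        ivs = iv_cache.get(site, [])
        if len(ivs) < max(params.min_iv, 1):
            continue
        x = cohort.phospho.loc[site].to_numpy(float)
        y = cohort.protein.loc[prot].to_numpy(float)
        bx, by, sy, used = [], [], [], []
        for s in ivs:
            j = id_to_col[s]
            rx = adjusted_regression(G[:, j], x, covmat)
            ry = adjusted_regression(G[:, j], y, covmat)
            if rx.degenerate or ry.degenerate or rx.beta == 0 or ry.se <= 0:
                continue
            if min(rx.n_used, ry.n_used) < params.min_complete:
                continue
            bx.append(rx.beta)
            by.append(ry.beta)
            sy.append(ry.se)
            used.append(s)
        if len(used) < max(params.min_iv, 1):
            continue
        est = ivw(np.array(bx), np.array(by), np.array(sy), iv_ids=used, model="default")
        rows.append(
            {
                "phosphosite": site,
                "protein": prot,
                "theta_hat": est.theta_hat,
                "se": est.se,
                "z": est.z,
                "pvalue": est.pvalue,
                "n_iv": est.n_iv,
                "iv_ids": ",".join(map(str, used)),
                "prefilter_r": r,
                "prefilter_p": pre_p,
                "same_gene": cohort.phospho_gene[site] == cohort.protein_gene[prot],
            }
        )
    links = pd.DataFrame(
        rows,
        columns=[
            "phosphosite",
            "protein",
            "theta_hat",
            "se",
            "z",
            "pvalue",
            "n_iv",
            "iv_ids",
            "prefilter_r",
            "prefilter_p",
            "same_gene",
        ],
    )
    log["pairs_tested"] = len(links)

    # step 6: BH over all tested pairs
    if len(links):
        links["p_adj"] = bh_adjust(links["pvalue"].to_numpy())
        links["significant"] = links["p_adj"] < params.link_alpha
        links = links.sort_values("p_adj", kind="stable").reset_index(drop=True)
    else:
        links["p_adj"] = pd.Series(dtype=float)
        links["significant"] = pd.Series(dtype=bool)
    log["links_significant"] = int(links["significant"].sum()) if len(links) else 0
    return links, log


def export_network(
    links: pd.DataFrame, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Significant links as an edge list plus a node-degree table.

    When ``out_dir`` is given, writes ``edges.tsv`` and ``nodes.tsv``.
    """
    sig = links[links.get("significant", pd.Series(dtype=bool))] if len(links) else links
    edges = pd.DataFrame(
        {
            "source": sig["phosphosite"] if len(sig) else pd.Series(dtype=str),
            "target": sig["protein"] if len(sig) else pd.Series(dtype=str),
            "weight": sig["theta_hat"] if len(sig) else pd.Series(dtype=float),
            "p_adj": sig["p_adj"] if len(sig) else pd.Series(dtype=float),
        }
    ).reset_index(drop=True)
    deg = pd.concat(
        [
            edges.groupby("source").size().rename("out_degree"),
            edges.groupby("target").size().rename("in_degree"),
        ],
        axis=1,
    ).fillna(0)
    nodes = deg.astype(int).rename_axis("node").reset_index()
    nodes["degree"] = nodes["out_degree"] + nodes["in_degree"]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        edges.to_csv(out_dir / "edges.tsv", sep="\t", index=False)
        nodes.to_csv(out_dir / "nodes.tsv", sep="\t", index=False)
    return edges, nodes
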