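"""Instrument selection strategies, SNP/feature filters, and LD pruning.

Four selection strategies are implemented:

``dual``
    the dual-evidence rule: internal support (raw SNP-exposure p < 0.05
    in the small cohort) AND external support (Bonferroni-significant in
    an external GWAS, and/or membership in a prior list of
    phosphorylation-related SNPs);
``fdr``
    all SNPs with BH-adjusted internal p below a threshold;
``minp``
    the single smallest-p SNP among the BH-significant ones;
``gwas``
    Bonferroni-significant SNPs in the external GWAS only.

Cohort-mode utilities cover the cis-window filter (gene boundary plus/minus
1 Mb by default), minor-allele-frequency and variation-rate SNP filters,
feature missingness filtering, and greedy p-value-ranked LD pruning at a
squared-correlation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import SummaryStats
from .mr import bh_adjust

__all__ = [
    "ExternalEvidence",
    "IVSet",
    "select_dual_evidence",
    "select_fdr",
    "select_min_p",
    "select_gwas",
    "ld_prune",
    "cis_filter",
    "filter_snps",
    "filter_features",
]


@dataclass
class ExternalEvidence:
    """External support for SNP-exposure relevance.

    At least one evidence channel must be present: GWAS p-values
    (simulation mode) and/or prior-list membership (cohort mode).
    ``n_tests`` is the Bonferroni denominator; it defaults to the number
    of SNPs carried.
    """

    snp_ids: np.ndarray
    gwas_pvalue: np.ndarray | None = None
    prior_member: np.ndarray | None = None
    n_tests: int | None = None

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        if self.gwas_pvalue is None and self.prior_member is None:
            raise ValueError("at least one of gwas_pvalue / prior_member required")
        if self.gwas_pvalue is not None:
            self.gwas_pvalue = np.asarray(self.gwas_pvalue, dtype=float)
            if len(self.gwas_pvalue) != len(self.snp_ids):
                raise ValueError("gwas_pvalue length mismatch")
            if self.n_tests is None:
                self.n_tests = len(self.snp_ids)
        if self.prior_member is not None:
            self.prior_member = np.asarray(self.prior_member, dtype=bool)
            if len(self.prior_member) != len(self.snp_ids):
                raise ValueError("prior_member length mismatch")


@dataclass
class IVSet:
    """A selected instrument set with per-SNP provenance of passed criteria."""

    snp_ids: list
    strategy: str
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP identifiers in IVSet")

    def __len__(self) -> int:
        return len(self.snp_ids)


def _check_aligned(internal: SummaryStats, external: ExternalEvidence) -> None:
    if len(internal) != len(external.snp_ids) or not np.array_equal(
        np.asarray(internal.snp_ids), external.snp_ids
    ):
        raise ValueError("internal and external SNP identifiers are misaligned")


def select_dual_evidence(
    internal: SummaryStats,
    external: ExternalEvidence,
    alpha_internal: float = 0.05,
    alpha_external: float = 0.05,
) -> IVSet:
    """Instruments supported by both internal and external evidence.

    Internal: raw small-cohort SNP-exposure p < ``alpha_internal``.
    External: GWAS Bonferroni (raw p < ``alpha_external / n_tests``)
    when GWAS p-values are supplied, and prior-list membership when a
    prior channel is supplied; all present channels must agree (AND).
    """
    _check_aligned(internal, external)
    keep = internal.pvalue < alpha_internal
    prov = {"internal": keep.copy()}
    if external.gwas_pvalue is not None:
        gw = external.gwas_pvalue < alpha_external / external.n_tests
        prov["gwas_bonferroni"] = gw
        keep = keep & gw
    if external.prior_member is not None:
        prov["prior"] = external.prior_member
        keep = keep & external.prior_member
    provenance = pd.DataFrame(prov, index=np.asarray(internal.snp_ids))
    return IVSet(list(np.asarray(internal.snp_ids)[keep]), "dual", provenance)


def select_fdr(internal: SummaryStats, q: float = 0.05) -> IVSet:
    """All SNPs with BH-adjusted internal p < ``q``."""
    adj = bh_adjust(internal.pvalue)
    keep = adj < q
    prov = pd.DataFrame({"bh_significant": keep}, index=np.asarray(internal.snp_ids))
    return IVSet(list(np.asarray(internal.snp_ids)[keep]), "fdr", prov)


def select_min_p(internal: SummaryStats, q: float = 0.05) -> IVSet:
    """The single smallest-raw-p SNP among the BH-significant SNPs.

    Ties in the raw p-value break by input order; no significant SNP
    yields an empty set.
    """
    adj = bh_adjust(internal.pvalue)
    sig = np.flatnonzero(adj < q)
    if sig.size == 0:
        return IVSet([], "minp")
    best = sig[np.argmin(internal.pvalue[sig])]  # argmin takes first on ties
    prov = pd.DataFrame(
        {"bh_significant": adj < q, "selected": np.arange(len(internal)) == best},
        index=np.asarray(internal.snp_ids),
    )
    return IVSet([np.asarray(internal.snp_ids)[best]], "minp", prov)


def select_gwas(external: ExternalEvidence, alpha: float = 0.05) -> IVSet:
    """Bonferroni-significant SNPs in the external GWAS."""
    if external.gwas_pvalue is None:
        raise ValueError("gwas strategy requires GWAS p-values")
    keep = external.gwas_pvalue < alpha / external.n_tests
    prov = pd.DataFrame({"gwas_bonferroni": keep}, index=external.snp_ids)
    return IVSet(list(external.snp_ids[keep]), "gwas", prov)


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        # constant column: treated as unlinked
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(genotypes, pvalues, snp_ids=None, r2_max: float = 0.2):
    """Greedy LD pruning: rank by ascending p, keep a SNP iff its squared
    correlation with every already-kept SNP is <= ``r2_max``.

    Ties in p break by input order, so the result is deterministic.
    Constant genotype columns are treated as unlinked (r^2 = 0).
    Returns the surviving SNP identifiers in input order.
    """
    G = np.asarray(genotypes, dtype=float)
    p = np.asarray(pvalues, dtype=float)
    if G.ndim != 2 or G.shape[1] != len(p):
        raise ValueError("genotype columns must align with pvalues")
    if snp_ids is None:
        snp_ids = np.arange(G.shape[1])
    snp_ids = np.asarray(snp_ids)
    order = np.argsort(p, kind="stable")
    kept: list[int] = []
    for j in order:
        if all(_pairwise_r2(G[:, j], G[:, k]) <= r2_max for k in kept):
            kept.append(j)
    kept_mask = np.zeros(G.shape[1], dtype=bool)
    kept_mask[kept] = True
    return list(snp_ids[kept_mask])


def cis_filter(
    snp_chrom,
    snp_pos,
    feature_region: tuple,
    window: int = 1_000_000,
) -> np.ndarray:
    """Boolean mask: SNP within ``window`` bp of the feature's gene.

    ``feature_region`` is (chrom, start, end), 1-based inclusive.  The
    window boundaries are inclusive: a SNP exactly ``window`` bp from the
    gene boundary passes.
    """
    chrom, start, end = feature_region
    snp_chrom = np.asarray(snp_chrom)
    snp_pos = np.asarray(snp_pos, dtype=np.int64)
    lo = max(1, int(start) - window)
    hi = int(end) + window
    return (snp_chrom == chrom) & (snp_pos >= lo) & (snp_pos <= hi)


def filter_snps(
    genotypes,
    snp_ids=None,
    maf_min: float = 0.01,
    variation_min: float = 0.10,
):
    """Keep SNPs with variation rate >= ``variation_min`` and MAF > ``maf_min``.

    Variation rate is the fraction of (non-missing) samples carrying at
    least one alternate allele; MAF is the dosage-derived allele
    frequency folded to <= 0.5.
    """
    G = np.asarray(genotypes, dtype=float)
    if snp_ids is None:
        snp_ids = np.arange(G.shape[1])
    snp_ids = np.asarray(snp_ids)
    keep = np.zeros(G.shape[1], dtype=bool)
    for j in range(G.shape[1]):
        col = G[:, j]
        col = col[np.isfinite(col)]
        if len(col) == 0:
            continue
        variation = np.mean(col > 0)
        af = col.mean() / 2.0
        maf = min(af, 1.0 - af)
        keep[j] = (variation >= variation_min) and (maf > maf_min)
    return list(snp_ids[keep])


def filter_features(matrix: pd.DataFrame, max_missing: float = 0.90) -> list:
    """Keep features (rows) whose missing-value fraction is <= ``max_missing``."""
    frac = matrix.isna().mean(axis=1)
    return list(matrix.index[frac <= max_missing])
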