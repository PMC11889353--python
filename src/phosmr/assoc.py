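"""Per-SNP association summary statistics and correlation baselines.

Summary statistics (slope, standard error, two-sided t p-value) come from
ordinary least squares of a trait on a single SNP dosage, optionally
adjusted for covariates (age, sex, smoking status in the cohort setting).
Missing values are handled complete-case per SNP; the per-SNP sample count
actually used is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "SummaryStats",
    "marginal_regression",
    "adjusted_regression",
    "batch_summary",
    "pearson_test",
    "spearman_test",
]


@dataclass(frozen=True)
class RegressionResult:
    beta: float
    se: float
    pvalue: float
    n_used: int
    degenerate: bool = False


@dataclass
class SummaryStats:
    """Per-SNP association results for one trait."""

    snp_ids: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    pvalue: np.ndarray
    n_used: np.ndarray
    trait_id: str = ""

    def __post_init__(self) -> None:
        lens = {len(self.snp_ids), len(self.beta), len(self.se), len(self.pvalue), len(self.n_used)}
        if len(lens) != 1:
            raise ValueError("SummaryStats fields must have equal length")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "beta": self.beta,
                "se": self.se,
                "pvalue": self.pvalue,
                "n": self.n_used,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, trait_id: str = "") -> "SummaryStats":
        df = pd.read_csv(path, sep="\t")
        return cls(
            snp_ids=df["snp_id"].to_numpy(),
            beta=df["beta"].to_numpy(float),
            se=df["se"].to_numpy(float),
            pvalue=df["pvalue"].to_numpy(float),
            n_used=df["n"].to_numpy(int),
            trait_id=trait_id,
        )


def _complete_cases(*arrays: np.ndarray) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        a = np.asarray(a, dtype=float)
        if a.ndim == 1:
            mask &= np.isfinite(a)
        else:
            mask &= np.isfinite(a).all(axis=1)
    return mask


def marginal_regression(genotype, trait) -> RegressionResult:
    """Simple OLS of ``trait`` on ``genotype`` with intercept.

    The standard error uses the residual variance with ``n - 2`` degrees
    of freedom and the p-value a two-sided t-test.  A constant genotype
    yields a flagged degenerate result (beta undefined, p = 1 by
    convention); an exact fit (zero residual variance) is likewise
    flagged.
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(trait, dtype=float)
    if g.shape != y.shape:
        raise ValueError("genotype and trait must have equal length")
    mask = _complete_cases(g, y)
    g, y = g[mask], y[mask]
    n = len(g)
    if n < 3:
        raise ValueError(f"need >= 3 complete cases, got {n}")
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = float(gc @ gc)
    if sxx == 0.0:
        return RegressionResult(np.nan, np.nan, 1.0, n, degenerate=True)
    sxy = float(gc @ yc)
    syy = float(yc @ yc)
    beta = sxy / sxx
    sse = max(syy - beta * sxy, 0.0)
    s2 = sse / (n - 2)
    se = float(np.sqrt(s2 / sxx))
    if se == 0.0:
        # exact fit / zero-variance response
        p = 1.0 if beta == 0.0 else 0.0
        return RegressionResult(beta, 0.0, p, n, degenerate=True)
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return RegressionResult(beta, se, float(p), n)


def adjusted_regression(genotype, trait, covariates) -> RegressionResult:
    """OLS of ``trait`` on ``genotype`` plus covariate columns.

    Returns the genotype coefficient with SE and two-sided t p-value on
    ``n - rank`` degrees of freedom.  Rows with any missing value are
    dropped.  A rank-deficient design raises, naming the collinear
    columns.
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(trait, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[1] == 0:
        return marginal_regression(g, y)
    mask = _complete_cases(g, y, C)
    g, y, C = g[mask], y[mask], C[mask]
    n = len(g)
    X = np.column_stack([np.ones(n), g, C])
    k = X.shape[1]
    if n < k + 1:
        raise ValueError(f"need >= {k + 1} complete cases, got {n}")
    if np.ptp(g) == 0.0:
        return RegressionResult(np.nan, np.nan, 1.0, n, degenerate=True)
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    if (diag < tol).any():
        names = ["intercept", "genotype"] + [f"covariate{i}" for i in range(C.shape[1])]
        bad = [names[i] for i in np.flatnonzero(diag < tol)]
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear columns: {bad}")
    coef = np.linalg.solve(r, q.T @ y)
    resid = y - X @ coef
    df = n - k
    s2 = float(resid @ resid) / df
    rinv = np.linalg.inv(r)
    xtx_inv = rinv @ rinv.T
    se = float(np.sqrt(s2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    if se == 0.0:
        return RegressionResult(beta, 0.0, 1.0 if beta == 0.0 else 0.0, n, degenerate=True)
    p = 2.0 * stats.t.sf(abs(beta / se), df)
    return RegressionResult(beta, se, float(p), n)


def _batch_marginal_fast(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized per-column simple regression (no missing values)."""
    n = G.shape[0]
    Gf = G.astype(np.float64, copy=False)
    gm = Gf.mean(axis=0)
    ym = y.mean()
    yc = y - ym
    sxy = Gf.T @ yc  # centering y suffices: sum(g * yc) == sum(gc * yc)
    sxx = (Gf * Gf).sum(axis=0) - n * gm * gm
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        sse = np.maximum(syy - beta * sxy, 0.0)
        s2 = sse / (n - 2)
        se = np.sqrt(np.where(sxx > 0, s2 / np.where(sxx > 0, sxx, 1.0), np.nan))
        t = np.abs(beta / se)
    p = 2.0 * stats.t.sf(t, n - 2)
    degenerate = (sxx == 0) | (se == 0)
    p = np.where(sxx == 0, 1.0, p)
    p = np.where((sxx > 0) & (se == 0), np.where(beta == 0, 1.0, 0.0), p)
    return beta, se, p, np.full(G.shape[1], n), degenerate


def batch_summary(
    genotypes,
    trait,
    covariates=None,
    snp_ids=None,
    trait_id: str = "",
) -> SummaryStats:
    """Column-wise association of a trait with every SNP in a matrix.

    Without covariates and without missing values this runs a fully
    vectorized path; results are identical (to float precision) to
    per-column :func:`marginal_regression` calls.
    """
    G = np.asarray(genotypes)
    y = np.asarray(trait, dtype=float)
    if G.ndim != 2 or G.shape[0] != len(y):
        raise ValueError("genotypes must be (n_samples, n_snps) matching trait length")
    J = G.shape[1]
    if snp_ids is None:
        snp_ids = np.array([f"snp{j}" for j in range(J)])
    snp_ids = np.asarray(snp_ids)
    if len(snp_ids) != J:
        raise ValueError("snp_ids length mismatch")
    if J == 0:
        z = np.array([])
        return SummaryStats(snp_ids, z, z, z, np.array([], dtype=int), trait_id)

    clean = np.isfinite(y).all() and (
        not np.issubdtype(G.dtype, np.floating) or np.isfinite(G).all()
    )
    if covariates is None and clean:
        beta, se, p, n_used, _ = _batch_marginal_fast(G, y)
        return SummaryStats(snp_ids, beta, se, p, n_used.astype(int), trait_id)

    res = []
    for j in range(J):
        if covariates is None:
            res.append(marginal_regression(G[:, j], y))
        else:
            res.append(adjusted_regression(G[:, j], y, covariates))
    return SummaryStats(
        snp_ids=snp_ids,
        beta=np.array([r.beta for r in res]),
        se=np.array([r.se for r in res]),
        pvalue=np.array([r.pvalue for r in res]),
        n_used=np.array([r.n_used for r in res]),
        trait_id=trait_id,
    )


def _paired_complete(x, y, min_pairs: int = 4):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < min_pairs:
        raise ValueError(f"need >= {min_pairs} complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input to correlation test")
    return x, y


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p-value."""
    x, y = _paired_complete(x, y)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), t-approximation p."""
    x, y = _paired_complete(x, y)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
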