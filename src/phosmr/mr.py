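"""Wald-ratio and fixed-effects inverse-variance-weighted causal estimation.

Given per-instrument summary statistics (``beta_x`` for SNP-exposure,
``beta_y`` and ``se_y`` for SNP-outcome), the IVW estimate is the
fixed-effects meta-analysis of per-variant Wald ratios

.. math::

    \\hat\\theta = \\frac{\\sum_j \\beta_{Xj}\\beta_{Yj}/se_{Yj}^2}
                        {\\sum_j \\beta_{Xj}^2/se_{Yj}^2},
    \\qquad
    se(\\hat\\theta) = \\Big(\\sum_j \\beta_{Xj}^2/se_{Yj}^2\\Big)^{-1/2}

equivalent to weighted least squares of ``beta_y`` on ``beta_x`` through
the origin with weights ``1/se_y^2``.  First-order weights only: the
exposure-side standard errors do not enter.  Inference uses a standard
normal reference for the Wald statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["MREstimate", "wald_ratio", "ivw", "bh_adjust", "decide", "estimates_to_tsv"]


@dataclass
class MREstimate:
    """One causal-effect estimate (or a distinguished no-instruments result)."""

    theta_hat: float
    se: float
    z: float
    pvalue: float
    n_iv: int
    iv_ids: list = field(default_factory=list)
    method: str = "ivw"

    @property
    def is_estimable(self) -> bool:
        return self.n_iv >= 1

    @classmethod
    def no_instruments(cls, method: str = "ivw") -> "MREstimate":
        return cls(np.nan, np.nan, np.nan, np.nan, 0, [], method)


def wald_ratio(beta_x: float, beta_y: float, se_y: float) -> tuple[float, float]:
    """Single-instrument ratio estimate ``beta_y / beta_x``.

    The first-order standard error ``se_y / |beta_x|`` ignores exposure
    uncertainty.
    """
    if beta_x == 0:
        raise ValueError("wald_ratio undefined for beta_x = 0")
    if se_y <= 0:
        raise ValueError("se_y must be > 0")
    return beta_y / beta_x, se_y / abs(beta_x)


def ivw(
    beta_x,
    beta_y,
    se_y,
    iv_ids=None,
    min_iv: int = 1,
    method: str = "ivw",
    model: str = "fixed",
) -> MREstimate:
    """IVW estimate from per-instrument summary statistics.

    ``model`` selects the meta-analysis variance: ``"fixed"`` uses the
    textbook fixed-effects standard error above; ``"random"`` multiplies
    it by ``max(1, RSE)``, the residual standard error of the weighted
    regression through the origin, penalizing between-instrument
    heterogeneity (e.g. from exclusion-restriction violations);
    ``"default"`` mirrors the widely used R implementation's behavior,
    applying the multiplicative random-effects correction only when four
    or more instruments are available.  The point estimate is identical
    in all three.

    An empty instrument set (or fewer than ``min_iv``) returns the
    distinguished no-instruments result rather than raising, so callers
    can record a non-discovery.  A zero exposure beta is an error:
    instrument selection should have excluded it.
    """
    if model not in ("fixed", "random", "default"):
        raise ValueError("model must be 'fixed', 'random' or 'default'")
    bx = np.asarray(beta_x, dtype=float)
    by = np.asarray(beta_y, dtype=float)
    sy = np.asarray(se_y, dtype=float)
    if not (bx.shape == by.shape == sy.shape):
        raise ValueError("beta_x, beta_y, se_y must have equal length")
    if iv_ids is None:
        iv_ids = [f"iv{j}" for j in range(len(bx))]
    iv_ids = list(iv_ids)
    if len(bx) < max(min_iv, 1):
        return MREstimate.no_instruments(method)
    if (sy <= 0).any():
        raise ValueError("all se_y must be > 0")
    if (bx == 0).any():
        raise ValueError("zero exposure beta among instruments")
    w = 1.0 / (sy * sy)
    denom = float(np.sum(bx * bx * w))
    theta = float(np.sum(bx * by * w)) / denom
    se = denom ** -0.5
    k = len(bx)
    use_random = model == "random" or (model == "default" and k >= 4)
    if use_random and k >= 2:
        rse2 = float(np.sum(w * (by - theta * bx) ** 2)) / (k - 1)
        se *= max(1.0, np.sqrt(rse2))
    z = theta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return MREstimate(theta, se, z, float(p), k, iv_ids, method)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1] and be non-missing")
    return multipletests(p, method="fdr_bh")[1]


def decide(estimate, alpha: float = 0.05) -> bool:
    """Raw-threshold discovery flag; no-instruments results never discover.

    Accepts an :class:`MREstimate` or a bare p-value.  Family-wise BH
    decisions are made by the caller via :func:`bh_adjust` over the
    relevant family.
    """
    if isinstance(estimate, MREstimate):
        if not estimate.is_estimable:
            return False
        p = estimate.pvalue
    else:
        p = float(estimate)
    return bool(np.isfinite(p) and p < alpha)


def estimates_to_tsv(records: list[dict], path: str | Path) -> None:
    """Write estimate records (exposure, outcome, MREstimate fields) to TSV."""
    rows = []
    for r in records:
        est: MREstimate = r["estimate"]
        rows.append(
            {
                "exposure": r.get("exposure", ""),
                "outcome": r.get("outcome", ""),
                "n_iv": est.n_iv,
                "theta": est.theta_hat,
                "se": est.se,
                "z": est.z,
                "p": est.pvalue,
                "p_adj": r.get("p_adj", np.nan),
                "iv_ids": ",".join(map(str, est.iv_ids)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
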