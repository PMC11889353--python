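"""Replicate engine: power / FDR evaluation of IV strategies vs correlation.

Each replicate draws a fresh (GWAS, small multiomics) cohort pair, derives
per-SNP summary statistics, applies the four instrument-selection
strategies followed by fixed-effects IVW, and runs Pearson and Spearman
correlation on the small cohort's (exposure, outcome) as baselines.
Power is the fraction of replicates flagged as discoveries when the true
causal effect is nonzero; under the null the same fraction is reported as
an FDR.  Two decision modes are supported: a raw per-replicate threshold,
and BH applied across all replicate p-values as one family.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .assoc import batch_summary, pearson_test, spearman_test
from .ivsel import (
    ExternalEvidence,
    select_dual_evidence,
    select_fdr,
    select_gwas,
    select_min_p,
)
from .mr import MREstimate, bh_adjust, ivw
from .simulate import ScenarioConfig, SimulatedCohort, make_paired_datasets, replicate_rng

__all__ = [
    "METHODS",
    "MR_METHODS",
    "run_replicate",
    "run_scenario",
    "evaluate",
    "run_grid",
    "randomize_snp_identities",
    "plot_estimate_density",
]

MR_METHODS = ("dual", "fdr", "minp", "gwas")
METHODS = MR_METHODS + ("pearson", "spearman")


def _mr_result(ivset, stats_x, stats_y, ids) -> MREstimate:
    sel = [i for i, s in enumerate(ids) if s in set(ivset.snp_ids)]
    # degenerate small-cohort columns (constant genotype or exact fit)
    # cannot enter IVW; drop them here
    sel = [
        i
        for i in sel
        if np.isfinite(stats_x.beta[i]) and stats_x.beta[i] != 0 and stats_y.se[i] > 0
    ]
    if not sel:
        return MREstimate.no_instruments(ivset.strategy)
    # "default" variance model: multiplicative random-effects correction
    # at >= 4 instruments, as in the reference MR implementation
    return ivw(
        stats_x.beta[sel],
        stats_y.beta[sel],
        stats_y.se[sel],
        iv_ids=[ids[i] for i in sel],
        method=ivset.strategy,
        model="default",
    )


def run_replicate(config: ScenarioConfig, rep_index: int) -> pd.DataFrame:
    """One full replicate; deterministic given (config.seed, rep_index).

    Returns one row per method with columns (method, pvalue, estimate,
    n_iv).  ``estimate`` is the IVW causal estimate for the MR strategies
    and the correlation coefficient for the Pearson/Spearman baselines.
    """
    rng = replicate_rng(config.seed, rep_index)
    gwas, small = make_paired_datasets(config, rng)
    ids = [f"snp{j}" for j in range(config.n_snps)]

    stats_x = batch_summary(small.genotypes, small.exposure, snp_ids=ids, trait_id="X")
    stats_y = batch_summary(small.genotypes, small.outcome, snp_ids=ids, trait_id="Y")
    gwas_x = batch_summary(gwas.genotypes, gwas.exposure, snp_ids=ids, trait_id="X_gwas")
    external = ExternalEvidence(
        snp_ids=np.asarray(ids), gwas_pvalue=gwas_x.pvalue, n_tests=config.n_snps
    )

    ivsets = {
        "dual": select_dual_evidence(stats_x, external),
        "fdr": select_fdr(stats_x),
        "minp": select_min_p(stats_x),
        "gwas": select_gwas(external),
    }
    rows = []
    for name, ivset in ivsets.items():
        est = _mr_result(ivset, stats_x, stats_y, ids)
        rows.append((name, est.pvalue, est.theta_hat, est.n_iv))
    for name, test in (("pearson", pearson_test), ("spearman", spearman_test)):
        r, p = test(small.exposure, small.outcome)
        rows.append((name, p, r, np.nan))
    df = pd.DataFrame(rows, columns=["method", "pvalue", "estimate", "n_iv"])
    df.insert(0, "rep", rep_index)
    return df


def run_scenario(
    config: ScenarioConfig,
    n_reps: int | None = None,
    n_workers: int = 1,
) -> pd.DataFrame:
    """All replicates of one scenario; independent of worker count."""
    n_reps = config.n_reps if n_reps is None else n_reps
    if n_workers > 1:
        frames = Parallel(n_jobs=n_workers)(
            delayed(run_replicate)(config, r) for r in range(n_reps)
        )
    else:
        frames = [run_replicate(config, r) for r in range(n_reps)]
    return pd.concat(frames, ignore_index=True)


def evaluate(
    results: pd.DataFrame,
    theta_true: float,
    alpha: float = 0.05,
    decision_mode: str = "bh",
) -> pd.DataFrame:
    """Summarize per-replicate results into power/FDR per method.

    ``decision_mode="raw"`` flags a replicate when its p-value is below
    ``alpha``; ``"bh"`` first applies BH across all replicate p-values of
    a method (one family) and flags adjusted p < ``alpha``.  Replicates
    with no instruments (missing p) are never discoveries.  The flagged
    fraction is reported as power when ``theta_true != 0`` and as an FDR
    under the null.
    """
    if decision_mode not in ("raw", "bh"):
        raise ValueError("decision_mode must be 'raw' or 'bh'")
    out = []
    for method, grp in results.groupby("method", sort=False):
        p = grp["pvalue"].to_numpy(float)
        ok = np.isfinite(p)
        flags = np.zeros(len(p), dtype=bool)
        if ok.any():
            if decision_mode == "raw":
                flags[ok] = p[ok] < alpha
            else:
                flags[ok] = bh_adjust(p[ok]) < alpha
        est = grp["estimate"].to_numpy(float)
        est = est[np.isfinite(est)]
        frac = flags.mean() if len(p) else np.nan
        out.append(
            {
                "method": method,
                "n_reps": len(p),
                "n_reps_effective": int(ok.sum()),
                "power": frac if theta_true != 0 else np.nan,
                "fdr": frac if theta_true == 0 else np.nan,
                "mean_estimate": est.mean() if len(est) else np.nan,
                "sd_estimate": est.std(ddof=1) if len(est) > 1 else np.nan,
                "decision_mode": decision_mode,
                "theta_true": theta_true,
                "alpha": alpha,
            }
        )
    return pd.DataFrame(out)


def run_grid(
    configs: list[ScenarioConfig],
    n_reps: int | None = None,
    alpha: float = 0.05,
    decision_mode: str = "bh",
    n_workers: int = 1,
) -> pd.DataFrame:
    """Evaluate every scenario in a grid; one row per (scenario, method)."""
    tables = []
    for config in configs:
        res = run_scenario(config, n_reps=n_reps, n_workers=n_workers)
        ev = evaluate(res, config.theta, alpha=alpha, decision_mode=decision_mode)
        ev.insert(0, "heterogeneity", config.heterogeneity)
        ev.insert(0, "invalid_frac", config.invalid_frac)
        ev.insert(0, "n_small", config.n_small)
        tables.append(ev)
    return pd.concat(tables, ignore_index=True)


def run_calibration(
    config: ScenarioConfig, n_reps: int, two_sample: bool = False
) -> pd.DataFrame:
    """IVW sampling-distribution check with the true instruments.

    Simulates cohorts each replicate and feeds the known instrument set
    straight into fixed-effects IVW, bypassing data-driven selection, to
    isolate the estimator's calibration (type-I error, bias, CI
    coverage) from selection effects such as the winner's curse.

    With ``two_sample=True`` the outcome-side summary statistics come
    from an independent cohort drawn with the same realized effects,
    matching the estimator's own (two-sample) sampling assumptions;
    one-sample mode reuses a single cohort for both sides and exhibits
    the mild conservatism and finite-sample effects discussed in the
    methods note.
    """
    from .simulate import NULL_SNP, draw_effects, simulate_cohort

    rows = []
    for r in range(n_reps):
        rng = replicate_rng(config.seed, r)
        effects = draw_effects(config, rng)
        small = simulate_cohort(config, effects, config.n_small, rng)
        outcome_cohort = (
            simulate_cohort(config, effects, config.n_small, rng) if two_sample else small
        )
        iv = np.flatnonzero(effects.iv_flags != NULL_SNP)
        sx = batch_summary(small.genotypes[:, iv], small.exposure)
        sy = batch_summary(outcome_cohort.genotypes[:, iv], outcome_cohort.outcome)
        keep = np.isfinite(sx.beta) & (sx.beta != 0) & (sy.se > 0)
        est = ivw(sx.beta[keep], sy.beta[keep], sy.se[keep])
        rows.append((r, est.theta_hat, est.se, est.pvalue, est.n_iv))
    return pd.DataFrame(rows, columns=["rep", "theta_hat", "se", "pvalue", "n_iv"])


def _group_derangement(groups: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Column permutation moving every equal-sized group to a different group."""
    labels, inverse = np.unique(groups, return_inverse=True)
    cols = [np.flatnonzero(inverse == i) for i in range(len(labels))]
    sizes = {len(c) for c in cols}
    if len(labels) < 2:
        raise ValueError("group-wise randomization needs at least two groups")
    if len(sizes) != 1:
        raise ValueError("group-wise randomization requires equal group sizes")
    while True:  # rejection-sample a derangement of group labels
        sigma = rng.permutation(len(labels))
        if not (sigma == np.arange(len(labels))).any():
            break
    perm = np.empty(len(groups), dtype=int)
    for i, target in enumerate(sigma):
        perm[cols[i]] = cols[target]
    return perm


def randomize_snp_identities(cohort, rng: np.random.Generator, groups=None):
    """Permute the SNP-identifier-to-genotype-column assignment.

    Breaks the SNP-exposure linkage that instrument selection relies on
    while leaving every marginal distribution intact.  Works on a
    :class:`~phosmr.simulate.SimulatedCohort` (columns permuted relative
    to the effect vectors) or a cohort object with a ``genotypes``
    matrix.  Returns ``(perturbed_copy, permutation)``; applying the
    inverse permutation restores the original.

    With ``groups`` (one label per SNP, e.g. the host-gene block), whole
    groups are reassigned to other groups' columns and no group maps to
    itself.  On small synthetic panels this emulates the genome-scale
    behavior of the check — with hundreds of thousands of cis-SNPs a
    uniform permutation essentially never returns a SNP to its own
    locus, but on a 72-SNP panel it would relink ~10% of sites to their
    own cis block by chance.
    """
    n_snps = np.asarray(cohort.genotypes).shape[1]
    if groups is not None:
        groups = np.asarray(groups)
        if len(groups) != n_snps:
            raise ValueError("groups must have one label per SNP")
        perm = _group_derangement(groups, rng)
    else:
        perm = rng.permutation(n_snps)
    if isinstance(cohort, SimulatedCohort):
        return dataclasses.replace(cohort, genotypes=cohort.genotypes[:, perm]), perm
    out = dataclasses.replace(cohort)
    out.genotypes = np.asarray(cohort.genotypes)[:, perm]
    return out, perm


def plot_estimate_density(results: pd.DataFrame, path, methods=None) -> None:
    """Density plot of per-replicate effect estimates, one curve per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    methods = methods or list(results["method"].unique())
    fig, ax = plt.subplots(figsize=(6, 4))
    for m in methods:
        est = results.loc[results["method"] == m, "estimate"].to_numpy(float)
        est = est[np.isfinite(est)]
        if len(est) < 3 or np.ptp(est) == 0:
            continue
        grid = np.linspace(est.min(), est.max(), 200)
        ax.plot(grid, gaussian_kde(est)(grid), label=m)
    ax.set_xlabel("effect estimate")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
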