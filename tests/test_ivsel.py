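"""Instrument-selection strategies, filters, and LD pruning vs oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosmr.assoc import SummaryStats
from phosmr.ivsel import (
    ExternalEvidence,
    IVSet,
    cis_filter,
    filter_features,
    filter_snps,
    ld_prune,
    select_dual_evidence,
    select_fdr,
    select_gwas,
    select_min_p,
)
from phosmr.mr import bh_adjust


def make_stats(pvalues, ids=None):
    p = np.asarray(pvalues, dtype=float)
    ids = np.array(ids if ids is not None else [f"snp{i}" for i in range(len(p))])
    ones = np.ones(len(p))
    return SummaryStats(ids, ones, ones, p, np.full(len(p), 100), "X")


class TestDualEvidence:
    def test_prior_conjunction(self):
        internal = make_stats([0.01, 0.2, 0.04])
        ext = ExternalEvidence(internal.snp_ids, prior_member=[True, True, False])
        assert select_dual_evidence(internal, ext).snp_ids == ["snp0"]

    def test_all_internal_p_one_gives_empty(self):
        internal = make_stats([1.0, 1.0, 1.0])
        ext = ExternalEvidence(internal.snp_ids, prior_member=[True, True, True])
        assert len(select_dual_evidence(internal, ext)) == 0

    def test_gwas_bonferroni_matches_elementwise_oracle(self, rng):
        n = 50
        internal = make_stats(rng.uniform(size=n))
        gwas_p = rng.uniform(0, 0.01, size=n)
        ext = ExternalEvidence(internal.snp_ids, gwas_pvalue=gwas_p, n_tests=n)
        got = set(select_dual_evidence(internal, ext).snp_ids)
        expected = {
            internal.snp_ids[i]
            for i in range(n)
            if internal.pvalue[i] < 0.05 and gwas_p[i] < 0.05 / n
        }
        assert got == expected

    def test_both_channels_are_anded(self):
        internal = make_stats([0.01, 0.01, 0.01])
        ext = ExternalEvidence(
            internal.snp_ids,
            gwas_pvalue=[1e-5, 0.5, 1e-5],
            prior_member=[True, True, False],
            n_tests=3,
        )
        assert select_dual_evidence(internal, ext).snp_ids == ["snp0"]

    def test_misaligned_ids_raise(self):
        internal = make_stats([0.01, 0.02])
        ext = ExternalEvidence(np.array(["a", "b"]), prior_member=[True, True])
        with pytest.raises(ValueError, match="misaligned"):
            select_dual_evidence(internal, ext)

    def test_subset_of_gwas_strategy(self, rng):
        n = 50
        internal = make_stats(rng.uniform(size=n))
        ext = ExternalEvidence(internal.snp_ids, gwas_pvalue=rng.uniform(0, 0.002, n), n_tests=n)
        dual = set(select_dual_evidence(internal, ext).snp_ids)
        gwas = set(select_gwas(ext).snp_ids)
        assert dual <= gwas


class TestFdrAndMinP:
    def test_bh_hand_example_all_selected(self):
        # p=[.01,.02,.03,.04], m=4: all adjusted to .04 < .05
        ivset = select_fdr(make_stats([0.01, 0.02, 0.03, 0.04]))
        assert len(ivset) == 4

    def test_single_p_is_identity(self):
        assert len(select_fdr(make_stats([0.04]))) == 1
        assert len(select_fdr(make_stats([0.06]))) == 0

    def test_null_uniform_selection_fraction_bounded(self, rng):
        # BH at q=.05 over independent uniforms selects ~0
        fracs = [len(select_fdr(make_stats(rng.uniform(size=50)))) / 50 for _ in range(200)]
        assert np.mean(fracs) <= 0.05

    def test_min_p_picks_single_smallest(self):
        ivset = select_min_p(make_stats([0.001, 0.01, 0.6]))
        assert ivset.snp_ids == ["snp0"]

    def test_min_p_empty_when_nothing_significant(self):
        assert len(select_min_p(make_stats([0.3, 0.4, 0.9]))) == 0

    def test_min_p_tie_breaks_by_input_order(self):
        ivset = select_min_p(make_stats([0.01, 0.01, 0.01]))
        assert ivset.snp_ids == ["snp0"]

    def test_min_p_subset_of_fdr(self, rng):
        for _ in range(20):
            s = make_stats(rng.uniform(0, 0.2, size=20))
            minp = set(select_min_p(s).snp_ids)
            fdr = set(select_fdr(s).snp_ids)
            assert minp <= fdr and len(minp) <= 1


class TestGwasSelection:
    def test_threshold_is_bonferroni(self):
        ext = ExternalEvidence(
            np.array([f"s{i}" for i in range(50)]),
            gwas_pvalue=[0.0009] + [0.0011] + [1.0] * 48,
            n_tests=50,
        )
        assert select_gwas(ext).snp_ids == ["s0"]

    def test_all_one_empty(self):
        ext = ExternalEvidence(np.array(["a", "b"]), gwas_pvalue=[1.0, 1.0])
        assert len(select_gwas(ext)) == 0

    def test_matches_elementwise_oracle(self, rng):
        p = rng.uniform(0, 0.01, size=30)
        ext = ExternalEvidence(np.arange(30).astype(str), gwas_pvalue=p, n_tests=30)
        assert set(select_gwas(ext).snp_ids) == set(np.arange(30).astype(str)[p < 0.05 / 30])


class TestIVSet:
    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            IVSet(["a", "a"], "dual")


def brute_force_prune(G, pvals, r2_max):
    """Independent reimplementation: explicit pairwise loop."""
    order = np.argsort(pvals, kind="stable")
    kept = []
    for j in order:
        ok = True
        for k in kept:
            a, b = G[:, j], G[:, k]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            if np.corrcoef(a, b)[0, 1] ** 2 > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return sorted(kept)


class TestLdPrune:
    def test_identical_columns_keep_smaller_p(self, rng):
        col = rng.integers(0, 3, 50).astype(float)
        G = np.column_stack([col, col])
        assert ld_prune(G, [0.01, 0.001], snp_ids=["a", "b"]) == ["b"]

    def test_independent_columns_all_kept(self, rng):
        G = rng.integers(0, 3, size=(500, 5)).astype(float)
        kept = ld_prune(G, rng.uniform(size=5), snp_ids=list("abcde"))
        assert kept == list("abcde")

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            base = rng.integers(0, 3, size=(40, 8)).astype(float)
            # inject correlation
            base[:, 3] = base[:, 0] + (rng.random(40) < 0.2)
            base[:, 7] = base[:, 1]
            pvals = rng.uniform(size=8)
            got = ld_prune(base, pvals)
            assert sorted(got) == brute_force_prune(base, pvals, 0.2)

    def test_constant_column_unlinked(self, rng):
        G = np.column_stack([np.ones(30), rng.integers(0, 3, 30).astype(float)])
        assert ld_prune(G, [0.5, 0.01], snp_ids=["const", "x"]) == ["const", "x"]

    def test_result_stable_under_column_permutation(self, rng):
        G = rng.integers(0, 3, size=(60, 6)).astype(float)
        G[:, 4] = G[:, 2]
        pvals = rng.uniform(size=6)
        ids = [f"s{i}" for i in range(6)]
        kept = set(ld_prune(G, pvals, snp_ids=ids))
        perm = rng.permutation(6)
        kept_perm = set(ld_prune(G[:, perm], pvals[perm], snp_ids=[ids[i] for i in perm]))
        assert kept == kept_perm


class TestCisFilter:
    region = ("chr1", 5_000_000, 5_010_000)

    @pytest.mark.parametrize(
        "chrom,pos,expected",
        [
            ("chr1", 4_000_000, True),  # exactly 1 Mb upstream: inclusive
            ("chr1", 3_999_999, False),
            ("chr1", 6_010_000, True),  # exactly 1 Mb downstream
            ("chr1", 6_010_001, False),
            ("chr1", 5_005_000, True),  # inside the gene
            ("chr2", 5_005_000, False),  # chromosome mismatch
        ],
    )
    def test_boundaries(self, chrom, pos, expected):
        assert cis_filter([chrom], [pos], self.region)[0] == expected

    def test_window_clipped_at_one(self):
        mask = cis_filter(["chr1"], [1], ("chr1", 500_000, 500_100))
        assert mask[0]


class TestSnpAndFeatureFilters:
    def test_variation_rate_boundary(self, rng):
        # 7/79 non-zero = 8.9% < 10%: excluded
        col = np.zeros(79)
        col[:7] = 1
        assert filter_snps(col[:, None], snp_ids=["s"]) == []
        col[7] = 1  # 8/79 = 10.1%
        assert filter_snps(col[:, None], snp_ids=["s"]) == ["s"]

    def test_monomorphic_excluded(self):
        assert filter_snps(np.zeros((50, 1)), snp_ids=["s"]) == []

    def test_matches_per_column_oracle(self, rng):
        G = rng.integers(0, 3, size=(60, 20)).astype(float)
        G[:, 0] = 0
        got = set(filter_snps(G, snp_ids=list(range(20))))
        for j in range(20):
            col = G[:, j]
            af = col.mean() / 2
            expected = (np.mean(col > 0) >= 0.10) and (min(af, 1 - af) > 0.01)
            assert (j in got) == expected

    def test_feature_missingness_boundary(self):
        m = pd.DataFrame(np.ones((2, 79)), index=["hi", "lo"])
        m.iloc[0, :72] = np.nan  # 72/79 = 91.1% missing: removed
        assert filter_features(m) == ["lo"]

    def test_fully_observed_kept(self, rng):
        m = pd.DataFrame(rng.normal(size=(3, 10)))
        assert filter_features(m) == [0, 1, 2]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_filters_idempotent(self, seed):
        r = np.random.default_rng(seed)
        G = r.integers(0, 3, size=(40, 10)).astype(float)
        ids = list(range(10))
        kept = filter_snps(G, snp_ids=ids)
        cols = [ids.index(k) for k in kept]
        assert filter_snps(G[:, cols], snp_ids=kept) == kept

    def test_bh_adjust_matches_step_up_oracle(self, rng):
        p = rng.uniform(size=25)
        adj = bh_adjust(p)
        # independent step-up computation
        m = len(p)
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(ranked, 1)
        np.testing.assert_allclose(adj, expected, atol=1e-12)
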