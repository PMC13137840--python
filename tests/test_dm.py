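"""Differential-methylation calling: merging, filtering, tests, annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from methylink.dm import (
    MethylationMatrix,
    adjust_bh,
    annotate_sites,
    call_dm,
    classify_gene_meth_status,
    filter_coverage,
    merge_samples,
    meth_diff,
)
from methylink.dm import test_sites as site_pvalues
from conftest import cov_frame


def matrix_from_counts(meth, total, groups=("test", "test", "ref", "ref")):
    """Build a MethylationMatrix from per-site count arrays."""
    meth = np.atleast_2d(np.asarray(meth))
    total = np.atleast_2d(np.asarray(total))
    samples = [f"s{i}" for i in range(meth.shape[1])]
    return MethylationMatrix(
        sites=pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(meth.shape[0])}
        ),
        count_meth=meth.astype(np.int64),
        count_total=total.astype(np.int64),
        samples=samples,
        design=dict(zip(samples, groups)),
    )


def bh_step_up_oracle(p):
    """Direct step-up definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    return float(pmf[pmf <= pmf[support == a][0] * (1 + 1e-12)].sum())


class TestMerge:
    def test_intersection_and_dropped_count(self):
        a = cov_frame([("chr1", i, 1, 1) for i in range(10)])
        b = cov_frame([("chr1", i, 2, 2) for i in range(2, 10)])
        m = merge_samples({"a": a, "b": b}, {"a": "test", "b": "ref"})
        assert m.n_sites == 8
        assert m.n_dropped_sites == 2

    def test_single_shared_site(self):
        a = cov_frame([("chr1", 5, 1, 1), ("chr1", 9, 1, 1)])
        b = cov_frame([("chr1", 5, 2, 2)])
        m = merge_samples({"a": a, "b": b}, {"a": "test", "b": "ref"})
        assert m.n_sites == 1

    def test_sample_missing_from_design(self):
        a = cov_frame([("chr1", 5, 1, 1)])
        with pytest.raises(ValueError, match="design"):
            merge_samples({"a": a}, {})


class TestCoverageFilter:
    @pytest.mark.parametrize(
        "totals,kept",
        [
            ((4, 4, 3), True),  # sum 11 > 10, all >= 1
            ((10, 0, 5), False),  # per-sample floor violated
            ((5, 5), False),  # sum exactly 10, strict
            ((6, 5), True),
        ],
    )
    def test_threshold_semantics(self, totals, kept):
        groups = ("test",) * (len(totals) - 1) + ("ref",)
        m = matrix_from_counts(
            [np.zeros(len(totals))], [totals], groups=groups
        )
        out = filter_coverage(m)
        assert out.n_sites == (1 if kept else 0)


class TestSiteTests:
    def test_null_identity_both_methods(self):
        m = matrix_from_counts([[5, 5, 5, 5]], [[10, 10, 10, 10]])
        assert site_pvalues(m, "fisher_pooled")[0] == pytest.approx(1.0)
        assert site_pvalues(m, "logistic")[0] == pytest.approx(1.0)

    def test_degenerate_all_zero_or_full(self):
        m0 = matrix_from_counts([[0, 0, 0, 0]], [[10, 10, 10, 10]])
        m1 = matrix_from_counts([[10, 10, 10, 10]], [[10, 10, 10, 10]])
        for m in (m0, m1):
            assert site_pvalues(m, "logistic")[0] == pytest.approx(1.0)

    def test_fisher_matches_enumeration_oracle(self):
        # frozen constant from the exhaustive enumeration of [[9,1],[1,9]]
        m = matrix_from_counts([[9, 1]], [[10, 10]], groups=("test", "ref"))
        p = site_pvalues(m, "fisher_pooled")[0]
        assert p == pytest.approx(0.001093333910671372, abs=1e-12)
        assert p == pytest.approx(fisher_enumeration_oracle(9, 1, 1, 9), abs=1e-12)

    def test_single_sample_group_auto_selects_fisher(self):
        m = matrix_from_counts(
            [[9, 1, 1]], [[10, 10, 10]], groups=("test", "ref", "ref")
        )
        p_auto = site_pvalues(m, "logistic")[0]
        p_fisher = site_pvalues(m, "fisher_pooled")[0]
        assert p_auto == p_fisher

    def test_logistic_matches_statsmodels_glm(self):
        """Dual route: closed-form LRT vs iterative statsmodels binomial GLM."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        total = rng.integers(10, 60, size=(15, 6))
        pi = np.where(np.arange(6) < 3, 0.4, 0.6)
        meth = rng.binomial(total, pi)
        m = matrix_from_counts(meth, total, groups=("test",) * 3 + ("ref",) * 3)
        ours = site_pvalues(m, "logistic")
        X = sm.add_constant(np.array([1.0] * 3 + [0.0] * 3))
        for i in range(15):
            y = np.column_stack([meth[i], total[i] - meth[i]])
            full = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            null = sm.GLM(y, X[:, :1], family=sm.families.Binomial()).fit()
            lrt = 2 * (full.llf - null.llf)
            p_ref = stats.chi2.sf(max(lrt, 0.0), 1)
            assert ours[i] == pytest.approx(p_ref, abs=1e-8)

    def test_fisher_monotone_in_test_methylation(self):
        """Adding DM-favourable counts never increases the Fisher p."""
        prev = 1.1
        for a in range(5, 20):
            m = matrix_from_counts(
                [[a, 5]], [[20, 20]], groups=("test", "ref")
            )
            p = site_pvalues(m, "fisher_pooled")[0]
            assert p <= prev + 1e-12
            prev = p

    def test_null_logistic_p_approximately_uniform(self):
        """3v3 null simulation: p-values uniform to KS tolerance (5,000 sites)."""
        rng = np.random.default_rng(1)
        n = 5000
        pi = rng.beta(2, 2, size=n)
        total = np.maximum(rng.negative_binomial(5, 5 / 45, size=(n, 6)), 1)
        meth = rng.binomial(total, pi[:, None])
        m = matrix_from_counts(meth, total, groups=("test",) * 3 + ("ref",) * 3)
        p = site_pvalues(m, "logistic")
        d = stats.kstest(p, "uniform").statistic
        assert d < 0.05


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate(self):
        assert adjust_bh([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=60,
        )
    )
    def test_matches_oracle_and_permutation_invariant(self, p):
        q = adjust_bh(p)
        np.testing.assert_allclose(q, bh_step_up_oracle(p), atol=1e-12)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        q_perm = adjust_bh(np.asarray(p)[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)


class TestMethDiff:
    def test_pooled_arithmetic(self):
        m = matrix_from_counts(
            [[20, 10, 4, 6]], [[20, 20, 20, 20]]
        )
        assert meth_diff(m)[0] == pytest.approx(100 * (30 / 40 - 10 / 40))

    def test_equal_proportions_zero(self):
        m = matrix_from_counts([[5, 5, 5, 5]], [[10, 10, 10, 10]])
        assert meth_diff(m)[0] == pytest.approx(0.0)

    def test_pooled_equals_sample_mean_only_under_equal_coverage(self):
        # equal coverage: pooling and per-sample averaging agree
        m = matrix_from_counts(
            [[9, 1, 5, 5]], [[10, 10, 10, 10]], groups=("test", "test", "ref", "ref")
        )
        sample_mean = 100 * ((0.9 + 0.1) / 2 - 0.5)
        assert meth_diff(m)[0] == pytest.approx(sample_mean)
        # unequal coverage: the coverage-weighted pooled difference diverges
        m2 = matrix_from_counts(
            [[90, 1, 5, 5]], [[100, 10, 10, 10]],
            groups=("test", "test", "ref", "ref"),
        )
        pooled2 = meth_diff(m2)[0]
        sample_mean2 = 100 * ((0.9 + 0.1) / 2 - 0.5)
        assert abs(pooled2 - sample_mean2) > 1.0


class TestCallDm:
    def test_strict_boundaries(self):
        table = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "pos": [1, 2, 3],
                "meth_diff": [15.0, 10.0, 15.0],
                "q": [0.04, 0.04, 0.05],
            }
        )
        keep = (table["q"] < 0.05) & (table["meth_diff"].abs() > 10.0)
        assert keep.tolist() == [True, False, False]

    def test_call_dm_directions(self):
        rng = np.random.default_rng(2)
        total = np.full((200, 6), 40)
        pi = np.full(200, 0.5)
        pi[:10] = 0.9
        meth = rng.binomial(total, pi[:, None])
        meth[:10, 3:] = rng.binomial(40, 0.1, size=(10, 3))
        m = matrix_from_counts(meth, total, groups=("test",) * 3 + ("ref",) * 3)
        dm = call_dm(m)
        assert len(dm) >= 8
        assert (dm["direction"] == "hyper").all()
        assert (dm["q"] < 0.05).all() and (dm["meth_diff"].abs() > 10).all()


class TestAnnotate:
    def test_feature_precedence_and_distances(self, toy_catalog):
        sites = pd.DataFrame(
            {
                "chrom": ["chr1"] * 5 + ["chr1"],
                "pos": [10_000, 11_000, 13_000, 69_999, 68_500, 300_000],
                "direction": ["hypo"] * 6,
            }
        )
        ann = annotate_sites(sites, toy_catalog)
        # at the plus-strand TSS
        assert ann.loc[0, "feature"] == "promoter"
        assert ann.loc[0, "signed_tss_distance"] == 0
        # inside exon 1 but beyond the promoter window
        assert ann.loc[1, "feature"] == "exon"
        # intron
        assert ann.loc[2, "feature"] == "intron"
        # minus-strand TSS
        assert ann.loc[3, "feature"] == "promoter"
        assert ann.loc[3, "gene_id"] == "minusB"
        assert ann.loc[3, "signed_tss_distance"] == 0
        # minus strand: downstream lies at smaller coordinates, beyond the
        # 1 kb promoter window here, inside exon 2
        assert ann.loc[4, "feature"] == "exon"
        assert ann.loc[4, "signed_tss_distance"] == 1499  # downstream positive
        # far from everything
        assert ann.loc[5, "feature"] == "intergenic"
        assert ann.loc[5, "gene_id"] == ""

    def test_intergenic_with_nearby_gene(self, toy_catalog):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [40_000], "direction": ["hypo"]})
        ann = annotate_sites(sites, toy_catalog)
        assert ann.loc[0, "feature"] == "intergenic"
        assert ann.loc[0, "gene_id"] in {"plusA", "minusB"}

    def test_unknown_chromosome_warns(self, toy_catalog):
        sites = pd.DataFrame({"chrom": ["chrZ"], "pos": [5], "direction": ["hypo"]})
        with pytest.warns(UserWarning, match="chrZ"):
            ann = annotate_sites(sites, toy_catalog)
        assert ann.loc[0, "feature"] == "intergenic"


class TestGeneStatus:
    def test_classification(self):
        ann = pd.DataFrame(
            {
                "gene_id": ["g1", "g1", "g2", "g2", "g3"],
                "feature": ["promoter"] * 5,
                "direction": ["hypo", "hypo", "hypo", "hyper", "hyper"],
            }
        )
        out = classify_gene_meth_status(ann).set_index("gene_id")
        assert out.loc["g1", "status"] == "hypo_only"
        assert out.loc["g2", "status"] == "mixed"
        assert out.loc["g3", "status"] == "hyper_only"

    def test_gene_without_sites_absent(self):
        ann = pd.DataFrame(
            {"gene_id": ["g1"], "feature": ["promoter"], "direction": ["hypo"]}
        )
        out = classify_gene_meth_status(ann)
        assert set(out["gene_id"]) == {"g1"}

    def test_scope_restricts_features(self):
        ann = pd.DataFrame(
            {
                "gene_id": ["g1", "g1"],
                "feature": ["promoter", "exon"],
                "direction": ["hypo", "hyper"],
            }
        )
        prom = classify_gene_meth_status(ann, scope="promoter")
        whole = classify_gene_meth_status(ann, scope="whole_gene")
        assert prom.loc[0, "status"] == "hypo_only"
        assert whole.loc[0, "status"] == "mixed"
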