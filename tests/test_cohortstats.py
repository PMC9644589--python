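from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from iskit.cohortstats import (
    bh_adjust,
    covariate_scan,
    differential_integration,
    diffint_frame,
    fisher_exact_2x2,
    group_summary,
    load_example_outcomes,
    load_sample_sheet,
    pca_samples,
    pearson_corr,
    ttest_two_sample,
)


def enumerate_fisher_p(a, b, c, d):
    """Independent oracle: two-sided Fisher p by direct enumeration of all
    2x2 tables with the observed margins, summing hypergeometric
    probabilities <= that of the observed table."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0

    def table_prob(x):  # x plays the role of cell a
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return None
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = table_prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        p = table_prob(x)
        if p is not None and p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestFisher:
    def test_five_zero_split(self):
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252)

    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2(1, 1, 1, 1) == 1.0

    def test_degenerate_empty_table(self):
        assert fisher_exact_2x2(0, 0, 0, 0) == 1.0

    def test_negative_or_fractional_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 0, 0, 0)

    def test_matches_enumeration_on_sampled_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 9, size=4))
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                enumerate_fisher_p(a, b, c, d), rel=1e-9, abs=1e-12
            ), (a, b, c, d)


class TestBH:
    def test_textbook_example(self):
        # p(i) * m / i then cumulative minimum from the largest rank:
        # [.01*4/1, .02*4/2, .03*4/3, .04*4/4] -> all 0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_monotone_in_ranks_and_bounded(self, pvals):
        q = bh_adjust(pvals)
        assert np.all(q <= 1.0 + 1e-12) and np.all(q >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestPearson:
    def test_perfect_positive_linear(self):
        x = np.arange(10.0)
        r, p = pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative_linear(self):
        x = np.arange(10.0)
        r, _ = pearson_corr(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_closed_form_on_random_pairs(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 30))
            x, y = rng.normal(size=n), rng.normal(size=n)
            r, p = pearson_corr(x, y)
            xc, yc = x - x.mean(), y - y.mean()
            r_direct = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
            t = r_direct * np.sqrt((n - 2) / (1 - r_direct**2))
            p_direct = 2 * stats.t.sf(abs(t), df=n - 2)
            assert r == pytest.approx(r_direct)
            assert p == pytest.approx(p_direct)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1, 1, 1], [1, 2, 3])


class TestTTest:
    def test_identical_groups(self):
        t, p = ttest_two_sample([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_separated_means_significant(self):
        t, p = ttest_two_sample([0.1, 0.2, 0.1, 0.15], [10.0, 10.2, 9.9, 10.1])
        assert p < 0.001

    def test_matches_textbook_formula_on_fixture(self):
        a = np.array([4.0, 5.0, 6.0, 7.0, 8.0])
        b = np.array([5.5, 6.5, 7.5, 8.5, 9.5])
        t, p = ttest_two_sample(a, b)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
        t_direct = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        p_direct = 2 * stats.t.sf(abs(t_direct), df=len(a) + len(b) - 2)
        assert t == pytest.approx(t_direct) and p == pytest.approx(p_direct)


class TestPCA:
    def test_rank_one_matrix_single_component(self):
        base = np.outer([1.0, 2.0, 3.0, 4.0], [1.0, 0.5, 2.0])
        res = pca_samples(pd.DataFrame(base, index=list("abcd")))
        assert res.pct_variance[0] == pytest.approx(100.0)

    def test_variance_percentages_sum_to_100(self, rng):
        mat = pd.DataFrame(rng.normal(size=(8, 20)))
        res = pca_samples(mat)
        assert res.pct_variance.sum() == pytest.approx(100.0)

    def test_reconstruction_from_all_components(self, rng):
        mat = pd.DataFrame(rng.normal(size=(6, 10)))
        res = pca_samples(mat)
        centered = mat.to_numpy() - mat.to_numpy().mean(axis=0)
        assert np.allclose(res.scores @ res.loadings.T, centered)


class TestGroupSummary:
    def test_reported_cohort_percentages(self):
        outcomes = load_example_outcomes()
        resp = group_summary(outcomes, "response").set_index("category")
        assert resp.loc["OR", "count"] == 23 and resp.loc["OR", "percent"] == 82.1
        assert resp.loc["NR", "count"] == 5 and resp.loc["NR", "percent"] == 17.9
        crs = group_summary(outcomes, "crs").set_index("category")
        assert crs.loc["high", "count"] == 4 and crs.loc["high", "percent"] == 14.3
        hlh = group_summary(outcomes, "hlh").set_index("category")
        assert hlh.loc["yes", "count"] == 13 and hlh.loc["yes", "percent"] == 46.4

    def test_single_category(self):
        df = pd.DataFrame({"x": ["a", "a", "a"]})
        out = group_summary(df, "x")
        assert out.loc[0, "percent"] == 100.0

    def test_missing_field_rejected(self):
        with pytest.raises(KeyError):
            group_summary(pd.DataFrame({"x": [1]}), "y")


class TestDifferentialIntegration:
    def test_fully_separated_gene(self):
        samples_a, samples_b = [f"A{i}" for i in range(5)], [f"B{i}" for i in range(5)]
        presence = pd.DataFrame(
            [[True] * 5 + [False] * 5], index=["G1"], columns=samples_a + samples_b
        )
        (res,) = differential_integration(presence, samples_a, samples_b)
        assert res.p_value == pytest.approx(2 / 252)
        assert res.log2_enrichment > 0
        assert res.q_value >= res.p_value

    def test_equal_prevalence_zero_enrichment(self):
        samples_a, samples_b = ["A1", "A2", "A3"], ["B1", "B2", "B3"]
        presence = pd.DataFrame(
            [[True, True, False, True, True, False]], index=["G1"], columns=samples_a + samples_b
        )
        (res,) = differential_integration(presence, samples_a, samples_b)
        assert res.log2_enrichment == 0.0 and res.p_value == 1.0

    def test_all_zero_genes_excluded(self):
        presence = pd.DataFrame(
            [[False, False], [True, False]], index=["G0", "G1"], columns=["A1", "B1"]
        )
        with pytest.raises(ValueError):
            differential_integration(presence, ["A1"], [])
        res = differential_integration(presence, ["A1"], ["B1"])
        assert [r.gene_id for r in res] == ["G1"]

    def test_invariant_to_within_group_reordering(self, rng):
        samples = [f"S{i}" for i in range(10)]
        presence = pd.DataFrame(
            rng.random((30, 10)) < 0.4, index=[f"G{i}" for i in range(30)], columns=samples
        )
        a, b = samples[:5], samples[5:]
        r1 = diffint_frame(differential_integration(presence, a, b))
        r2 = diffint_frame(differential_integration(presence, a[::-1], b[::-1]))
        pd.testing.assert_frame_equal(r1, r2)

    def test_permuted_labels_not_anticonservative(self, rng):
        """Type-I sanity: under label permutation the Fisher p-values must
        show no excess of small values relative to uniform (the discrete
        test is conservative, so the one-sided comparison is the meaningful
        one)."""
        n_genes, n_samples = 200, 20
        presence = pd.DataFrame(
            rng.random((n_genes, n_samples)) < 0.35,
            index=[f"G{i}" for i in range(n_genes)],
            columns=[f"S{i}" for i in range(n_samples)],
        )
        pvals = []
        for _ in range(20):
            perm = rng.permutation(n_samples)
            a = [f"S{i}" for i in perm[:10]]
            b = [f"S{i}" for i in perm[10:]]
            pvals.extend(r.p_value for r in differential_integration(presence, a, b))
        ks = stats.kstest(pvals, "uniform", alternative="greater")
        assert ks.pvalue > 0.01


class TestCovariateScan:
    def _fixture(self, rng):
        samples = [f"S{i}" for i in range(12)]
        meta = pd.DataFrame(
            {
                "sample_id": samples,
                "vector_class": ["lentiviral"] * 6 + ["retroviral"] * 6,
                "cd4_pct": np.linspace(20, 70, 12),
            }
        )
        rows = []
        for i, sid in enumerate(samples):
            for cls in ("promoter", "utr"):
                pct = meta.loc[i, "cd4_pct"] * (0.5 if cls == "promoter" else 0.2)
                if cls == "utr":
                    pct += rng.normal(scale=3)
                rows.append((sid, cls, pct))
        coverage = pd.DataFrame(rows, columns=["sample_id", "feature_class", "percent"])
        return coverage, meta

    def test_proportional_covariate_gives_r_one(self, rng):
        coverage, meta = self._fixture(rng)
        table = covariate_scan(coverage, meta, "cd4_pct").set_index(["feature_class", "vector_class"])
        assert table.loc[("promoter", "lentiviral"), "r"] == pytest.approx(1.0)
        assert table.loc[("promoter", "retroviral"), "r"] == pytest.approx(1.0)

    def test_small_stratum_not_computable(self, rng):
        coverage, meta = self._fixture(rng)
        meta = meta.iloc[:8]  # retroviral stratum shrinks to 2 samples
        coverage = coverage[coverage.sample_id.isin(meta.sample_id)]
        table = covariate_scan(coverage, meta, "cd4_pct").set_index(["feature_class", "vector_class"])
        assert np.isnan(table.loc[("promoter", "retroviral"), "r"])

    def test_matches_per_cell_direct_computation(self, rng):
        coverage, meta = self._fixture(rng)
        table = covariate_scan(coverage, meta, "cd4_pct")
        for row in table.itertuples(index=False):
            if np.isnan(row.r):
                continue
            sub = coverage[coverage.feature_class == row.feature_class].merge(meta, on="sample_id")
            sub = sub[sub.vector_class == row.vector_class]
            r_direct, p_direct = stats.pearsonr(sub["percent"], sub["cd4_pct"])
            assert row.r == pytest.approx(r_direct) and row.p == pytest.approx(p_direct)


def test_sample_sheet_validation(tmp_path):
    path = tmp_path / "sheet.tsv"
    pd.DataFrame(
        {
            "sample_id": ["S1"], "vector_class": ["lentiviral"], "car_target": ["CD22"],
            "disease": ["B-ALL"], "gender": ["F"], "cd4_pct": [150.0], "cd8_pct": [40.0],
            "transduction_eff_pct": [50.0], "vcn": [2.0],
        }
    ).to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="cd4_pct"):
        load_sample_sheet(path)
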