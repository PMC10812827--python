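"""Time-course matrices, Pearson HCA, PCA, wave filters, enrichment and
rank tests — including the exhaustive small-n oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from oxwave.io import DesignTable
from oxwave.waves import (avg_gt, build_timecourse_matrix, extract_wave_cluster,
                          group_difference_tests, hca_pearson, hypergeom_sf,
                          max_gt, monte_carlo_enrichment_p,
                          oxidized_protein_enrichment, pca_scores, ptm_enrichment)


def _design(n_tp=4, n_rep=2):
    rows = []
    for r in range(n_rep):
        plex = f"plex{r + 1}"
        rows.append((plex, 1, f"{plex}_ref", "reference", "", True))
        for g in range(n_tp):
            rows.append((plex, 2 + g, f"t{g}_r{r + 1}", f"t{g}", f"t{g}", False))
    return DesignTable(pd.DataFrame(rows, columns=[
        "plex_id", "channel_index", "sample_id", "group_label",
        "timepoint_label", "is_reference"]))


class TestMatrix:
    def test_replicate_average(self):
        design = _design()
        z = pd.DataFrame({
            "row_id": ["a"] * 8,
            "sample_id": [f"t{g}_r{r}" for g in range(4) for r in (1, 2)],
            "z": [0.0, 2.0] + [1.0] * 6,
        })
        tc = build_timecourse_matrix(z, design)
        assert tc.values.loc["a", "t0"] == 1.0
        assert tc.n.loc["a", "t0"] == 2
        assert list(tc.values.columns) == ["t0", "t1", "t2", "t3"]

    def test_rows_with_missing_timepoint_dropped(self):
        design = _design()
        z = pd.DataFrame({"row_id": ["a", "a", "a"],
                          "sample_id": ["t0_r1", "t1_r1", "t2_r1"],
                          "z": [1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning, match="dropped"):
            tc = build_timecourse_matrix(z, design)
        assert tc.values.empty


class TestHca:
    def test_identical_rows_merge_first(self):
        m = pd.DataFrame([[0, 1, 2, 3], [0, 1, 2, 3], [3, 2, 1, 0]],
                         index=["a", "b", "c"], dtype=float)
        hca = hca_pearson(m)
        assert hca.distance.loc["a", "b"] == 0.0
        assert set(hca.linkage[0, :2]) == {0, 1}

    def test_anticorrelated_distance_two(self):
        m = pd.DataFrame([[0, 1, 2, 3], [3, 2, 1, 0]], index=["a", "b"],
                         dtype=float)
        hca = hca_pearson(m)
        assert np.isclose(hca.distance.loc["a", "b"], 2.0)

    def test_constant_row_dropped(self):
        m = pd.DataFrame([[1, 1, 1, 1], [0, 1, 2, 3], [3, 2, 1, 0]],
                         index=["flat", "up", "down"], dtype=float)
        with pytest.warns(UserWarning, match="constant"):
            hca = hca_pearson(m)
        assert "flat" not in hca.labels.index

    def test_two_templates_recovered(self):
        rng = np.random.default_rng(3)
        t1 = np.array([0, 2.5, 1.0, 0.4, 0.2, 0.1, 0.1, 0.0])
        t2 = np.array([0, 0.1, 0.3, 0.8, 1.8, 2.5, 2.0, 1.4])
        rows = np.vstack([t1 + rng.normal(0, 0.3, (100, 8)),
                          t2 + rng.normal(0, 0.3, (100, 8))])
        m = pd.DataFrame(rows, index=[f"r{i}" for i in range(200)])
        hca = hca_pearson(m, n_clusters=2)
        from sklearn.metrics import adjusted_rand_score
        truth = [0] * 100 + [1] * 100
        assert adjusted_rand_score(truth, hca.labels.to_numpy()) >= 0.9

    def test_row_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(30, 6)),
                         index=[f"r{i}" for i in range(30)])
        a = hca_pearson(m, n_clusters=3).labels
        b = hca_pearson(m.sample(frac=1.0, random_state=1), n_clusters=3).labels
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(a.loc[m.index], b.loc[m.index]) == 1.0


class TestExtract:
    def _matrix(self):
        from oxwave.waves import TimeCourseMatrix
        v = pd.DataFrame([[-1.0, -0.5, -0.2], [0.1, 0.6, 0.2], [0.0, 0.3, 0.1]],
                         index=["neg", "big", "mid"], columns=list("abc"))
        return TimeCourseMatrix(v, v * 0 + 4)

    def test_max_gt_zero_excludes_nonpositive(self):
        m = self._matrix()
        labels = pd.Series([1, 1, 1], index=m.values.index)
        res = extract_wave_cluster(m, labels, 1, filter_rule=max_gt(0.0))
        assert "neg" not in res["rows"] and set(res["rows"]) == {"big", "mid"}

    def test_avg_gt_half_includes_point_six(self):
        m = self._matrix()
        labels = pd.Series([1, 1, 1], index=m.values.index)
        res = extract_wave_cluster(m, labels, 1, filter_rule=avg_gt(0.5))
        assert res["rows"] == ["big"]

    def test_minus_infinity_is_identity(self):
        m = self._matrix()
        labels = pd.Series([1, 1, 1], index=m.values.index)
        res = extract_wave_cluster(m, labels, 1, filter_rule=max_gt(-math.inf))
        assert set(res["rows"]) == set(m.values.index)


class TestPca:
    def test_duplicated_row_identical_scores(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(10, 5)))
        m.loc[10] = m.loc[3]
        scores, _, _ = pca_scores(m)
        assert np.allclose(scores.loc[3], scores.loc[10])

    def test_variance_conserved(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(20, 5)))
        scores, _, explained = pca_scores(m, n_components=5)
        total = ((m - m.mean()) ** 2).to_numpy().sum() / (len(m) - 1)
        assert np.isclose(explained.sum(), total)

    def test_sign_convention(self):
        m = pd.DataFrame([[0, 1, 2, 3], [0, 2, 4, 6], [0, 1.1, 2.2, 3.1]])
        _, loadings, _ = pca_scores(m)
        assert loadings["PC1"].iloc[np.argmax(np.abs(loadings["PC1"]))] > 0

    def test_component_reduction_warns(self):
        m = pd.DataFrame(np.random.default_rng(7).normal(size=(5, 3)))
        with pytest.warns(UserWarning, match="reducing"):
            pca_scores(m, n_components=4)


class TestHypergeometric:
    def test_hand_example(self):
        # N=10, K=5, n=4, k=4: C(5,4)/C(10,4) = 5/210
        assert np.isclose(hypergeom_sf(4, 10, 5, 4), 5 / 210)

    def test_certainty_when_all_marked(self):
        assert hypergeom_sf(3, 10, 10, 5) == 1.0

    def test_exhaustive_enumeration_oracle(self):
        """P(X >= k) agrees with brute-force enumeration of all draws for
        every (N <= 12, K, n, k)."""
        for N in range(1, 13):
            items = list(range(N))
            for K in range(N + 1):
                marked = set(items[:K])
                for n in range(N + 1):
                    draws = list(itertools.combinations(items, n))
                    for k in range(min(K, n) + 2):
                        exact = sum(1 for d in draws
                                    if len(marked & set(d)) >= k) / len(draws)
                        assert np.isclose(hypergeom_sf(k, N, K, n), exact,
                                          atol=1e-12), (N, K, n, k)

    def test_ptm_enrichment_table(self):
        pop = pd.DataFrame({"ptm_name": ["Ox"] * 60 + ["Diox"] * 60,
                            "site_residue": ["K"] * 60 + ["C"] * 60})
        cluster = pop.iloc[:55]          # heavily enriched for (Ox, K)
        out = ptm_enrichment(cluster, pop, min_psms=50)
        best = out.iloc[0]
        assert (best["ptm_name"], best["site_residue"]) == ("Ox", "K")
        assert best["p"] < 1e-6

    def test_inconsistent_counts_rejected(self):
        pop = pd.DataFrame({"ptm_name": ["Ox"], "site_residue": ["K"]})
        cluster = pd.DataFrame({"ptm_name": ["Ox", "Ox"],
                                "site_residue": ["K", "K"]})
        with pytest.raises(ValueError, match="inconsistent"):
            ptm_enrichment(cluster, pop, min_psms=0)

    def test_monte_carlo_null_agrees(self):
        rng = np.random.default_rng(8)
        cluster = np.zeros(60, bool)
        cluster[:20] = True
        marked = rng.random(60) < 0.4
        k = int((cluster & marked).sum())
        p_hyper = hypergeom_sf(k, 60, int(marked.sum()), 20)
        p_mc = monte_carlo_enrichment_p(cluster, marked, n_permutations=10_000,
                                        seed=9)
        se = math.sqrt(p_hyper * (1 - p_hyper) / 10_000)
        assert abs(p_mc - p_hyper) < 2 * se + 2e-4


class TestOxidizedProteinEnrichment:
    def test_flat_protein_not_enriched(self):
        counts = pd.DataFrame({"protein": [f"P{i}" for i in range(20)],
                               "total_psms": 50,
                               "oxidized_psms": 5})     # everyone at 10%
        out = oxidized_protein_enrichment(counts)
        assert (out["p"] > 0.3).all()

    def test_fully_oxidized_protein_enriched(self):
        counts = pd.DataFrame({"protein": [f"P{i}" for i in range(20)],
                               "total_psms": [10] * 20,
                               "oxidized_psms": [10] + [1] * 19})
        out = oxidized_protein_enrichment(counts)
        assert out.iloc[0]["protein"] == "P0" and out.iloc[0]["p"] < 0.01


class TestGroupTests:
    def test_mann_whitney_exact_hand_case(self):
        u, p = group_difference_tests([[1, 2, 3], [4, 5, 6]], test="mann_whitney")
        assert u == 0.0 and np.isclose(p, 0.1)

    def test_identical_groups(self):
        h, p = group_difference_tests([[1.0, 1.0], [1.0, 1.0]],
                                      test="kruskal_wallis")
        assert h == 0.0 and p == 1.0

    def test_kruskal_matches_permutation_oracle(self):
        """Exact KW p agrees with an independent enumeration over all
        distinct value-to-group assignments (total n <= 8)."""
        from scipy.stats import rankdata
        rng = np.random.default_rng(10)
        for sizes in [(3, 3), (2, 3, 3), (4, 4), (2, 2, 2)]:
            vals = rng.normal(size=sum(sizes))
            groups = []
            start = 0
            for s in sizes:
                groups.append(vals[start:start + s])
                start += s
            h_obs, p = group_difference_tests(groups, test="kruskal_wallis")

            def oracle_h(assign):
                ranks = rankdata(vals)
                h = 0.0
                for gi in range(len(sizes)):
                    r = ranks[[i for i, a in enumerate(assign) if a == gi]]
                    h += r.sum() ** 2 / len(r)
                n = len(vals)
                return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)

            assign0 = [gi for gi, s in enumerate(sizes) for _ in range(s)]
            count = total = 0
            for perm in set(itertools.permutations(assign0)):
                # enumerate group-label multisets instead of value orders
                ranks = rankdata(vals)
                h = 0.0
                for gi in range(len(sizes)):
                    r = ranks[[i for i, a in enumerate(perm) if a == gi]]
                    h += r.sum() ** 2 / len(r)
                n = len(vals)
                h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
                total += 1
                count += h >= h_obs - 1e-12
            assert np.isclose(p, count / total), sizes

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_difference_tests([[1.0], []], test="mann_whitney")
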