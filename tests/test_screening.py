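"""Fractional differences, outlier masking, clustering, tests, PCA."""

import numpy as np
import pandas as pd
import pytest

import cytoscreen as cs
from cytoscreen.screening import FDMatrix, _masked_distance


def fd_matrix(values: np.ndarray, columns=None) -> FDMatrix:
    columns = columns or [f"drug{i+1}" for i in range(values.shape[1])]
    idx = pd.MultiIndex.from_tuples(
        [("subset", f"m{i}") for i in range(values.shape[0])]
    )
    return FDMatrix(pd.DataFrame(values, index=idx, columns=columns))


class TestFractionalDifference:
    def test_equal_mfis_give_exactly_zero(self):
        assert cs.fractional_difference(432.1, 432.1) == 0.0

    def test_doubling_and_quartering(self):
        assert cs.fractional_difference(200.0, 100.0) == pytest.approx(1.0)
        assert cs.fractional_difference(25.0, 100.0) == pytest.approx(-0.75)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            cs.fractional_difference(10.0, 0.0)

    def test_missing_treatment_propagates(self):
        out = cs.fractional_difference(np.array([np.nan, 100.0]), np.array([50.0, 50.0]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(1.0)

    def test_fd_of_condition_against_itself_is_zero_everywhere(self):
        rng = np.random.default_rng(0)
        mfi = rng.lognormal(7, 1, 50)
        assert np.all(cs.fractional_difference(mfi, mfi) == 0.0)


class TestMaskOutliers:
    def test_figure_legend_example(self):
        fd = fd_matrix(np.array([[-1.7], [-1.2], [0.0], [1.2], [1.7]]))
        masked = cs.mask_outliers(fd)
        assert masked.mask.to_numpy().ravel().tolist() == [True, False, False, False, True]

    def test_values_exactly_at_150_percent_retained(self):
        fd = fd_matrix(np.array([[-1.5], [1.5]]))
        assert not cs.mask_outliers(fd).mask.any().any()

    def test_all_zero_matrix_unchanged(self):
        fd = fd_matrix(np.zeros((4, 2)))
        out = cs.mask_outliers(fd)
        assert not out.mask.any().any()
        assert out.values.equals(fd.values)

    def test_masking_is_idempotent_and_preserves_values(self):
        rng = np.random.default_rng(1)
        fd = fd_matrix(rng.normal(0, 1.2, (30, 3)))
        once = cs.mask_outliers(fd)
        twice = cs.mask_outliers(once)
        assert once.mask.equals(twice.mask)
        assert once.values.equals(fd.values)


class TestClusterColumns:
    def test_duplicate_pairs_merge_before_cross_merges(self):
        a = np.zeros(10)
        b = np.full(10, 50.0)
        fd = fd_matrix(np.column_stack([a, a, b, b]), ["A", "A2", "B", "B2"])
        clust = cs.cluster_columns(fd)
        heights = clust.linkage[:, 2]
        assert heights[0] == 0.0 and heights[1] == 0.0  # the two twin merges
        order = clust.order
        assert abs(order.index("A") - order.index("A2")) == 1
        assert abs(order.index("B") - order.index("B2")) == 1

    def test_matches_naive_agglomeration_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0, 1, (12, 5))
        fd = fd_matrix(values)
        clust = cs.cluster_columns(fd)

        # brute-force complete-linkage agglomeration
        clusters = [{i} for i in range(5)]
        d = {(i, j): np.linalg.norm(values[:, i] - values[:, j])
             for i in range(5) for j in range(i + 1, 5)}
        merge_heights = []
        while len(clusters) > 1:
            best, pair = None, None
            for ci in range(len(clusters)):
                for cj in range(ci + 1, len(clusters)):
                    h = max(
                        d[tuple(sorted((i, j)))]
                        for i in clusters[ci] for j in clusters[cj]
                    )
                    if best is None or h < best:
                        best, pair = h, (ci, cj)
            merge_heights.append(best)
            ci, cj = pair
            clusters[ci] |= clusters[cj]
            del clusters[cj]
        assert np.allclose(np.sort(clust.linkage[:, 2]), np.sort(merge_heights))

    def test_single_pair_merges_at_euclidean_distance(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, (8, 2))
        clust = cs.cluster_columns(fd_matrix(values))
        expected = np.linalg.norm(values[:, 0] - values[:, 1])
        assert clust.linkage[0, 2] == pytest.approx(expected)

    def test_masked_distance_rescales_for_missingness(self):
        # homogeneous per-row differences: dropping observations must leave
        # the rescaled distance unchanged
        values = np.array([[0.0, 3.0]] * 4)
        mask = np.zeros_like(values, dtype=bool)
        full = _masked_distance(values, mask)[0]
        mask[2:, 0] = True  # half the rows unobserved in column 0
        half = _masked_distance(values, mask)[0]
        assert half == pytest.approx(full)

    def test_no_overlap_raises_connectivity_error(self):
        values = np.array([[1.0, np.nan], [np.nan, 1.0]])
        fd = fd_matrix(values)
        with pytest.raises(ValueError, match="no unmasked rows"):
            cs.cluster_columns(fd)


class TestTTests:
    def test_symmetric_pair_is_null(self):
        t, df, p, stars = cs.one_sample_t([-1.0, 1.0])
        assert t == 0.0 and p == pytest.approx(1.0) and stars == "ns" and df == 1

    def test_textbook_one_sample_case(self):
        t, df, p, stars = cs.one_sample_t([1, 2, 3, 4, 5, 6])
        assert t == pytest.approx(4.583, abs=1e-3)
        assert df == 5
        assert p == pytest.approx(0.0060, abs=2e-4)
        assert stars == "**"

    def test_zero_variance_is_not_testable(self):
        with pytest.raises(cs.UndefinedTestError):
            cs.one_sample_t([2.0, 2.0, 2.0])

    def test_two_sample_identical_groups_null(self):
        x = [1.0, 2.0, 3.0]
        t, df, p, stars = cs.two_sample_t(x, x)
        assert t == 0.0 and p == pytest.approx(1.0) and df == 4

    def test_two_sample_extreme_separation(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1e-3, 5)
        b = 1 + rng.normal(0, 1e-3, 5)
        _, _, p, stars = cs.two_sample_t(a, b)
        assert p < 0.001 and stars == "***"

    def test_pooled_variance_formula_oracle(self):
        a = np.array([3.1, 2.8, 3.5, 3.0, 2.9])
        b = np.array([2.2, 2.6, 2.1, 2.5, 2.0])
        t, df, p, _ = cs.two_sample_t(a, b)
        sp2 = ((4 * a.var(ddof=1)) + (4 * b.var(ddof=1))) / 8
        expected_t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 5 + 1 / 5))
        assert t == pytest.approx(expected_t, rel=1e-12)
        assert df == 8

    def test_type_one_error_rate_near_alpha(self):
        # small-scale null calibration; the 10k-feature version runs in the
        # acceptance suite
        rng = np.random.default_rng(6)
        rejections = 0
        n_feat = 2000
        for _ in range(n_feat):
            _, _, p, _ = cs.one_sample_t(rng.normal(0, 0.2, 6))
            rejections += p < 0.05
        assert 0.035 <= rejections / n_feat <= 0.065


class TestNormalisationAndPCA:
    def test_minmax_simple_and_constant(self):
        assert cs.minmax_normalize([2.0, 4.0, 6.0]) == pytest.approx([0.0, 0.5, 1.0])
        assert cs.minmax_normalize([3.0, 3.0, 3.0]) == pytest.approx([0.0, 0.0, 0.0])

    def test_minmax_bounds(self):
        x = np.random.default_rng(7).normal(0, 10, 100)
        out = cs.minmax_normalize(x)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_variance_filter_drops_constant_feature(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(0, 1, (20, 10)),
                          columns=[f"f{i}" for i in range(10)])
        df["f3"] = 1.0
        retained = cs.variance_filter(df, 0.10)
        assert "f3" not in retained and len(retained) == 9

    def test_variance_filter_zero_fraction_keeps_all(self):
        df = pd.DataFrame(np.random.default_rng(9).normal(0, 1, (5, 7)))
        assert cs.variance_filter(df, 0.0) == list(df.columns)

    def test_variance_filter_matches_sort_oracle(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(0, rng.uniform(0.1, 3, 20), (30, 20)),
                          columns=[f"f{i}" for i in range(20)])
        retained = cs.variance_filter(df, 0.10)
        order = df.var(ddof=1).sort_values(kind="stable")
        dropped = set(order.index[:2])
        assert set(df.columns) - set(retained) == dropped

    def test_rank_one_data_loads_on_first_component(self):
        rng = np.random.default_rng(11)
        t = rng.normal(0, 1, 10)
        df = pd.DataFrame(np.outer(t, [1.0, 2.0, -1.0, 0.5]))
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=df.index)
        emb = cs.pca_embed(df, groups, n_components=3)
        assert emb.explained_variance_ratio[0] >= 0.999

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, (6, 8))
        df = pd.DataFrame(X)
        groups = pd.Series(["a", "a", "a", "b", "b", "b"], index=df.index)
        emb = cs.pca_embed(df, groups, n_components=3)
        C = np.cov((X - X.mean(axis=0)).T, bias=False)
        w, v = np.linalg.eigh(C)
        idx = np.argsort(w)[::-1][:3]
        for k, j in enumerate(idx):
            oracle = (X - X.mean(axis=0)) @ v[:, j]
            got = emb.scores.iloc[:, k].to_numpy()
            assert np.allclose(np.abs(got), np.abs(oracle), atol=1e-8)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(rng.normal(0, 1, (8, 5)))
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=df.index)
        emb = cs.pca_embed(df, groups)
        for c in emb.loadings.columns:
            col = emb.loadings[c].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_too_few_donors_rejected(self):
        df = pd.DataFrame(np.random.default_rng(14).normal(0, 1, (3, 5)))
        groups = pd.Series(["a", "a", "b"], index=df.index)
        with pytest.raises(ValueError, match="donors"):
            cs.pca_embed(df, groups, n_components=3)


class TestSeparationScore:
    def _embed(self, scores, labels):
        scores = pd.DataFrame(scores, columns=["PC1", "PC2", "PC3"])
        return cs.CohortEmbedding(
            scores=scores,
            loadings=pd.DataFrame(),
            explained_variance_ratio=np.array([1.0, 0.0, 0.0]),
            retained_features=[],
            groups=pd.Series(labels, index=scores.index),
        )

    def test_well_separated_clouds_score_high(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0, 1, (10, 3))
        b = rng.normal(10, 1, (10, 3))  # 10 sigma apart
        emb = self._embed(np.vstack([a, b]), ["a"] * 10 + ["b"] * 10)
        assert cs.separation_score(emb) > 0.5

    def test_shuffled_labels_score_near_zero(self):
        rng = np.random.default_rng(16)
        pts = rng.normal(0, 1, (10, 3))
        labels = list("ababababab")
        emb = self._embed(pts, labels)
        assert abs(cs.separation_score(emb)) < 0.3

    def test_vanishing_within_group_spread_approaches_one(self):
        for eps in (1e-1, 1e-3):
            rng = np.random.default_rng(17)
            a = rng.normal(0, eps, (5, 3))
            b = 5 + rng.normal(0, eps, (5, 3))
            emb = self._embed(np.vstack([a, b]), ["a"] * 5 + ["b"] * 5)
            last = cs.separation_score(emb)
        assert last > 0.999

    def test_single_group_rejected(self):
        emb = self._embed(np.random.default_rng(18).normal(0, 1, (6, 3)), ["a"] * 6)
        with pytest.raises(ValueError, match="2 groups"):
            cs.separation_score(emb)


class TestScreenOrchestration:
    def _mfi_table(self, effect_on=None, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        base = {("s1", "m1"): 1000.0, ("s1", "m2"): 300.0, ("s2", "m1"): 5000.0}
        for donor in [f"D{i}" for i in range(6)]:
            for cond in ("DMSO", "drugA", "drugB"):
                for (sub, mark), mu in base.items():
                    noise = rng.lognormal(0, 0.02)
                    k = 1.5 if (effect_on == (cond, sub, mark)) else 1.0
                    rows.append(
                        dict(donor=donor, condition=cond, subset=sub,
                             marker=mark, mfi=mu * k * noise)
                    )
        return pd.DataFrame(rows)

    def test_self_control_yields_zero_fd(self):
        table = self._mfi_table()
        dup = table[table.condition == "DMSO"].assign(condition="copy")
        merged = pd.concat(
            [table[table.condition == "DMSO"], dup], ignore_index=True
        )
        # identical per-donor values: FD must be exactly 0 feature-wise
        result = cs.screen(merged, control="DMSO")
        assert (result.fd.values["copy"] == 0.0).all()

    def test_injected_effect_recovered_and_significant(self):
        table = self._mfi_table(effect_on=("drugA", "s1", "m2"), seed=1)
        result = cs.screen(table)
        hit = result.tests.query(
            "subset=='s1' and marker=='m2' and treatment=='drugA'"
        ).iloc[0]
        assert hit["mean_fd"] == pytest.approx(0.5, abs=0.05)
        assert hit["p"] < 0.01

    def test_missing_control_rejected(self):
        table = self._mfi_table()
        with pytest.raises(ValueError, match="control"):
            cs.screen(table[table.condition != "DMSO"], control="DMSO")

    def test_row_permutation_of_donors_commutes_with_pipeline(self):
        rng = np.random.default_rng(20)
        df = pd.DataFrame(rng.normal(0, 1, (8, 10)),
                          index=[f"D{i}" for i in range(8)])
        perm = df.sample(frac=1, random_state=1)
        a = df.apply(lambda c: pd.Series(cs.minmax_normalize(c), index=c.index))
        b = perm.apply(lambda c: pd.Series(cs.minmax_normalize(c), index=c.index))
        assert cs.variance_filter(a, 0.1) == cs.variance_filter(b, 0.1)
        assert np.allclose(a.loc[df.index], b.loc[df.index])
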