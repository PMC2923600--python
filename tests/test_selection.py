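import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pcaim import (
    PCAIMSelector,
    PCAModel,
    ValidationError,
    build_panels,
    build_pool,
    compute_pcaim_scores,
    encode_and_center,
    fit_pca,
    greedy_redundancy_prune,
    write_panel,
)

from conftest import make_genotypes


def naive_greedy(pool_cols, r2_threshold, target_size):
    """Independent re-execution of the greedy definition: scan candidates in
    order, accept iff squared Pearson correlation with every accepted
    candidate stays <= threshold."""
    accepted = []
    for i in range(pool_cols.shape[1]):
        ok = True
        for j in accepted:
            a, b = pool_cols[:, i], pool_cols[:, j]
            if a.std() == 0 or b.std() == 0:
                continue  # zero-variance columns correlate with nothing
            r = np.corrcoef(a, b)[0, 1]
            if r**2 > r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(i)
            if len(accepted) == target_size:
                break
    return accepted


def centered_matrix(values, ids=None):
    g = make_genotypes(values, snp_ids=ids)
    return encode_and_center(g)


class TestScores:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 3))
    def test_scores_sum_to_component_count(self, seed, k):
        rng = np.random.default_rng(seed)
        x = centered_matrix(rng.integers(0, 3, size=(12, 8)).astype(float))
        m = fit_pca(x, k=k)
        table = compute_pcaim_scores(m)
        assert table["score"].sum() == pytest.approx(k, abs=1e-6)
        assert sorted(table["rank"]) == list(range(1, 9))

    def test_identity_loadings_give_unit_scores(self):
        m = PCAModel(
            k=2,
            right_vectors=np.eye(2),
            singular_values=np.array([2.0, 1.0]),
            column_means=np.zeros(2),
            training_scores=np.zeros((3, 2)),
            snp_ids=["a", "b"],
        )
        table = compute_pcaim_scores(m)
        np.testing.assert_allclose(table["score"], [1.0, 1.0])

    def test_scores_match_gram_eigendecomposition_oracle(self):
        rng = np.random.default_rng(11)
        x = centered_matrix(rng.integers(0, 3, size=(10, 8)).astype(float))
        m = fit_pca(x, k=2)
        table = compute_pcaim_scores(m).set_index("snp_id")
        evals, evecs = np.linalg.eigh(x.values.T @ x.values)
        top = np.argsort(evals)[::-1][:2]
        oracle = (evecs[:, top] ** 2).sum(axis=1)
        for j, sid in enumerate(x.snp_ids):
            assert table.loc[sid, "score"] == pytest.approx(oracle[j], abs=1e-8)

    def test_ties_broken_lexicographically(self):
        # two identical columns -> equal scores; ranking must order by id
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=10).astype(float)
        other = rng.integers(0, 3, size=(10, 2)).astype(float)
        values = np.column_stack([col, other, col])
        x = centered_matrix(values, ids=["zz", "mm", "aa", "bb"])
        m = fit_pca(x, k=2)
        table = compute_pcaim_scores(m)
        dup = table[table["snp_id"].isin(["zz", "bb"])]
        assert dup.iloc[0]["snp_id"] == "bb"  # lexicographic before "zz"


class TestPool:
    def test_pool_of_all_snps_is_rank_order(self, small_cohort):
        g, _, _ = small_cohort
        x = encode_and_center(g)
        m = fit_pca(x, k=2)
        table = compute_pcaim_scores(m)
        pool = build_pool(table, g.n_snps)
        assert pool == table.sort_values("rank")["snp_id"].tolist()

    def test_pool_size_one_is_top_snp(self, small_cohort):
        g, _, _ = small_cohort
        table = compute_pcaim_scores(fit_pca(encode_and_center(g), k=2))
        pool = build_pool(table, 1)
        assert pool == [table.loc[table["rank"] == 1, "snp_id"].iloc[0]]

    def test_oversized_pool_rejected(self, small_cohort):
        g, _, _ = small_cohort
        table = compute_pcaim_scores(fit_pca(encode_and_center(g), k=2))
        with pytest.raises(ValidationError):
            build_pool(table, g.n_snps + 1)


class TestGreedyPruning:
    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, size=12).astype(float)
        others = rng.integers(0, 3, size=(12, 3)).astype(float)
        values = np.column_stack([col, col, others])
        x = centered_matrix(values, ids=["keep", "dupe", "c", "d", "e"])
        panel = greedy_redundancy_prune(
            ["keep", "dupe", "c", "d", "e"], x, r2_threshold=0.99, target_size=4
        )
        assert "keep" in panel.snp_ids and "dupe" not in panel.snp_ids

    def test_orthogonal_columns_untouched(self):
        # pairwise-uncorrelated centered columns: nothing is pruned
        values = np.array(
            [
                [0, 0, 0, 0, 0],
                [2, 0, 0, 0, 0],
                [1, 2, 0, 0, 0],
                [1, 0, 2, 0, 0],
                [1, 1, 1, 2, 0],
                [1, 1, 1, 0, 2],
                [1, 1, 1, 1, 1],
                [1, 1, 1, 1, 1],
            ],
            dtype=float,
        )
        x = centered_matrix(values)
        corr = np.corrcoef(x.values.T)
        ids = x.snp_ids
        panel = greedy_redundancy_prune(ids, x, r2_threshold=0.95, target_size=5)
        expected = naive_greedy(x.values, 0.95, 5)
        assert panel.snp_ids == [ids[i] for i in expected]

    def test_constructed_instance_matches_exhaustive_oracle(self):
        # 6 SNPs with a planted correlation structure
        rng = np.random.default_rng(3)
        base = rng.normal(size=20)
        cols = np.column_stack(
            [
                base,
                base + 0.1 * rng.normal(size=20),  # r2 ~ 0.99 with base
                rng.normal(size=20),
                base + rng.normal(size=20),  # moderate correlation
                rng.normal(size=20),
                -base + 0.2 * rng.normal(size=20),  # strongly anticorrelated
            ]
        )
        cols = np.round((cols - cols.min()) / (cols.max() - cols.min()) * 2)
        x = centered_matrix(cols)
        ids = x.snp_ids
        for thr in (0.3, 0.6, 0.9):
            panel = greedy_redundancy_prune(ids, x, r2_threshold=thr, target_size=6)
            expected = naive_greedy(x.values, thr, 6)
            assert panel.snp_ids == [ids[i] for i in expected], thr

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.integers(0, 2**31 - 1),
        st.integers(4, 10),
        st.sampled_from([0.2, 0.5, 0.8, 1.0]),
    )
    def test_random_instances_match_naive_greedy(self, seed, p, thr):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 3, size=(15, p)).astype(float)
        x = centered_matrix(values)
        ids = x.snp_ids
        panel = greedy_redundancy_prune(ids, x, r2_threshold=thr, target_size=p)
        expected = naive_greedy(x.values, thr, p)
        assert panel.snp_ids == [ids[i] for i in expected]

    def test_emitted_panel_satisfies_pairwise_r2_bound(self, small_cohort):
        g, _, _ = small_cohort
        x = encode_and_center(g)
        panels = build_panels(x, sizes=[30], pool_size=200, r2_threshold=0.5)
        cols = [x.snp_ids.index(s) for s in panels[0].snp_ids]
        sub = x.values[:, cols]
        corr = np.corrcoef(sub.T)
        np.fill_diagonal(corr, 0.0)
        assert (corr**2).max() <= 0.5 + 1e-12

    def test_target_exceeding_pool_rejected(self, small_cohort):
        g, _, _ = small_cohort
        x = encode_and_center(g)
        with pytest.raises(ValidationError):
            greedy_redundancy_prune(x.snp_ids[:5], x, target_size=6)

    def test_exhausted_pool_warns_and_returns_short_panel(self):
        rng = np.random.default_rng(4)
        col = rng.integers(0, 3, size=12).astype(float)
        values = np.column_stack([col, col, col])
        x = centered_matrix(values)
        with pytest.warns(UserWarning, match="exhausted"):
            panel = greedy_redundancy_prune(
                x.snp_ids, x, r2_threshold=0.5, target_size=3
            )
        assert len(panel) == 1 and panel.provenance["exhausted"]


class TestBuildPanels:
    def test_nested_panels(self, small_cohort):
        g, _, _ = small_cohort
        x = encode_and_center(g)
        panels = build_panels(x, sizes=[10, 20, 40], pool_size=200)
        assert [len(p) for p in panels] == [10, 20, 40]
        assert panels[2].snp_ids[:10] == panels[0].snp_ids
        assert panels[2].snp_ids[:20] == panels[1].snp_ids

    def test_all_snps_with_unit_threshold_is_score_order(self, small_cohort):
        g, _, _ = small_cohort
        x = encode_and_center(g)
        n = g.n_snps
        panels = build_panels(x, sizes=[n], pool_size=n, r2_threshold=1.0)
        table = compute_pcaim_scores(fit_pca(x, k=2))
        assert panels[0].snp_ids == table.sort_values("rank")["snp_id"].tolist()

    def test_single_snp_panel_is_top_scored(self, small_cohort):
        g, _, _ = small_cohort
        x = encode_and_center(g)
        panels = build_panels(x, sizes=[1], pool_size=100)
        table = compute_pcaim_scores(fit_pca(x, k=2))
        assert panels[0].snp_ids == [table.loc[table["rank"] == 1, "snp_id"].iloc[0]]

    def test_byte_identical_panel_files_across_runs(self, tmp_path, small_cohort):
        g, _, _ = small_cohort
        for run in ("a", "b"):
            x = encode_and_center(g)
            panels = build_panels(x, sizes=[25], pool_size=150)
            write_panel(panels[0], tmp_path / f"panel_{run}.tsv")
        assert (tmp_path / "panel_a.tsv").read_bytes() == (
            tmp_path / "panel_b.tsv"
        ).read_bytes()

    def test_descending_score_order(self, small_cohort):
        g, _, _ = small_cohort
        panels = build_panels(encode_and_center(g), sizes=[30], pool_size=200)
        s = panels[0].scores
        assert (np.diff(s) <= 1e-15).all()


class TestSelectorEstimator:
    def test_selector_agrees_with_build_panels(self, small_cohort):
        g, _, _ = small_cohort
        x = encode_and_center(g)
        panels = build_panels(x, sizes=[15], pool_size=100)
        sel = PCAIMSelector(panel_size=15, pool_size=100).fit(g.values)
        got = [g.snp_ids[j] for j in sel.panel_indices_]
        assert got == panels[0].snp_ids

    def test_transform_selects_panel_columns(self, small_cohort):
        g, _, _ = small_cohort
        sel = PCAIMSelector(panel_size=10, pool_size=50).fit(g.values)
        out = sel.transform(g.values)
        assert out.shape == (g.n_samples, 10)
        np.testing.assert_array_equal(out, g.values[:, sel.panel_indices_])

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        sel = PCAIMSelector(panel_size=9, r2_threshold=0.7)
        params = clone(sel).get_params()
        assert params["panel_size"] == 9 and params["r2_threshold"] == 0.7
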