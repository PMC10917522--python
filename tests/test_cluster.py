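"""Profile clustering, node-depth extraction and enrichment."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import brewtrack as bt
from brewtrack.errors import InputError


def exact_hypergeom_tail(M, K, N, k):
    """Exhaustive-enumeration upper tail P(X >= k) with exact arithmetic."""
    total = Fraction(0)
    for i in range(k, min(K, N) + 1):
        total += Fraction(math.comb(K, i) * math.comb(M - K, N - i), math.comb(M, N))
    return float(total)


class TestRowMeanNormalizeFilter:
    def test_flat_rows_filtered_changing_rows_kept(self):
        df = pd.DataFrame({
            "t1": [5.0, 0.0, 1.0],
            "t2": [5.0, 2.5, 1.2],
            "t3": [5.0, 0.0, 0.8],
        }, index=["flat", "spiky", "small"])
        out = bt.row_mean_normalize_filter(df, fold_threshold=2.0)
        assert list(out.index) == ["spiky"]
        assert np.allclose(out.sum(axis=1), 0.0)

    def test_retained_set_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(0, 1, (200, 8)),
                          index=[f"P{i}" for i in range(200)])
        out = bt.row_mean_normalize_filter(df, fold_threshold=2.0)
        expected = [idx for idx, row in df.iterrows()
                    if np.max(np.abs(row - row.mean())) >= 1.0]
        assert list(out.index) == expected

    def test_empty_matrix_rejected(self):
        with pytest.raises(InputError):
            bt.row_mean_normalize_filter(pd.DataFrame())


def _planted_profiles(n_per_group=4, noise=0.01, seed=0):
    rng = np.random.default_rng(seed)
    up = np.linspace(-1, 1, 6)
    down = -up
    rows, names = [], []
    for g, base in enumerate((up, down)):
        for i in range(n_per_group):
            rows.append(base + rng.normal(0, noise, 6))
            names.append(f"g{g}_p{i}")
    return pd.DataFrame(rows, index=names)


class TestClusterRows:
    def test_identical_rows_merge_first_at_zero_distance(self):
        df = _planted_profiles(n_per_group=2)
        df.loc["g0_p1"] = df.loc["g0_p0"]
        tree = bt.cluster_rows(df)
        first = tree.linkage[0]
        assert first[2] == pytest.approx(0.0, abs=1e-12)
        merged = {tree.ids[int(first[0])], tree.ids[int(first[1])]}
        assert merged == {"g0_p0", "g0_p1"}

    def test_first_merges_stay_within_planted_groups(self):
        df = _planted_profiles()
        tree = bt.cluster_rows(df)
        for row in tree.linkage[:2]:
            a, b = int(row[0]), int(row[1])
            if a < len(df) and b < len(df):
                assert tree.ids[a][:2] == tree.ids[b][:2]

    def test_tree_invariant_to_row_permutation(self):
        df = _planted_profiles(n_per_group=5, noise=0.05, seed=3)
        labels_a = bt.cut_at_node_depth(bt.cluster_rows(df), depth=1)
        shuffled = df.sample(frac=1.0, random_state=1)
        labels_b = bt.cut_at_node_depth(bt.cluster_rows(shuffled), depth=1)
        joined = labels_a.join(labels_b, rsuffix="_b")
        table = pd.crosstab(joined["label"], joined["label_b"])
        assert (table.to_numpy() > 0).sum() == 2  # one-to-one label matching

    def test_constant_row_gets_fallback_distance(self):
        df = _planted_profiles(n_per_group=3)
        df.loc["const"] = 0.5
        with pytest.warns(UserWarning, match="constant"):
            tree = bt.cluster_rows(df)
        assert tree.n_leaves == 7

    def test_newick_export_contains_all_leaves(self):
        df = _planted_profiles()
        nwk = bt.cluster_rows(df).to_newick()
        assert nwk.endswith(";")
        for name in df.index:
            assert name in nwk


class TestCutAtNodeDepth:
    def _balanced_tree(self, n=8):
        """Profiles engineered so the dendrogram is a balanced binary tree."""
        base = np.eye(n)
        # hierarchical similarity: pair structure then quads
        df = pd.DataFrame(base + 0.001, index=[f"L{i}" for i in range(n)])
        return bt.cluster_rows(df, metric="euclidean")

    def test_full_depth_cut_gives_singletons(self):
        tree = self._balanced_tree(8)
        labels = bt.cut_at_node_depth(tree, depth=7, refine_depth=9)
        assert labels["label"].nunique() == 8

    def test_depth_one_gives_two_clusters(self):
        df = _planted_profiles(n_per_group=4, noise=0.05, seed=2)
        tree = bt.cluster_rows(df)
        labels = bt.cut_at_node_depth(tree, depth=1)
        assert labels["label"].nunique() == 2
        # the root split separates the two planted groups
        groups = labels.groupby("label").groups
        prefixes = [{name[:2] for name in idx} for idx in groups.values()]
        assert prefixes[0] != prefixes[1] and all(len(p) == 1 for p in prefixes)

    def test_cluster_count_bounded_by_two_to_depth(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            df = pd.DataFrame(rng.normal(0, 1, (30, 6)))
            df.index = [f"P{i}" for i in range(30)]
            tree = bt.cluster_rows(df)
            for depth in (1, 2, 3, 4):
                labels = bt.cut_at_node_depth(tree, depth=depth,
                                              refine_depth=depth + 2)
                assert labels["label"].nunique() <= 2 ** depth

    def test_excessive_depth_warns_and_returns_singletons(self):
        df = _planted_profiles(n_per_group=2)  # 4 leaves, height <= 3
        tree = bt.cluster_rows(df)
        with pytest.warns(UserWarning, match="depth"):
            labels = bt.cut_at_node_depth(tree, depth=10, refine_depth=12)
        assert labels["label"].nunique() == 4

    def test_large_clusters_are_refined_deeper(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(0, 1, (64, 6)),
                          index=[f"P{i}" for i in range(64)])
        tree = bt.cluster_rows(df)
        refined = bt.cut_at_node_depth(tree, depth=1, large_cluster_size=10,
                                       refine_depth=3)
        assert refined["cluster"].nunique() == 2
        assert refined["label"].str.contains(r"\.").any()
        # clusters partition the input
        assert len(refined) == 64

    def test_clusters_partition_filtered_proteins(self, small_dataset):
        m = bt.merge_replicates(bt.intensity_matrix(
            small_dataset["evidence"], small_dataset["proteome"],
            small_dataset["metadata"]))
        centred = bt.row_mean_normalize_filter(bt.log2_transform(m).values)
        tree = bt.cluster_rows(centred)
        labels = bt.cut_at_node_depth(tree, depth=2)
        assert sorted(labels.index) == sorted(centred.index)


class TestEnrich:
    def test_term_equal_to_population_has_p_one(self):
        pop = [f"P{i}" for i in range(10)]
        res = bt.enrich(pop[:4], pop, {"all": set(pop)})
        assert res.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_matches_exact_enumeration_oracle(self):
        pop = [f"P{i}" for i in range(20)]
        term = set(pop[:5])
        sample = set(pop[:4]) | {pop[10]}  # overlap 4
        res = bt.enrich(sample, pop, {"t": term})
        assert res.loc[0, "overlap"] == 4
        assert res.loc[0, "p_raw"] == pytest.approx(exact_hypergeom_tail(20, 5, 5, 4))

    def test_growing_population_without_new_overlap_decreases_p(self):
        pop_small = [f"P{i}" for i in range(20)]
        pop_big = pop_small + [f"Q{i}" for i in range(20)]
        sample = set(pop_small[:5])
        term = set(pop_small[:6])
        p_small = bt.enrich(sample, pop_small, {"t": term}).loc[0, "p_raw"]
        p_big = bt.enrich(sample, pop_big, {"t": term}).loc[0, "p_raw"]
        assert p_big < p_small

    def test_sample_outside_population_rejected(self):
        with pytest.raises(InputError):
            bt.enrich({"X"}, {"A", "B"}, {"t": {"A"}})

    def test_planted_cluster_terms_come_out_enriched(self, small_dataset):
        truth = small_dataset["truth"]
        ann = bt.generate_annotations(small_dataset["config"], truth)
        population = list(truth.cluster_labels.index)
        cluster1 = set(truth.cluster_labels.index[truth.cluster_labels == 1])
        res = bt.enrich(cluster1, population, ann["terms"])
        top = res.iloc[0]
        assert top["term_id"] == "T_cluster01"
        assert bool(top["passes"])


def test_planted_archetypes_recovered_at_depth_three():
    """Six planted trajectory archetypes are recovered by the depth-3 cut."""
    from sklearn.metrics import adjusted_rand_score

    cfg = bt.SimulationConfig(n_proteins=240, background_fraction=0.0,
                              temporal_cv=0.10, replicate_cv=0.10,
                              detection_limit=1e2, complex_specs=(), seed=21)
    records, truth = bt.generate_proteome(cfg)
    ev, meta = bt.generate_evidence(cfg, records, truth)
    m = bt.merge_replicates(bt.intensity_matrix(ev, bt.proteome_dict(records), meta))
    centred = bt.row_mean_normalize_filter(bt.log2_transform(m).values)
    labels = bt.cut_at_node_depth(bt.cluster_rows(centred), depth=3)
    ari = adjusted_rand_score(truth.cluster_labels.loc[centred.index], labels["label"])
    assert ari >= 0.9
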