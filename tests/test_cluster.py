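"""Correlation-distance UPGMA clustering and Ph-like labeling."""

import io

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from phlike import (
    DistanceMatrix,
    ExpressionMatrix,
    PH_LIKE,
    classify_samples,
    cut_tree,
    export_dendrogram,
    label_phlike,
    log_transform,
    marker_tests,
    pearson_distance_matrix,
    upgma,
)
from phlike.panel import PanelDefinition, compute_rpm, filter_genes, normalize_to_housekeeping, select_housekeeping
from phlike.stats import ContingencyTable, fisher_exact


def dm(ids, arr):
    return DistanceMatrix(values=np.asarray(arr, float), ids=tuple(ids))


def naive_upgma(d: DistanceMatrix):
    """Oracle: re-averages the original distances from leaf sets each step."""
    n = d.n
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                pairs = [d.values[x, y] for x in clusters[a] for y in clusters[b]]
                avg = float(np.mean(pairs))
                if best is None or avg < best[0]:
                    best = (avg, a, b)
        avg, a, b = best
        merges.append((clusters[a], clusters[b], avg))
        clusters[min(a, b)] = clusters[a] | clusters[b]
        del clusters[max(a, b)]
    return merges


class TestLogTransform:
    def test_anchor_values(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [0.0, 1.0]}, index=["a", "b"]), stage="normalized")
        out = log_transform(m, pseudocount=1.0).values["s"]
        assert list(out) == pytest.approx([0.0, 1.0])

    def test_monotone_within_rows(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.uniform(0, 10, (3, 6)), index=list("abc"),
                          columns=[f"s{i}" for i in range(6)])
        out = log_transform(ExpressionMatrix(df, stage="normalized")).values
        for g in "abc":
            assert (np.argsort(df.loc[g]).to_numpy() == np.argsort(out.loc[g]).to_numpy()).all()

    def test_requires_positive_pseudocount(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [1.0]}, index=["a"]), stage="normalized")
        with pytest.raises(ValueError):
            log_transform(m, pseudocount=0.0)


class TestPearsonDistance:
    def test_identical_anticorrelated_and_hand_value(self):
        df = pd.DataFrame(
            {"A": [1.0, 2, 3], "B": [2.0, 4, 6], "C": [3.0, 2, 1], "D": [1.0, 3, 2]},
            index=["g1", "g2", "g3"],
        )
        d = pearson_distance_matrix(ExpressionMatrix(df, stage="normalized"), axis="samples")
        i = {s: k for k, s in enumerate(d.ids)}
        assert d.values[i["A"], i["B"]] == pytest.approx(0.0, abs=1e-12)  # r = 1
        assert d.values[i["A"], i["C"]] == pytest.approx(2.0)  # r = -1
        assert d.values[i["A"], i["D"]] == pytest.approx(0.5)  # r = 0.5

    def test_zero_variance_entity_named(self):
        df = pd.DataFrame({"A": [1.0, 1, 1], "B": [1.0, 2, 3]}, index=["g1", "g2", "g3"])
        with pytest.raises(ValueError, match="A"):
            pearson_distance_matrix(ExpressionMatrix(df, stage="normalized"), axis="samples")


class TestUpgma:
    def test_two_leaves(self):
        t = upgma(dm("AB", [[0, 0.8], [0.8, 0]]))
        assert len(t.merges) == 1 and t.merges[0].height == pytest.approx(0.8)

    def test_three_leaf_hand_example(self):
        t = upgma(dm("ABC", [[0, 0.1, 0.5], [0.1, 0, 0.7], [0.5, 0.7, 0]]))
        assert t.merges[0].members == frozenset({0, 1})
        assert t.merges[0].height == pytest.approx(0.1)
        assert t.merges[1].height == pytest.approx(0.6)  # mean(0.5, 0.7)

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n = int(rng.integers(3, 9))
            x = rng.uniform(0.01, 2, size=(n, n))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0)
            dmat = dm([f"L{i}" for i in range(n)], d)
            mine = upgma(dmat)
            oracle = naive_upgma(dmat)
            for m, (oa, ob, oh) in zip(mine.merges, oracle):
                assert {m.left, m.right} == {oa, ob}
                assert m.height == pytest.approx(oh, rel=1e-9)

    def test_heights_match_scipy_average_linkage(self):
        rng = np.random.default_rng(22)
        for _ in range(25):
            n = int(rng.integers(4, 10))
            x = rng.uniform(0.01, 2, size=(n, n))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0)
            mine = sorted(m.height for m in upgma(dm([str(i) for i in range(n)], d)).merges)
            ref = sorted(sch.linkage(squareform(d), method="average")[:, 2])
            assert mine == pytest.approx(ref, rel=1e-9)

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(23)
        x = rng.uniform(0, 2, size=(12, 12))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        h = upgma(dm([str(i) for i in range(12)], d)).heights()
        assert all(h[i] <= h[i + 1] + 1e-12 for i in range(len(h) - 1))

    def test_exact_tie_breaks_lexicographically(self):
        # equilateral triangle: all pairs tie at 1; (0,1) must merge first
        t = upgma(dm("ABC", 1 - np.eye(3)))
        assert t.merges[0].members == frozenset({0, 1})


class TestCutTree:
    def tree(self):
        return upgma(dm("ABC", [[0, 0.1, 0.5], [0.1, 0, 0.7], [0.5, 0.7, 0]]))

    def test_k1_and_kn(self):
        t = self.tree()
        assert set(cut_tree(t, 1).values()) == {0}
        assert sorted(cut_tree(t, 3).values()) == [0, 1, 2]

    def test_k2_hand_example(self):
        got = cut_tree(self.tree(), 2)
        assert got == {"A": 0, "B": 0, "C": 1}

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            cut_tree(self.tree(), 0)
        with pytest.raises(ValueError):
            cut_tree(self.tree(), 4)


def two_cluster_matrix():
    """6 samples: first 3 high in up-markers U1,U2, low in down-marker D1."""
    p = PanelDefinition(panel_genes=("U1", "U2", "D1", "F1", "HK"),
                        housekeeping_candidates=frozenset({"HK"}),
                        markers_up=frozenset({"U1", "U2"}), markers_down=frozenset({"D1"}))
    cols = [f"s{i}" for i in range(6)]
    df = pd.DataFrame(
        [
            [8.0, 8, 9, 1, 1, 1],     # U1
            [6.0, 7, 6, 0.5, 1, 0.7], # U2
            [0.2, 0.1, 0.2, 2, 3, 2], # D1
            [1.0, 1.2, 0.9, 1.1, 1.0, 1.0],  # F1
            [1.0, 1, 1, 1, 1, 1],     # HK
        ],
        index=list(p.panel_genes), columns=cols)
    assignment = {c: (0 if i < 3 else 1) for i, c in enumerate(cols)}
    return ExpressionMatrix(df, stage="normalized"), assignment, p


class TestLabelPhlike:
    def test_dominant_cluster_labeled(self):
        m, assignment, p = two_cluster_matrix()
        calls = label_phlike(m, assignment, p)
        by = {c.sample_id: c for c in calls}
        assert all(by[f"s{i}"].label == PH_LIKE for i in range(3))
        assert all(by[f"s{i}"].label != PH_LIKE for i in range(3, 6))
        assert len({c.cluster for c in calls if c.label == PH_LIKE}) == 1

    def test_identical_profiles_tie_to_lowest_cluster_with_warning(self):
        p = PanelDefinition(panel_genes=("U1", "HK"), housekeeping_candidates=frozenset({"HK"}),
                            markers_up=frozenset({"U1"}), markers_down=frozenset())
        df = pd.DataFrame([[2.0, 2, 2, 2], [1.0, 1, 1, 1]], index=["U1", "HK"],
                          columns=list("abcd"))
        m = ExpressionMatrix(df, stage="normalized")
        with pytest.warns(UserWarning, match="tie"):
            calls = label_phlike(m, {"a": 0, "b": 0, "c": 1, "d": 1}, p)
        assert {c.label for c in calls if c.cluster == 0} == {PH_LIKE}

    def test_missing_all_markers_is_error(self):
        p = PanelDefinition(panel_genes=("U1", "F1", "HK"),
                            housekeeping_candidates=frozenset({"HK"}),
                            markers_up=frozenset({"U1"}), markers_down=frozenset())
        df = pd.DataFrame([[1.0, 2, 1, 2], [1.0, 1, 1, 1]], index=["F1", "HK"],
                          columns=list("abcd"))
        with pytest.raises(Exception, match="marker"):
            label_phlike(ExpressionMatrix(df, stage="normalized"),
                         {"a": 0, "b": 0, "c": 1, "d": 1}, p)


class TestMarkerTests:
    def test_identical_groups_give_p_one(self):
        m, assignment, p = two_cluster_matrix()
        flat = pd.concat([m.values[["s0", "s1", "s2"]]] * 2, axis=1)
        flat.columns = [f"s{i}" for i in range(6)]
        with pytest.warns(UserWarning):
            res = marker_tests(ExpressionMatrix(flat, stage="normalized"), assignment, p, 0)
        assert all(r.p_value == 1.0 for r in res)

    def test_separated_groups_match_fisher_oracle(self):
        p = PanelDefinition(panel_genes=("U1", "HK"), housekeeping_candidates=frozenset({"HK"}),
                            markers_up=frozenset({"U1"}), markers_down=frozenset())
        cols = [f"s{i}" for i in range(14)]
        vals = list(range(20, 27)) + list(range(1, 8))  # 7 high then 7 low
        df = pd.DataFrame([vals, [1] * 14], index=["U1", "HK"], columns=cols)
        m = ExpressionMatrix(df.astype(float), stage="normalized")
        assignment = {c: (0 if i < 7 else 1) for i, c in enumerate(cols)}
        res = marker_tests(m, assignment, p, 0)
        oracle = fisher_exact(ContingencyTable.from_cells(7, 0, 0, 7))
        assert res[0].p_value == pytest.approx(oracle.p_value, rel=1e-12)
        assert res[0].median_phlike > res[0].median_rest

    def test_planted_cohort_markers_significant(self, default_cohort, panel):
        rpm = compute_rpm(default_cohort.counts)
        rpm, _ = filter_genes(rpm, panel)
        hk, _ = select_housekeeping(rpm, panel=panel)
        normalized = normalize_to_housekeeping(rpm, hk)
        calls, _ = classify_samples(normalized, panel)
        phc = next(c.cluster for c in calls if c.label == PH_LIKE)
        res = marker_tests(normalized, {c.sample_id: c.cluster for c in calls}, panel, phc)
        ups = [r for r in res if r.direction == "up"]
        assert all(r.p_value <= 0.015 for r in ups)
        mdfic = next(r for r in res if r.gene == "MDFIC")
        assert mdfic.median_phlike < mdfic.median_rest


class TestNewickExport:
    def test_two_leaf_convention(self):
        t = upgma(dm("AB", [[0, 0.8], [0.8, 0]]))
        assert export_dendrogram(t) == "(A:0.4,B:0.4);"

    def test_three_leaf_round_trip(self):
        t = upgma(dm("ABC", [[0, 0.1, 0.5], [0.1, 0, 0.7], [0.5, 0.7, 0]]))
        s = export_dendrogram(t)
        tree = skbio.TreeNode.read(io.StringIO(s))
        assert sorted(x.name for x in tree.tips()) == ["A", "B", "C"]
        ab = tree.lca(["A", "B"])
        assert ab.distance(tree.find("A")) == pytest.approx(0.05)
        assert tree.find("C").length == pytest.approx(0.3)

    def test_leaf_count_preserved(self):
        rng = np.random.default_rng(30)
        x = rng.uniform(0.1, 2, size=(7, 7))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        t = upgma(dm([f"L{i}" for i in range(7)], d))
        tree = skbio.TreeNode.read(io.StringIO(export_dendrogram(t)))
        assert sum(1 for _ in tree.tips()) == 7


class TestClassificationInvariance:
    def test_depth_and_order_invariance(self, default_cohort, panel):
        counts = default_cohort.counts

        def run(c):
            rpm = compute_rpm(c)
            rpm, _ = filter_genes(rpm, panel)
            hk, _ = select_housekeeping(rpm, panel=panel)
            calls, _ = classify_samples(normalize_to_housekeeping(rpm, hk), panel)
            return {x.sample_id: x.label for x in calls}

        base = run(counts)
        scaled_vals = counts.values.copy()
        scaled_vals.iloc[:, 5] *= 7  # integer scaling keeps the counts stage valid
        scaled = run(ExpressionMatrix(scaled_vals, stage="counts"))
        assert scaled == base
        reordered = run(ExpressionMatrix(counts.values[counts.values.columns[::-1]],
                                         stage="counts"))
        assert reordered == base
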