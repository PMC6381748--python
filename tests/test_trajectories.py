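"""Trajectory measures, factor-based selection, k-medoids, heatmap ordering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from phosphoflux import differential as diff
from phosphoflux import trajectories as traj


def _diffs(fc_by_key_time, regulated_keys):
    out = {}
    for t in (5, 30, 60):
        out[t] = [diff.DiffResult(k, t, fc[t], 0.01, 5, k in regulated_keys,
                                  "up" if fc[t] > 0 else "none")
                  for k, fc in fc_by_key_time.items()]
    return out


class TestBuildTrajectories:
    def test_union_rule_includes_late_only_site(self):
        fcs = {"SP1_S1": {5: 0.0, 30: 0.1, 60: 0.9},
               "SP2_S2": {5: 0.0, 30: 0.0, 60: 0.0}}
        trs = traj.build_trajectories(_diffs(fcs, {"SP1_S1"}))
        assert [t.key for t in trs] == ["SP1_S1"]
        assert trs[0].values == (0.0, 0.0, 0.1, 0.9)
        assert trs[0].times == (0.0, 5.0, 30.0, 60.0)

    def test_no_regulated_sites(self):
        fcs = {"SP1_S1": {5: 0.0, 30: 0.0, 60: 0.0}}
        assert traj.build_trajectories(_diffs(fcs, set())) == []

    def test_site_missing_a_time_excluded(self):
        d = _diffs({"SP1_S1": {5: 0.5, 30: 0.5, 60: 0.5}}, {"SP1_S1"})
        d[60] = []
        assert traj.build_trajectories(d) == []

    def test_top_n_by_max_abs_fc(self):
        """Sort-oracle check of the most-markedly-changed selection."""
        rng = np.random.default_rng(1)
        fcs = {f"SP{i:02d}_S1": {5: rng.normal(), 30: rng.normal(),
                                 60: rng.normal()} for i in range(20)}
        keys = set(fcs)
        expected = sorted(keys, key=lambda k: (-max(abs(v)
                                                    for v in fcs[k].values()), k))[:10]
        trs = traj.build_trajectories(_diffs(fcs, keys), top_n=10)
        assert sorted(t.key for t in trs) == sorted(expected)


class TestMeasures:
    def test_constant_trajectory(self):
        m = traj.trajectory_measures(traj.Trajectory("k", (0, 5, 30, 60),
                                                     (2.0, 2.0, 2.0, 2.0)))
        for name in ("range", "sd", "slope", "total_change", "max_first_diff",
                     "mean_abs_first_diff", "mean_second_diff",
                     "mean_abs_second_diff"):
            assert m[name] == 0.0
        assert m["mean_over_time"] == 2.0
        assert m["cv"] == 0.0
        # 0/0 ratios are flagged missing, not imputed
        assert np.isnan(m["ratio_mean_abs_first_to_total"])
        assert np.isnan(m["ratio_second_to_first"])

    def test_linear_trajectory_zero_second_differences(self):
        # linear in index: equal steps, so all second differences vanish
        m = traj.trajectory_measures(traj.Trajectory("k", (0, 5, 30, 60),
                                                     (0.0, 1.0, 2.0, 3.0)))
        assert m["mean_second_diff"] == 0.0
        assert m["mean_abs_second_diff"] == 0.0

    def test_slope_normal_equation_oracle(self):
        t = np.array([0.0, 5.0, 30.0, 60.0])
        y = np.array([0.0, 0.8, 0.9, 1.0])
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        m = traj.trajectory_measures(traj.Trajectory("k", tuple(t), tuple(y)))
        assert m["slope"] == pytest.approx(beta[1], rel=1e-12)

    def test_translation_consistency(self):
        y = (0.0, 0.8, 0.9, 1.0)
        m0 = traj.trajectory_measures(traj.Trajectory("k", (0, 5, 30, 60), y))
        m1 = traj.trajectory_measures(traj.Trajectory(
            "k", (0, 5, 30, 60), tuple(v + 3.0 for v in y)))
        for name in ("range", "sd", "slope", "max_first_diff",
                     "sd_first_diff", "mean_abs_first_diff",
                     "mean_second_diff"):
            assert m1[name] == pytest.approx(m0[name], abs=1e-12)
        assert m1["mean_over_time"] == pytest.approx(m0["mean_over_time"] + 3.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            traj.trajectory_measures(traj.Trajectory("k", (0, 5), (0.0, 1.0)))


class TestMeasureSelection:
    def test_single_nonconstant_measure_selected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0],
                           "b": [0.1, 0.5, 0.9, 0.2]})
        assert traj.select_informative_measures(df, exclude=()) == ["b"]

    def test_all_constant_errors(self):
        df = pd.DataFrame({"a": [1.0] * 4, "b": [2.0] * 4})
        with pytest.raises(ValueError, match="no variance"):
            traj.select_informative_measures(df, exclude=())

    def test_two_blocks_one_representative_each(self):
        """Two internally correlated, mutually independent blocks of
        measures yield exactly one selected measure per block."""
        rng = np.random.default_rng(3)
        f1, f2 = rng.normal(size=60), rng.normal(size=60)
        df = pd.DataFrame({
            "a1": f1 + rng.normal(0, 0.05, 60),
            "a2": 2 * f1 + rng.normal(0, 0.05, 60),
            "a3": -f1 + rng.normal(0, 0.05, 60),
            "b1": f2 + rng.normal(0, 0.05, 60),
            "b2": 3 * f2 + rng.normal(0, 0.05, 60),
        })
        sel = traj.select_informative_measures(df, exclude=())
        assert len(sel) == 2
        assert any(s.startswith("a") for s in sel)
        assert any(s.startswith("b") for s in sel)

    def test_excluded_measure_absent_by_default(self):
        rng = np.random.default_rng(5)
        trs = [traj.Trajectory(f"k{i}", (0, 5, 30, 60),
                               tuple(rng.normal(size=4))) for i in range(30)]
        mm = traj.measure_matrix(trs)
        sel = traj.select_informative_measures(mm)
        assert traj.EXCLUDED_MEASURE not in sel


class TestClustering:
    def _planted(self, k, per_cluster, noise, seed):
        rng = np.random.default_rng(seed)
        centers = rng.normal(0, 5, size=(k, 3))
        rows, labels = [], []
        for c in range(k):
            for i in range(per_cluster):
                rows.append(centers[c] + rng.normal(0, noise, 3))
                labels.append(c)
        idx = [f"t{i:03d}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=idx), np.array(labels)

    def test_two_separated_clusters_perfect_recovery(self):
        X, truth = self._planted(2, 10, 0.05, seed=2)
        model = traj.cluster_trajectories(X, 2, seed=1)
        assert adjusted_rand_score(truth, model.assignments) == 1.0

    def test_k_equals_n_singletons(self):
        X, _ = self._planted(2, 3, 0.01, seed=4)
        model = traj.cluster_trajectories(X, len(X), seed=1)
        assert sorted(model.cluster_sizes().values()) == [1] * len(X)

    def test_k_exceeds_n_errors(self):
        X, _ = self._planted(2, 2, 0.01, seed=4)
        with pytest.raises(ValueError):
            traj.cluster_trajectories(X, len(X) + 1)

    def test_sizes_sum_and_seed_reproducibility(self):
        X, _ = self._planted(3, 8, 1.0, seed=6)
        m1 = traj.cluster_trajectories(X, 3, seed=9)
        m2 = traj.cluster_trajectories(X, 3, seed=9)
        assert sum(m1.cluster_sizes().values()) == len(X)
        np.testing.assert_array_equal(m1.assignments, m2.assignments)
        assert m1.medoid_keys == m2.medoid_keys

    def test_four_archetypes_label_one_to_one(self):
        """Four planted kinetic archetypes at low noise map onto the four
        named classes."""
        rng = np.random.default_rng(8)
        profiles = {
            "early-sustained": (0, 0.8, 0.8, 0.8),
            "early-transient": (0, 0.8, 0.05, 0.05),
            "intermediate": (0, 0.05, 0.8, 0.8),
            "late": (0, 0.05, 0.05, 0.8),
        }
        trs, truth = [], []
        for arch, prof in profiles.items():
            for i in range(12):
                vals = np.array(prof) + np.concatenate(
                    [[0.0], rng.normal(0, 0.04, 3)])
                trs.append(traj.Trajectory(f"{arch}-{i:02d}",
                                           (0, 5, 30, 60), tuple(vals)))
                truth.append(arch)
        mm = traj.measure_matrix(trs)
        sel = traj.select_informative_measures(mm)
        model = traj.cluster_trajectories(mm[sel], 4, seed=1,
                                          trajectories=trs)
        assert adjusted_rand_score(truth, model.assignments) == 1.0
        assert sorted(model.archetype_labels.values()) == sorted(profiles)


def _brute_force_complete_linkage_merges(D):
    """Naive agglomeration oracle: repeatedly merge the pair of clusters
    with the smallest complete-linkage (max) dissimilarity; returns the
    sequence of merged leaf sets."""
    clusters = [frozenset([i]) for i in range(len(D))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(D[i][j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
        merges.append(merged)
    return merges


def _scipy_complete_linkage_merges(D):
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform
    Z = linkage(squareform(D, checks=False), method="complete")
    n = len(D)
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        merges.append(merged)
    return merges


class TestHeatmapOrdering:
    def test_identical_rows_adjacent(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0], [9.0, 1.0, 0.0], [1.0, 2.0, 3.0]],
                          index=["a", "b", "c"])
        order = traj.order_for_heatmap(df)
        assert abs(order.index("a") - order.index("c")) == 1

    def test_single_row_identity(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["only"])
        assert traj.order_for_heatmap(df) == ["only"]

    def test_gower_matrix_direct_summation(self):
        df = pd.DataFrame([[0.0, 0.0, 0.0], [1.0, 2.0, 0.5],
                           [2.0, 4.0, 1.0], [0.0, 2.0, 0.5]],
                          index=list("abcd"))
        D = traj.gower_dissimilarity(df)
        ranges = df.max() - df.min()
        for i in range(4):
            for j in range(4):
                expected = np.mean([abs(df.iloc[i, k] - df.iloc[j, k])
                                    / ranges.iloc[k] for k in range(3)])
                assert D[i, j] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n,m,seed", [(4, 3, 0), (6, 4, 1), (8, 5, 2)])
    def test_matches_brute_force_agglomeration(self, n, m, seed):
        """The merge sequence of the agglomeration used for ordering equals
        a naive complete-linkage oracle, and the resulting leaf order keeps
        the closest pair adjacent."""
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(n, m)),
                          index=[f"r{i}" for i in range(n)])
        D = traj.gower_dissimilarity(df.sort_index())
        assert (_scipy_complete_linkage_merges(D)
                == _brute_force_complete_linkage_merges(D.tolist()))
        order = traj.order_for_heatmap(df)
        assert set(order) == set(df.index)
        pair = np.unravel_index(
            np.argmin(np.where(np.eye(n, dtype=bool), np.inf, D)), D.shape)
        ids = list(df.sort_index().index)
        assert abs(order.index(ids[pair[0]]) - order.index(ids[pair[1]])) == 1

    def test_constant_column_invariance(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(size=(6, 3)),
                          index=[f"r{i}" for i in range(6)])
        with_const = df.copy()
        with_const["const"] = 7.0
        assert traj.order_for_heatmap(df) == traj.order_for_heatmap(with_const)

    def test_row_permutation_consistency(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(rng.normal(size=(7, 4)),
                          index=[f"r{i}" for i in range(7)])
        shuffled = df.sample(frac=1.0, random_state=5)
        assert traj.order_for_heatmap(df) == traj.order_for_heatmap(shuffled)
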