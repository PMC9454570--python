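"""SOTA growth, rescue-pattern labels and hierarchical sample clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from mirrescue.clustering import (ClusteringError, SotaParams,
                                  assign_patterns, classify_pattern,
                                  default_delta, hcluster_samples,
                                  linkage_to_newick, relative_profiles,
                                  sample_distance_matrix, sota_cluster)
from mirrescue.matrix import ExpressionMatrix
from mirrescue.simulate import SimulationConfig, simulate_mrna

from conftest import make_matrix


class TestRelativeProfiles:
    def test_mean_centering(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        out = relative_profiles(df)
        assert np.allclose(out.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_row_becomes_zero(self):
        df = pd.DataFrame([[5.0] * 4], index=["g"])
        assert np.allclose(relative_profiles(df).to_numpy(), 0.0)

    def test_all_rows_centered(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(8, 2, (50, 12)))
        out = relative_profiles(df)
        assert np.abs(out.mean(axis=1)).max() < 1e-12


class TestClassifyPattern:
    @pytest.mark.parametrize("means,expected", [
        ({"C": 0, "C+P": 0, "D": 1, "D+P": 0}, "up_rescued"),
        ({"C": 0, "C+P": 0, "D": -1, "D+P": 0}, "down_rescued"),
        ({"C": 0, "C+P": 0.5, "D": 1, "D+P": 0}, "other"),  # C+P moved
        ({"C": 0, "C+P": 0, "D": 1, "D+P": 1}, "other"),    # not rescued
        ({"C": 0, "C+P": 0, "D": 0.1, "D+P": 0}, "other"),  # below delta
    ])
    def test_patterns(self, means, expected):
        assert classify_pattern(means, delta=0.2) == expected

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5),
           st.floats(-5, 5), st.floats(-10, 10))
    def test_shift_invariance(self, c, cp, d, dp, shift):
        base = {"C": c, "C+P": cp, "D": d, "D+P": dp}
        shifted = {k: v + shift for k, v in base.items()}
        assert classify_pattern(base, 0.3) == classify_pattern(shifted, 0.3)

    def test_missing_group_is_an_error(self):
        with pytest.raises(ClusteringError):
            classify_pattern({"C": 0, "D": 1}, 0.2)

    def test_default_delta_is_half_median_diff(self):
        assert default_delta([1.0, -2.0, 3.0]) == pytest.approx(1.0)


def _two_group_profiles(rng, n=10, sep=2.0, sigma=0.5, p=6):
    half = n // 2
    a = rng.normal(-sep / 2, sigma, (half, p))
    b = rng.normal(sep / 2, sigma, (n - half, p))
    X = np.vstack([a, b])[rng.permutation(n)]
    return pd.DataFrame(X, index=[f"x{i}" for i in range(n)])


def _best_2partition(X: np.ndarray) -> frozenset:
    """Exhaustive minimum within-cluster-distance 2-partition (euclidean
    distance to the cluster centroid)."""
    n = X.shape[0]
    best, best_cost = None, np.inf
    for bits in range(1, 2 ** (n - 1)):
        mask = np.array([(bits >> i) & 1 for i in range(n)], bool)
        if mask.all() or (~mask).all():
            continue
        cost = 0.0
        for m in (mask, ~mask):
            c = X[m].mean(axis=0)
            cost += np.sqrt(((X[m] - c) ** 2).sum(axis=1)).sum()
        if cost < best_cost:
            best_cost, best = cost, mask
    return frozenset(np.flatnonzero(best))


class TestSota:
    def test_two_separated_groups_match_bruteforce_partition(self):
        rng = np.random.default_rng(1)
        agree = 0
        for _ in range(20):
            prof = _two_group_profiles(rng, n=10, sep=2.0, sigma=0.5)
            params = SotaParams(max_cycles=1, distance="euclidean",
                                epochs_per_cycle=300)
            _, assignment = sota_cluster(prof, params)
            got = frozenset(np.flatnonzero(
                assignment.labels.to_numpy() == assignment.labels.iloc[0]))
            X = prof.to_numpy()
            want = _best_2partition(X)
            n = X.shape[0]
            if got in (want, frozenset(range(n)) - want):
                agree += 1
        assert agree >= 19

    def test_duplicated_profile_degenerates_to_one_leaf(self):
        prof = pd.DataFrame(np.tile([1.0, 2.0, 3.0, 4.0], (8, 1)),
                            index=[f"x{i}" for i in range(8)])
        params = SotaParams(distance="euclidean", max_cycles=5,
                            epochs_per_cycle=50,
                            variability_threshold=1e-6)
        tree, assignment = sota_cluster(prof, params)
        assert assignment.labels.nunique() == 1
        assert len(tree.leaf_ids) == 2  # growth halted at the first cycle
        assert max(tree.resources.values()) == 0.0

    def test_seeded_run_is_deterministic(self):
        rng = np.random.default_rng(2)
        prof = _two_group_profiles(rng, n=12)
        params = SotaParams(max_cycles=3, epochs_per_cycle=100,
                            distance="euclidean", shuffle=True, seed=5)
        t1, a1 = sota_cluster(prof, params)
        t2, a2 = sota_cluster(prof, params)
        pd.testing.assert_series_equal(a1.labels, a2.labels)
        assert t1.to_newick() == t2.to_newick()

    def test_nan_profiles_rejected(self):
        prof = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ClusteringError):
            sota_cluster(prof, SotaParams())

    def test_final_assignment_is_nearest_leaf(self):
        rng = np.random.default_rng(3)
        prof = _two_group_profiles(rng, n=16, sep=1.0)
        params = SotaParams(max_cycles=4, epochs_per_cycle=100,
                            distance="euclidean")
        tree, assignment = sota_cluster(prof, params)
        leaf_ids = [lid for lid in tree.leaf_ids]
        C = np.stack([tree.nodes[lid].centroid for lid in leaf_ids])
        X = prof.to_numpy()
        d = np.sqrt(((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2))
        nearest = [leaf_ids[k] for k in d.argmin(axis=1)]
        assert list(assignment.labels) == nearest

    def test_total_resource_nonincreasing_with_more_cycles(self):
        rng = np.random.default_rng(4)
        prof = _two_group_profiles(rng, n=20, sep=1.5)
        totals = []
        for cycles in (1, 2, 4, 6):
            params = SotaParams(max_cycles=cycles, epochs_per_cycle=150,
                                distance="euclidean")
            tree, assignment = sota_cluster(prof, params)
            counts = assignment.labels.value_counts()
            totals.append(sum(tree.resources[lid] * counts.get(lid, 0)
                              for lid in tree.leaf_ids))
        assert all(b <= a + 1e-9 for a, b in zip(totals, totals[1:]))


def test_rescue_pattern_recovery_on_planted_genes():
    """With effect = 4*sigma and 3 replicates, at least 90% of planted
    rescue genes land in clusters labeled with the matching pattern."""
    cfg = SimulationConfig(n_genes=300, effect=2.0, sigma=0.5,
                           frac_up_rescued=0.1, frac_down_rescued=0.1,
                           dropout_p=0.0, seed=17, n_true_pairs=0)
    matrix, truth = simulate_mrna(cfg)
    profiles = relative_profiles(matrix.values)
    params = SotaParams(max_cycles=8, epochs_per_cycle=100)
    _, assignment = sota_cluster(profiles, params)
    assignment = assign_patterns(assignment, matrix.groups,
                                 delta=cfg.effect / 2)
    hits = total = 0
    for pattern in ("up_rescued", "down_rescued"):
        for g in truth.genes_with(pattern):
            total += 1
            hits += assignment.pattern_of(g) == pattern
    assert hits / total >= 0.9


def _naive_complete_linkage_cophenet(D: np.ndarray) -> np.ndarray:
    """O(n^3) agglomeration oracle returning the condensed cophenetic
    distance matrix under complete linkage."""
    n = D.shape[0]
    clusters = {i: {i} for i in range(n)}
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        keys = sorted(clusters)
        best, pair = np.inf, None
        for a, b in itertools.combinations(keys, 2):
            d = max(D[i, j] for i in clusters[a] for j in clusters[b])
            if d < best:
                best, pair = d, (a, b)
        a, b = pair
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = best
        clusters[a] |= clusters.pop(b)
    return squareform(coph)


class TestHcluster:
    def test_duplicate_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(5)
        base = rng.normal(8, 1, 100)
        values = np.column_stack([base, base] + [
            base + rng.normal(0, 1, 100) for _ in range(10)])
        Z, labels = hcluster_samples(make_matrix(values))
        first = Z[0]
        assert {labels[int(first[0])], labels[int(first[1])]} == \
            {"C_1", "C_2"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_three_point_complete_linkage_by_hand(self):
        D = pd.DataFrame([[0.0, 0.1, 0.5],
                          [0.1, 0.0, 0.6],
                          [0.5, 0.6, 0.0]],
                         index=list("abc"), columns=list("abc"))
        Z = hierarchy.linkage(squareform(D.to_numpy()), method="complete")
        # the 0.1 pair merges first; c joins at max(0.5, 0.6) = 0.6
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.6)

    def test_eight_samples_match_naive_oracle(self):
        rng = np.random.default_rng(6)
        values = rng.normal(8, 2, (60, 8))
        samples = [f"s{i}" for i in range(8)]
        m = ExpressionMatrix(
            values=pd.DataFrame(values, columns=samples),
            groups=pd.Series("C", index=samples))
        for metric in ("pearson", "dot_product"):
            D = sample_distance_matrix(m, metric)
            Z, labels = hcluster_samples(m, distance=metric)
            got = hierarchy.cophenet(Z)
            want = _naive_complete_linkage_cophenet(D.to_numpy())
            assert np.allclose(got, want, atol=1e-12)

    def test_constant_sample_under_pearson_names_the_sample(self):
        values = np.random.default_rng(7).normal(size=(50, 12))
        values[:, 3] = 1.0
        m = make_matrix(values)
        with pytest.raises(ClusteringError, match="C\\+P_1"):
            hcluster_samples(m)

    def test_newick_export_contains_all_samples(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.normal(8, 1, (40, 12)))
        Z, labels = hcluster_samples(m)
        nwk = linkage_to_newick(Z, labels)
        assert nwk.endswith(";")
        for s in labels:
            assert s in nwk
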