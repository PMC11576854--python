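"""Trajectory classification, stage counts, co-occurrence, fuzzy clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans

from chromtraj.atlas import OpenThreshold, SignalMatrix
from chromtraj.trajectories import (
    binarize,
    categorize_clusters,
    classify,
    classify_matrix,
    cluster_transient,
    co_occurrence,
    fuzzy_cmeans,
    stage_counts,
    FuzzyClusters,
)
from oracles import classify_oracle

STAGES = ["hiF-T", "d6", "d8", "d14", "d20", "d24", "iPSC"]


class TestBinarize:
    def test_strictly_above_is_open(self):
        m = SignalMatrix(values=pd.DataFrame([[4.2, 4.2001, 4.1]],
                                             index=["r1"], columns=STAGES[:3]),
                         condition="naive")
        calls = binarize(m, OpenThreshold(value=4.2, source="fixed"))
        assert calls.loc["r1"].tolist() == [False, True, False]

    def test_base_mismatch_rejected(self):
        m = SignalMatrix(values=pd.DataFrame([[1.0] * 3], index=["r"],
                                             columns=STAGES[:3]),
                         condition="naive", log_base=2)
        with pytest.raises(ValueError, match="base"):
            binarize(m, OpenThreshold(value=1.0, source="fixed", log_base=10))


class TestClassify:
    @pytest.mark.parametrize("pattern,klass,switch", [
        ([1, 1, 1, 1, 1, 1, 1], "PO", None),
        ([0, 0, 0, 0, 0, 0, 0], "NEVER", None),
        ([0, 0, 1, 1, 1, 1, 1], "CO", "d8"),
        ([1, 1, 1, 0, 0, 0, 0], "OC", "d14"),
        ([1, 0, 1, 1, 1, 1, 1], "TRANSIENT", None),
        ([0, 1, 1, 0, 0, 0, 0], "TRANSIENT", None),
    ])
    def test_canonical_patterns(self, pattern, klass, switch):
        tc = classify(pattern, STAGES)
        assert (tc.klass, tc.switch_stage) == (klass, switch)

    def test_matches_truth_table_oracle_exhaustively(self):
        for n in (3, 5, 7, 8):
            for bits in itertools.product([False, True], repeat=n):
                got = classify(bits, [f"s{i}" for i in range(n)])
                assert got.klass == classify_oracle(bits), bits

    def test_fewer_than_three_stages_rejected(self):
        with pytest.raises(ValueError):
            classify([True, False], ["a", "b"])


class TestStageCounts:
    def test_single_co_switch_cumulative(self):
        calls = pd.DataFrame([[0, 0, 0, 1, 1, 1, 1]], index=["r1"],
                             columns=STAGES).astype(bool)
        traj = classify_matrix(calls, "naive")
        counts = stage_counts(traj, STAGES)
        assert counts["CO"].tolist() == [0, 0, 0, 1, 1, 1, 1]

    def test_all_po_flat(self):
        calls = pd.DataFrame(np.ones((5, 7), dtype=bool), columns=STAGES,
                             index=[f"r{i}" for i in range(5)])
        counts = stage_counts(classify_matrix(calls, "naive"), STAGES)
        assert (counts["PO"] == 5).all() and (counts[["CO", "OC"]] == 0).all().all()

    def test_matches_planted_cumulative_tallies(self, default_study):
        cond = "naive"
        gt = default_study.ground_truth
        states = default_study.true_states[cond].astype(bool)
        traj = classify_matrix(states, cond)  # noiseless: planted states
        counts = stage_counts(traj, STAGES)
        order = {s: i for i, s in enumerate(STAGES)}
        for si, stage in enumerate(STAGES):
            expected_co = sum(
                1 for rid, k in gt.region_class[cond].items()
                if k == "CO" and order[gt.switch_stage[cond][rid]] <= si)
            assert counts.loc[stage, "CO"] == expected_co


class TestCoOccurrence:
    def test_single_region_same_switch(self):
        calls = pd.DataFrame([[0, 0, 1, 1, 1, 1, 1]], index=["r"],
                             columns=STAGES).astype(bool)
        ta = classify_matrix(calls, "naive")
        tb = classify_matrix(calls, "primed")
        mat, excl = co_occurrence(ta, tb, "CO", STAGES)
        assert mat.loc["d8", "d8"] == 1 and mat.to_numpy().sum() == 1 and excl == 0

    def test_disjoint_classes_empty(self):
        a = classify_matrix(pd.DataFrame([[0, 0, 1, 1, 1, 1, 1]], index=["r"],
                                         columns=STAGES).astype(bool), "naive")
        b = classify_matrix(pd.DataFrame([[1, 1, 0, 0, 0, 0, 0]], index=["r"],
                                         columns=STAGES).astype(bool), "primed")
        mat, _ = co_occurrence(a, b, "CO", STAGES)
        assert mat.to_numpy().sum() == 0

    def test_matches_planted_joint_histogram(self, default_study):
        gt = default_study.ground_truth
        ta = classify_matrix(default_study.true_states["naive"].astype(bool), "naive")
        tb = classify_matrix(default_study.true_states["primed"].astype(bool), "primed")
        mat, excl = co_occurrence(ta, tb, "CO", STAGES)
        assert excl == 0
        joint = np.zeros((7, 7), dtype=int)
        order = {s: i for i, s in enumerate(STAGES)}
        for rid, k in gt.region_class["naive"].items():
            if k == "CO" and gt.region_class["primed"][rid] == "CO":
                joint[order[gt.switch_stage["naive"][rid]],
                      order[gt.switch_stage["primed"][rid]]] += 1
        np.testing.assert_array_equal(mat.to_numpy(), joint)
        assert mat.to_numpy().sum() == joint.sum()


def _planted_shapes(n_per: int, seed: int, noise: float = 0.2):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, 7)
    rising = 2 * t - 1
    peaked = 1 - 4 * np.abs(t - 0.5)
    rows, labels = [], []
    for shape, lab in ((rising, 0), (peaked, 1)):
        rows.append(shape + rng.normal(0, noise, (n_per, 7)))
        labels += [lab] * n_per
    data = np.vstack(rows)
    idx = [f"r{i}" for i in range(len(labels))]
    df = pd.DataFrame(data, index=idx, columns=STAGES)
    return df, np.array(labels)


class TestFuzzyCMeans:
    def test_memberships_row_sum_to_one(self):
        rng = np.random.default_rng(0)
        u, centers, _, _ = fuzzy_cmeans(rng.normal(size=(40, 5)), c=4, seed=1)
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-9)

    def test_single_cluster_full_membership(self):
        u, _, _, _ = fuzzy_cmeans(np.random.default_rng(0).normal(size=(10, 3)),
                                  c=1, seed=0)
        np.testing.assert_array_equal(u, np.ones((10, 1)))

    def test_fewer_regions_than_clusters_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            fuzzy_cmeans(np.zeros((3, 2)), c=5, seed=0)

    def test_recovers_planted_shapes_and_agrees_with_kmeans(self):
        df, labels = _planted_shapes(100, seed=3)
        clusters = cluster_transient({"naive": df}, c=2, seed=0)
        hard = clusters.hard_assignment().to_numpy()
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, hard) >= 0.95
        # independent cross-check: hard k-means on the same standardised data
        from chromtraj.trajectories import zscore_rows

        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(
            zscore_rows(df).to_numpy())
        assert adjusted_rand_score(km, hard) >= 0.95

    def test_deterministic_given_seed(self):
        df, _ = _planted_shapes(30, seed=5)
        a = cluster_transient({"naive": df}, c=3, seed=11)
        b = cluster_transient({"naive": df}, c=3, seed=11)
        pd.testing.assert_frame_equal(a.membership, b.membership)


class TestCategorize:
    def _clusters(self, center_naive, center_primed):
        n = len(STAGES)
        centers = np.array([np.concatenate([center_naive, center_primed])])
        membership = pd.DataFrame([[1.0]], index=["r0"], columns=["C1"])
        return FuzzyClusters(membership=membership, centers=centers,
                             conditions=["naive", "primed"], stages=STAGES,
                             m=2.0, n_iter=1, converged=True)

    def test_shared_up(self):
        rise = np.linspace(-1.0, 1.5, 7)
        cats = categorize_clusters(self._clusters(rise, rise))
        assert cats["C1"] == "shared up"

    def test_naive_transient_with_flat_primed(self):
        peak = np.array([-0.8, 0.2, 1.2, 0.3, -0.5, -0.7, -0.8])
        flat = np.full(7, 0.1)
        cats = categorize_clusters(self._clusters(peak, flat))
        assert cats["C1"] == "naive transient"

    def test_shared_loss(self):
        fall = np.linspace(1.2, -1.2, 7)
        cats = categorize_clusters(self._clusters(fall, fall))
        assert cats["C1"] == "shared loss"

    def test_planted_category_mix_mostly_correct(self):
        rng = np.random.default_rng(21)
        shapes = {
            "shared up": (np.linspace(-1.2, 1.2, 7), np.linspace(-1.2, 1.2, 7)),
            "shared loss": (np.linspace(1.2, -1.2, 7), np.linspace(1.2, -1.2, 7)),
            "shared transient": (np.array([-1, 0.5, 1.4, 0.5, -0.6, -1, -1.2]),) * 2,
            "naive up": (np.linspace(-1.2, 1.2, 7), np.full(7, 0.0)),
            "primed up": (np.full(7, 0.0), np.linspace(-1.2, 1.2, 7)),
        }
        correct = 0
        total = 0
        for expected, (cn, cp) in shapes.items():
            for rep in range(4):
                jn = cn + rng.normal(0, 0.05, 7)
                jp = cp + rng.normal(0, 0.05, 7)
                cats = categorize_clusters(self._clusters(jn, jp))
                total += 1
                correct += cats["C1"] == expected
        assert correct / total >= 0.9
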