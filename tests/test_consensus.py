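"""PAM, consensus indices, PAC/CHI selection, membership and boundary rules."""

import itertools

import numpy as np
import pandas as pd
import pytest

import mechanotypes.consensus as cons
from mechanotypes.consensus import (
    ClusteringConfig,
    ConsensusMatrix,
    chi,
    consensus_run,
    discover_mechanotypes,
    final_membership,
    hierarchical_labels,
    pac,
    pam_cluster,
    select_k,
)
from mechanotypes.data_model import extract_pair_samples
from mechanotypes.distances import pairwise_distances
from mechanotypes.errors import InputError
from mechanotypes.synthetic import default_area_design, simulate_measurements


def abs_diff_matrix(points):
    p = np.asarray(points, dtype=float)
    return np.abs(p[:, None] - p[None, :])


def exhaustive_pam_cost(D, k):
    """Brute-force optimum over all medoid subsets."""
    n = D.shape[0]
    return min(
        D[list(m)].min(axis=0).sum() for m in itertools.combinations(range(n), k)
    )


class TestPAM:
    def test_two_cluster_partition_matches_exhaustive_optimum(self):
        D = abs_diff_matrix([0.0, 1.0, 10.0, 11.0])
        labels, medoids = pam_cluster(D, 2)
        assert labels[0] == labels[1] != labels[2] == labels[3]
        cost = D[medoids].min(axis=0).sum()
        assert cost == pytest.approx(exhaustive_pam_cost(D, 2))

    def test_swap_local_optimality_on_random_instances(self, rng):
        # no single (medoid, non-medoid) exchange can lower the cost
        for _ in range(20):
            pts = rng.normal(size=8)
            D = abs_diff_matrix(pts)
            k = int(rng.integers(2, 5))
            labels, medoids = pam_cluster(D, k)
            cost = D[medoids].min(axis=0).sum()
            assert cost >= 0
            others = [i for i in range(8) if i not in set(medoids)]
            for mi in range(k):
                for h in others:
                    trial = np.array([h if i == mi else m for i, m in enumerate(medoids)])
                    assert cost <= D[trial].min(axis=0).sum() + 1e-9

    def test_k_equals_n_gives_singletons(self):
        D = abs_diff_matrix([0.0, 3.0, 9.0])
        labels, medoids = pam_cluster(D, 3)
        assert len(set(labels)) == 3
        assert D[medoids].min(axis=0).sum() == 0.0

    def test_duplicate_rows_cluster_together(self):
        D = abs_diff_matrix([0.0, 0.0, 0.0, 7.0, 7.0])
        labels, _ = pam_cluster(D, 2)
        assert len({labels[0], labels[1], labels[2]}) == 1
        assert labels[3] == labels[4] != labels[0]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(InputError):
            pam_cluster(abs_diff_matrix([0.0, 1.0]), 3)


class TestConsensusRun:
    LABELS4 = tuple((f"L{i}", "Glass") for i in range(4))

    def test_always_coclustered_gives_one(self):
        D = abs_diff_matrix([0.0, 0.1, 10.0, 10.1])
        cfg = ClusteringConfig(k_range=(2,), n_reps=20, subsample_rate=1.0, seed=0)
        cm = consensus_run(self.LABELS4, D, cfg)[2]
        assert cm.M[0, 1] == 1.0
        assert cm.M[2, 3] == 1.0
        assert cm.M[0, 2] == 0.0

    def test_consensus_index_is_cocluster_over_cosample(self, monkeypatch):
        # items 0 and 1 co-cluster in 3 of 4 repetitions -> M_01 = 0.75
        patterns = iter(
            [np.array([0, 0, 1, 1]), np.array([0, 0, 1, 1]),
             np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1])]
        )
        monkeypatch.setattr(cons, "pam_cluster", lambda D, k, seed=None: (next(patterns), None))
        cfg = ClusteringConfig(k_range=(2,), n_reps=4, subsample_rate=1.0, seed=0)
        cm = consensus_run(self.LABELS4, abs_diff_matrix([0, 1, 2, 3.0]), cfg)[2]
        assert cm.M[0, 1] == pytest.approx(0.75)
        assert cm.cosample_counts[0, 1] == 4

    def test_never_cosampled_warns_and_zeroes(self):
        D = abs_diff_matrix([0.0, 1.0, 10.0, 11.0])
        cfg = ClusteringConfig(k_range=(2,), n_reps=1, subsample_rate=0.5, seed=1)
        with pytest.warns(UserWarning, match="never co-sampled"):
            cm = consensus_run(self.LABELS4, D, cfg)[2]
        never = cm.cosample_counts == 0
        np.fill_diagonal(never, False)
        assert cm.M[never].max() == 0.0

    def test_seed_determinism(self):
        D = abs_diff_matrix(np.arange(10.0))
        cfg = ClusteringConfig(k_range=(2, 3), n_reps=30, seed=42)
        labels = tuple((f"L{i}", "Glass") for i in range(10))
        m1 = consensus_run(labels, D, cfg)
        m2 = consensus_run(labels, D, cfg)
        for k in (2, 3):
            np.testing.assert_array_equal(m1[k].M, m2[k].M)


def cm_from_upper(entries, n=3):
    M = np.eye(n)
    iu = np.triu_indices(n, 1)
    M[iu] = entries
    M = M + np.triu(M, 1).T
    return ConsensusMatrix(
        labels=tuple((f"L{i}", "Glass") for i in range(n)),
        M=M,
        cosample_counts=np.full((n, n), 10.0),
        k=2,
    )


class TestPAC:
    def test_crisp_matrix_zero(self):
        assert pac(cm_from_upper([1.0, 0.0, 0.0])) == 0.0

    def test_fully_ambiguous_one(self):
        assert pac(cm_from_upper([0.5, 0.5, 0.5])) == 1.0

    def test_counting_by_hand(self):
        assert pac(cm_from_upper([0.05, 0.5, 0.95])) == pytest.approx(1 / 3)

    def test_strict_bounds(self):
        assert pac(cm_from_upper([0.1, 0.9, 0.5])) == pytest.approx(1 / 3)


class TestCHI:
    def test_hand_pseudo_f(self):
        # two 2-item clusters, within 1, across 10: W=1, T=100.5 -> 199
        D = np.array(
            [
                [0.0, 1.0, 10.0, 10.0],
                [1.0, 0.0, 10.0, 10.0],
                [10.0, 10.0, 0.0, 1.0],
                [10.0, 10.0, 1.0, 0.0],
            ]
        )
        assert chi(D, np.array([0, 0, 1, 1])) == pytest.approx(199.0)

    def test_identical_points_infinite_separation(self):
        D = np.zeros((4, 4))
        assert chi(D, np.array([0, 0, 1, 1])) == np.inf

    def test_non_negative_on_random_labels(self, rng):
        pts = rng.normal(size=12)
        D = abs_diff_matrix(pts)
        for _ in range(10):
            labels = rng.integers(0, 3, 12)
            if len(np.unique(labels)) < 2:
                continue
            assert chi(D, labels) >= 0.0

    def test_empty_cluster_rejected(self):
        with pytest.raises(InputError):
            chi(np.zeros((3, 3)), np.array([0, 0, 0]))


class TestSelectK:
    def _frame(self, ks, pacs, chis):
        return pd.DataFrame({"k": ks, "pac": pacs, "chi": chis})

    def test_worked_example(self):
        sel = select_k(self._frame((2, 3, 4), (0.40, 0.05, 0.30), (5, 50, 9)))
        assert sel.k_optimal == 3

    def test_unique_minimum_wins_regardless_of_chi(self):
        sel = select_k(self._frame((2, 3, 4), (0.40, 0.02, 0.30), (500, 1, 400)))
        assert sel.k_optimal == 3

    def test_chi_breaks_near_ties(self):
        sel = select_k(self._frame((2, 3, 4), (0.050, 0.055, 0.30), (5, 50, 9)), eps=0.02)
        assert sel.k_optimal == 3


class TestFinalMembership:
    def test_item_consensus_is_mean_over_other_members(self):
        M = np.array(
            [
                [1.0, 1.0, 0.9, 0.0],
                [1.0, 1.0, 0.95, 0.0],
                [0.9, 0.95, 1.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        cm = ConsensusMatrix(
            labels=tuple((c, "Glass") for c in "abcd"),
            M=M, cosample_counts=np.full((4, 4), 5.0), k=2,
        )
        res = final_membership(cm, 2, ClusteringConfig())
        i_a = 0
        cls_a = res.assigned[i_a]
        col = list(np.unique(res.assigned)).index(cls_a)
        assert res.item_consensus[i_a].max() == pytest.approx(0.95)
        assert not res.is_boundary.any()

    def test_boundary_case_flagged_with_top_two_classes(self):
        n = 5
        M = np.eye(n)
        strong = [(0, 1), (3, 4)]
        for i, j in strong:
            M[i, j] = M[j, i] = 1.0
        for j in (0, 1):
            M[2, j] = M[j, 2] = 0.75
        for j in (3, 4):
            M[2, j] = M[j, 2] = 0.30
        cm = ConsensusMatrix(
            labels=tuple((f"L{i}", "Glass") for i in range(n)),
            M=M, cosample_counts=np.full((n, n), 5.0), k=2,
        )
        res = final_membership(cm, 2, ClusteringConfig())
        assert bool(res.is_boundary[2])
        top, second = res.boundary_classes[2]
        assert top == res.assigned[2]
        assert res.item_consensus[2].max() == pytest.approx(0.75)

    def test_perfect_blocks_no_boundary(self):
        M = np.zeros((6, 6))
        M[:3, :3] = 1.0
        M[3:, 3:] = 1.0
        cm = ConsensusMatrix(
            labels=tuple((f"L{i}", "Glass") for i in range(6)),
            M=M, cosample_counts=np.full((6, 6), 5.0), k=2,
        )
        res = final_membership(cm, 2, ClusteringConfig())
        assert not res.is_boundary.any()
        assert np.all(res.item_consensus.max(axis=1) == 1.0)


@pytest.fixture(scope="module")
def planted():
    table, labels = simulate_measurements(default_area_design(seed=11))
    samples = extract_pair_samples(table, "area")
    dm = pairwise_distances(samples)
    return dm, labels


class TestEndToEnd:

    def test_planted_recovery_and_determinism(self, planted):
        dm, labels = planted
        cfg = ClusteringConfig(n_reps=60, seed=5)
        res1 = discover_mechanotypes(dm, cfg)
        res2 = discover_mechanotypes(dm, cfg)
        np.testing.assert_array_equal(res1.membership.assigned, res2.membership.assigned)
        assert res1.selection.k_optimal == 4
        planted_ids = [labels[p] for p in res1.membership.labels]
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(planted_ids, res1.membership.assigned) == 1.0

    def test_label_permutation_invariance(self, planted):
        dm, _ = planted
        perm = np.random.default_rng(3).permutation(dm.n)
        from mechanotypes.distances import DistanceMatrix

        dm_perm = DistanceMatrix(
            labels=tuple(dm.labels[i] for i in perm),
            D=dm.D[np.ix_(perm, perm)],
            metric=dm.metric,
        )
        cfg = ClusteringConfig(n_reps=60, seed=5)
        res = discover_mechanotypes(dm, cfg)
        res_p = discover_mechanotypes(dm_perm, cfg)
        # pairwise_distances sorts labels, but here we feed the permuted
        # matrix directly: co-membership of every item pair must agree
        pos = {lab: i for i, lab in enumerate(res_p.membership.labels)}
        a, b = res.membership.assigned, res_p.membership.assigned
        for i in range(dm.n):
            for j in range(i + 1, dm.n):
                same1 = a[i] == a[j]
                same2 = b[pos[res.membership.labels[i]]] == b[pos[res.membership.labels[j]]]
                assert same1 == same2

    def test_consensus_entries_within_unit_interval(self, planted):
        dm, _ = planted
        cfg = ClusteringConfig(k_range=(2, 4), n_reps=40, seed=8)
        for cm in consensus_run(dm.labels, dm.D, cfg).values():
            assert cm.M.min() >= 0.0 and cm.M.max() <= 1.0
            assert 0.0 <= pac(cm) <= 1.0
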