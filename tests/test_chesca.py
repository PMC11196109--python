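"""Covariance networks: response matrix, correlations, clusters, scores."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from allokin.chesca import (
    CorrelationNetwork,
    ResponseMatrix,
    cluster_residues,
    community_scores,
    correlation_matrix,
    correlation_score,
    read_community_map,
    response_matrix,
)
from allokin.synthetic_data import NetworkSpec, gen_shift_tables

from conftest import make_states


def net_from_matrix(r, residues=None, rcutoff=0.98):
    res = residues or list(range(1, len(r) + 1))
    return CorrelationNetwork(
        matrix=pd.DataFrame(np.asarray(r, dtype=float), index=res, columns=res),
        rcutoff=rcutoff)


class TestResponseMatrix:
    def test_deviations_center_to_zero_per_nucleus(self):
        s = make_states({
            "a": {1: (8.0, 119.0)}, "b": {1: (8.1, 119.2)},
            "c": {1: (8.3, 119.1)}, "d": {1: (8.2, 119.4)}})
        m = response_matrix(s, {1})
        assert m.values.shape == (1, 8)
        assert m.values[0, :4].sum() == pytest.approx(0.0, abs=1e-12)
        assert m.values[0, 4:].sum() == pytest.approx(0.0, abs=1e-12)

    def test_planted_cluster_rows_proportional(self, default_network):
        states, truth = default_network
        c1 = [r for r in truth.network_residues if truth.cluster_of[r] == 1]
        m = response_matrix(states, set(c1))
        v = m.values
        # rows of a shared-coordinate cluster are proportional up to noise
        for i in range(1, len(c1)):
            cos = abs(v[0] @ v[i]) / (np.linalg.norm(v[0]) * np.linalg.norm(v[i]))
            assert cos > 0.99

    def test_all_zero_shifts_flagged_downstream(self):
        s = make_states({f"s{i}": {1: (8.0, 119.0), 2: (8.0, 119.0)}
                         for i in range(4)})
        m = response_matrix(s, {1, 2})
        with pytest.raises(ValueError, match="zero response variance"):
            correlation_matrix(m)

    def test_needs_three_states(self):
        s = make_states({"a": {1: (8.0, 119.0)}, "b": {1: (8.1, 119.1)}})
        with pytest.raises(ValueError, match=">= 3 states"):
            response_matrix(s, {1})


class TestCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self, default_network):
        states, truth = default_network
        net = correlation_matrix(response_matrix(states, set(states.retained)))
        m = net.matrix.to_numpy()
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)
        assert np.all(np.abs(m) <= 1.0)

    def test_proportional_responses_correlate_perfectly(self):
        m = ResponseMatrix(residues=[1, 2], states=list("abcd"),
                           values=np.array([[0., 1, 2, 3, 0, .5, 1, 1.5],
                                            [0., 2, 4, 6, 0, 1, 2, 3]]))
        # center rows per nucleus first, as response_matrix would
        v = m.values
        v[:, :4] -= v[:, :4].mean(axis=1, keepdims=True)
        v[:, 4:] -= v[:, 4:].mean(axis=1, keepdims=True)
        net = correlation_matrix(m)
        assert net.matrix.loc[1, 2] == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 2.0, 2.5])
        m = ResponseMatrix(residues=[1, 2], states=list("abcd"),
                           values=np.vstack([x - x.mean(), y - y.mean()]))
        net = correlation_matrix(m)
        expected = np.corrcoef(x, y)[0, 1]  # brute-force Pearson
        assert net.matrix.loc[1, 2] == pytest.approx(expected, abs=1e-12)
        assert net.matrix.loc[1, 2] == pytest.approx(0.9898, abs=5e-4)

    def test_affine_rescaling_invariance(self, default_network):
        states, _ = default_network
        m = response_matrix(states, set(list(states.retained)[:10]))
        net1 = correlation_matrix(m)
        m2 = ResponseMatrix(residues=m.residues, states=m.states,
                            values=m.values * 3.7)
        net2 = correlation_matrix(m2)
        assert np.allclose(net1.matrix, net2.matrix)

    def test_short_vectors_rejected(self):
        m = ResponseMatrix(residues=[1, 2], states=["a", "b"],
                           values=np.array([[0.1, -0.1], [0.2, -0.2]]))
        with pytest.raises(ValueError, match="length >= 3"):
            correlation_matrix(m, mode="H-only")


class TestClustering:
    def test_planted_partition_recovered(self, default_network):
        states, truth = default_network
        m = response_matrix(states, set(states.retained))
        net = cluster_residues(correlation_matrix(m), response=m)
        nr = truth.network_residues
        recovered = {}
        for lab, grp in net.clusters.items():
            for r in grp:
                recovered[r] = lab
        for r in net.singletons:
            recovered[r] = -r
        ari = adjusted_rand_score(truth.labels(nr),
                                  [recovered[r] for r in nr])
        assert ari == pytest.approx(1.0)

    def test_uncorrelated_residues_are_singletons(self):
        r = np.eye(4)
        net = cluster_residues(net_from_matrix(r))
        assert net.clusters == {}
        assert net.singletons == [1, 2, 3, 4]

    def test_single_cluster_svd_dominated_by_first_component(self):
        # noiseless rank-1 construction
        base = np.array([-1.5, -0.5, 0.5, 1.5])
        rows = np.vstack([a * np.concatenate([base, 0.5 * base])
                          for a in (0.5, 1.0, 1.5, 2.0)])
        m = ResponseMatrix(residues=[1, 2, 3, 4], states=list("abcd"),
                           values=rows)
        net = cluster_residues(correlation_matrix(m), response=m)
        assert net.svd_variance_fractions[0] > 0.9
        assert list(net.clusters.values()) == [[1, 2, 3, 4]]

    def test_anticorrelated_residues_cluster_together(self):
        base = np.array([-1.5, -0.5, 0.5, 1.5])
        rows = np.vstack([np.concatenate([base, base]),
                          -np.concatenate([base, base])])
        m = ResponseMatrix(residues=[1, 2], states=list("abcd"), values=rows)
        net = cluster_residues(correlation_matrix(m))
        assert list(net.clusters.values()) == [[1, 2]]


class TestCorrelationScore:
    def test_all_pairs_above_cutoff(self):
        net = net_from_matrix(np.full((3, 3), 0.99) + 0.01 * np.eye(3))
        assert correlation_score(net, [1], [2, 3]) == 1.0

    def test_no_pairs_above_cutoff(self):
        net = net_from_matrix(np.eye(3))
        assert correlation_score(net, [1], [2, 3]) == 0.0

    def test_half_the_pairs_qualify(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.99
        r[0, 2] = r[2, 0] = 0.97
        net = net_from_matrix(r, rcutoff=0.98)
        assert correlation_score(net, [1], [2, 3]) == 0.5

    def test_whole_protein_score_consistent_with_per_residue(self,
                                                             default_network):
        states, _ = default_network
        residues = sorted(states.retained)[:30]
        m = response_matrix(states, set(residues))
        net = correlation_matrix(m)
        whole = correlation_score(net, residues, residues)
        # pair-count-weighted mean of single-residue-vs-rest scores
        num = den = 0.0
        for r in residues:
            rest = [q for q in residues if q != r]
            num += correlation_score(net, [r], rest) * len(rest)
            den += len(rest)
        assert whole == pytest.approx(num / den)

    def test_empty_subset_rejected(self):
        net = net_from_matrix(np.eye(2))
        with pytest.raises(ValueError, match="empty"):
            correlation_score(net, [], [1])


class TestCommunityScores:
    def test_hand_counted_example(self):
        # A = {1, 2}, B = {3}: one of the two cross pairs qualifies
        r = np.eye(3)
        r[0, 2] = r[2, 0] = 0.99
        r[1, 2] = r[2, 1] = 0.5
        net = net_from_matrix(r)
        scores = community_scores(net, {"A": {1, 2}, "B": {3}}, rcutoff=0.98)
        assert scores.loc["A", "B"] == pytest.approx(0.5)
        assert scores.loc["A", "B"] == scores.loc["B", "A"]

    def test_disjoint_communities_score_zero(self):
        net = net_from_matrix(np.eye(4))
        scores = community_scores(net, {"A": {1, 2}, "B": {3, 4}})
        assert scores.loc["A", "B"] == 0.0

    def test_fully_correlated_network_scores_one(self):
        n = 4
        r = np.full((n, n), 0.99)
        np.fill_diagonal(r, 1.0)
        net = net_from_matrix(r)
        scores = community_scores(net, {"A": {1, 2}, "B": {3, 4}},
                                  rcutoff=0.8)
        assert (scores.to_numpy() == 1.0).all()

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 12
            a = rng.uniform(-1, 1, (n, n))
            r = np.clip((a + a.T) / 2, -1, 1)
            np.fill_diagonal(r, 1.0)
            residues = list(range(1, n + 1))
            net = net_from_matrix(r, residues)
            labels = rng.integers(0, 3, n)
            comm = {f"C{k}": {residues[i] for i in np.flatnonzero(labels == k)}
                    for k in range(3)}
            comm = {k: v for k, v in comm.items() if v}
            cutoff = rng.uniform(0.2, 0.9)
            scores = community_scores(net, comm, rcutoff=cutoff)
            for na_, a_name in enumerate(scores.index):
                for b_name in scores.columns:
                    ra = sorted(comm[a_name])
                    rb = sorted(comm[b_name])
                    # brute-force pair counting
                    count = total = 0
                    for i in ra:
                        for j in rb:
                            if i == j:
                                continue
                            total += 1
                            if abs(r[i - 1, j - 1]) > cutoff:
                                count += 1
                    expected = count / total if total else 0.0
                    assert scores.loc[a_name, b_name] == pytest.approx(
                        expected), (seed, a_name, b_name)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        n = 8
        a = rng.uniform(-1, 1, (n, n))
        r = (a + a.T) / 2
        np.fill_diagonal(r, 1.0)
        residues = list(range(1, n + 1))
        net = net_from_matrix(r, residues)
        comm = {"A": {1, 2, 3}, "B": {4, 5, 6, 7, 8}}
        s1 = community_scores(net, comm, rcutoff=0.5)
        perm = rng.permutation(n)
        r2 = r[np.ix_(perm, perm)]
        relabel = {residues[i]: residues[j] for j, i in enumerate(perm)}
        net2 = net_from_matrix(r2, residues)
        comm2 = {k: {relabel[x] for x in v} for k, v in comm.items()}
        s2 = community_scores(net2, comm2, rcutoff=0.5)
        assert np.allclose(s1, s2)

    def test_community_missing_from_network_is_an_error(self):
        net = net_from_matrix(np.eye(2))
        with pytest.raises(ValueError, match="C2"):
            community_scores(net, {"C1": {1}, "C2": {99}})


class TestCommunityMapIO:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "communities.csv"
        p.write_text("# label,start,end\nComA,45,60\nComA,70,75\nComB,100,110\n")
        comm = read_community_map(p)
        assert comm["ComA"] == set(range(45, 61)) | set(range(70, 76))
        assert comm["ComB"] == set(range(100, 111))

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "communities.csv"
        p.write_text("ComA,45,60\nComB,60,70\n")
        with pytest.raises(ValueError, match="60"):
            read_community_map(p)
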