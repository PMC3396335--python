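"""Weighted similarity and agglomerative clustering of call profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

from acghcall.calling import CallMatrix
from acghcall.clustering import call_similarity, cluster_samples, to_newick
from acghcall.regions import reduce_regions, region_weights
from acghcall.simulate import SimConfig, simulate_cohort, truth_call_matrix


def _region_calls_from_probs(probs, weights_probes=None):
    """RegionCallMatrix with one probe per region and given merged probs."""
    probs = np.asarray(probs, dtype=float)  # (R, S, 3)
    n, s = probs.shape[:2]
    calls = np.where(probs.max(axis=2) > 0.5,
                     np.array([-1, 0, 1])[probs.argmax(axis=2)], 0).astype(np.int8)
    raw = np.zeros((n, s, 4))
    raw[..., :3] = probs
    probes = pd.DataFrame(
        {"chromosome": np.arange(n) + 1, "position": [1] * n},
        index=[f"p{i}" for i in range(n)])
    cm = CallMatrix(probes=probes, samples=[f"s{j}" for j in range(s)],
                    calls=calls, probs=raw)
    return reduce_regions(cm, threshold=0.0)


class TestSimilarity:
    def test_identical_hard_profiles_score_one(self):
        p = np.zeros((4, 2, 3))
        p[:, :, 2] = 1.0  # both samples all-gain
        rc = _region_calls_from_probs(p)
        sim = call_similarity(rc, region_weights(rc))
        assert sim == pytest.approx(np.ones((2, 2)))

    def test_opposite_profiles_score_zero(self):
        p = np.zeros((3, 2, 3))
        p[:, 0, 0] = 1.0  # all loss
        p[:, 1, 2] = 1.0  # all gain
        rc = _region_calls_from_probs(p)
        sim = call_similarity(rc, region_weights(rc))
        assert sim[0, 1] == pytest.approx(0.0)
        assert sim[0, 0] == pytest.approx(1.0)

    def test_hand_computed_overlap(self):
        p = np.zeros((3, 2, 3))
        p[0, 0] = [1, 0, 0]; p[1, 0] = [0, 1, 0]; p[2, 0] = [0, 0, 1]
        p[0, 1] = [1, 0, 0]; p[1, 1] = [0, 1, 0]; p[2, 1] = [0, 1, 0]
        rc = _region_calls_from_probs(p)
        sim = call_similarity(rc, np.full(3, 1 / 3))
        assert sim[0, 1] == pytest.approx(2 / 3)

    def test_dissimilarity_axioms(self, small_cohort):
        rc = reduce_regions(truth_call_matrix(small_cohort))
        sim = call_similarity(rc, region_weights(rc))
        d = 1 - sim
        assert np.allclose(d, d.T)
        assert np.all(d >= -1e-12)
        assert np.allclose(np.diag(d), 0.0)

    def test_weight_length_mismatch(self, small_cohort):
        rc = reduce_regions(truth_call_matrix(small_cohort))
        with pytest.raises(ValueError, match="weights"):
            call_similarity(rc, np.ones(3))


class TestClusterSamples:
    def test_two_blocks_recovered(self):
        sim = np.array([
            [1.0, 0.9, 0.1, 0.1],
            [0.9, 1.0, 0.1, 0.1],
            [0.1, 0.1, 1.0, 0.8],
            [0.1, 0.1, 0.8, 1.0],
        ])
        res = cluster_samples(sim, ["a", "b", "c", "d"])
        assert res.labels_k2["a"] == res.labels_k2["b"]
        assert res.labels_k2["c"] == res.labels_k2["d"]
        assert res.labels_k2["a"] != res.labels_k2["c"]

    def test_label_a_is_larger_cluster(self):
        sim = np.eye(5)
        sim[:3, :3] = 0.9
        sim[3:, 3:] = 0.9
        np.fill_diagonal(sim, 1.0)
        res = cluster_samples(sim, [f"x{i}" for i in range(5)])
        members_a = res.cluster_members("A")
        assert len(members_a) == 3

    def test_equal_similarities_degenerate(self):
        sim = np.full((4, 4), 0.5)
        np.fill_diagonal(sim, 1.0)
        res = cluster_samples(sim, list("abcd"))
        heights = res.merges[:, 2]
        assert np.allclose(heights, 0.5)
        # deterministic tie-break: first merge joins the first two samples
        assert set(res.merges[0, :2]) == {0, 1}

    def test_permutation_invariance(self, small_cohort):
        rc = reduce_regions(truth_call_matrix(small_cohort))
        sim = call_similarity(rc, region_weights(rc))
        res = cluster_samples(sim, rc.samples)
        perm = np.random.default_rng(0).permutation(len(rc.samples))
        sim2 = sim[np.ix_(perm, perm)]
        names2 = [rc.samples[i] for i in perm]
        res2 = cluster_samples(sim2, names2)
        part1 = {s: res.labels_k2[s] for s in rc.samples}
        part2 = {s: res2.labels_k2[s] for s in rc.samples}
        same = all(
            (part1[a] == part1[b]) == (part2[a] == part2[b])
            for a in rc.samples for b in rc.samples
        )
        assert same

    def test_average_linkage_heights_monotone(self, small_cohort):
        rc = reduce_regions(truth_call_matrix(small_cohort))
        sim = call_similarity(rc, region_weights(rc))
        res = cluster_samples(sim, rc.samples)
        heights = res.merges[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)
        # cophenetic distances are consistent with a valid linkage matrix
        coph = cophenet(res.merges)
        assert np.all(squareform(coph) >= -1e-12)

    def test_asymmetric_similarity_rejected(self):
        sim = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            cluster_samples(sim, ["a", "b"])

    def test_disjoint_groups_perfect_recovery_noise_free(self):
        co = simulate_cohort(SimConfig(seed=21, disjoint_aberrations=True,
                                       noise_sd=0.0, wave_amplitude=0.0))
        rc = reduce_regions(truth_call_matrix(co))
        res = cluster_samples(call_similarity(rc, region_weights(rc)), rc.samples)
        groups = {s: co.true_group[s] for s in rc.samples}
        label_of = {}
        for s in rc.samples:
            label_of.setdefault(groups[s], set()).add(res.labels_k2[s])
        assert label_of["early"].isdisjoint(label_of["advanced"])

    def test_ari_with_group_specific_aberrations(self):
        """Two-cluster cut recovers the groups (ARI >= 0.8 across seeds)."""
        from sklearn.metrics import adjusted_rand_score
        aris = []
        for s in range(20):
            co = simulate_cohort(SimConfig(seed=600 + s,
                                           disjoint_aberrations=True))
            rc = reduce_regions(truth_call_matrix(co))
            res = cluster_samples(call_similarity(rc, region_weights(rc)), rc.samples)
            aris.append(adjusted_rand_score(
                [co.true_group[x] for x in rc.samples],
                [res.labels_k2[x] for x in rc.samples]))
        assert np.mean(aris) >= 0.8


def test_newick_export_roundtrip_structure():
    sim = np.array([
        [1.0, 0.9, 0.1],
        [0.9, 1.0, 0.1],
        [0.1, 0.1, 1.0],
    ])
    res = cluster_samples(sim, ["a", "b", "c"])
    nwk = to_newick(res)
    assert nwk.endswith(";")
    assert sorted(t for t in ("a", "b", "c") if t in nwk) == ["a", "b", "c"]
    # parses as a tree with the right leaf set
    from io import StringIO
    from Bio import Phylo
    tree = Phylo.read(StringIO(nwk), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == ["a", "b", "c"]
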