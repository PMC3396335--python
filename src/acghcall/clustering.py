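"""Weighted hierarchical clustering of called copy-number profiles.

Samples are compared through their per-region call probabilities: the
similarity of two samples is the region-size-weighted probability that
they are in the same state, rescaled so that two identical hard-called
profiles score exactly 1.  Agglomerative clustering (average linkage by
default) on 1 - similarity yields a dendrogram; the two-cluster cut
labels the larger cluster "A", as in the study's 19/13 convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regions import RegionCallMatrix


@dataclass
class ClusterResult:
    samples: list[str]
    merges: np.ndarray          # scipy-style linkage matrix (n-1, 4)
    labels_k2: dict[str, str]   # sample -> 'A' | 'B'
    linkage: str

    def cluster_members(self, label: str) -> list[str]:
        return [s for s in self.samples if self.labels_k2[s] == label]


def call_similarity(
    regioncalls: RegionCallMatrix, weights: np.ndarray | None = None
) -> np.ndarray:
    """Probability-overlap similarity matrix in [0, 1].

    sim(i, j) = sum_r w_r sum_s P_ir(s) P_jr(s), rescaled by
    1/sqrt(sim(i,i) sim(j,j)).  Uncalled regions contribute their
    averaged posteriors, so no sample has a zero row.
    """
    probs = regioncalls.probs  # (R, S, 3)
    if weights is None:
        from .regions import region_weights
        weights = region_weights(regioncalls)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != probs.shape[0]:
        raise ValueError(
            f"{len(weights)} weights for {probs.shape[0]} regions"
        )
    raw = np.einsum("rik,rjk,r->ij", probs, probs, weights)
    diag = np.sqrt(np.diag(raw))
    sim = raw / np.outer(diag, diag)
    return np.clip(sim, 0.0, 1.0)


def cluster_samples(
    similarity: np.ndarray,
    samples: list[str],
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering on 1 - similarity with a k=2 cut.

    Deterministic: among merge candidates tied on dissimilarity the
    lexicographically smallest cluster pair (by smallest original member
    index) is merged.  'A' is the larger of the two final clusters; on a
    size tie, the cluster containing the first sample.
    """
    sim = np.asarray(similarity, dtype=float)
    n = sim.shape[0]
    if sim.shape != (n, n) or not np.allclose(sim, sim.T, atol=1e-9):
        raise ValueError("similarity matrix must be square and symmetric")
    if len(samples) != n:
        raise ValueError("sample list does not match similarity matrix")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)

    # active clusters: id -> (member original indices, row in current matrix)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist = d.copy()
    active = list(range(n))
    next_id = n
    Z = np.zeros((n - 1, 4))
    cluster_id = {i: i for i in range(n)}  # position -> linkage id

    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                dd = dist[a, b]
                key = (dd, min(members[a][0], members[b][0]),
                       max(members[a][0], members[b][0]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (dd, _, _), a, b = best
        Z[step] = [cluster_id[a], cluster_id[b], dd, len(members[a]) + len(members[b])]
        # update distances to the merged cluster (stored in slot a)
        na, nb = len(members[a]), len(members[b])
        for c in active:
            if c in (a, b):
                continue
            if linkage == "average":
                dist[a, c] = dist[c, a] = (na * dist[a, c] + nb * dist[b, c]) / (na + nb)
            else:
                dist[a, c] = dist[c, a] = max(dist[a, c], dist[b, c])
        members[a] = sorted(members[a] + members[b])
        cluster_id[a] = next_id
        next_id += 1
        active.remove(b)
        del members[b]

    # k=2 cut: children of the final merge
    left, right = _leaves(Z, n, int(Z[-1, 0])), _leaves(Z, n, int(Z[-1, 1]))
    if len(left) > len(right):
        big, small = left, right
    elif len(right) > len(left):
        big, small = right, left
    else:
        big, small = (left, right) if 0 in left else (right, left)
    labels = {}
    for i in big:
        labels[samples[i]] = "A"
    for i in small:
        labels[samples[i]] = "B"
    return ClusterResult(samples=list(samples), merges=Z, labels_k2=labels,
                         linkage=linkage)


def _leaves(Z: np.ndarray, n: int, node: int) -> set[int]:
    if node < n:
        return {node}
    row = Z[node - n]
    return _leaves(Z, n, int(row[0])) | _leaves(Z, n, int(row[1]))


def to_newick(result: ClusterResult) -> str:
    """Dendrogram as a Newick string, branch lengths = height differences."""
    n = len(result.samples)
    Z = result.merges
    heights = {i: 0.0 for i in range(n)}
    for k, row in enumerate(Z):
        heights[n + k] = float(row[2])

    def build(node: int) -> str:
        if node < n:
            return result.samples[node]
        row = Z[node - n]
        parts = []
        for child in (int(row[0]), int(row[1])):
            length = max(heights[node] - heights[child], 0.0)
            parts.append(f"{build(child)}:{length:.6g}")
        return "(" + ",".join(parts) + ")"

    return build(2 * n - 2) + ";"
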