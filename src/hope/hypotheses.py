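"""Verification experiments: does network topology predict function?

Two group-comparison experiments test the working hypothesis that
co-occurring OTUs share functions:

1. **adjacency test** — Jaccard distances between the KO label rows of
   randomly drawn *adjacent* node pairs versus pairs that cannot reach
   each other within three steps; repeated many times, each repeat
   contributing one mean per group.
2. **neighborhood test** — pairs ranked by the Hamming distance between
   their adjacency rows; the most similar neighborhoods versus the most
   different ones, compared on the same label Jaccard distance.

If topology carries functional signal, the adjacent/similar groups show
smaller label distances.  Label-shuffled inputs are the negative control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import LabelMatrix
from .network import CooccurrenceNetwork, reachability_within

logger = logging.getLogger(__name__)


@dataclass
class GroupTestResult:
    """Per-repeat group means plus the raw distances of the last repeat."""

    group_a_name: str
    group_b_name: str
    group_a_distances: list
    group_b_distances: list
    group_a_means: list
    group_b_means: list

    @property
    def n_repeats(self) -> int:
        return len(self.group_a_means)

    def summary(self) -> dict:
        a, b = np.asarray(self.group_a_means), np.asarray(self.group_b_means)
        return {
            "group_a": self.group_a_name,
            "group_b": self.group_b_name,
            "n_repeats": self.n_repeats,
            "a_median": float(np.median(a)),
            "a_min": float(a.min()),
            "a_max": float(a.max()),
            "b_median": float(np.median(b)),
            "b_min": float(b.min()),
            "b_max": float(b.max()),
            "a_mean": float(a.mean()),
            "b_mean": float(b.mean()),
            "fraction_a_below_b": float((a < b).mean()),
        }


def jaccard_distance(u, v) -> float:
    """1 - |support(u) & support(v)| / |support(u) | support(v)|."""
    u = np.asarray(u).astype(bool)
    v = np.asarray(v).astype(bool)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    union = (u | v).sum()
    if union == 0:
        raise ValueError("Jaccard distance undefined for two all-zero vectors")
    return float(1.0 - (u & v).sum() / union)


def hamming_distance(u, v) -> int:
    """Number of differing positions."""
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    return int((u != v).sum())


def _aligned_labels(net: CooccurrenceNetwork, labels: LabelMatrix) -> np.ndarray:
    index = {o: i for i, o in enumerate(labels.otu_ids)}
    try:
        rows = [index[o] for o in net.otu_ids]
    except KeyError as e:
        raise ValueError(f"no labels for network node {e.args[0]!r}") from None
    return labels.Y[rows].astype(bool)


def _pair_jaccard(Y: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    a, b = Y[pairs[:, 0]], Y[pairs[:, 1]]
    inter = (a & b).sum(axis=1)
    union = (a | b).sum(axis=1)
    return 1.0 - inter / union


def adjacency_function_test(
    net: CooccurrenceNetwork,
    labels: LabelMatrix,
    n_pairs: int = 1000,
    n_repeats: int = 1000,
    seed: int = 0,
) -> GroupTestResult:
    """Adjacent vs 3-step-unreachable pairs, compared on label Jaccard.

    Each repeat draws ``n_pairs`` edges and ``n_pairs`` unreachable pairs
    without replacement (with replacement across repeats) among OTUs with
    at least one annotation, and records each group's mean Jaccard
    distance.
    """
    Y = _aligned_labels(net, labels)
    labeled = Y.any(axis=1)
    n_dropped = int((~labeled).sum())
    if n_dropped:
        logger.info("excluding %d unlabeled OTU(s) from pair sampling", n_dropped)

    A = net.adjacency.astype(bool)
    reach3 = reachability_within(net, 3).astype(bool)
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    ok = labeled[iu] & labeled[ju]
    adj_pairs = np.column_stack([iu[(A[iu, ju]) & ok], ju[(A[iu, ju]) & ok]])
    far_mask = (~reach3[iu, ju]) & ok
    far_pairs = np.column_stack([iu[far_mask], ju[far_mask]])
    if len(adj_pairs) < n_pairs:
        raise ValueError(
            f"need {n_pairs} labeled adjacent pairs, only {len(adj_pairs)} exist"
        )
    if len(far_pairs) < n_pairs:
        raise ValueError(
            f"need {n_pairs} labeled 3-step-unreachable pairs, "
            f"only {len(far_pairs)} exist"
        )

    rng = np.random.default_rng(seed)
    a_means, b_means = [], []
    a_last = b_last = None
    for _ in range(n_repeats):
        sel_a = rng.choice(len(adj_pairs), size=n_pairs, replace=False)
        sel_b = rng.choice(len(far_pairs), size=n_pairs, replace=False)
        a_last = _pair_jaccard(Y, adj_pairs[sel_a])
        b_last = _pair_jaccard(Y, far_pairs[sel_b])
        a_means.append(float(a_last.mean()))
        b_means.append(float(b_last.mean()))
    return GroupTestResult(
        "adjacent", "non-adjacent",
        a_last.tolist(), b_last.tolist(), a_means, b_means,
    )


def neighborhood_similarity_test(
    net: CooccurrenceNetwork,
    labels: LabelMatrix,
    n_pairs: int = 10000,
    max_pairs: int = 2_000_000,
    seed: int = 0,
) -> GroupTestResult:
    """Similar- vs different-neighborhood pairs, compared on label Jaccard.

    Neighborhood similarity of two OTUs is the Hamming distance between
    their adjacency rows.  The ``n_pairs`` smallest-distance pairs form
    the Similar Group and the ``n_pairs`` largest the Different Group
    (ties broken by lexicographic pair order).  When the number of node
    pairs exceeds ``max_pairs`` a seeded uniform sample of that size is
    ranked instead of the full set.
    """
    Y = _aligned_labels(net, labels)
    labeled = Y.any(axis=1)
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    ok = labeled[iu] & labeled[ju]
    iu, ju = iu[ok], ju[ok]
    if len(iu) < 2 * n_pairs:
        raise ValueError(
            f"need at least {2 * n_pairs} labeled pairs, only {len(iu)} exist"
        )
    if len(iu) > max_pairs:
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(iu), size=max_pairs, replace=False)
        iu, ju = iu[sel], ju[sel]

    A = net.adjacency.astype(np.int16)
    ham = (A[iu] != A[ju]).sum(axis=1)
    order = np.lexsort((ju, iu, ham))  # distance, then pair order for ties
    similar = order[:n_pairs]
    different = order[-n_pairs:]
    a = _pair_jaccard(Y, np.column_stack([iu[similar], ju[similar]]))
    b = _pair_jaccard(Y, np.column_stack([iu[different], ju[different]]))
    return GroupTestResult(
        "similar-neighborhood", "different-neighborhood",
        a.tolist(), b.tolist(), [float(a.mean())], [float(b.mean())],
    )
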