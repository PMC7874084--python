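"""Inductive graph embedding by neighbor sampling and aggregation.

A node's embedding is computed from a sampled tree of its K-hop
neighborhood: at each hop a fixed number of neighbors is drawn uniformly
with replacement (fanouts S1, S2, ... per hop), their feature vectors are
combined by a permutation-invariant aggregator (elementwise SUM by
default), and the aggregate is concatenated with the node's own transformed
features before a nonlinearity:

    h_E = sigma([W1 . h_T] || [W2 . h_N])

The deepest hop consumes raw node features; each shallower hop consumes the
previous hop's outputs as its neighbor features.  Because the computation
only needs a node's sampled neighborhood, the embedding is inductive: it
applies to nodes unseen during training.

Mean and elementwise-max aggregators are provided behind the same
interface; they realize the mean- and pooling-aggregator baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import CooccurrenceNetwork


@dataclass
class SamplerConfig:
    """Neighbor-sampling schedule: depth K and per-hop fanouts."""

    fanouts: list = field(default_factory=lambda: [25, 10])
    seed: int = 0

    def __post_init__(self) -> None:
        self.fanouts = [int(s) for s in self.fanouts]
        if not self.fanouts or any(s < 1 for s in self.fanouts):
            raise ValueError("fanouts must be a non-empty list of positive ints")

    @property
    def depth(self) -> int:
        return len(self.fanouts)


@dataclass
class NodeFeatures:
    """Feature rows aligned with an ordered OTU id list."""

    otu_ids: list
    h: np.ndarray

    def __post_init__(self) -> None:
        self.otu_ids = list(self.otu_ids)
        self.h = np.asarray(self.h, dtype=float)
        if self.h.ndim != 2 or self.h.shape[0] != len(self.otu_ids):
            raise ValueError("feature matrix must have one row per OTU id")


@dataclass
class EmbedLayerParams:
    """One aggregation layer: self-transform W1, neighbor-transform W2.

    Both matrices map the layer input width to half the layer output
    width; the output is the activated concatenation of the two halves.
    """

    W1: np.ndarray
    W2: np.ndarray
    activation: str = "relu"

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        if self.W1.shape != self.W2.shape:
            raise ValueError("W1 and W2 must have identical shapes")
        if self.activation not in ("relu", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def in_dim(self) -> int:
        return self.W1.shape[1]

    @property
    def out_dim(self) -> int:
        return self.W1.shape[0] + self.W2.shape[0]


def sample_neighbors(net: CooccurrenceNetwork, node, fanout: int, seed=None, rng=None):
    """Uniform with-replacement sample of a node's neighbors.

    Returns exactly ``fanout`` OTU ids.  An isolated node falls back to
    sampling itself, so downstream aggregation always has input.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    i = net.index_of(node)
    nbrs = net.neighbors_of(i)
    if len(nbrs) == 0:
        return [node] * fanout
    picks = rng.integers(0, len(nbrs), size=fanout)
    return [net.otu_ids[nbrs[p]] for p in picks]


def aggregate_sum(neighbor_features) -> np.ndarray:
    """Elementwise sum of a non-empty list of equal-length vectors."""
    stack = _stack(neighbor_features)
    return stack.sum(axis=0)


def aggregate_mean(neighbor_features) -> np.ndarray:
    return _stack(neighbor_features).mean(axis=0)


def aggregate_maxpool(neighbor_features) -> np.ndarray:
    return _stack(neighbor_features).max(axis=0)


def _stack(neighbor_features) -> np.ndarray:
    arr = np.asarray(list(neighbor_features), dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("aggregator needs a non-empty list of equal-length vectors")
    return arr

AGGREGATORS = {"sum": aggregate_sum, "mean": aggregate_mean, "pooling": aggregate_maxpool}


def build_sample_tree(
    net: CooccurrenceNetwork, batch_idx: np.ndarray, fanouts, rng
) -> list:
    """Sampled neighborhood tree for a batch of node indices.

    Level 0 is the batch itself; level t+1 holds, for each node of level t
    in order, its ``fanouts[t]`` sampled neighbor indices (contiguous
    blocks).  Isolated nodes self-sample.
    """
    levels = [np.asarray(batch_idx, dtype=np.int64)]
    for S in fanouts:
        parents = levels[-1]
        children = np.empty(len(parents) * S, dtype=np.int64)
        for p, node in enumerate(parents):
            nbrs = net.neighbors_of(node)
            if len(nbrs) == 0:
                children[p * S : (p + 1) * S] = node
            else:
                children[p * S : (p + 1) * S] = nbrs[rng.integers(0, len(nbrs), size=S)]
        levels.append(children)
    return levels


def _apply_activation(x: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(x, 0.0)
    return x


def forward_tree(feature_matrix: np.ndarray, tree, fanouts, params, aggregator="sum"):
    """Evaluate the K-layer aggregation over a sampled tree.

    ``params[0]`` is the deepest layer (consumes raw features); the last
    layer produces the output embedding of the level-0 nodes.  Returns the
    embedding and a cache of intermediates for backpropagation.
    """
    K = len(fanouts)
    if len(params) != K:
        raise ValueError(f"need {K} layers of params, got {len(params)}")
    H = [feature_matrix[lvl] for lvl in tree]
    cache = []
    for layer_i, layer in enumerate(params):
        new_H = []
        layer_cache = []
        for t in range(K - layer_i):
            self_in = H[t]
            if self_in.shape[1] != layer.in_dim:
                raise ValueError(
                    f"depth {layer_i}: layer expects input width {layer.in_dim}, "
                    f"features have width {self_in.shape[1]}"
                )
            S = fanouts[t]
            child = H[t + 1].reshape(len(self_in), S, -1)
            if aggregator == "sum":
                agg = child.sum(axis=1)
                agg_extra = None
            elif aggregator == "mean":
                agg = child.mean(axis=1)
                agg_extra = None
            elif aggregator == "pooling":
                argmax = child.argmax(axis=1)
                agg = np.take_along_axis(child, argmax[:, None, :], axis=1)[:, 0, :]
                agg_extra = argmax
            else:
                raise ValueError(f"unknown aggregator {aggregator!r}")
            pre = np.concatenate([self_in @ layer.W1.T, agg @ layer.W2.T], axis=1)
            out = _apply_activation(pre, layer.activation)
            new_H.append(out)
            layer_cache.append((self_in, agg, pre, agg_extra))
        cache.append(layer_cache)
        H = new_H
    return H[0], cache


def backward_tree(grad_out: np.ndarray, tree, fanouts, params, cache, aggregator="sum"):
    """Gradients of a scalar loss wrt every W1/W2, given d loss / d embedding.

    Mirrors :func:`forward_tree`; returns a list of (gW1, gW2) per layer in
    the same order as ``params``.
    """
    K = len(fanouts)
    grads = [
        (np.zeros_like(layer.W1), np.zeros_like(layer.W2)) for layer in params
    ]
    # grad wrt the outputs of the current layer, keyed by level
    level_grads = {0: grad_out}
    for layer_i in range(K - 1, -1, -1):
        layer = params[layer_i]
        h = layer.W1.shape[0]
        new_level_grads = {}
        for t, g in level_grads.items():
            self_in, agg, pre, agg_extra = cache[layer_i][t]
            if layer.activation == "relu":
                g = g * (pre > 0)
            g1, g2 = g[:, :h], g[:, h:]
            gW1, gW2 = grads[layer_i]
            gW1 += g1.T @ self_in
            gW2 += g2.T @ agg
            new_level_grads[t] = new_level_grads.get(t, 0) + g1 @ layer.W1
            g_agg = g2 @ layer.W2
            S = fanouts[t]
            n, f = self_in.shape[0], g_agg.shape[1]
            if aggregator == "sum":
                g_child = np.repeat(g_agg, S, axis=0)
            elif aggregator == "mean":
                g_child = np.repeat(g_agg / S, S, axis=0)
            else:  # pooling: route gradient to the argmax child only
                g_child3 = np.zeros((n, S, f))
                np.put_along_axis(g_child3, agg_extra[:, None, :], g_agg[:, None, :], axis=1)
                g_child = g_child3.reshape(n * S, f)
            new_level_grads[t + 1] = new_level_grads.get(t + 1, 0) + g_child
        level_grads = new_level_grads
    return grads


def embed_forward(
    net: CooccurrenceNetwork,
    features: NodeFeatures,
    params,
    cfg: SamplerConfig,
    batch,
    aggregator: str = "sum",
    tree=None,
) -> np.ndarray:
    """Embed a batch of nodes; deterministic given ``cfg.seed``.

    Parameters
    ----------
    batch : list of OTU ids
    tree : optional precomputed sample tree (as from
        :func:`build_sample_tree`); when omitted one is drawn from
        ``cfg.seed``.
    """
    if features.otu_ids != net.otu_ids:
        raise ValueError("features must be row-aligned with the network's OTU ids")
    batch_idx = np.array([net.index_of(b) for b in batch], dtype=np.int64)
    if tree is None:
        rng = np.random.default_rng(cfg.seed)
        tree = build_sample_tree(net, batch_idx, cfg.fanouts, rng)
    emb, _ = forward_tree(features.h, tree, cfg.fanouts, params, aggregator)
    return emb
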