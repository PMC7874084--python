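"""Hierarchical multitask multilabel classifier over a co-occurrence network.

Microbial function annotations are long-tailed: a few KEGG Orthology (KO)
classes cover most OTUs while most classes are rare, and a single
classifier trained on the pooled label matrix drifts toward the dominant
classes.  The model here splits the KO vocabulary at a prevalence
threshold tau into a *majority* task and a *minority* task and trains two
parallel stacks — each a graph-aggregation embedding followed by an MLP
head with per-class sigmoid outputs — over the same network and features,
minimizing the sum of the two summed binary cross-entropy losses with one
Adam optimizer.  Because neither task mixes frequent and rare classes, the
minority stack is free to fit the rare classes.

The model-fitting surface follows the statsmodels convention: build a
:class:`HopeClassifier` from data, call :meth:`~HopeClassifier.fit`, and
work with the returned :class:`HopeResults` (history, predictions,
``summary()``).  Configuration variants reachable from the same class:

========== ============== ===============  ==========
variant    task split     graph embedding  aggregator
========== ============== ===============  ==========
hope       yes            yes              sum
hope-one   no             yes              sum
hope-seq   yes            no               —
gs-mean    no             yes              mean
gs-pooling no             yes              pooling
========== ============== ===============  ==========
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import LabelMatrix
from .embedding import (
    EmbedLayerParams,
    NodeFeatures,
    SamplerConfig,
    backward_tree,
    build_sample_tree,
    forward_tree,
)
from .features import KmerFeatureMatrix
from .network import CooccurrenceNetwork

logger = logging.getLogger(__name__)

_CLIP = 1e-7
VARIANTS = ("hope", "hope-one", "hope-seq", "gs-mean", "gs-pooling")


# ---------------------------------------------------------------------------
# task split


@dataclass
class TaskSplit:
    """Partition of the KO vocabulary into majority and minority tasks."""

    prevalence_threshold: float
    ko_ma: list
    ko_mi: list

    def __post_init__(self) -> None:
        if set(self.ko_ma) & set(self.ko_mi):
            raise ValueError("majority and minority tasks must be disjoint")


def split_tasks(labels: LabelMatrix, tau: float = 0.5) -> TaskSplit:
    """Assign each class to the majority task iff its prevalence exceeds tau.

    Prevalence is the column sum divided by the number of labeled OTUs
    (rows with at least one annotation).  If either side comes out empty a
    warning is logged and training degenerates to a single task.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    labeled = labels.Y.any(axis=1)
    n_labeled = max(int(labeled.sum()), 1)
    prev = labels.Y[labeled].sum(axis=0) / n_labeled
    ko_ma = [k for k, p in zip(labels.ko_ids, prev) if p > tau]
    ko_mi = [k for k, p in zip(labels.ko_ids, prev) if p <= tau]
    if not ko_ma or not ko_mi:
        side = "majority" if not ko_ma else "minority"
        logger.warning(
            "task split at tau=%.3g leaves the %s side empty; "
            "training degenerates to a single task", tau, side,
        )
    return TaskSplit(tau, ko_ma, ko_mi)


def task_loss(pred: np.ndarray, truth: np.ndarray, reduction: str = "sum") -> float:
    """Binary cross-entropy over all OTU x class cells of one task.

    Predictions are clipped to [1e-7, 1 - 1e-7] for numerical stability.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = np.clip(pred, _CLIP, 1.0 - _CLIP)
    cells = -(truth * np.log(p) + (1.0 - truth) * np.log(1.0 - p))
    return float(cells.sum() if reduction == "sum" else cells.mean())


def make_splits(otu_ids, test_fraction: float = 0.2, n_folds: int = 8, seed: int = 0):
    """Held-out test set plus cross-validation folds over the rest.

    Returns ``(test_ids, folds)`` where ``folds`` is a list of
    ``(train_ids, val_ids)`` pairs, each fold serving once as validation.
    """
    otu_ids = list(otu_ids)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(otu_ids) < n_folds + 1:
        raise ValueError(f"need more than {n_folds} OTUs, got {len(otu_ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(otu_ids))
    n_test = int(round(len(otu_ids) * test_fraction))
    test_ids = [otu_ids[i] for i in order[:n_test]]
    rest = order[n_test:]
    fold_chunks = np.array_split(rest, n_folds)
    folds = []
    for f in range(n_folds):
        val = [otu_ids[i] for i in fold_chunks[f]]
        train = [
            otu_ids[i]
            for g, chunk in enumerate(fold_chunks)
            if g != f
            for i in chunk
        ]
        folds.append((train, val))
    return test_ids, folds


# ---------------------------------------------------------------------------
# parameter stacks


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the reference training recipe: Adam, learning rate
    0.01, minibatch 128, dropout 0.4, with L2 weight decay; losses are
    summed over cells (``loss_reduction="mean"`` only rescales the
    effective learning rate).
    """

    learning_rate: float = 0.01
    batch_size: int = 128
    dropout: float = 0.4
    weight_decay: float = 1e-4
    epochs: int = 100
    seed: int = 0
    optimizer: str = "adam"
    loss_reduction: str = "sum"
    embed_dim: int = 128
    hidden_dim: int = 128

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if min(self.batch_size, self.epochs, self.embed_dim, self.hidden_dim) < 1:
            raise ValueError("sizes must be positive")
        if self.embed_dim % 2:
            raise ValueError("embed_dim must be even (concatenation of two halves)")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss_reduction not in ("sum", "mean"):
            raise ValueError("loss_reduction must be 'sum' or 'mean'")


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


class _Stack:
    """One task's trainable parameters: embedding layers + MLP head."""

    def __init__(self, rng, in_dim, n_classes, K, embed_dim, hidden_dim, use_graph):
        self.use_graph = use_graph
        self.embed_layers = []
        if use_graph:
            d_in = in_dim
            half = embed_dim // 2
            for _ in range(K):
                self.embed_layers.append(
                    EmbedLayerParams(
                        _glorot(rng, (half, d_in)), _glorot(rng, (half, d_in))
                    )
                )
                d_in = embed_dim
            head_in = embed_dim
        else:
            head_in = in_dim
        self.Wh = _glorot(rng, (hidden_dim, head_in))
        self.bh = np.zeros(hidden_dim)
        self.Wo = _glorot(rng, (n_classes, hidden_dim))
        self.bo = np.zeros(n_classes)

    def parameters(self):
        ps = []
        for layer in self.embed_layers:
            ps += [layer.W1, layer.W2]
        ps += [self.Wh, self.bh, self.Wo, self.bo]
        return ps

    def forward(self, feat, batch_idx, net, fanouts, aggregator,
                rng_tree=None, dropout=0.0, rng_dropout=None):
        """Probabilities for a batch; returns (P, cache) for backprop."""
        if self.use_graph:
            tree = build_sample_tree(net, batch_idx, fanouts, rng_tree)
            emb, tree_cache = forward_tree(
                feat, tree, fanouts, self.embed_layers, aggregator
            )
        else:
            tree = tree_cache = None
            emb = feat[batch_idx]
        a1 = emb @ self.Wh.T + self.bh
        r1 = np.maximum(a1, 0.0)
        if dropout > 0 and rng_dropout is not None:
            mask = rng_dropout.random(r1.shape) >= dropout
            d1 = r1 * mask / (1.0 - dropout)
        else:
            mask = None
            d1 = r1
        logits = d1 @ self.Wo.T + self.bo
        P = 1.0 / (1.0 + np.exp(-logits))
        cache = (tree, tree_cache, emb, a1, mask, d1, dropout)
        return P, cache

    def backward(self, P, Y, cache, fanouts, aggregator, reduction):
        """Gradients in the order of :meth:`parameters`."""
        tree, tree_cache, emb, a1, mask, d1, dropout = cache
        g_logits = P - Y
        if reduction == "mean":
            g_logits = g_logits / P.size
        gWo = g_logits.T @ d1
        gbo = g_logits.sum(axis=0)
        g_d1 = g_logits @ self.Wo
        if mask is not None:
            g_d1 = g_d1 * mask / (1.0 - dropout)
        g_a1 = g_d1 * (a1 > 0)
        gWh = g_a1.T @ emb
        gbh = g_a1.sum(axis=0)
        g_emb = g_a1 @ self.Wh
        grads = []
        if self.use_graph:
            tree_grads = backward_tree(
                g_emb, tree, fanouts, self.embed_layers, tree_cache, aggregator
            )
            for gW1, gW2 in tree_grads:
                grads += [gW1, gW2]
        grads += [gWh, gbh, gWo, gbo]
        return grads


class _Adam:
    def __init__(self, params, lr, weight_decay, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g + self.wd * p
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# fitted-model container and prediction


@dataclass
class HopeModel:
    """Fitted parameters: one stack per task plus bookkeeping."""

    stack_ma: _Stack
    stack_mi: _Stack  # None when the variant disables the split
    split: TaskSplit
    sampler: SamplerConfig
    ko_ids: list
    variant: str
    aggregator: str
    dropout: float
    eval_seed: int = 12345
    # feature standardization learned at construction (None = raw features)
    feat_mean: np.ndarray = None
    feat_std: np.ndarray = None


def predict(
    model: HopeModel,
    net: CooccurrenceNetwork,
    features,
    node_ids,
    binarize_at: float = 0.5,
):
    """Class probabilities and binary calls in the original KO order.

    Evaluation-time neighbor sampling uses the model's fixed evaluation
    seed, so repeated calls are identical.
    """
    feat = _feature_matrix(features, net)
    if model.feat_mean is not None:
        feat = (feat - model.feat_mean) / model.feat_std
    batch_idx = np.array([net.index_of(n) for n in node_ids], dtype=np.int64)
    rng = np.random.default_rng(model.eval_seed)
    fanouts = model.sampler.fanouts
    P_ma, _ = model.stack_ma.forward(
        feat, batch_idx, net, fanouts, model.aggregator, rng_tree=rng
    )
    if model.stack_mi is not None:
        P_mi, _ = model.stack_mi.forward(
            feat, batch_idx, net, fanouts, model.aggregator, rng_tree=rng
        )
        cols = model.split.ko_ma + model.split.ko_mi
        P = np.concatenate([P_ma, P_mi], axis=1)
    else:
        cols = model.split.ko_ma + model.split.ko_mi
        P = P_ma
    order = [cols.index(k) for k in model.ko_ids]
    P = P[:, order]
    # sigmoid outputs live in (0, 1); keep them strictly inside despite
    # floating-point saturation at large logits
    P = np.clip(P, _CLIP, 1.0 - _CLIP)
    return P, (P > binarize_at).astype(np.int8)


def _feature_matrix(features, net: CooccurrenceNetwork) -> np.ndarray:
    if isinstance(features, KmerFeatureMatrix):
        ids, mat = features.otu_ids, features.freq
    elif isinstance(features, NodeFeatures):
        ids, mat = features.otu_ids, features.h
    else:
        raise TypeError("features must be KmerFeatureMatrix or NodeFeatures")
    if ids == net.otu_ids:
        return np.asarray(mat, dtype=float)
    index = {o: i for i, o in enumerate(ids)}
    try:
        rows = [index[o] for o in net.otu_ids]
    except KeyError as e:
        raise ValueError(f"features missing OTU {e.args[0]!r}") from None
    return np.asarray(mat, dtype=float)[rows]


# ---------------------------------------------------------------------------
# the Model / Results pair


class HopeClassifier:
    """Multilabel KO-function classifier over a co-occurrence network.

    Parameters
    ----------
    net : CooccurrenceNetwork
    features : KmerFeatureMatrix or NodeFeatures
        Node features row-alignable with the network.
    labels : LabelMatrix
        Multihot annotations; rows may be a superset of the network nodes.
    variant : str
        One of ``hope`` (task split + graph embedding, sum aggregator),
        ``hope-one`` (no split), ``hope-seq`` (no graph), ``gs-mean``,
        ``gs-pooling`` (no split, alternative aggregators).
    task_threshold : float
        Prevalence threshold tau for the majority/minority split.
    sampler : SamplerConfig, optional
        Neighbor-sampling schedule; defaults to depth 2, fanouts [25, 10].
    standardize : bool
        Z-score each feature column over the network's nodes before
        training (default).  k-mer frequencies live on a tiny scale
        (~4^-k) with discriminative variation smaller still; column
        standardization puts them on unit scale for the optimizer.  The
        fitted mean/sd travel with the model so prediction applies the
        same transform.
    """

    def __init__(
        self,
        net: CooccurrenceNetwork,
        features,
        labels: LabelMatrix,
        variant: str = "hope",
        task_threshold: float = 0.5,
        sampler: SamplerConfig = None,
        standardize: bool = True,
    ):
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        self.net = net
        self.features = features
        self.labels = labels
        self.variant = variant
        self.task_threshold = task_threshold
        self.sampler = sampler if sampler is not None else SamplerConfig()
        self._feat = _feature_matrix(features, net)
        if standardize:
            self._feat_mean = self._feat.mean(axis=0)
            self._feat_std = np.maximum(self._feat.std(axis=0), 1e-12)
            self._feat = (self._feat - self._feat_mean) / self._feat_std
        else:
            self._feat_mean = self._feat_std = None
        self._label_index = {o: i for i, o in enumerate(labels.otu_ids)}
        if variant in ("hope", "hope-seq"):
            self.split = split_tasks(labels, task_threshold)
        else:  # single task over all classes
            self.split = TaskSplit(task_threshold, list(labels.ko_ids), [])
        self.aggregator = {
            "gs-mean": "mean", "gs-pooling": "pooling"
        }.get(variant, "sum")
        self.use_graph = variant != "hope-seq"

    # -- helpers

    def _label_rows(self, node_ids) -> np.ndarray:
        try:
            rows = [self._label_index[n] for n in node_ids]
        except KeyError as e:
            raise ValueError(f"no labels for OTU {e.args[0]!r}") from None
        return self.labels.Y[rows].astype(float)

    def _task_columns(self):
        ko_index = {k: i for i, k in enumerate(self.labels.ko_ids)}
        cols_ma = [ko_index[k] for k in self.split.ko_ma]
        cols_mi = [ko_index[k] for k in self.split.ko_mi]
        return cols_ma, cols_mi

    # -- fitting

    def fit(self, train_ids, val_ids=None, cfg: TrainConfig = None) -> "HopeResults":
        """Train both task stacks jointly and return a results object.

        One Adam optimizer takes a step on ``Loss_ma + Loss_mi`` per
        minibatch; fresh neighbor samples are drawn every minibatch, and
        everything (init, shuffling, sampling, dropout) derives from
        ``cfg.seed``, so runs are reproducible.
        """
        cfg = cfg if cfg is not None else TrainConfig()
        rng = np.random.default_rng(cfg.seed)
        feat = self._feat
        K = self.sampler.depth
        cols_ma, cols_mi = self._task_columns()
        split = self.split
        if not cols_ma:  # degenerate: all classes minority -> single stack
            cols_ma, cols_mi = cols_mi, []
            split = TaskSplit(split.prevalence_threshold, list(split.ko_mi), [])
        two_tasks = len(cols_ma) > 0 and len(cols_mi) > 0

        stack_ma = _Stack(rng, feat.shape[1], len(cols_ma), K,
                          cfg.embed_dim, cfg.hidden_dim, self.use_graph)
        stack_mi = (
            _Stack(rng, feat.shape[1], len(cols_mi), K, cfg.embed_dim,
                   cfg.hidden_dim, self.use_graph)
            if two_tasks else None
        )

        params = stack_ma.parameters() + (stack_mi.parameters() if stack_mi else [])
        opt = _Adam(params, cfg.learning_rate, cfg.weight_decay)

        train_ids = list(train_ids)
        train_idx = np.array([self.net.index_of(n) for n in train_ids], dtype=np.int64)
        Y_train = self._label_rows(train_ids)
        model = HopeModel(
            stack_ma, stack_mi, split, self.sampler, list(self.labels.ko_ids),
            self.variant, self.aggregator, cfg.dropout,
            feat_mean=self._feat_mean, feat_std=self._feat_std,
        )

        history = []
        from .evaluate import macro_f1, micro_f1  # local import avoids a cycle

        for epoch in range(cfg.epochs):
            order = rng.permutation(len(train_idx))
            ep_loss_ma = ep_loss_mi = 0.0
            for start in range(0, len(order), cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                bidx = train_idx[sel]
                Yb = Y_train[sel]
                loss_ma, loss_mi = self._step(
                    stack_ma, stack_mi, opt, feat, bidx, Yb,
                    cols_ma, cols_mi, cfg, rng,
                )
                ep_loss_ma += loss_ma
                ep_loss_mi += loss_mi
            total = ep_loss_ma + ep_loss_mi
            if not np.isfinite(total):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            row = {
                "epoch": epoch,
                "train_loss": total,
                "train_loss_ma": ep_loss_ma,
                "train_loss_mi": ep_loss_mi,
            }
            if val_ids:
                P, B = predict(model, self.net, self.features, val_ids)
                Yv = self._label_rows(val_ids)
                row["val_loss"] = task_loss(P, Yv, cfg.loss_reduction)
                row["val_micro_f1"] = micro_f1(B, Yv)
                row["val_macro_f1"] = macro_f1(B, Yv)
            history.append(row)

        return HopeResults(self, model, pd.DataFrame(history), cfg,
                           list(train_ids), list(val_ids) if val_ids else [])

    def _step(self, stack_ma, stack_mi, opt, feat, bidx, Yb,
              cols_ma, cols_mi, cfg, rng):
        fanouts = self.sampler.fanouts
        Y_ma = Yb[:, cols_ma]
        P_ma, cache_ma = stack_ma.forward(
            feat, bidx, self.net, fanouts, self.aggregator,
            rng_tree=rng, dropout=cfg.dropout, rng_dropout=rng,
        )
        loss_ma = task_loss(P_ma, Y_ma, cfg.loss_reduction)
        grads = stack_ma.backward(
            P_ma, Y_ma, cache_ma, fanouts, self.aggregator, cfg.loss_reduction
        )
        loss_mi = 0.0
        if stack_mi is not None:
            Y_mi = Yb[:, cols_mi]
            P_mi, cache_mi = stack_mi.forward(
                feat, bidx, self.net, fanouts, self.aggregator,
                rng_tree=rng, dropout=cfg.dropout, rng_dropout=rng,
            )
            loss_mi = task_loss(P_mi, Y_mi, cfg.loss_reduction)
            grads = grads + stack_mi.backward(
                P_mi, Y_mi, cache_mi, fanouts, self.aggregator, cfg.loss_reduction
            )
        opt.step(grads)
        return loss_ma, loss_mi


class HopeResults:
    """Fitted-model results: parameters, history, predictions, summary."""

    def __init__(self, spec_model, model, history, cfg, train_ids, val_ids):
        self.model_spec = spec_model
        self.model = model
        self.history = history
        self.config = cfg
        self.train_ids = train_ids
        self.val_ids = val_ids

    def predict(self, node_ids, binarize_at: float = 0.5):
        """Probabilities and binary calls in the label matrix's KO order."""
        return predict(
            self.model, self.model_spec.net, self.model_spec.features,
            node_ids, binarize_at,
        )

    @property
    def final_train_loss(self) -> float:
        return float(self.history["train_loss"].iloc[-1])

    def summary(self) -> str:
        m = self.model
        lines = [
            "HOPE hierarchical multitask classifier",
            "=" * 54,
            f"variant:            {m.variant}",
            f"aggregator:         {m.aggregator}",
            f"sampler fanouts:    {m.sampler.fanouts}",
            f"majority classes:   {len(m.split.ko_ma)}",
            f"minority classes:   {len(m.split.ko_mi)}",
            f"tau (split):        {m.split.prevalence_threshold}",
            f"train nodes:        {len(self.train_ids)}",
            f"epochs:             {len(self.history)}",
            f"final train loss:   {self.final_train_loss:.4f}",
        ]
        if "val_micro_f1" in self.history:
            lines += [
                f"final val micro-F1: {self.history['val_micro_f1'].iloc[-1]:.4f}",
                f"final val macro-F1: {self.history['val_macro_f1'].iloc[-1]:.4f}",
            ]
        return "\n".join(lines)


def save_model(model: HopeModel, path) -> None:
    """Serialize a fitted model: one .npz of arrays + a JSON sidecar."""
    import json

    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    arrays = {}
    meta_stacks = {}
    for name, stack in (("ma", model.stack_ma), ("mi", model.stack_mi)):
        if stack is None:
            continue
        for i, layer in enumerate(stack.embed_layers):
            arrays[f"{name}_W1_{i}"] = layer.W1
            arrays[f"{name}_W2_{i}"] = layer.W2
        arrays[f"{name}_Wh"] = stack.Wh
        arrays[f"{name}_bh"] = stack.bh
        arrays[f"{name}_Wo"] = stack.Wo
        arrays[f"{name}_bo"] = stack.bo
        meta_stacks[name] = {
            "n_embed_layers": len(stack.embed_layers),
            "use_graph": stack.use_graph,
        }
    if model.feat_mean is not None:
        arrays["feat_mean"] = model.feat_mean
        arrays["feat_std"] = model.feat_std
    np.savez(path, **arrays)
    meta = {
        "variant": model.variant,
        "aggregator": model.aggregator,
        "dropout": model.dropout,
        "eval_seed": model.eval_seed,
        "fanouts": model.sampler.fanouts,
        "sampler_seed": model.sampler.seed,
        "tau": model.split.prevalence_threshold,
        "ko_ma": model.split.ko_ma,
        "ko_mi": model.split.ko_mi,
        "ko_ids": model.ko_ids,
        "stacks": meta_stacks,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path) -> HopeModel:
    import json

    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    with open(path + ".json") as fh:
        meta = json.load(fh)
    data = np.load(path)
    stacks = {}
    for name, sm in meta["stacks"].items():
        stack = _Stack.__new__(_Stack)
        stack.use_graph = sm["use_graph"]
        stack.embed_layers = [
            EmbedLayerParams(data[f"{name}_W1_{i}"], data[f"{name}_W2_{i}"])
            for i in range(sm["n_embed_layers"])
        ]
        stack.Wh = data[f"{name}_Wh"]
        stack.bh = data[f"{name}_bh"]
        stack.Wo = data[f"{name}_Wo"]
        stack.bo = data[f"{name}_bo"]
        stacks[name] = stack
    return HopeModel(
        stack_ma=stacks["ma"],
        stack_mi=stacks.get("mi"),
        split=TaskSplit(meta["tau"], meta["ko_ma"], meta["ko_mi"]),
        sampler=SamplerConfig(meta["fanouts"], meta["sampler_seed"]),
        ko_ids=meta["ko_ids"],
        variant=meta["variant"],
        aggregator=meta["aggregator"],
        dropout=meta["dropout"],
        eval_seed=meta["eval_seed"],
        feat_mean=data["feat_mean"] if "feat_mean" in data else None,
        feat_std=data["feat_std"] if "feat_std" in data else None,
    )


def train(net, features, labels, split: TaskSplit, cfg: TrainConfig,
          sampler: SamplerConfig, train_ids, val_ids=None, variant: str = "hope"):
    """Functional wrapper: returns ``(HopeModel, history DataFrame)``."""
    clf = HopeClassifier(
        net, features, labels, variant=variant,
        task_threshold=split.prevalence_threshold, sampler=sampler,
    )
    clf.split = split if variant in ("hope", "hope-seq") else clf.split
    res = clf.fit(train_ids, val_ids, cfg)
    return res.model, res.history
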