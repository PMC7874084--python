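"""Canned desk-scale studies: ablations, hypothesis tests, metric checks.

These functions freeze the study conditions used to exercise the method's
claims on synthetic communities:

* the **ablation study** compares the full model against its single-task
  (``hope-one``) and sequence-only (``hope-seq``) ablations on a
  long-tailed assortative community (16 guilds x 8 OTUs, 40 classes,
  power-law prevalence with exponent 2, 15% within-guild sequence
  divergence), averaged over independent replicate seeds;
* the **support regression** pools the full model's per-class F1 against
  training-set support across the replicates;
* the **hypothesis study** runs the adjacent-vs-distant and
  similar-vs-different-neighborhood comparisons on an assortative
  community (6 guilds x 10 OTUs, 5% label noise), plus label-shuffled
  negative controls in which the label rows are freshly permuted for
  every repeat.

Communities are intentionally small enough that every study runs on one
CPU in well under a minute per replicate; within-guild sequence
divergence is set where sequence composition alone does not saturate the
task, so the ablations have headroom to differ.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import LabelMatrix
from .embedding import SamplerConfig
from .evaluate import macro_f1, micro_f1, per_class_table, roc_auc, accuracy
from .features import kmer_frequencies
from .hypotheses import adjacency_function_test, neighborhood_similarity_test
from .model import HopeClassifier, TrainConfig, make_splits
from .network import build_network, sparcc_correlation
from .synthetic import SyntheticConfig, generate_community

# conditions of the long-tailed ablation community
ABLATION_COMMUNITY = dict(
    n_guilds=16,
    otus_per_guild=8,
    n_samples=50,
    n_classes=40,
    mutation_rate=0.15,
    label_noise=0.05,
    class_prevalence_exponent=2.0,
)

# conditions of the assortative hypothesis-test community
HYPOTHESIS_COMMUNITY = dict(
    n_guilds=6,
    otus_per_guild=10,
    n_samples=50,
    label_noise=0.05,
)

ABLATION_TRAIN = dict(epochs=100, embed_dim=32, hidden_dim=32)
ABLATION_KMER = 3
ABLATION_FANOUTS = [10, 5]


def _community_net_features(syn: SyntheticConfig, k: int):
    com = generate_community(syn)
    corr = sparcc_correlation(com.abundance)
    net = build_network(corr)
    fm = kmer_frequencies(com.sequences, k)
    return com, net, fm


def run_ablation_variant(seed: int, variant: str, epochs: int = None) -> dict:
    """Train one variant on the ablation community and score the test set.

    Returns the four scalar metrics plus the per-class table (with
    training-set supports) for the held-out 20% of OTUs.
    """
    syn = SyntheticConfig(seed=seed, **ABLATION_COMMUNITY)
    com, net, fm = _community_net_features(syn, ABLATION_KMER)
    test_ids, folds = make_splits(net.otu_ids, 0.2, 8, seed=seed)
    train_ids, val_ids = folds[0]
    fit_ids = train_ids + val_ids
    clf = HopeClassifier(
        net, fm, com.labels, variant=variant,
        sampler=SamplerConfig(ABLATION_FANOUTS, seed),
    )
    tc_kwargs = dict(ABLATION_TRAIN)
    if epochs is not None:
        tc_kwargs["epochs"] = epochs
    res = clf.fit(fit_ids, None, TrainConfig(seed=seed, **tc_kwargs))
    P, B = res.predict(test_ids)
    Yt = clf._label_rows(test_ids)
    support = clf._label_rows(fit_ids).sum(axis=0)
    return {
        "seed": seed,
        "variant": variant,
        "micro_f1": micro_f1(B, Yt),
        "macro_f1": macro_f1(B, Yt),
        "accuracy": accuracy(B, Yt),
        "roc_auc": roc_auc(P, Yt),
        "per_class": per_class_table(B, Yt, com.labels.ko_ids, support),
    }


def ablation_study(seeds=(1, 2, 3, 4, 5),
                   variants=("hope", "hope-one", "hope-seq"),
                   epochs: int = None):
    """Replicated ablation comparison.

    Returns ``(summary, pooled_per_class)``: a DataFrame of per-run scalar
    metrics and the concatenated per-class tables of the full model's runs
    (input to :func:`hope.evaluate.support_performance_regression`).
    """
    rows, hope_tables = [], []
    for variant in variants:
        for seed in seeds:
            out = run_ablation_variant(seed, variant, epochs)
            table = out.pop("per_class")
            if variant == "hope":
                hope_tables.append(table)
            rows.append(out)
    pooled = pd.concat(hope_tables, ignore_index=True) if hope_tables else None
    return pd.DataFrame(rows), pooled


def shuffled_labels(labels: LabelMatrix, rng) -> LabelMatrix:
    """Label rows permuted across OTUs — breaks any topology association."""
    perm = rng.permutation(labels.n_otus)
    return LabelMatrix(labels.otu_ids, labels.ko_ids, labels.Y[perm])


def hypothesis_study(seed: int = 2, n_pairs: int = 200, n_repeats: int = 100,
                     neighborhood_n_pairs: int = 100,
                     n_control_shuffles: int = 100) -> dict:
    """Both topology-predicts-function tests plus negative controls.

    The negative control redraws a fresh label permutation for every
    repeat, so its per-repeat directions are independent under the null.
    """
    syn = SyntheticConfig(seed=seed, **HYPOTHESIS_COMMUNITY)
    com = generate_community(syn)
    net = build_network(sparcc_correlation(com.abundance))

    adj = adjacency_function_test(net, com.labels, n_pairs, n_repeats, seed)
    nbr = neighborhood_similarity_test(net, com.labels, neighborhood_n_pairs,
                                       seed=seed)

    rng = np.random.default_rng(seed + 1_000_003)
    adj_ctrl_wins = nbr_ctrl_wins = 0
    for _ in range(n_control_shuffles):
        shuf = shuffled_labels(com.labels, rng)
        r = adjacency_function_test(net, shuf, n_pairs, 1,
                                    seed=int(rng.integers(2**31)))
        adj_ctrl_wins += r.group_a_means[0] < r.group_b_means[0]
        n = neighborhood_similarity_test(net, shuf, neighborhood_n_pairs,
                                         seed=0)
        nbr_ctrl_wins += n.group_a_means[0] < n.group_b_means[0]
    return {
        "adjacency": adj,
        "neighborhood": nbr,
        "adjacency_control_wins": int(adj_ctrl_wins),
        "neighborhood_control_wins": int(nbr_ctrl_wins),
        "n_control_shuffles": n_control_shuffles,
    }
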