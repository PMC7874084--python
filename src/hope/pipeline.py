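"""End-to-end pipeline: simulate -> network -> features -> train -> predict
-> evaluate -> verify, with a manifest for exact reproducibility.

Every tunable lives in :class:`PipelineConfig`, which round-trips
losslessly through YAML/JSON and rejects unknown keys.  ``run_pipeline``
executes the stages in order, writes every intermediate as a plain-text
artifact, and records a manifest with the configuration hash and all
seeds, so a rerun from the same manifest reproduces byte-identical
output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as hio
from .embedding import SamplerConfig
from .evaluate import evaluate_predictions, support_performance_regression
from .features import kmer_frequencies
from .hypotheses import adjacency_function_test, neighborhood_similarity_test
from .model import (
    HopeClassifier,
    TrainConfig,
    make_splits,
    save_model,
)
from .network import build_network, sparcc_correlation, spearman_correlation
from .synthetic import SyntheticConfig, generate_community

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline tunables in one flat, serializable record."""

    # synthetic community (used when no input files are given)
    n_guilds: int = 4
    otus_per_guild: int = 10
    n_samples: int = 50
    seq_length: int = 1000
    mutation_rate: float = 0.1
    n_classes: int = 20
    class_prevalence_exponent: float = 2.0
    label_noise: float = 0.05
    within_guild_log_sd: float = 0.1
    between_sample_log_sd: float = 1.0
    # network
    correlation_backend: str = "sparcc"
    pseudocount: float = 1.0
    n_exclusion_iters: int = 0
    threshold: float = 0.3
    mode: str = "positive-only"
    # features
    k: int = 7
    # training
    variant: str = "hope"
    tau: float = 0.5
    fanouts: list = field(default_factory=lambda: [25, 10])
    learning_rate: float = 0.01
    batch_size: int = 128
    dropout: float = 0.4
    weight_decay: float = 1e-4
    epochs: int = 100
    embed_dim: int = 128
    hidden_dim: int = 128
    test_fraction: float = 0.2
    n_folds: int = 8
    binarize_at: float = 0.5
    # verification
    verify: bool = True
    verify_n_pairs: int = 200
    verify_n_repeats: int = 100
    neighborhood_n_pairs: int = 100
    # randomness
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _stage(name):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

        return wrapper

    return decorate


def correlation_for(cfg: PipelineConfig, table):
    if cfg.correlation_backend == "sparcc":
        return sparcc_correlation(table, cfg.pseudocount, cfg.n_exclusion_iters)
    if cfg.correlation_backend == "spearman":
        return spearman_correlation(table)
    raise ValueError(f"unknown correlation backend {cfg.correlation_backend!r}")


def run_pipeline(cfg: PipelineConfig, outdir,
                 fasta=None, abundance=None, labels_path=None):
    """Run all stages and return the metrics report.

    When ``fasta``/``abundance``/``labels_path`` are omitted the synthetic
    generator provides the community (and its guild map is written too).
    All artifacts, the metrics report and the manifest land in ``outdir``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "defaults in effect: threshold=%.3g (%s), tau=%.3g, binarize_at=%.3g",
        cfg.threshold, cfg.mode, cfg.tau, cfg.binarize_at,
    )

    # ----- inputs
    if fasta is None or abundance is None or labels_path is None:
        syn = SyntheticConfig(
            n_guilds=cfg.n_guilds, otus_per_guild=cfg.otus_per_guild,
            n_samples=cfg.n_samples, seq_length=cfg.seq_length,
            mutation_rate=cfg.mutation_rate, n_classes=cfg.n_classes,
            class_prevalence_exponent=cfg.class_prevalence_exponent,
            label_noise=cfg.label_noise,
            within_guild_log_sd=cfg.within_guild_log_sd,
            between_sample_log_sd=cfg.between_sample_log_sd, seed=cfg.seed,
        )
        community = _stage("simulate")(generate_community)(syn)
        records = community.sequences
        table = community.abundance
        labels = community.labels
        hio.write_fasta(records, out / "sequences.fasta")
        hio.write_abundance_tsv(table, out / "abundance.tsv")
        hio.write_labels_tsv(labels, out / "labels.tsv")
        hio.write_guilds_tsv(community.guild_assignment, out / "guilds.tsv")
    else:
        records = _stage("read-fasta")(hio.read_fasta)(fasta)
        table = _stage("read-abundance")(hio.read_abundance_tsv)(abundance)
        labels = _stage("read-labels")(hio.read_labels_tsv)(labels_path)

    # ----- network
    corr = _stage("network")(correlation_for)(cfg, table)
    net = _stage("network")(build_network)(corr, cfg.threshold, cfg.mode)
    hio.write_edges_tsv(net, out / "edges.tsv", corr)

    # ----- features
    fm = _stage("features")(kmer_frequencies)(records, cfg.k)
    hio.write_features_tsv(fm, out / "features.tsv")

    # ----- splits + training
    test_ids, folds = _stage("split")(make_splits)(
        net.otu_ids, cfg.test_fraction, cfg.n_folds, cfg.seed
    )
    train_ids, val_ids = folds[0]
    clf = HopeClassifier(
        net, fm, labels, variant=cfg.variant, task_threshold=cfg.tau,
        sampler=SamplerConfig(cfg.fanouts, cfg.seed),
    )
    tc = TrainConfig(
        learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
        dropout=cfg.dropout, weight_decay=cfg.weight_decay,
        epochs=cfg.epochs, seed=cfg.seed, embed_dim=cfg.embed_dim,
        hidden_dim=cfg.hidden_dim,
    )
    res = _stage("train")(clf.fit)(train_ids, val_ids, tc)
    res.history.to_csv(out / "history.tsv", sep="\t", index=False,
                       float_format="%.8g")
    save_model(res.model, out / "model.npz")

    # ----- predict + evaluate on the held-out test set
    probs, binary = _stage("predict")(res.predict)(test_ids, cfg.binarize_at)
    hio.write_predictions_tsv(test_ids, labels.ko_ids, probs, binary,
                              out / "predictions.tsv")
    truth = clf._label_rows(test_ids)
    train_support = clf._label_rows(train_ids).sum(axis=0)
    report = _stage("evaluate")(evaluate_predictions)(
        probs, binary, truth, labels.ko_ids, train_support
    )
    report.per_class.to_csv(out / "per_class.tsv", sep="\t", index=False,
                            float_format="%.8g")
    metrics = {k: (None if np.isnan(v) else round(float(v), 10))
               for k, v in report.to_dict().items()}
    if report.per_class["f1"].notna().sum() >= 3:
        try:
            slope, intercept, pvalue = support_performance_regression(
                report.per_class
            )
            metrics["support_slope"] = round(slope, 10)
            metrics["support_slope_pvalue"] = round(pvalue, 10)
        except ValueError:
            pass
    hio.write_json(metrics, out / "metrics.json")

    # ----- hypothesis verification
    if cfg.verify:
        adj = _stage("verify")(adjacency_function_test)(
            net, labels, cfg.verify_n_pairs, cfg.verify_n_repeats, cfg.seed
        )
        nbr = _stage("verify")(neighborhood_similarity_test)(
            net, labels, cfg.neighborhood_n_pairs, seed=cfg.seed
        )
        hio.write_json(
            {"adjacency": adj.summary(), "neighborhood": nbr.summary()},
            out / "verify.json",
        )
        with open(out / "verify_repeats.tsv", "w") as fh:
            fh.write("repeat\tadjacent_mean\tnonadjacent_mean\n")
            for r, (a, b) in enumerate(zip(adj.group_a_means, adj.group_b_means)):
                fh.write(f"{r}\t{a:.8g}\t{b:.8g}\n")

    # ----- manifest
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_train": len(train_ids),
        "n_val": len(val_ids),
        "n_test": len(test_ids),
        "artifacts": sorted(
            p.name for p in out.iterdir() if p.name != "manifest.json"
        ),
    }
    hio.write_json(manifest, out / "manifest.json")
    return report
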