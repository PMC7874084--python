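"""Readers and writers for the pipeline's plain-text formats.

Native formats are deliberately minimal and diffable: FASTA for
sequences, TSV for the abundance table (first column OTU id, header row
sample ids), a two-column TSV for labels (OTU id, comma-separated KO
ids), TSV edge lists for networks, and JSON for metrics and manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import AbundanceTable, LabelMatrix
from .features import KmerFeatureMatrix
from .network import CooccurrenceNetwork, CorrelationMatrix


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path):
    """Ordered (id, sequence) records; wrapped lines are joined.

    Raises on duplicate ids and on records with empty sequences.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for otu_id, seq in records:
            fh.write(f">{otu_id}\n")
            for start in range(0, len(seq), width):
                fh.write(seq[start : start + width] + "\n")


# ---------------------------------------------------------------------------
# abundance


def read_abundance_tsv(path) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = np.empty(df.shape, dtype=float)
    for i, (otu, row) in enumerate(df.iterrows()):
        for j, (sample, cell) in enumerate(row.items()):
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric abundance {cell!r} at OTU {otu!r}, "
                    f"sample {sample!r}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"negative abundance {cell!r} at OTU {otu!r}, sample {sample!r}"
                )
            values[i, j] = v
    return AbundanceTable(list(df.index), list(df.columns), values)


def write_abundance_tsv(table: AbundanceTable, path) -> None:
    df = pd.DataFrame(table.counts, index=table.otu_ids, columns=table.sample_ids)
    int_like = np.allclose(table.counts, np.round(table.counts))
    if int_like:
        df = df.astype(int)
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# labels


def read_labels_tsv(path, ko_vocabulary=None) -> LabelMatrix:
    """Two-column TSV: OTU id, comma-separated KO ids (empty allowed).

    The KO vocabulary is the sorted union of observed ids unless one is
    supplied; a KO absent from a supplied vocabulary is an error.
    """
    otu_ids, ko_sets = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("otu_id"):
            raise ValueError(f"expected 'otu_id' header in {path}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = [parts[0], ""]
            otu, kos = parts[0], parts[1]
            otu_ids.append(otu)
            ko_sets.append([k for k in kos.split(",") if k])
    if ko_vocabulary is None:
        vocab = sorted({k for ks in ko_sets for k in ks})
    else:
        vocab = list(ko_vocabulary)
        known = set(vocab)
        for otu, ks in zip(otu_ids, ko_sets):
            unknown = [k for k in ks if k not in known]
            if unknown:
                raise ValueError(
                    f"KO {unknown[0]!r} of OTU {otu!r} is not in the vocabulary"
                )
    index = {k: j for j, k in enumerate(vocab)}
    Y = np.zeros((len(otu_ids), len(vocab)), dtype=np.int8)
    for i, ks in enumerate(ko_sets):
        for k in ks:
            Y[i, index[k]] = 1
    return LabelMatrix(otu_ids, vocab, Y)


def write_labels_tsv(labels: LabelMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tko_ids\n")
        for i, otu in enumerate(labels.otu_ids):
            kos = [labels.ko_ids[j] for j in np.flatnonzero(labels.Y[i])]
            fh.write(f"{otu}\t{','.join(kos)}\n")


# ---------------------------------------------------------------------------
# network / correlation


def write_edges_tsv(net: CooccurrenceNetwork, path,
                    corr: CorrelationMatrix = None) -> None:
    with open(path, "w") as fh:
        fh.write("otu_a\totu_b\trho\n")
        for a, b in net.edges():
            if corr is not None:
                i, j = corr.otu_ids.index(a), corr.otu_ids.index(b)
                rho = f"{corr.rho[i, j]:.6f}"
            else:
                rho = "1"
            fh.write(f"{a}\t{b}\t{rho}\n")


def write_graphml(net: CooccurrenceNetwork, path) -> None:
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(net.otu_ids)
    G.add_edges_from(net.edges())
    nx.write_graphml(G, str(path))


# ---------------------------------------------------------------------------
# features / embeddings / predictions


def write_features_tsv(fm: KmerFeatureMatrix, path, sparse: bool = None) -> None:
    """Dense table for small k, sparse (otu, kmer, freq) triplets for large."""
    if sparse is None:
        sparse = fm.k >= 6
    if sparse:
        kmers = fm.column_kmers()
        with open(path, "w") as fh:
            fh.write("otu_id\tkmer\tfreq\n")
            for i, otu in enumerate(fm.otu_ids):
                for j in np.flatnonzero(fm.freq[i]):
                    fh.write(f"{otu}\t{kmers[j]}\t{fm.freq[i, j]:.10g}\n")
    else:
        df = pd.DataFrame(fm.freq, index=fm.otu_ids, columns=fm.column_kmers())
        df.index.name = "otu_id"
        df.to_csv(path, sep="\t", float_format="%.10g")


def write_embeddings_tsv(otu_ids, emb: np.ndarray, path) -> None:
    df = pd.DataFrame(
        emb, index=list(otu_ids),
        columns=[f"e{j}" for j in range(emb.shape[1])],
    )
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t", float_format="%.8g")


def write_predictions_tsv(otu_ids, ko_ids, probs, binary, path) -> None:
    """Long-form TSV: one row per (OTU, KO) pair."""
    with open(path, "w") as fh:
        fh.write("otu_id\tko_id\tprobability\tcall\n")
        for i, otu in enumerate(otu_ids):
            for j, ko in enumerate(ko_ids):
                fh.write(f"{otu}\t{ko}\t{probs[i, j]:.6f}\t{int(binary[i, j])}\n")


def write_guilds_tsv(guild_assignment: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tguild\n")
        for otu, g in guild_assignment.items():
            fh.write(f"{otu}\t{g}\n")


def read_guilds_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"otu_id": str, "guild": int})
    return dict(zip(df["otu_id"], df["guild"]))


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
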