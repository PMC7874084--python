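"""Core in-memory containers shared across the pipeline.

The pipeline's native tabular format is plain TSV with string identifiers;
these containers wrap validated NumPy arrays together with the ordered id
lists that give rows and columns their meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class AbundanceTable:
    """Non-negative OTU x sample count matrix.

    Parameters
    ----------
    otu_ids : list of str
        Row identifiers, one per OTU.
    sample_ids : list of str
        Column identifiers, one per community sample.
    counts : ndarray of shape (n_otus, n_samples)
        Non-negative abundances (raw counts or estimated counts).
    """

    otu_ids: list
    sample_ids: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.otu_ids = list(self.otu_ids)
        self.sample_ids = list(self.sample_ids)
        self.counts = np.asarray(self.counts, dtype=float)
        _check_unique(self.otu_ids, "OTU")
        _check_unique(self.sample_ids, "sample")
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.otu_ids)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative abundance at OTU {self.otu_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def require_correlatable(self) -> None:
        """Raise unless the table is large enough for correlation estimation."""
        if self.n_otus < 2 or self.n_samples < 3:
            raise ValueError(
                "correlation estimation needs at least 2 OTUs and 3 samples; "
                f"got {self.n_otus} OTUs x {self.n_samples} samples"
            )


@dataclass
class LabelMatrix:
    """Multihot OTU x KO annotation matrix.

    Each row is the binary function profile of one OTU: ``Y[i, c] == 1``
    means OTU ``otu_ids[i]`` is annotated with function ``ko_ids[c]``.
    """

    otu_ids: list
    ko_ids: list
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.otu_ids = list(self.otu_ids)
        self.ko_ids = list(self.ko_ids)
        self.Y = np.asarray(self.Y)
        _check_unique(self.otu_ids, "OTU")
        _check_unique(self.ko_ids, "KO")
        if self.Y.shape != (len(self.otu_ids), len(self.ko_ids)):
            raise ValueError(
                f"label matrix shape {self.Y.shape} does not match "
                f"({len(self.otu_ids)}, {len(self.ko_ids)})"
            )
        if not np.isin(self.Y, (0, 1)).all():
            raise ValueError("label matrix entries must be 0 or 1")
        self.Y = self.Y.astype(np.int8)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_classes(self) -> int:
        return len(self.ko_ids)

    def prevalence(self) -> np.ndarray:
        """Per-class fraction of OTUs carrying the annotation."""
        return self.Y.mean(axis=0)

    def reorder_classes(self, ko_ids: list) -> "LabelMatrix":
        idx = [self.ko_ids.index(k) for k in ko_ids]
        return LabelMatrix(self.otu_ids, list(ko_ids), self.Y[:, idx])
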