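"""Synthetic microbial communities with the structure the model assumes.

The generator emulates three properties of real amplicon datasets that the
pipeline exploits, without requiring any download:

* **co-abundant guilds** — OTUs belong to guilds that rise and fall
  together across samples, so abundance correlation recovers guild
  structure (each guild draws one log-normal latent abundance per sample
  and members add independent log-normal noise around it);
* **sequence similarity within guilds** — each guild has one random DNA
  prototype and members are noisy copies with i.i.d. substitutions, so
  k-mer signatures cluster by guild;
* **long-tailed, network-assortative function labels** — function class c
  is carried by a random subset of guilds whose size decays as
  ``(c + 1) ** -alpha``, every OTU of a carrying guild inherits the label,
  and independent bit flips add annotation noise.  A few classes cover
  most OTUs while most classes are rare, the long-tail regime the
  hierarchical multitask split is designed for.

All generators are pure functions of the configuration (including its
seed): calling one twice yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import AbundanceTable, LabelMatrix

_BASES = np.array(list("ACGT"))

# median guild abundance (counts) around which samples fluctuate
_BASE_ABUNDANCE = 200.0


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic community generator.

    Parameters
    ----------
    n_guilds, otus_per_guild : int
        Community layout; OTU ids are ``OTU0001``.. row-major by guild.
    n_samples : int
        Number of community samples in the abundance table.
    seq_length : int
        Length of each representative sequence in bp (default 1000,
        the typical 16S representative length).
    mutation_rate : float
        Per-base substitution probability applied to a guild prototype to
        produce each member sequence.  The default 0.1 keeps guild members
        recognisably related while still more divergent than the ~3%
        dissimilarity that separates distinct OTUs.
    n_classes : int
        Number of function classes (KO ids ``K00001``..).
    class_prevalence_exponent : float
        Power-law decay of per-class guild coverage; larger -> heavier tail.
    prevalence_scale : float
        Proportionality constant of the coverage schedule, in (0, 1].  Kept
        below 1 so even the most prevalent class is absent from some guilds
        (a function carried by every OTU would be uninformative).
    label_noise : float
        Independent per-cell flip probability applied to the label matrix.
    within_guild_log_sd : float
        Log-scale sd of per-OTU noise around the guild latent abundance.
    between_sample_log_sd : float
        Log-scale sd of the guild latent abundance across samples; this is
        what makes guild members co-vary.
    seed : int
        Seed for all randomness in the generator.
    """

    n_guilds: int = 4
    otus_per_guild: int = 10
    n_samples: int = 50
    seq_length: int = 1000
    mutation_rate: float = 0.1
    n_classes: int = 20
    class_prevalence_exponent: float = 2.0
    prevalence_scale: float = 0.9
    label_noise: float = 0.05
    within_guild_log_sd: float = 0.1
    between_sample_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_guilds < 1 or self.otus_per_guild < 1:
            raise ValueError("n_guilds and otus_per_guild must be positive")
        if self.n_guilds * self.otus_per_guild < 2:
            raise ValueError("community must contain at least 2 OTUs")
        if min(self.n_samples, self.seq_length) < 1:
            raise ValueError("n_samples and seq_length must be positive")
        for name in ("mutation_rate", "label_noise"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_classes < 1:
            raise ValueError("n_classes must be positive")
        if self.class_prevalence_exponent <= 0:
            raise ValueError("class_prevalence_exponent must be positive")
        if not 0 < self.prevalence_scale <= 1:
            raise ValueError("prevalence_scale must be in (0, 1]")
        if self.within_guild_log_sd <= 0 or self.between_sample_log_sd <= 0:
            raise ValueError("log-sd parameters must be positive")

    @property
    def n_otus(self) -> int:
        return self.n_guilds * self.otus_per_guild

    def otu_ids(self) -> list:
        return [f"OTU{i + 1:04d}" for i in range(self.n_otus)]

    def guild_assignment(self) -> dict:
        """OTU id -> guild index, row-major: guild g holds a block of OTUs."""
        return {
            oid: i // self.otus_per_guild for i, oid in enumerate(self.otu_ids())
        }


@dataclass
class SyntheticCommunity:
    """Bundle of all generated artifacts for one synthetic community."""

    sequences: list  # (otu_id, sequence) pairs
    abundance: AbundanceTable
    labels: LabelMatrix
    guild_assignment: dict = field(default_factory=dict)


def generate_sequences(cfg: SyntheticConfig):
    """One random DNA prototype per guild; members are mutated copies.

    Substitutions replace a base by one of the three other bases chosen
    uniformly, so ``mutation_rate`` is the expected per-base Hamming
    divergence from the prototype.

    Returns
    -------
    list of (otu_id, sequence) pairs in OTU-id order.
    """
    rng = np.random.default_rng(cfg.seed)
    prototypes = rng.integers(0, 4, size=(cfg.n_guilds, cfg.seq_length))
    records = []
    guild_of = cfg.guild_assignment()
    for oid in cfg.otu_ids():
        codes = prototypes[guild_of[oid]].copy()
        mutate = rng.random(cfg.seq_length) < cfg.mutation_rate
        # substitute with one of the 3 other bases
        shifts = rng.integers(1, 4, size=int(mutate.sum()))
        codes[mutate] = (codes[mutate] + shifts) % 4
        records.append((oid, "".join(_BASES[codes])))
    return records


def generate_abundance(cfg: SyntheticConfig, guild_assignment=None) -> AbundanceTable:
    """Guild-latent log-normal abundance table.

    Per sample s and guild g a latent abundance
    ``L_gs = base * exp(N(0, between_sample_log_sd))`` is drawn; each member
    OTU's count is ``round(L_gs * exp(N(0, within_guild_log_sd)))``.  Counts
    are non-negative integers; guild members share the latent factor and
    are therefore strongly rank-correlated across samples.
    """
    if guild_assignment is None:
        guild_assignment = cfg.guild_assignment()
    otu_ids = cfg.otu_ids()
    missing = [o for o in otu_ids if o not in guild_assignment]
    if missing:
        raise ValueError(f"guild_assignment misses OTUs: {missing[:3]}...")
    rng = np.random.default_rng(cfg.seed + 1)
    latent = _BASE_ABUNDANCE * np.exp(
        rng.normal(0.0, cfg.between_sample_log_sd, size=(cfg.n_guilds, cfg.n_samples))
    )
    guild_idx = np.array([guild_assignment[o] for o in otu_ids])
    noise = np.exp(
        rng.normal(0.0, cfg.within_guild_log_sd, size=(cfg.n_otus, cfg.n_samples))
    )
    counts = np.round(latent[guild_idx] * noise)
    sample_ids = [f"S{j + 1:03d}" for j in range(cfg.n_samples)]
    return AbundanceTable(otu_ids, sample_ids, counts)


def generate_labels(cfg: SyntheticConfig, guild_assignment=None) -> LabelMatrix:
    """Long-tailed, guild-assortative multihot labels.

    Class c (0-based) is assigned to a uniformly random subset of
    ``round(n_guilds * prevalence_scale * (c + 1) ** -alpha)`` guilds
    (clipped to [1, n_guilds]), so early classes cover most guilds
    (majority classes) while late classes cover a single guild each
    (minority classes).  Every OTU in a carrying guild gets the label;
    each cell is then flipped independently with probability
    ``label_noise``.
    """
    if cfg.n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if guild_assignment is None:
        guild_assignment = cfg.guild_assignment()
    otu_ids = cfg.otu_ids()
    rng = np.random.default_rng(cfg.seed + 2)
    guild_idx = np.array([guild_assignment[o] for o in otu_ids])
    coverage = np.clip(
        np.round(
            cfg.n_guilds
            * cfg.prevalence_scale
            * (np.arange(1, cfg.n_classes + 1) ** -cfg.class_prevalence_exponent)
        ).astype(int),
        1,
        cfg.n_guilds,
    )
    carrier = np.zeros((cfg.n_guilds, cfg.n_classes), dtype=np.int8)
    for c in range(cfg.n_classes):
        guilds = rng.choice(cfg.n_guilds, size=coverage[c], replace=False)
        carrier[guilds, c] = 1
    Y = carrier[guild_idx]
    flips = rng.random(Y.shape) < cfg.label_noise
    Y = np.where(flips, 1 - Y, Y)
    if Y.sum() == 0:
        raise ValueError("prevalence schedule produced an all-zero label matrix")
    ko_ids = [f"K{c + 1:05d}" for c in range(cfg.n_classes)]
    return LabelMatrix(otu_ids, ko_ids, Y)


def generate_community(cfg: SyntheticConfig) -> SyntheticCommunity:
    """Generate sequences, abundance and labels with one consistent layout."""
    guilds = cfg.guild_assignment()
    return SyntheticCommunity(
        sequences=generate_sequences(cfg),
        abundance=generate_abundance(cfg, guilds),
        labels=generate_labels(cfg, guilds),
        guild_assignment=guilds,
    )
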