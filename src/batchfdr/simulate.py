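"""Negative-binomial RNA-seq count simulator with known DE truth.

Generates batches (families) of two-group count matrices in the style of
standard NB read-count simulators: per-gene relative abundances and
dispersions are drawn from log-normal distributions, a fixed fraction pi
of genes is differentially expressed with a multiplicative fold change
applied to group 2 (half up-, half down-regulated by default), and counts
are drawn from a negative binomial with

    mean      m_ij = a_i * d_j * fold_ij
    variance  m_ij + phi_i * m_ij**2        (dispersion phi_i)

where d_j = seq_depth * Uniform(depth_factor_min, depth_factor_max) is the
per-sample sequencing depth.  Defaults follow a 5-vs-5 design with 10^7
reads, depth factors 0.9-1.1, fold change 1.5 and 50% upregulated genes.

Empirical simulators resample (mu, phi) pairs estimated from real
datasets; here parametric log-normal stand-ins are used instead (an
emulation, not a reproduction), with parameters exposed in
:class:`SimulationConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticCountMatrix",
    "simulate_batch",
    "derive_seed",
    "nb_counts",
]


def nb_counts(rng: np.random.Generator, mu, phi, size=None) -> np.ndarray:
    """Negative-binomial draws with mean mu and variance mu + phi*mu^2.

    Parameterized by shape n = 1/phi and success probability n/(n + mu);
    this is the mean/dispersion convention used throughout the simulator.
    """
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0):
        raise ValueError("dispersion phi must be positive")
    shape = 1.0 / phi
    return rng.negative_binomial(shape, shape / (shape + mu), size=size)


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for a stream of simulated families.

    Defaults mirror a 50-batch, 10,000-gene, 5-vs-5 study; scale down
    ``n_batches``/``genes_per_batch`` for quick experiments.
    """

    n_batches: int = 50
    genes_per_batch: int = 10_000
    replicates_per_group: int = 5
    pi_de: float = 0.1
    effect_size: float = 1.5
    seq_depth: float = 1e7
    depth_factor_min: float = 0.9
    depth_factor_max: float = 1.1
    prop_up: float = 0.5
    # log-normal stand-ins for empirically-resampled (abundance, dispersion)
    abundance_logmean: float | None = None  # None: log(1/genes_per_batch)
    abundance_logsd: float = 1.5
    dispersion_logmean: float = math.log(0.1)
    dispersion_logsd: float = 0.7
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi_de <= 1.0):
            raise ValueError("pi_de must be in [0, 1]")
        if self.effect_size <= 1.0:
            raise ValueError("effect_size must be > 1")
        if self.depth_factor_min > self.depth_factor_max:
            raise ValueError("depth_factor_min must be <= depth_factor_max")
        if min(self.n_batches, self.genes_per_batch, self.replicates_per_group) < 1:
            raise ValueError("batch, gene and replicate counts must be >= 1")
        if not (0.0 <= self.prop_up <= 1.0):
            raise ValueError("prop_up must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticCountMatrix:
    """One simulated family: counts plus per-gene ground truth."""

    counts: np.ndarray  # (genes, samples) non-negative ints
    group_labels: np.ndarray  # (samples,) of {1, 2}
    is_de: np.ndarray  # (genes,) bool
    direction: np.ndarray  # (genes,) of {+1, -1, 0}
    mu: np.ndarray  # (genes, samples) NB mean parameter
    phi: np.ndarray  # (genes,) dispersion
    batch_index: int

    @property
    def gene_ids(self) -> list[str]:
        return [f"b{self.batch_index}_g{i + 1}" for i in range(self.counts.shape[0])]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        """(counts, design, truth) DataFrames matching the on-disk TSV layout."""
        samples = [f"s{j + 1}" for j in range(self.counts.shape[1])]
        counts = pd.DataFrame(self.counts, index=self.gene_ids, columns=samples)
        counts.index.name = "gene_id"
        design = pd.DataFrame({"sample_id": samples, "group": self.group_labels})
        truth = pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "is_de": self.is_de,
                "direction": self.direction,
            }
        )
        return counts, design, truth


def derive_seed(master_seed: int, batch_index: int, replicate: int = 0) -> int:
    """Deterministic, collision-resistant seed for (master, batch, replicate).

    Uses numpy's SeedSequence keyed on the triple, so the same triple
    always yields the same stream and distinct triples yield independent
    streams; the result fits in 31 bits.
    """
    if min(master_seed, batch_index, replicate) < 0:
        raise ValueError("seed components must be non-negative")
    ss = np.random.SeedSequence([int(master_seed), int(batch_index), int(replicate)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def simulate_batch(
    config: SimulationConfig, batch_index: int, replicate: int = 0
) -> SyntheticCountMatrix:
    """Simulate one family (count matrix) with ground-truth DE labels.

    ``replicate`` separates independent simulation runs sharing a config;
    batches are mutually independent given distinct (batch, replicate)
    pairs and reproducible in any order.
    """
    if not (1 <= batch_index <= config.n_batches):
        raise ValueError(f"batch_index must be in [1, {config.n_batches}]")
    rng = np.random.default_rng(derive_seed(config.master_seed, batch_index, replicate))
    n = config.genes_per_batch
    n_rep = config.replicates_per_group
    n_samples = 2 * n_rep

    logmean = (
        config.abundance_logmean
        if config.abundance_logmean is not None
        else math.log(1.0 / n)
    )
    abundance = rng.lognormal(mean=logmean, sigma=config.abundance_logsd, size=n)
    abundance /= abundance.sum()
    phi = rng.lognormal(config.dispersion_logmean, config.dispersion_logsd, size=n)

    n_de = round(config.pi_de * n)
    n_up = round(config.prop_up * n_de)
    de_genes = rng.choice(n, size=n_de, replace=False)
    is_de = np.zeros(n, dtype=bool)
    is_de[de_genes] = True
    direction = np.zeros(n, dtype=int)
    direction[de_genes[:n_up]] = 1
    direction[de_genes[n_up:]] = -1

    depths = config.seq_depth * rng.uniform(
        config.depth_factor_min, config.depth_factor_max, size=n_samples
    )
    group_labels = np.repeat([1, 2], n_rep)

    fold = np.ones((n, n_samples))
    group2 = group_labels == 2
    fold[np.ix_(direction == 1, group2)] = config.effect_size
    fold[np.ix_(direction == -1, group2)] = 1.0 / config.effect_size

    mu = abundance[:, None] * depths[None, :] * fold
    counts = nb_counts(rng, mu, phi[:, None])

    return SyntheticCountMatrix(
        counts=counts.astype(np.int64),
        group_labels=group_labels,
        is_de=is_de,
        direction=direction,
        mu=mu,
        phi=phi,
        batch_index=batch_index,
    )
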