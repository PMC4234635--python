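"""Synthetic two-library count experiments with planted ground truth.

Emulates the data structure the exact test assumes: two mRNA tag libraries
sequenced to fixed depths, tens of thousands of genes, independent Poisson
count noise per gene per library, a planted fraction of genes whose
library-B abundance is shifted by a known log2 fold change, and a term
table in which chosen terms recruit their members preferentially from the
DE genes.  Everything is reproducible from a single integer seed.

The real libraries this mirrors ran to ~38-39 million tags over ~72k
assembled transcripts; the defaults here keep the same per-gene coverage
(depth / genes, roughly 200 tags per gene) at a scale where a full
simulate-test-enrich round trip takes seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import GeneCount, LibraryPair, TermAssignment

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate_pair", "simulate_terms"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic two-library experiment.

    ``expression_shape`` is the gamma shape of the baseline relative
    abundance profile (smaller = more skewed, 0.7 default resembles the
    long-tailed abundance of a real transcriptome); ``None`` gives every
    gene the same expected expression, the profile used for calibration
    studies.  ``planted_odds`` is the sampling weight of a DE gene over a
    non-DE gene when a planted term recruits members.
    """

    n_genes: int = 5000
    total_a: int = 1_000_000
    total_b: int = 1_000_000
    de_fraction: float = 0.05
    log2_fc_magnitude: float = 2.0
    length_range_bp: tuple[int, int] = (200, 3000)
    expression_shape: Optional[float] = 0.7
    n_terms: int = 50
    planted_terms: int = 2
    planted_odds: float = 10.0
    term_size_range: tuple[int, int] = (40, 160)
    overdispersion: float = 0.0
    length_weighted: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.total_a < 1 or self.total_b < 1:
            raise ValueError("n_genes and library totals must be positive")
        if not (0.0 <= self.de_fraction < 1.0):
            raise ValueError("de_fraction must lie in [0, 1)")
        if self.de_fraction > 0 and self.de_fraction * self.n_genes < 1:
            raise ValueError("de_fraction * n_genes must be >= 1 when de_fraction > 0")
        if self.log2_fc_magnitude <= 0:
            raise ValueError("log2_fc_magnitude must be positive")
        if self.expression_shape is not None and self.expression_shape <= 0:
            raise ValueError("expression_shape must be positive or None")
        lo, hi = self.length_range_bp
        if not (1 <= lo <= hi):
            raise ValueError("length_range_bp must be a non-degenerate positive interval")
        tlo, thi = self.term_size_range
        if not (1 <= tlo <= thi <= self.n_genes):
            raise ValueError("term_size_range must fit inside the gene set")
        if self.planted_terms > self.n_terms:
            raise ValueError("cannot plant more terms than n_terms")
        if self.planted_odds <= 0 or self.overdispersion < 0:
            raise ValueError("planted_odds must be > 0 and overdispersion >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one synthetic gene."""

    gene_id: str
    true_log2_fc: float
    is_de: bool
    planted_term_ids: tuple[str, ...] = field(default_factory=tuple)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent child streams from the one experiment seed
    return np.random.default_rng([config.seed, stream])


def simulate_pair(config: SimulationConfig) -> tuple[LibraryPair, list[SyntheticTruth]]:
    """Draw a two-library count table plus its per-gene ground truth.

    Baseline relative abundances come from a normalised gamma profile (or
    a flat profile when ``expression_shape`` is None).  A ``de_fraction``
    subset of genes, chosen uniformly, gets ``+/-log2_fc_magnitude``
    applied to its library-B abundance with equal sign probability; the B
    profile is deliberately NOT renormalised afterwards, so non-DE genes
    remain exactly null.  Counts are independent Poisson (or
    gamma-Poisson when ``overdispersion`` > 0) with mean = abundance x
    nominal depth, optionally weighted by gene length.
    """
    rng = _rng(config, 0)
    n = config.n_genes

    lengths = rng.integers(config.length_range_bp[0], config.length_range_bp[1] + 1, size=n)
    if config.expression_shape is None:
        abundance = np.full(n, 1.0)
    else:
        abundance = rng.gamma(config.expression_shape, 1.0, size=n)
        abundance = np.maximum(abundance, 1e-12)
    if config.length_weighted:
        abundance = abundance * lengths
    abundance = abundance / abundance.sum()

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    log2_fc = np.zeros(n)
    log2_fc[de_idx] = signs * config.log2_fc_magnitude

    mean_a = abundance * config.total_a
    mean_b = abundance * (2.0**log2_fc) * config.total_b
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        mean_a = mean_a * rng.gamma(shape, 1.0 / shape, size=n)
        mean_b = mean_b * rng.gamma(shape, 1.0 / shape, size=n)
    counts_a = rng.poisson(mean_a)
    counts_b = rng.poisson(mean_b)

    width = len(str(n - 1))
    genes = tuple(
        GeneCount(f"gene{i:0{width}d}", int(lengths[i]), int(counts_a[i]), int(counts_b[i]))
        for i in range(n)
    )
    truth = [
        SyntheticTruth(genes[i].gene_id, float(log2_fc[i]), bool(log2_fc[i] != 0.0))
        for i in range(n)
    ]
    return LibraryPair("A", "B", genes), truth


def simulate_terms(
    truth: list[SyntheticTruth], config: SimulationConfig, namespace: str = "GO"
) -> tuple[list[TermAssignment], list[str]]:
    """Draw a term table over the simulated genes; returns (assignments,
    planted term ids).

    Background terms sample members uniformly without replacement; each
    planted term samples with ``planted_odds``-fold weight on DE genes, so
    its expected DE share is odds*f / (odds*f + 1 - f) for DE fraction f.
    Term sizes are uniform over ``term_size_range``.
    """
    if not truth:
        raise ValueError("truth must be non-empty")
    rng = _rng(config, 1)
    gene_ids = np.array([t.gene_id for t in truth])
    is_de = np.array([t.is_de for t in truth])
    n = len(truth)

    width = len(str(max(config.n_terms - 1, 1)))
    term_ids = [f"{namespace}T{i:0{width}d}" for i in range(config.n_terms)]
    planted = list(rng.choice(term_ids, size=config.planted_terms, replace=False))

    weights = np.ones(n)
    weights[is_de] = config.planted_odds
    weights = weights / weights.sum()

    assignments: list[TermAssignment] = []
    for term_id in term_ids:
        size = int(rng.integers(config.term_size_range[0], config.term_size_range[1] + 1))
        if term_id in planted:
            members = rng.choice(gene_ids, size=size, replace=False, p=weights)
            name = "planted enriched term"
        else:
            members = rng.choice(gene_ids, size=size, replace=False)
            name = "background term"
        for gid in members:
            assignments.append(TermAssignment(str(gid), term_id, namespace, name))
    return assignments, sorted(planted)
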