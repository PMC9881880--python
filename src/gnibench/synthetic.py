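"""Synthetic RNA-seq counts with a planted regulatory network.

The generator emulates the situation the benchmark is built for: negative
binomially distributed counts (variance = mu + dispersion * mu^2, so larger
counts have larger variance), a hub-shaped ground-truth network (a few
regulators each driving many targets), uneven library sizes, log-normal
gene lengths, and an *incomplete* reference network obtained by dropping a
fraction of true edges and adding decoy pairs — mimicking a literature
interaction database that is far from complete.

Latent model: each hub h carries a standard-normal latent variable per
sample; each of its targets mixes that regulator with independent noise at
correlation ``signal`` (target = signal * hub + sqrt(1 - signal^2) * eps).
Latent values feed an exponential link to per-gene NB means, scaled so each
sample's expected total equals its sampled library size.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .data_io import GeneNetwork, canonical_edge

__all__ = ["SyntheticConfig", "generate_planted_dataset", "degrade_reference"]


@dataclass
class SyntheticConfig:
    """Study conditions for the planted-network fixture.

    Defaults are the desk-scale conditions the benchmark is validated
    under: 200 genes × 100 samples with 5 hubs of 10 targets at latent
    correlation 0.9, NB dispersion 0.05 (a typical bulk RNA-seq asymptotic
    dispersion), library sizes uniform in 0.5–2 million (scaled down from
    the tens of millions of real libraries purely in depth, not in shape),
    log-normal gene lengths around 1.5 kb, and a reference that keeps 60%
    of true edges plus 50 decoys.
    """

    n_genes: int = 200
    n_samples: int = 100
    n_hubs: int = 5
    targets_per_hub: int = 10
    signal: float = 0.9
    dispersion: float = 0.05
    lib_size_range: tuple[float, float] = (0.5e6, 2.0e6)
    length_log_mean: float = np.log(1500.0)
    length_log_sd: float = 0.6
    reference_coverage: float = 0.6
    reference_noise_edges: int = 50
    latent_scale: float = 0.7
    base_log_mean: float = np.log(50.0)
    base_log_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.signal < 1:
            raise ValueError("signal must be in [0, 1)")
        if not 0 <= self.reference_coverage <= 1:
            raise ValueError("reference_coverage must be in [0, 1]")
        if self.n_hubs * (self.targets_per_hub + 1) > self.n_genes:
            raise ValueError("hub topology needs n_hubs * (targets_per_hub + 1) <= n_genes")
        if self.n_hubs * self.targets_per_hub >= comb(self.n_genes, 2):
            raise ValueError("too many planted edges for the gene count")


def _gene_symbols(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{str(i).zfill(width)}" for i in range(n)]


def generate_planted_dataset(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.Series, GeneNetwork]:
    """Generate (counts, gene lengths, ground-truth network), seeded.

    Gene layout: the first ``n_hubs`` symbols are regulators, the next
    ``n_hubs * targets_per_hub`` their targets (in hub blocks), and the
    remainder independent background genes.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_symbols(cfg.n_genes)
    samples = [f"S{str(j).zfill(len(str(cfg.n_samples - 1)))}" for j in range(cfg.n_samples)]

    latent = rng.standard_normal((cfg.n_genes, cfg.n_samples))
    edges = []
    for h in range(cfg.n_hubs):
        hub_idx = h
        for t in range(cfg.targets_per_hub):
            tgt_idx = cfg.n_hubs + h * cfg.targets_per_hub + t
            noise = latent[tgt_idx]
            latent[tgt_idx] = cfg.signal * latent[hub_idx] + np.sqrt(1 - cfg.signal**2) * noise
            edges.append(canonical_edge(genes[hub_idx], genes[tgt_idx]))

    # exponential link: per-gene baseline abundance times exp(scale * latent)
    base = np.exp(rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=cfg.n_genes))
    mu = base[:, None] * np.exp(cfg.latent_scale * latent)
    lib = rng.uniform(*cfg.lib_size_range, size=cfg.n_samples)
    mu = mu * (lib / mu.sum(axis=0))

    if cfg.dispersion > 0:
        n_param = 1.0 / cfg.dispersion
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)
    else:
        counts = rng.poisson(mu)

    lengths = pd.Series(
        np.round(np.exp(rng.normal(cfg.length_log_mean, cfg.length_log_sd, size=cfg.n_genes))).astype(int),
        index=genes,
    ).clip(lower=100)
    counts_df = pd.DataFrame(counts.astype(np.int64), index=genes, columns=samples)
    truth = GeneNetwork(edges=frozenset(edges))
    return counts_df, lengths, truth


def degrade_reference(truth: GeneNetwork, cfg: SyntheticConfig) -> GeneNetwork:
    """Build an incomplete reference: keep a coverage fraction, add decoys.

    A seeded ``reference_coverage`` fraction (rounded to the nearest count)
    of true edges is kept and ``reference_noise_edges`` decoy pairs not in
    the truth are added among the same genes.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    true_edges = sorted(truth.edges)
    n_keep = int(round(cfg.reference_coverage * len(true_edges)))
    keep_idx = rng.choice(len(true_edges), size=n_keep, replace=False) if true_edges else []
    kept = {true_edges[i] for i in keep_idx}

    genes = _gene_symbols(cfg.n_genes)
    available = comb(cfg.n_genes, 2) - len(true_edges)
    if cfg.reference_noise_edges > available:
        raise ValueError(f"cannot add {cfg.reference_noise_edges} decoys; only {available} non-true pairs")
    decoys: set[tuple[str, str]] = set()
    while len(decoys) < cfg.reference_noise_edges:
        i, j = rng.integers(0, cfg.n_genes, size=2)
        if i == j:
            continue
        e = canonical_edge(genes[int(i)], genes[int(j)])
        if e not in truth.edges and e not in decoys:
            decoys.add(e)
    return GeneNetwork(edges=frozenset(kept | decoys))
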