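"""Literature-overlap evaluation: precision, overlap tests, random baselines.

Because a literature reference network is incomplete, only the positive
cases are trusted: a predicted edge present in the reference is a true
positive, one absent is a false positive, and precision = TP / (TP + FP) is
the headline metric — recall/F1 over unknown negatives are deliberately not
reported by default. Overlap significance comes from the upper-tail
hypergeometric test (or Fisher's exact test) over the universe of candidate
gene pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from math import comb

import numpy as np
from scipy import stats

from .data_io import GeneNetwork, canonical_edge

__all__ = [
    "Universe",
    "PerformanceRecord",
    "overlap",
    "precision",
    "hypergeom_overlap_test",
    "fisher_overlap_test",
    "random_network",
    "random_baseline",
    "evaluate_network",
]


@dataclass
class Universe:
    """The gene pairs eligible for prediction and the reference edges among them."""

    genes: frozenset[str]
    reference_in_universe: frozenset[tuple[str, str]]

    @classmethod
    def from_genes(cls, genes, ref: GeneNetwork) -> "Universe":
        gs = frozenset(genes)
        in_univ = frozenset(e for e in ref.edges if e[0] in gs and e[1] in gs)
        return cls(genes=gs, reference_in_universe=in_univ)

    @property
    def n_pairs(self) -> int:
        return comb(len(self.genes), 2)


@dataclass
class PerformanceRecord:
    """One combination's precision and overlap statistics."""

    combination: str
    gni: str
    dataset: str
    precision: float
    tp: int
    predicted: int
    p_value: float
    test: str = "hypergeometric"

    def as_dict(self) -> dict:
        return asdict(self)


def overlap(pred: GeneNetwork, ref: GeneNetwork) -> int:
    """Number of predicted edges present in the reference (orientation-free)."""
    return len(pred.edges & ref.edges)


def precision(pred: GeneNetwork, ref: GeneNetwork) -> float:
    """TP / (TP + FP); undefined (raises) for an empty prediction."""
    if len(pred) == 0:
        raise ValueError("precision is undefined for an empty predicted network")
    return overlap(pred, ref) / len(pred)


def _check_universe(pred: GeneNetwork, universe: Universe) -> None:
    stray = [e for e in pred.edges if e[0] not in universe.genes or e[1] not in universe.genes]
    if stray:
        raise ValueError(f"predicted edges outside the universe, e.g. {stray[0]}")


def hypergeom_overlap_test(pred: GeneNetwork, ref: GeneNetwork, universe: Universe) -> float:
    """Upper-tail hypergeometric probability of at least the achieved overlap.

    Drawing |pred| pairs without replacement from the universe's C(n, 2)
    pairs, of which |reference ∩ universe| are successes.
    """
    _check_universe(pred, universe)
    tp = len(pred.edges & universe.reference_in_universe)
    n_ref = len(universe.reference_in_universe)
    n_pairs = universe.n_pairs
    n_pred = len(pred)
    if tp > min(n_pred, n_ref):
        raise ValueError("overlap exceeds the smaller of prediction and reference")
    return float(stats.hypergeom.sf(tp - 1, n_pairs, n_ref, n_pred))


def fisher_overlap_test(pred: GeneNetwork, ref: GeneNetwork, universe: Universe) -> float:
    """One-sided Fisher's exact test on the pred × ref 2×2 table over universe pairs."""
    _check_universe(pred, universe)
    tp = len(pred.edges & universe.reference_in_universe)
    n_ref = len(universe.reference_in_universe)
    n_pairs = universe.n_pairs
    n_pred = len(pred)
    table = [
        [tp, n_pred - tp],
        [n_ref - tp, n_pairs - n_pred - n_ref + tp],
    ]
    if min(min(row) for row in table) < 0:
        raise ValueError("inconsistent overlap counts for the 2x2 table")
    return float(stats.fisher_exact(table, alternative="greater")[1])


def random_network(genes, n_edges: int, seed: int) -> GeneNetwork:
    """Uniform sample of ``n_edges`` distinct unordered gene pairs, seeded."""
    genes = sorted(set(genes))
    n = len(genes)
    n_pairs = comb(n, 2)
    if n_edges > n_pairs:
        raise ValueError(f"requested {n_edges} edges but only {n_pairs} pairs exist")
    rng = np.random.default_rng(seed)
    if n_pairs <= 2_000_000:
        chosen = rng.choice(n_pairs, size=n_edges, replace=False)
        edges = {_pair_from_index(int(c), n, genes) for c in chosen}
    else:
        # rejection sampling for very large universes
        edges = set()
        while len(edges) < n_edges:
            i, j = rng.integers(0, n, size=2)
            if i != j:
                edges.add(canonical_edge(genes[int(i)], genes[int(j)]))
    return GeneNetwork(edges=frozenset(edges))


def _pair_from_index(idx: int, n: int, genes: list[str]) -> tuple[str, str]:
    """Map a linear index in [0, C(n,2)) to the idx-th pair (i < j)."""
    # row i starts at offset i*n - i*(i+1)/2 - i ... solve by scanning rows
    i = int(n - 2 - np.floor(np.sqrt(-8 * idx + 4 * n * (n - 1) - 7) / 2.0 - 0.5))
    j = int(idx + i + 1 - i * n + i * (i + 1) // 2)
    return canonical_edge(genes[i], genes[j])


def random_baseline(
    genes,
    n_edges: int,
    ref: GeneNetwork,
    universe: Universe,
    n_networks: int = 10,
    seed: int = 0,
) -> tuple[float, list[float], list[float]]:
    """Mean precision and per-network overlap p-values of seeded random networks.

    Returns (mean precision, per-network precisions, per-network
    hypergeometric p-values). The expected mean precision is the analytic
    ratio |reference ∩ universe| / C(|genes|, 2).
    """
    precisions = []
    p_values = []
    for i in range(n_networks):
        net = random_network(genes, n_edges, seed=seed + i)
        precisions.append(overlap(net, ref) / n_edges if n_edges else 0.0)
        p_values.append(hypergeom_overlap_test(net, ref, universe))
    return float(np.mean(precisions)), precisions, p_values


def evaluate_network(
    pred: GeneNetwork,
    ref: GeneNetwork,
    universe: Universe,
    combination: str = "",
    gni: str = "",
    dataset: str = "",
    test: str = "hypergeometric",
) -> PerformanceRecord:
    """Bundle precision and overlap test into one record."""
    tp = overlap(pred, ref)
    if test == "hypergeometric":
        p = hypergeom_overlap_test(pred, ref, universe)
    elif test == "fisher":
        p = fisher_overlap_test(pred, ref, universe)
    else:
        raise ValueError(f"unknown overlap test: {test}")
    return PerformanceRecord(
        combination=combination,
        gni=gni,
        dataset=dataset,
        precision=tp / len(pred) if len(pred) else float("nan"),
        tp=tp,
        predicted=len(pred),
        p_value=p,
        test=test,
    )
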