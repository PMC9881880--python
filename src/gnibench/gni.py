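"""Network inference from a symmetric association matrix.

Three algorithms: RELNET keeps every pair above a significance threshold;
C3NET keeps, per gene, only its single strongest above-threshold partner;
ARACNE starts from RELNET and prunes, in every triangle, the strictly
weakest edge (data processing inequality, tolerance eps, default 0).
At equal threshold the outputs nest: c3net ⊆ aracne(eps=0) ⊆ relnet.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .association import AssociationMatrix, EstimatorConfig, association_matrix
from .data_io import GeneNetwork, canonical_edge

__all__ = [
    "GniAlgorithm",
    "GniConfig",
    "significance_threshold",
    "relnet",
    "c3net",
    "aracne",
    "infer_network",
]


class GniAlgorithm(str, Enum):
    RELNET = "relnet"
    C3NET = "c3net"
    ARACNE = "aracne"


class ThresholdMode(str, Enum):
    PERMUTATION = "permutation"
    TOP_K = "top_k"
    ABSOLUTE = "absolute"


@dataclass
class GniConfig:
    algorithm: GniAlgorithm = GniAlgorithm.C3NET
    threshold_mode: ThresholdMode = ThresholdMode.PERMUTATION
    alpha: float = 0.01
    n_permutations: int = 1000
    k: int | None = None
    absolute_threshold: float | None = None
    dpi_eps: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.algorithm = GniAlgorithm(self.algorithm)
        self.threshold_mode = ThresholdMode(self.threshold_mode)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.dpi_eps < 0:
            raise ValueError("dpi_eps must be >= 0")


def _offdiag(scores: pd.DataFrame) -> np.ndarray:
    a = scores.to_numpy()
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]


def significance_threshold(
    A: AssociationMatrix,
    m: pd.DataFrame | None,
    cfg: GniConfig,
    estimator_cfg: EstimatorConfig | None = None,
) -> float:
    """Choose the association-score cutoff.

    * ``permutation``: each gene's samples are independently shuffled
      (seeded), the association matrix recomputed per permutation, and the
      threshold is the (1 - alpha) quantile of the pooled null off-diagonal
      scores. Requires the expression matrix ``m`` and the estimator config.
    * ``top_k``: the k-th largest off-diagonal score.
    * ``absolute``: a user-supplied value.
    """
    if cfg.threshold_mode is ThresholdMode.ABSOLUTE:
        if cfg.absolute_threshold is None:
            raise ValueError("absolute threshold mode requires a value")
        return float(cfg.absolute_threshold)
    if cfg.threshold_mode is ThresholdMode.TOP_K:
        pairs = _offdiag(A.scores)
        if cfg.k is None or not 1 <= cfg.k <= len(pairs):
            raise ValueError(f"top_k mode requires 1 <= k <= {len(pairs)}")
        return float(np.sort(pairs)[-cfg.k])
    if m is None or estimator_cfg is None:
        raise ValueError("permutation mode requires the expression matrix and estimator config")
    rng = np.random.default_rng(cfg.seed)
    null_scores = []
    for _ in range(cfg.n_permutations):
        shuffled = m.to_numpy(dtype=float).copy()
        for i in range(shuffled.shape[0]):
            rng.shuffle(shuffled[i])
        perm = pd.DataFrame(shuffled, index=m.index, columns=m.columns)
        null_scores.append(_offdiag(association_matrix(perm, estimator_cfg).scores))
    pooled = np.concatenate(null_scores)
    return float(np.quantile(pooled, 1.0 - cfg.alpha))


def _edges_from_mask(scores: pd.DataFrame, mask: np.ndarray, signs: pd.DataFrame | None) -> GeneNetwork:
    genes = list(scores.index)
    vals = scores.to_numpy()
    ii, jj = np.nonzero(np.triu(mask, k=1))
    edges = set()
    weights = {}
    sgn = {}
    for i, j in zip(ii, jj):
        e = canonical_edge(genes[i], genes[j])
        edges.add(e)
        weights[e] = float(vals[i, j])
        if signs is not None:
            sgn[e] = int(signs.iat[i, j])
    return GeneNetwork(edges=frozenset(edges), weights=weights, signs=sgn)


def relnet(A: AssociationMatrix, threshold: float) -> GeneNetwork:
    """Relevance network: every pair with score >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    vals = A.scores.to_numpy().copy()
    np.fill_diagonal(vals, -np.inf)
    mask = vals >= threshold
    return _edges_from_mask(A.scores, mask, A.signs)


def c3net(A: AssociationMatrix, threshold: float) -> GeneNetwork:
    """Conservative network: each gene contributes its single maximal significant edge.

    Sub-threshold scores are zeroed out; each gene with any surviving score
    adds the edge to its highest-scoring partner (ties broken toward the
    lexicographically smallest partner symbol); the union over genes is the
    network.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    genes = list(A.scores.index)
    vals = A.scores.to_numpy().copy()
    np.fill_diagonal(vals, -np.inf)
    surviving = np.where(vals >= threshold, vals, -np.inf)
    # lexicographic tie-break: scan partners in symbol order
    symbol_order = np.argsort(np.array(genes, dtype=object))
    mask = np.zeros_like(surviving, dtype=bool)
    for i in range(len(genes)):
        row = surviving[i]
        best = row.max()
        if not np.isfinite(best):
            continue
        candidates = symbol_order[np.isfinite(row[symbol_order]) & (row[symbol_order] == best)]
        j = int(candidates[0])
        mask[i, j] = mask[j, i] = True
    return _edges_from_mask(A.scores, mask, A.signs)


def aracne(A: AssociationMatrix, threshold: float, dpi_eps: float = 0.0) -> GeneNetwork:
    """ARACNE: relevance network pruned by the data processing inequality.

    Edge (i, j) is removed iff some gene k forms a triangle with both (i, k)
    and (j, k) present and score_ij < min(score_ik, score_jk) - eps. All
    removal decisions are evaluated against the pre-pruning edge set, so the
    result is order-independent.
    """
    if dpi_eps < 0:
        raise ValueError("dpi_eps must be >= 0")
    vals = A.scores.to_numpy().copy()
    np.fill_diagonal(vals, -np.inf)
    adj = vals >= threshold
    n = adj.shape[0]
    remove = np.zeros_like(adj)
    w = np.where(adj, vals, -np.inf)
    for k in range(n):
        nbrs = np.nonzero(adj[k])[0]
        if len(nbrs) < 2:
            continue
        wk = w[k, nbrs]
        # pairwise min(score_ik, score_jk) for neighbors of k
        pair_min = np.minimum.outer(wk, wk)
        sub = w[np.ix_(nbrs, nbrs)]
        weak = adj[np.ix_(nbrs, nbrs)] & (sub < pair_min - dpi_eps)
        remove[np.ix_(nbrs, nbrs)] |= weak
    mask = adj & ~remove & ~remove.T
    return _edges_from_mask(A.scores, mask, A.signs)


def infer_network(
    A: AssociationMatrix,
    cfg: GniConfig,
    m: pd.DataFrame | None = None,
    estimator_cfg: EstimatorConfig | None = None,
) -> GeneNetwork:
    """Threshold selection + algorithm dispatch in one call."""
    threshold = significance_threshold(A, m, cfg, estimator_cfg)
    if cfg.algorithm is GniAlgorithm.RELNET:
        return relnet(A, threshold)
    if cfg.algorithm is GniAlgorithm.C3NET:
        return c3net(A, threshold)
    if cfg.algorithm is GniAlgorithm.ARACNE:
        return aracne(A, threshold, cfg.dpi_eps)
    raise ValueError(f"unknown GNI algorithm: {cfg.algorithm}")  # pragma: no cover
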