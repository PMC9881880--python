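"""Copula transform and pairwise association estimators.

Five estimators produce a symmetric gene × gene score matrix: Pearson (PCC)
and Spearman (SCC) correlation (stored as |r| with the sign kept
separately), the Pearson-based Gaussian mutual information
PBG = -0.5 ln(1 - r^2), the B-spline fuzzy-histogram mutual-information
estimator, and the Chao-Shen coverage-adjusted entropy MI estimator. All
mutual information is in nats; negative MI estimates are clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

__all__ = [
    "Estimator",
    "EstimatorConfig",
    "AssociationMatrix",
    "copula_transform",
    "pcc_matrix",
    "scc_matrix",
    "pbg_matrix",
    "bspline_mi",
    "chao_shen_mi",
    "association_matrix",
]


class Estimator(str, Enum):
    PCC = "PCC"
    SCC = "SCC"
    PBG = "PBG"
    BSPLINE = "bspline"
    CS = "CS"


@dataclass
class EstimatorConfig:
    """Estimator choice plus discretization settings for the MI estimators.

    ``bins`` is the number of B-spline basis functions / hard bins;
    ``spline_order`` the B-spline order k (k = 2 → piecewise linear,
    k = 1 → hard equal-width binning). ``clamp_negative`` zeroes small
    negative plug-in MI estimates.
    """

    estimator: Estimator = Estimator.PCC
    bins: int = 10
    spline_order: int = 2
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        self.estimator = Estimator(self.estimator)
        if self.spline_order < 1:
            raise ValueError("spline_order must be >= 1")
        if self.bins < self.spline_order:
            raise ValueError("bins must be >= spline_order")


@dataclass
class AssociationMatrix:
    """Symmetric gene × gene association scores; diagonal fixed at 0."""

    scores: pd.DataFrame
    signs: pd.DataFrame | None = None

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.scores.index)

    def pair_score(self, a: str, b: str) -> float:
        return float(self.scores.at[a, b])


def copula_transform(m: pd.DataFrame) -> pd.DataFrame:
    """Replace each gene's values by average ranks scaled by 1/(n_samples + 1).

    Output lies strictly inside (0, 1); ties share the mean rank.
    """
    if m.shape[1] < 2:
        raise ValueError("copula transform requires at least 2 samples")
    ranks = stats.rankdata(m.to_numpy(dtype=float), axis=1, method="average")
    return pd.DataFrame(ranks / (m.shape[1] + 1), index=m.index, columns=m.columns)


def _corr_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation with constant rows mapped to r = 0."""
    sd = x.std(axis=1)
    const = sd == 0
    xc = x - x.mean(axis=1, keepdims=True)
    denom = np.where(const, 1.0, sd * x.shape[1])
    xn = xc / denom[:, None]
    r = xn @ xn.T * x.shape[1]
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def pcc_matrix(m: pd.DataFrame) -> AssociationMatrix:
    """Pairwise Pearson correlations; score = |r|, sign kept separately."""
    r = _corr_rows(m.to_numpy(dtype=float))
    np.fill_diagonal(r, 0.0)
    scores = pd.DataFrame(np.abs(r), index=m.index, columns=m.index)
    signs = pd.DataFrame(np.sign(r).astype(int), index=m.index, columns=m.index)
    return AssociationMatrix(scores=scores, signs=signs)


def scc_matrix(m: pd.DataFrame) -> AssociationMatrix:
    """Pairwise Spearman correlations (Pearson on per-row average ranks)."""
    ranks = stats.rankdata(m.to_numpy(dtype=float), axis=1, method="average")
    r = _corr_rows(ranks)
    np.fill_diagonal(r, 0.0)
    scores = pd.DataFrame(np.abs(r), index=m.index, columns=m.index)
    signs = pd.DataFrame(np.sign(r).astype(int), index=m.index, columns=m.index)
    return AssociationMatrix(scores=scores, signs=signs)


def pbg_score(r: float | np.ndarray) -> float | np.ndarray:
    """Gaussian mutual information -0.5 ln(1 - r^2) in nats."""
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    return -0.5 * np.log1p(-(r**2))


def pbg_matrix(m: pd.DataFrame) -> AssociationMatrix:
    """Pearson-based Gaussian MI: -0.5 ln(1 - r^2), strictly increasing in |r|."""
    r = _corr_rows(m.to_numpy(dtype=float))
    np.fill_diagonal(r, 0.0)
    scores = pd.DataFrame(pbg_score(r), index=m.index, columns=m.index)
    np.fill_diagonal(scores.values, 0.0)
    return AssociationMatrix(scores=scores)


def _bspline_weights(x: np.ndarray, bins: int, order: int) -> np.ndarray:
    """Fractional bin memberships (n × bins), rows summing to 1.

    Values are affinely mapped to the spline domain [0, bins - order + 1]
    and evaluated against the open-uniform B-spline basis of the given
    order; a constant vector gets full membership in bin 0.
    """
    n = len(x)
    lo, hi = x.min(), x.max()
    if hi == lo:
        w = np.zeros((n, bins))
        w[:, 0] = 1.0
        return w
    top = bins - order + 1
    z = (x - lo) / (hi - lo) * top
    degree = order - 1
    # open-uniform knot vector: order-fold end knots, unit-spaced interior
    t = np.concatenate([
        np.zeros(degree + 1),
        np.arange(1, top),
        np.full(degree + 1, float(top)),
    ])
    dm = BSpline.design_matrix(z, t, degree, extrapolate=False).toarray()
    return dm


def _plugin_mi(joint: np.ndarray) -> float:
    """Plug-in mutual information (nats) from a joint probability table."""
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def bspline_mi(
    x: np.ndarray, y: np.ndarray, cfg: EstimatorConfig | None = None
) -> float:
    """B-spline mutual information between two sample vectors.

    Each observation is spread fractionally over ``cfg.bins`` bins via the
    B-spline basis of order ``cfg.spline_order``; MI is the plug-in value of
    the weighted joint histogram, in nats. Order 1 is hard equal-width
    binning. Constant vectors score 0.
    """
    cfg = cfg or EstimatorConfig(estimator=Estimator.BSPLINE)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    if len(x) < cfg.bins:
        raise ValueError(f"need at least {cfg.bins} observations for {cfg.bins} bins")
    if x.min() == x.max() or y.min() == y.max():
        return 0.0
    wx = _bspline_weights(x, cfg.bins, cfg.spline_order)
    wy = _bspline_weights(y, cfg.bins, cfg.spline_order)
    joint = wx.T @ wy / len(x)
    mi = _plugin_mi(joint)
    return max(mi, 0.0) if cfg.clamp_negative else mi


def _hard_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width bin index per observation (last bin closed on the right)."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(len(x), dtype=int)
    idx = np.floor((x - lo) / (hi - lo) * bins).astype(int)
    return np.minimum(idx, bins - 1)


def chao_shen_entropy(counts: np.ndarray) -> float:
    """Coverage-adjusted (Horvitz–Thompson) entropy in nats from cell counts."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n <= 0 or len(counts) == 1:
        return 0.0
    f1 = np.sum(counts == 1)
    coverage = 1.0 - f1 / n
    if coverage <= 0:
        # every observation is a singleton; fall back to full coverage
        coverage = 1.0
    p = coverage * counts / n
    inclusion = 1.0 - (1.0 - p) ** n
    return float(np.sum(-p * np.log(p) / inclusion))


def chao_shen_mi(
    x: np.ndarray, y: np.ndarray, cfg: EstimatorConfig | None = None
) -> float:
    """Chao-Shen mutual information from hard equal-width discretization.

    MI = H(X) + H(Y) - H(X, Y) with each entropy coverage-adjusted; clamped
    at zero (the three adjustments need not be jointly consistent).
    """
    cfg = cfg or EstimatorConfig(estimator=Estimator.CS)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    if x.min() == x.max() or y.min() == y.max():
        return 0.0
    bx = _hard_bins(x, cfg.bins)
    by = _hard_bins(y, cfg.bins)
    hx = chao_shen_entropy(np.bincount(bx, minlength=cfg.bins))
    hy = chao_shen_entropy(np.bincount(by, minlength=cfg.bins))
    hxy = chao_shen_entropy(np.bincount(bx * cfg.bins + by, minlength=cfg.bins**2))
    mi = hx + hy - hxy
    return max(mi, 0.0) if cfg.clamp_negative else mi


def _mi_matrix(m: pd.DataFrame, cfg: EstimatorConfig, weight_fn) -> pd.DataFrame:
    """Shared pairwise loop for the two histogram MI estimators."""
    n_genes, n = m.shape
    vals = m.to_numpy(dtype=float)
    scores = np.zeros((n_genes, n_genes))
    if cfg.estimator is Estimator.BSPLINE:
        weights = np.stack([_bspline_weights(vals[i], cfg.bins, cfg.spline_order) for i in range(n_genes)])
        for i in range(n_genes):
            if vals[i].min() == vals[i].max():
                continue
            # batched joint histograms of gene i against all later genes
            joints = np.einsum("nb,jnc->jbc", weights[i], weights[i + 1:]) / n
            for off, joint in enumerate(joints):
                j = i + 1 + off
                if vals[j].min() == vals[j].max():
                    continue
                mi = _plugin_mi(joint)
                scores[i, j] = scores[j, i] = max(mi, 0.0) if cfg.clamp_negative else mi
    else:
        for i in range(n_genes):
            for j in range(i + 1, n_genes):
                scores[i, j] = scores[j, i] = weight_fn(vals[i], vals[j], cfg)
    return pd.DataFrame(scores, index=m.index, columns=m.index)


def association_matrix(m: pd.DataFrame, cfg: EstimatorConfig) -> AssociationMatrix:
    """Full symmetric association matrix for the configured estimator."""
    if m.shape[0] < 3:
        raise ValueError("association_matrix needs at least 3 genes")
    est = cfg.estimator
    if est is Estimator.PCC:
        return pcc_matrix(m)
    if est is Estimator.SCC:
        return scc_matrix(m)
    if est is Estimator.PBG:
        return pbg_matrix(m)
    if est is Estimator.BSPLINE:
        return AssociationMatrix(scores=_mi_matrix(m, cfg, None))
    if est is Estimator.CS:
        return AssociationMatrix(scores=_mi_matrix(m, cfg, chao_shen_mi))
    raise ValueError(f"unknown estimator: {est}")  # pragma: no cover
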