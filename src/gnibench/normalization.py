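"""Library-size and distribution normalizations: TMM, RLE, VST, quantile.

TMM and RLE produce per-sample scaling factors (standardized to product 1)
that are estimated from raw counts and applied column-wise to whatever
expression matrix the pipeline is carrying. VST fits a parametric
negative-binomial dispersion trend on counts and applies the closed-form
monotone variance-stabilizing map. Quantile normalization forces identical
per-sample value distributions by averaging order statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationMethod",
    "NormalizationFactors",
    "VSTFit",
    "tmm_factors",
    "rle_factors",
    "apply_factors",
    "vst_fit",
    "vst_apply",
    "quantile_normalize",
    "apply_normalization",
]


class NormalizationMethod(str, Enum):
    TMM = "TMM"
    RLE = "RLE"
    VST = "VST"
    QN = "QN"
    NONORM = "NoNorm"


@dataclass
class NormalizationFactors:
    """Per-sample scaling factors, standardized so their product is 1."""

    factors: pd.Series
    library_sizes: pd.Series

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")


@dataclass
class VSTFit:
    """Parametric NB dispersion trend alpha(mu) = a0 + a1 / mu.

    ``a0`` is the asymptotic dispersion at large mean; ``a1`` captures the
    extra-Poisson variance at small means. ``size_factors`` are the RLE
    factors the counts were normalized with before fitting. ``fallback``
    marks degenerate fits where log2(x + 1) replaces the closed form.
    """

    a0: float
    a1: float
    size_factors: pd.Series
    fallback: bool = False


def _standardize(f: pd.Series) -> pd.Series:
    """Rescale factors so their geometric mean (hence product) is 1."""
    return f / np.exp(np.log(f).mean())


def tmm_factors(m: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05) -> NormalizationFactors:
    """Trimmed mean of M-values scaling factors.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those across samples. For every other sample, the
    per-gene log2 ratio M and average abundance A (both library-size
    adjusted, over genes expressed in both samples) are doubly trimmed
    (``trim_m`` of the M extremes, ``trim_a`` of the A extremes on each
    side) and the factor is 2 to the inverse-variance-weighted mean of the
    surviving M values. Factors are standardized to product 1.
    """
    if m.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    counts = m.to_numpy(dtype=float)
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("zero library size")
    q75 = np.array([np.quantile(counts[:, j][counts[:, j] > 0], 0.75) for j in range(m.shape[1])])
    frac = q75 / libsize
    ref = int(np.argmin(np.abs(frac - frac.mean())))
    f = np.ones(m.shape[1])
    for j in range(m.shape[1]):
        if j == ref:
            continue
        f[j] = _tmm_pair_factor(counts[:, j], counts[:, ref], libsize[j], libsize[ref], trim_m, trim_a)
    series = _standardize(pd.Series(f, index=m.columns))
    return NormalizationFactors(factors=series, library_sizes=pd.Series(libsize, index=m.columns))


def _tmm_pair_factor(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float, trim_m: float, trim_a: float
) -> float:
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValueError("sample shares no expressed genes with the TMM reference")
    o, r = obs[both], ref[both]
    p_o, p_r = o / n_obs, r / n_ref
    M = np.log2(p_o / p_r)
    A = 0.5 * np.log2(p_o * p_r)
    # asymptotic (delta-method) variance of M; weight is its inverse
    var = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    # double trim: drop the trim fraction of extremes on each side, by rank
    n = len(M)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = stats.rankdata(M, method="average")
    rank_a = stats.rankdata(A, method="average")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or var[keep].min() <= 0:
        return 1.0
    w = 1.0 / var[keep]
    logf = np.sum(w * M[keep]) / np.sum(w)
    if not np.isfinite(logf):
        return 1.0
    return float(2.0 ** logf)


def rle_factors(m: pd.DataFrame) -> NormalizationFactors:
    """Relative log expression (median-of-ratios) factors, product-1 standardized.

    The pseudo-reference is the per-gene geometric mean over samples, using
    only genes with nonzero counts in every sample; each sample's raw factor
    is the median ratio of its counts to that reference.
    """
    counts = m.to_numpy(dtype=float)
    libsize = counts.sum(axis=0)
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("RLE requires at least one gene with nonzero counts in all samples")
    sub = counts[allpos]
    georef = np.exp(np.log(sub).mean(axis=1))
    f = np.median(sub / georef[:, None], axis=0)
    series = _standardize(pd.Series(f, index=m.columns))
    return NormalizationFactors(factors=series, library_sizes=pd.Series(libsize, index=m.columns))


def apply_factors(m: pd.DataFrame, nf: NormalizationFactors) -> pd.DataFrame:
    """Rescale column j by 1/f_j, as if library sizes were the effective ones."""
    if list(m.columns) != list(nf.factors.index):
        raise ValueError("factor index does not match matrix columns")
    return m / nf.factors


def vst_fit(m: pd.DataFrame, min_disp_genes: int = 10) -> VSTFit:
    """Fit the parametric dispersion trend alpha(mu) = a0 + a1/mu on counts.

    Per-gene means and method-of-moments dispersions are computed on
    RLE-size-factor-normalized counts; the trend is fit by iteratively
    reweighted least squares on (1/mu, alpha) with two rounds of outlier
    down-weighting. With fewer than ``min_disp_genes`` positive-dispersion
    genes the fit falls back to a log2(x + 1) transform.
    """
    if m.shape[0] < 10 or m.shape[1] < 3:
        raise ValueError("VST fit needs at least 10 genes and 3 samples")
    sf = rle_factors(m).factors
    norm = (m / sf).to_numpy(dtype=float)
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu > 0, np.maximum(0.0, (var - mu) / mu**2), 0.0)
    ok = (alpha > 0) & (mu > 0)
    if ok.sum() < min_disp_genes:
        logger.warning("vst_fit: only %d positive-dispersion genes; falling back to log2(x+1)", ok.sum())
        return VSTFit(a0=np.nan, a1=np.nan, size_factors=sf, fallback=True)
    x = 1.0 / mu[ok]
    y = alpha[ok]
    X = np.column_stack([np.ones_like(x), x])
    w = np.ones_like(y)
    coef = np.array([np.median(y), 0.0])
    for _ in range(3):  # initial fit + 2 reweighting rounds
        W = w[:, None]
        coef, *_ = np.linalg.lstsq(X * W, y * w, rcond=None)
        resid = np.abs(y - X @ coef)
        scale = np.median(resid) + 1e-12
        w = 1.0 / (1.0 + (resid / (3.0 * scale)) ** 2)
    a0 = float(max(coef[0], 1e-8))
    a1 = float(max(coef[1], 0.0))
    return VSTFit(a0=a0, a1=a1, size_factors=sf)


def vst_transform_values(x: np.ndarray, fit: VSTFit) -> np.ndarray:
    """Closed-form monotone VST for the NB trend; approaches log2(x) for large x."""
    if fit.fallback:
        return np.log2(x + 1.0)
    a0, a1 = fit.a0, fit.a1
    return np.log2(
        (1 + a1 + 2 * a0 * x + 2 * np.sqrt(a0 * x * (1 + a1 + a0 * x))) / (4 * a0)
    )


def vst_apply(m: pd.DataFrame, fit: VSTFit) -> pd.DataFrame:
    """Apply the fitted VST to size-factor-normalized counts."""
    norm = (m / fit.size_factors).to_numpy(dtype=float)
    return pd.DataFrame(vst_transform_values(norm, fit), index=m.index, columns=m.columns)


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force identical per-sample distributions via mean order statistics.

    Every column's values are replaced by the across-column mean of the
    sorted values at each rank; ties within a column receive the mean of
    the values their tied ranks imply.
    """
    if m.shape[1] < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    vals = m.to_numpy(dtype=float)
    order_means = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        # average ranks (1-based); fractional ranks from ties are mapped to
        # the mean of the implied order statistics
        ranks = stats.rankdata(vals[:, j], method="average")
        idx = ranks - 1.0
        lo = np.floor(idx).astype(int)
        hi = np.ceil(idx).astype(int)
        out[:, j] = 0.5 * (order_means[lo] + order_means[hi])
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def apply_normalization(
    m: pd.DataFrame,
    counts: pd.DataFrame,
    method: NormalizationMethod | str,
) -> pd.DataFrame:
    """Apply one normalization to expression matrix ``m``.

    ``counts`` is the pre-transform (pseudocounted) count matrix: TMM/RLE
    factors and the VST dispersion trend are always estimated on counts.
    TMM/RLE rescale ``m`` column-wise; VST output replaces ``m`` (the
    stabilized scale is the point of the method); QN operates on ``m``
    directly; NoNorm is the identity.
    """
    method = NormalizationMethod(method)
    if method is NormalizationMethod.NONORM:
        return m
    if method is NormalizationMethod.TMM:
        return apply_factors(m, tmm_factors(counts))
    if method is NormalizationMethod.RLE:
        return apply_factors(m, rle_factors(counts))
    if method is NormalizationMethod.VST:
        return vst_apply(counts, vst_fit(counts))
    if method is NormalizationMethod.QN:
        return quantile_normalize(m)
    raise ValueError(f"unknown normalization method: {method}")  # pragma: no cover
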