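"""Grid enumeration, the full evaluation loop, rank aggregation and
sample-size / variance-filter studies.

A *preprocessing combination* is one choice in the cross product
data type (6) × normalization (5) × copula transform (2) × estimator (5)
— 300 combinations in all, 192 once the consistently poor CS estimator and
QN normalization are excluded. Each combination, run through one of three
inference algorithms, yields one performance record; ranks of precision per
dataset are aggregated by their median across datasets (minimum rank on
ties) to compare combinations without trusting any single dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import filtering
from .association import Estimator, EstimatorConfig, association_matrix, copula_transform
from .data_io import GeneNetwork
from .evaluation import PerformanceRecord, Universe, evaluate_network
from .gni import GniAlgorithm, GniConfig, aracne, c3net, relnet, significance_threshold
from .normalization import NormalizationMethod, apply_normalization
from .transforms import DataType, add_pseudocount, apply_datatype

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessingCombo",
    "enumerate_grid",
    "run_combo",
    "run_grid",
    "rank_combos",
    "sample_size_curve",
    "variance_filter_comparison",
    "GNI_PREFIX",
]

GNI_PREFIX = {
    GniAlgorithm.RELNET: "rn",
    GniAlgorithm.C3NET: "c3",
    GniAlgorithm.ARACNE: "ar",
}


@dataclass(frozen=True)
class PreprocessingCombo:
    """One cell of the preprocessing grid."""

    datatype: DataType
    normalization: NormalizationMethod
    ct: bool
    estimator_cfg: EstimatorConfig

    @property
    def label(self) -> str:
        """Deterministic label: ``{estimator}_{CT|noCT}_{norm}_{datatype}``."""
        return "_".join(
            [
                self.estimator_cfg.estimator.value,
                "CT" if self.ct else "noCT",
                self.normalization.value,
                self.datatype.value,
            ]
        )


def enumerate_grid(
    exclude_estimators: list[str] | None = None,
    exclude_normalizations: list[str] | None = None,
    bins: int = 10,
    spline_order: int = 2,
) -> list[PreprocessingCombo]:
    """The full cross-product grid, minus exclusions, in stable order.

    Order: datatype-major, then normalization, then CT, then estimator.
    No exclusions → 300 combinations; excluding CS and QN → 192.
    """
    excl_est = {Estimator(e) for e in (exclude_estimators or [])}
    excl_norm = {NormalizationMethod(n) for n in (exclude_normalizations or [])}
    combos = []
    for dt in DataType:
        for norm in NormalizationMethod:
            if norm in excl_norm:
                continue
            for ct in (False, True):
                for est in Estimator:
                    if est in excl_est:
                        continue
                    combos.append(
                        PreprocessingCombo(
                            datatype=dt,
                            normalization=norm,
                            ct=ct,
                            estimator_cfg=EstimatorConfig(
                                estimator=est, bins=bins, spline_order=spline_order
                            ),
                        )
                    )
    return combos


def preprocess(
    counts: pd.DataFrame,
    combo: PreprocessingCombo,
    lengths: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Steps 2–4 of the pipeline: pseudocount, data type, normalization, CT."""
    pc = add_pseudocount(counts, pseudocount)
    m = apply_datatype(pc, combo.datatype, lengths)
    m = apply_normalization(m, pc, combo.normalization)
    if combo.ct:
        m = copula_transform(m)
    return m


def run_combo(
    counts: pd.DataFrame,
    combo: PreprocessingCombo,
    gni_cfg: GniConfig,
    ref: GeneNetwork,
    universe: Universe,
    lengths: pd.Series | None = None,
    dataset: str = "D1",
    test: str = "hypergeometric",
) -> PerformanceRecord:
    """Run one preprocessing combination end to end and evaluate it.

    ``counts`` must already be filtered. Errors at any stage are re-raised
    with the stage name attached.
    """
    stage = "preprocess"
    try:
        m = preprocess(counts, combo, lengths)
        stage = "association"
        A = association_matrix(m, combo.estimator_cfg)
        stage = "threshold"
        threshold = significance_threshold(A, m, gni_cfg, combo.estimator_cfg)
        stage = "inference"
        if gni_cfg.algorithm is GniAlgorithm.RELNET:
            net = relnet(A, threshold)
        elif gni_cfg.algorithm is GniAlgorithm.C3NET:
            net = c3net(A, threshold)
        else:
            net = aracne(A, threshold, gni_cfg.dpi_eps)
        stage = "evaluation"
        return evaluate_network(
            net, ref, universe,
            combination=combo.label,
            gni=GNI_PREFIX[gni_cfg.algorithm],
            dataset=dataset,
            test=test,
        )
    except Exception as exc:
        raise RuntimeError(f"combo {combo.label!r} failed at stage {stage!r}: {exc}") from exc


def run_grid(
    datasets: dict[str, pd.DataFrame],
    combos: list[PreprocessingCombo],
    gni_cfgs: list[GniConfig],
    ref: GeneNetwork,
    universes: dict[str, Universe],
    lengths: pd.Series | None = None,
    skip_failures: bool = True,
    completed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One record per (dataset × combo × GNI algorithm), as a DataFrame.

    ``completed`` (a previous records table) lets an interrupted run resume:
    records already present are not recomputed. Per-record failures are
    logged and skipped unless ``skip_failures`` is False.
    """
    done = set()
    rows = []
    if completed is not None and len(completed):
        rows = completed.to_dict("records")
        done = {(r["dataset"], r["combination"], r["gni"]) for r in rows}
    for ds_name, counts in datasets.items():
        for combo in combos:
            for gcfg in gni_cfgs:
                key = (ds_name, combo.label, GNI_PREFIX[gcfg.algorithm])
                if key in done:
                    continue
                try:
                    rec = run_combo(
                        counts, combo, gcfg, ref, universes[ds_name],
                        lengths=lengths, dataset=ds_name,
                    )
                    rows.append(rec.as_dict())
                except Exception:
                    if not skip_failures:
                        raise
                    logger.exception("record %s failed; continuing", key)
    return pd.DataFrame(rows)


def rank_combos(records: pd.DataFrame, per_gni: bool = True) -> pd.DataFrame:
    """Aggregate per-dataset precision ranks across datasets.

    Within each dataset (and each GNI algorithm when ``per_gni``),
    combinations are ranked by descending precision with ties sharing the
    minimum rank. The output has one row per combination with median, mean,
    best and worst rank plus the per-dataset raw ranks, sorted ascending by
    median rank (ties by mean rank, then label). Raises if any combination
    is missing from any dataset.
    """
    df = records.copy()
    df["unit"] = df["gni"] + "." + df["combination"] if per_gni else df["combination"]
    if not per_gni:
        # without the per-GNI split, a combination's score per dataset is its
        # best precision over algorithms
        df = df.groupby(["dataset", "unit"], as_index=False)["precision"].max()
    datasets = sorted(df["dataset"].unique())
    units = sorted(df["unit"].unique())
    pivot = df.pivot_table(index="unit", columns="dataset", values="precision", aggfunc="first")
    holes = [(u, d) for u in units for d in datasets if pd.isna(pivot.at[u, d])]
    if holes:
        raise ValueError(f"missing records for {len(holes)} combo-dataset cells, e.g. {holes[:5]}")
    ranks = pd.DataFrame(index=pivot.index)
    for d in datasets:
        # descending precision, minimum rank on ties
        ranks[d] = stats.rankdata(-pivot[d].to_numpy(), method="min").astype(int)
    out = pd.DataFrame(
        {
            "combination": ranks.index,
            "median_rank": ranks.median(axis=1),
            "mean_rank": ranks.mean(axis=1),
            "best_rank": ranks.min(axis=1),
            "worst_rank": ranks.max(axis=1),
        }
    )
    for d in datasets:
        out[f"rank_{d}"] = ranks[d].to_numpy()
    out = out.sort_values(
        ["median_rank", "mean_rank", "combination"], kind="mergesort"
    ).reset_index(drop=True)
    return out


def sample_size_curve(
    counts: pd.DataFrame,
    combo: PreprocessingCombo,
    gni_cfgs: list[GniConfig],
    sizes: list[int],
    ref: GeneNetwork,
    universe: Universe,
    lengths: pd.Series | None = None,
    reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Precision as a function of sample size, by nested seeded subsampling.

    For each replicate a random ordering of samples is drawn once and each
    size takes its prefix, so smaller subsets nest inside larger ones; the
    ``reps`` replicate precisions are averaged per (size, algorithm).
    """
    sizes = sorted(sizes)
    if sizes[-1] > counts.shape[1]:
        raise ValueError(f"max size {sizes[-1]} exceeds available samples {counts.shape[1]}")
    if sizes[0] < 8:
        logger.warning("sample sizes below 8 give unstable association estimates")
    if sizes != sorted(set(sizes)):
        raise ValueError("sizes must be strictly increasing")
    rows = []
    for rep in range(reps):
        rng = np.random.default_rng(seed + rep)
        order = rng.permutation(counts.shape[1])
        for size in sizes:
            sub = counts.iloc[:, order[:size]]
            for gcfg in gni_cfgs:
                rec = run_combo(
                    sub, combo, gcfg, ref, universe, lengths=lengths, dataset=f"n{size}"
                )
                rows.append(
                    {
                        "size": size,
                        "rep": rep,
                        "gni": GNI_PREFIX[gcfg.algorithm],
                        "precision": rec.precision,
                        "tp": rec.tp,
                        "predicted": rec.predicted,
                    }
                )
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["size", "gni"], as_index=False)["precision"].mean()
        .rename(columns={"precision": "mean_precision"})
    )
    return df.merge(summary, on=["size", "gni"])


def variance_filter_comparison(
    datasets: dict[str, pd.DataFrame],
    combos: list[PreprocessingCombo],
    gni_cfgs: list[GniConfig],
    ref: GeneNetwork,
    lengths: pd.Series | None = None,
    drop_fraction: float = 0.20,
) -> pd.DataFrame:
    """Paired records: each dataset as-is vs with the bottom-variance fifth removed.

    The filtered variant is labeled ``{name}HV`` ("high variance", i.e. only
    the higher-variance genes kept). The universe of candidate pairs is
    rebuilt per variant from its surviving genes.
    """
    paired: dict[str, pd.DataFrame] = {}
    for name, counts in datasets.items():
        paired[name] = counts
        paired[f"{name}HV"] = filtering.variance_filter(counts, drop_fraction)
    universes = {
        name: Universe.from_genes(counts.index, ref) for name, counts in paired.items()
    }
    return run_grid(paired, combos, gni_cfgs, ref, universes, lengths=lengths)
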