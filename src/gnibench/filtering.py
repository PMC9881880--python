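"""Gene cleaning and expression/variance filters applied to raw counts.

Order in the pipeline: drop unannotated symbols, collapse duplicate symbols
to the highest-variance row, then the three CPM expression rules. All
filters are order-stable (surviving rows keep their relative order), and
the expression filter is computed on CPM of the raw counts — the add-one
pseudocount belongs to the later transformation step, not here, because
thresholds like 0.1 CPM (≈2 counts at 20M depth) are meant on raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .transforms import cpm

__all__ = [
    "FilterReport",
    "drop_unannotated",
    "collapse_duplicates",
    "expression_filter",
    "variance_filter",
    "default_filter",
]

#: symbols treated as "not annotated"
NA_SYMBOLS = {"", "NA", "nan", "NaN", "<NA>", "None"}


@dataclass
class FilterReport:
    n_input_genes: int = 0
    n_removed_unannotated: int = 0
    n_removed_duplicates: int = 0
    n_removed_low_expression: dict = field(
        default_factory=lambda: {"frac_low": 0, "max": 0, "mean": 0}
    )
    n_output_genes: int = 0

    def reconciles(self) -> bool:
        removed = (
            self.n_removed_unannotated
            + self.n_removed_duplicates
            + sum(self.n_removed_low_expression.values())
        )
        return self.n_input_genes - removed == self.n_output_genes

    def as_dict(self) -> dict:
        return asdict(self)


def drop_unannotated(m: pd.DataFrame) -> pd.DataFrame:
    """Remove rows whose gene symbol is missing / literal NA."""
    keep = ~m.index.astype(str).str.strip().isin(NA_SYMBOLS)
    out = m.loc[keep]
    if out.shape[0] == 0:
        raise ValueError("all genes are unannotated; nothing left after cleaning")
    return out


def collapse_duplicates(m: pd.DataFrame) -> pd.DataFrame:
    """Keep, for each duplicated symbol, only the row with the highest variance.

    Variance is the sample variance of the raw counts across samples; ties
    are broken by first occurrence. Row order of the survivors is preserved.
    """
    if m.index.is_unique:
        return m
    variances = m.var(axis=1, ddof=1).to_numpy()
    keep = np.zeros(m.shape[0], dtype=bool)
    best: dict[str, tuple[float, int]] = {}
    for i, sym in enumerate(m.index):
        v = variances[i]
        if sym not in best or v > best[sym][0]:
            best[sym] = (v, i)
    for _, i in best.values():
        keep[i] = True
    return m.loc[keep]


def expression_filter(
    m: pd.DataFrame,
    low_cpm: float = 0.1,
    low_frac: float = 0.20,
    max_cpm: float = 0.7,
    mean_cpm: float = 0.35,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the three CPM expression rules to a raw count matrix.

    A gene is removed when

    1. its CPM is ≤ ``low_cpm`` in at least ``low_frac`` of the samples, or
    2. its maximum CPM over samples is ≤ ``max_cpm``, or
    3. its mean CPM over samples is < ``mean_cpm``.

    The report attributes each removal to the first matching rule.
    """
    report = FilterReport(n_input_genes=m.shape[0])
    c = cpm(m)  # raises on zero library size, naming the sample
    frac_low = (c <= low_cpm).mean(axis=1)
    rule1 = frac_low >= low_frac
    rule2 = c.max(axis=1) <= max_cpm
    rule3 = c.mean(axis=1) < mean_cpm
    report.n_removed_low_expression = {
        "frac_low": int(rule1.sum()),
        "max": int((~rule1 & rule2).sum()),
        "mean": int((~rule1 & ~rule2 & rule3).sum()),
    }
    keep = ~(rule1 | rule2 | rule3)
    out = m.loc[keep]
    report.n_output_genes = out.shape[0]
    return out, report


def variance_filter(m: pd.DataFrame, drop_fraction: float = 0.20) -> pd.DataFrame:
    """Drop the ``floor(drop_fraction × n_genes)`` lowest-variance genes.

    Variance is computed on the CPM scale of the input so sequencing depth
    does not confound the cross-gene comparison; ties keep the earlier row.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError(f"drop_fraction must be in [0, 1), got {drop_fraction}")
    n_drop = int(np.floor(drop_fraction * m.shape[0]))
    if n_drop == 0:
        return m
    variances = cpm(m).var(axis=1, ddof=1).to_numpy()
    # stable argsort → among ties the earlier row sorts first, i.e. is dropped;
    # spec wants earlier rows KEPT, so sort on (variance, -position)
    order = np.lexsort((-np.arange(len(variances)), variances))
    drop = set(order[:n_drop])
    keep = np.array([i not in drop for i in range(m.shape[0])])
    return m.loc[keep]


def default_filter(
    m: pd.DataFrame,
    low_cpm: float = 0.1,
    low_frac: float = 0.20,
    max_cpm: float = 0.7,
    mean_cpm: float = 0.35,
) -> tuple[pd.DataFrame, FilterReport]:
    """Full default cleaning: NA symbols → duplicate collapse → expression rules."""
    step1 = drop_unannotated(m)
    step2 = collapse_duplicates(step1)
    out, report = expression_filter(step2, low_cpm, low_frac, max_cpm, mean_cpm)
    report.n_input_genes = m.shape[0]
    report.n_removed_unannotated = m.shape[0] - step1.shape[0]
    report.n_removed_duplicates = step1.shape[0] - step2.shape[0]
    return out, report
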