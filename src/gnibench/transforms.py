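"""Basic data-type transformations: raw, CPM, TPM and their log2 variants.

Six data types are supported. The add-one pseudocount is applied once, to
the raw counts, before any of these transformations; CPM/TPM library sizes
are column sums of the matrix actually passed in (i.e. the pseudocounted
one when called from the pipeline).
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd

__all__ = ["DataType", "add_pseudocount", "cpm", "tpm", "log2_transform", "apply_datatype"]


class DataType(str, Enum):
    RAW = "raw"
    L2 = "l2"
    CPM = "cpm"
    L2CPM = "l2cpm"
    TPM = "tpm"
    L2TPM = "l2tpm"

    @property
    def needs_lengths(self) -> bool:
        return self in (DataType.TPM, DataType.L2TPM)


def add_pseudocount(m: pd.DataFrame, c: float = 1.0) -> pd.DataFrame:
    """Add a constant offset to every cell (guards log/ratio steps against zeros)."""
    if c < 0:
        raise ValueError(f"pseudocount must be non-negative, got {c}")
    return m + c


def cpm(m: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: scale each column so it sums to 10^6."""
    libsizes = m.sum(axis=0)
    zero = libsizes[libsizes <= 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s): {list(zero.index)}")
    return m * (1e6 / libsizes)


def tpm(m: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates rescaled to sum 10^6 per column.

    ``lengths`` maps gene symbol to length in bases; the rate divides counts
    by length in kilobases before the per-column million scaling.
    """
    missing = m.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing gene lengths for: {sorted(missing)[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    kb = lengths.reindex(m.index).astype(float) / 1e3
    if (kb <= 0).any():
        bad = kb.index[kb <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    rates = m.div(kb, axis=0)
    return rates * (1e6 / rates.sum(axis=0))


def log2_transform(m: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; all values must be positive (pseudocount applied upstream)."""
    vals = m.to_numpy()
    if (vals <= 0).any():
        g, s = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"non-positive value at gene {m.index[g]!r}, sample {m.columns[s]!r}; "
            "was the pseudocount skipped?"
        )
    return pd.DataFrame(np.log2(vals), index=m.index, columns=m.columns)


def apply_datatype(
    m: pd.DataFrame, datatype: DataType | str, lengths: pd.Series | None = None
) -> pd.DataFrame:
    """Dispatch one of the six data types on an (already pseudocounted) matrix."""
    datatype = DataType(datatype)
    if datatype.needs_lengths and lengths is None:
        raise ValueError(f"data type {datatype.value!r} requires gene lengths")
    if datatype is DataType.RAW:
        return m.copy()
    if datatype is DataType.L2:
        return log2_transform(m)
    if datatype is DataType.CPM:
        return cpm(m)
    if datatype is DataType.L2CPM:
        return log2_transform(cpm(m))
    if datatype is DataType.TPM:
        return tpm(m, lengths)
    if datatype is DataType.L2TPM:
        return log2_transform(tpm(m, lengths))
    raise ValueError(f"unknown data type: {datatype}")  # pragma: no cover
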