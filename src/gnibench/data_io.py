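"""Readers, writers and core containers.

Count matrices are plain pandas DataFrames (genes in rows, samples in
columns); networks are :class:`GeneNetwork` objects holding a canonical set
of undirected gene-symbol pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "canonical_edge",
    "read_counts",
    "read_gene_lengths",
    "read_edge_list",
    "write_network",
    "write_records",
    "read_records",
]

RECORD_COLUMNS = ["combination", "gni", "dataset", "precision", "tp", "predicted", "p_value"]


class ParseError(ValueError):
    """Malformed input file."""


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) in canonical (sorted) order."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected, self-loop-free set of gene-symbol pairs.

    Edges are stored canonically (lexicographically sorted pair), so
    orientation never matters for membership or set operations. Optional
    per-edge weights (association scores) and signs (+1/-1, for correlation
    based estimators) are keyed by the canonical pair.
    """

    edges: frozenset[tuple[str, str]]
    weights: Mapping[tuple[str, str], float] = field(default_factory=dict)
    signs: Mapping[tuple[str, str], int] = field(default_factory=dict)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        weights: Mapping[tuple[str, str], float] | None = None,
        signs: Mapping[tuple[str, str], int] | None = None,
    ) -> "GeneNetwork":
        """Build a network from raw pairs, canonicalizing and dropping self-loops."""
        edges = frozenset(canonical_edge(a, b) for a, b in pairs if a != b)
        w = {canonical_edge(a, b): v for (a, b), v in (weights or {}).items()}
        s = {canonical_edge(a, b): v for (a, b), v in (signs or {}).items()}
        return cls(edges=edges, weights=w, signs=s)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return canonical_edge(a, b) in self.edges

    def genes(self) -> set[str]:
        return {g for e in self.edges for g in e}

    def intersection(self, other: "GeneNetwork") -> frozenset[tuple[str, str]]:
        return self.edges & other.edges

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges)


# alias kept for call-site clarity: a reference network has the same shape
ReferenceNetwork = GeneNetwork


def _sniff_delimiter(header: str) -> str:
    """Pick tab vs comma from the header line (tab wins on a draw)."""
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_counts(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a gene-by-sample count matrix from TSV/CSV.

    First column holds gene symbols, the header row sample IDs. Symbols are
    whitespace-trimmed and kept case-sensitive; duplicated symbols are
    retained (to be collapsed by the filtering step). Negative or
    non-numeric cells raise :class:`ParseError` naming the offending cell.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.strip():
            raise ParseError(f"{path}: empty file or blank header")
    delim = delimiter or _sniff_delimiter(first)
    try:
        df = pd.read_csv(path, sep=delim, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty count matrix ({df.shape[0]} genes, {df.shape[1]} samples)")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(f"{path}: non-numeric value for gene {gene!r}, sample {col!r}")
        values[:, j] = converted.to_numpy()
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    if out.isna().any().any():
        g, s = np.argwhere(out.isna().to_numpy())[0]
        raise ParseError(f"{path}: missing value for gene {out.index[g]!r}, sample {out.columns[s]!r}")
    if (out.to_numpy() < 0).any():
        g, s = np.argwhere(out.to_numpy() < 0)[0]
        raise ParseError(f"{path}: negative count for gene {out.index[g]!r}, sample {out.columns[s]!r}")
    if not out.columns.is_unique:
        dup = out.columns[out.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicated sample ID {dup!r}")
    return out


def write_counts(m: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    m.to_csv(path, sep=delimiter, index_label="gene")


def read_gene_lengths(path: str | Path, delimiter: str | None = None) -> pd.Series:
    """Read a symbol → length (bases) table; lengths must be positive."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = delimiter or _sniff_delimiter(first)
    df = pd.read_csv(path, sep=delim, header=None, comment="#", skip_blank_lines=True)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected at least 2 columns (symbol, length)")
    # tolerate a header row
    if not str(df.iloc[0, 1]).strip().lstrip("-").replace(".", "", 1).isdigit():
        df = df.iloc[1:]
    lengths = pd.Series(
        pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(dtype=float),
        index=df.iloc[:, 0].astype(str).str.strip(),
    )
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ParseError(f"{path}: non-positive length for gene {bad!r}")
    return lengths


def read_edge_list(path: str | Path, delimiter: str | None = None) -> GeneNetwork:
    """Read an undirected edge list (2+ columns of gene symbols per row).

    SIF rows (node, relation, node) are accepted: any 3-column row whose
    middle field is non-numeric is read as endpoints (col 1, col 3).
    Reversed duplicates and self-loops are dropped with a logged count.
    Streams line by line, so literature-scale files (~10^6 rows) are fine.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    weights: dict[tuple[str, str], float] = {}
    n_dup = n_self = 0
    header_names = {"gene_a", "gene_b", "weight", "source", "target", "from", "to", "node1", "node2"}
    with open(path) as fh:
        first_line = fh.readline()
        if not first_line.strip():
            raise ParseError(f"{path}: empty edge-list file")
        delim = delimiter or _sniff_delimiter(first_line)
        lines = [first_line] + fh.readlines()
    first_fields = [f.strip().lower() for f in first_line.rstrip("\n").split(delim)]
    start = 1 if set(first_fields) <= header_names else 0
    if start == 1 and len(lines) == 1:
        return GeneNetwork(edges=frozenset())
    for lineno, line in enumerate(lines[start:], start=start + 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: fewer than 2 fields")
        a, b = fields[0], fields[1]
        weight = None
        if _looks_like_sif(fields) and not _is_number(fields[1]):
            a, b = fields[0], fields[2]
        elif len(fields) >= 3 and _is_number(fields[2]):
            weight = float(fields[2])
        if a == b:
            n_self += 1
            continue
        e = canonical_edge(a, b)
        if e in edges:
            n_dup += 1
        else:
            edges.add(e)
            if weight is not None:
                weights[e] = weight
    if n_dup or n_self:
        logger.info(
            "read_edge_list(%s): dropped %d duplicate and %d self-loop rows", path, n_dup, n_self
        )
    return GeneNetwork(edges=frozenset(edges), weights=weights)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _looks_like_sif(fields: list[str]) -> bool:
    # SIF: node <relation> node — middle field is a short relation keyword
    return len(fields) == 3 and not _is_number(fields[2])


def write_network(net: GeneNetwork, path: str | Path) -> None:
    """Write a network as TSV (gene_a, gene_b[, weight]); round-trips via read_edge_list."""
    has_w = bool(net.weights)
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b" + ("\tweight" if has_w else "") + "\n")
        for a, b in net.sorted_edges():
            if has_w:
                fh.write(f"{a}\t{b}\t{net.weights.get((a, b), float('nan')):.10g}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def write_records(records: pd.DataFrame | list, path: str | Path) -> None:
    """Write performance records as TSV with the canonical column schema."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame([r.as_dict() for r in records])
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records table is missing columns: {missing}")
    df.to_csv(path, sep="\t", index=False, columns=RECORD_COLUMNS + [c for c in df.columns if c not in RECORD_COLUMNS])


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: records table missing columns {missing}")
    return df
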