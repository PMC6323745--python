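"""Readers and writers for the package's plain-text formats.

Expression matrices are tab- or comma-separated text, genes in rows: the
first column holds gene identifiers and the header row holds sample
identifiers.  Edge tables are tab-separated with an "NA" convention for
absent p/q-values, directly importable into Cytoscape; a SIF export
("gene_a pp gene_b") is also provided.  Network structures travel as
two-column edge lists.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import BinaryNetwork, EdgeTable, ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_edge_table",
    "write_edge_table",
    "write_sif",
    "read_structure",
    "write_structure",
    "read_hub_list",
    "apply_hub_weights",
]


def _sniff_delimiter(first_line: str, dialect: str | None) -> str:
    if dialect in ("tab", "\t"):
        return "\t"
    if dialect in ("comma", ","):
        return ","
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def read_expression(path: str | Path, dialect: str | None = None, transpose: bool = False) -> ExpressionMatrix:
    """Parse an expression matrix; errors carry 1-based line numbers.

    ``dialect`` may be "tab" or "comma"; by default the delimiter is
    sniffed from the header.  ``transpose`` accepts samples-in-rows files.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ValueError(f"{path}: empty file")
        delim = _sniff_delimiter(first, dialect)
        fh.seek(0)
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader)
        sample_ids = [c.strip() for c in header[1:]]
        width = len(header)
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != width:
                raise ValueError(f"{path}:{lineno}: expected {width} fields, found {len(row)}")
            gid = row[0].strip()
            if gid in gene_ids:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            try:
                vals = [float(c) for c in row[1:]]
            except ValueError:
                bad = next(c for c in row[1:] if not _is_number(c))
                raise ValueError(f"{path}:{lineno}: non-numeric cell {bad!r}") from None
            gene_ids.append(gid)
            rows.append(vals)
    values = np.array(rows, dtype=float)
    if transpose:
        values, gene_ids, sample_ids = values.T, sample_ids, gene_ids
    return ExpressionMatrix(values, gene_ids, sample_ids)


def _is_number(c: str) -> bool:
    try:
        float(c)
        return True
    except ValueError:
        return False


def write_expression(x: ExpressionMatrix, path: str | Path, dialect: str = "tab") -> None:
    sep = "\t" if dialect in ("tab", "\t") else ","
    df = pd.DataFrame(x.values, index=x.gene_ids, columns=x.sample_ids)
    df.to_csv(path, sep=sep, index_label="gene", float_format="%.17g")


def write_edge_table(t: EdgeTable, path: str | Path) -> None:
    """Tab-separated edge list; NaN p/q written as "NA"."""
    t.records.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_edge_table(path: str | Path) -> EdgeTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"gene_a": str, "gene_b": str})
    return EdgeTable(df)


def write_sif(t: EdgeTable, path: str | Path, relation: str = "pp") -> None:
    """Simple interaction format: one "gene_a pp gene_b" line per edge."""
    with Path(path).open("w") as fh:
        for rec in t.records.itertuples(index=False):
            fh.write(f"{rec.gene_a}\t{relation}\t{rec.gene_b}\n")


def write_structure(b: BinaryNetwork, path: str | Path) -> None:
    """Two-column edge list by gene identifier."""
    with Path(path).open("w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, bb in b.edge_id_pairs():
            fh.write(f"{a}\t{bb}\n")


def read_structure(path: str | Path, gene_ids: Sequence[str] | None = None) -> BinaryNetwork:
    """Edge list -> BinaryNetwork; gene order from ``gene_ids`` if given,
    otherwise sorted order of the identifiers seen in the file."""
    pairs: list[tuple[str, str]] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[:2] == ["gene_a", "gene_b"]:
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            pairs.append((parts[0], parts[1]))
    if gene_ids is None:
        gene_ids = sorted({g for pr in pairs for g in pr})
    index = {g: i for i, g in enumerate(gene_ids)}
    for a, b in pairs:
        if a not in index or b not in index:
            raise ValueError(f"edge gene {a if a not in index else b!r} not in gene list")
    edges = frozenset((min(index[a], index[b]), max(index[a], index[b])) for a, b in pairs)
    return BinaryNetwork(edges, tuple(gene_ids))


def read_hub_list(path: str | Path) -> list[str]:
    """Plain text, one hub gene identifier per line; blanks ignored."""
    with Path(path).open() as fh:
        return [line.strip() for line in fh if line.strip()]


def apply_hub_weights(
    base_penalty: float,
    hub_gene_ids: Sequence[str],
    gene_ids: Sequence[str],
    hub_confidence: float,
) -> np.ndarray:
    """Entrywise penalty matrix down-weighting edges incident to hub genes.

    Entries whose pair touches a declared hub get ``base_penalty *
    hub_confidence``; all other off-diagonals get ``base_penalty``.
    ``hub_confidence = 1`` reproduces the uniform-penalty run (a neutral
    prior); smaller values encourage hub connectivity.  This is a generic
    penalty-rescaling hook for feeding prior hub knowledge into the
    penalized estimators; it is experimental and deliberately minimal.
    """
    if not 0.0 < hub_confidence <= 1.0:
        raise ValueError("hub_confidence must lie in (0, 1]")
    if base_penalty <= 0:
        raise ValueError("base_penalty must be positive")
    index = {g: i for i, g in enumerate(gene_ids)}
    unknown = [g for g in hub_gene_ids if g not in index]
    if unknown:
        raise ValueError(f"hub gene(s) not in expression data: {unknown}")
    p = len(gene_ids)
    pen = np.full((p, p), float(base_penalty))
    hub_idx = [index[g] for g in hub_gene_ids]
    pen[hub_idx, :] = base_penalty * hub_confidence
    pen[:, hub_idx] = base_penalty * hub_confidence
    np.fill_diagonal(pen, 0.0)
    return pen
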