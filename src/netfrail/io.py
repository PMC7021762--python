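"""Readers and writers for the tabular formats of the toolkit.

Formats (all TSV-based, UTF-8, ``#`` comment lines):

- edge list: two tab-separated node labels per line, one undirected edge per
  line; duplicate and reversed edges are deduplicated.
- adjacency matrix: square table with a header row and a label column.
- GMT gene sets: ``name<TAB>description<TAB>gene1<TAB>gene2...``
- mutation matrix: genes as rows, samples as columns, 0/1 entries, header row
  of sample labels, first column of gene labels.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .network import Network, NetworkError
from .synthetic import MutationMatrix

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_adjacency",
    "write_adjacency",
    "read_network",
    "read_gmt",
    "write_gmt",
    "read_mutation_matrix",
    "write_mutation_matrix",
    "read_query_file",
    "provenance_header",
]

logger = logging.getLogger(__name__)


def _data_lines(path: str | Path) -> list[tuple[int, str]]:
    lines = []
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            lines.append((i, line))
    return lines


def read_edge_list(path: str | Path) -> Network:
    """Network from a two-column tab-separated edge list."""
    edges = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            raise NetworkError(f"{path}:{lineno}: expected two tab-separated labels")
        edges.append((parts[0], parts[1]))
    if not edges:
        raise NetworkError(f"{path}: no edges found")
    return Network.from_edges(edges)


def write_edge_list(network: Network, path: str | Path, header: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        ii, jj = np.nonzero(np.triu(network.adjacency))
        for i, j in zip(ii, jj):
            fh.write(f"{network.labels[i]}\t{network.labels[j]}\n")


def read_adjacency(path: str | Path) -> Network:
    """Network from a square labeled adjacency TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if list(df.index) != list(df.columns):
        raise NetworkError(f"{path}: row and column labels differ")
    return Network(tuple(str(l) for l in df.index), df.to_numpy(dtype=float))


def write_adjacency(network: Network, path: str | Path, header: str = "") -> None:
    df = pd.DataFrame(network.adjacency.astype(int),
                      index=network.labels, columns=network.labels)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t")


def read_network(path: str | Path) -> Network:
    """Dispatch on content: a square labeled table is an adjacency, else edge list."""
    first = None
    for _, line in _data_lines(path):
        first = line
        break
    if first is not None and len(first.split("\t")) > 2:
        return read_adjacency(path)
    return read_edge_list(path)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Gene sets from a GMT file (name, description, then member genes).

    Duplicate genes within a set are deduplicated (logged); malformed lines
    (< 3 fields) raise with the line number; an empty file yields an empty
    collection with a warning.
    """
    sets: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
            )
        name, genes = parts[0], [g for g in parts[2:] if g]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        dedup = set(genes)
        if len(dedup) < len(genes):
            logger.info("gene set %s: %d duplicate genes removed",
                        name, len(genes) - len(dedup))
        sets[name] = dedup
    if not sets:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *sorted(str(g) for g in genes)]) + "\n")


def read_mutation_matrix(path: str | Path) -> MutationMatrix:
    """Binary genes-by-samples matrix from TSV; validates labels and 0/1 entries."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate gene labels {dupes}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample labels {dupes}")
    arr = df.to_numpy()
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-binary value {arr[i, j]!r} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    return MutationMatrix(df.astype(np.int8))


def write_mutation_matrix(muts: MutationMatrix, path: str | Path, header: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        muts.a.to_csv(fh, sep="\t")


def read_query_file(path: str | Path) -> list[str]:
    """Query node labels, one per line."""
    return [line for _, line in _data_lines(path)]


def provenance_header(seed: int | None = None, **params) -> str:
    """Comment block recording the package version, a config hash and the seed."""
    from . import __version__

    items = sorted(params.items())
    digest = hashlib.sha1(repr(items).encode()).hexdigest()[:12]
    lines = [f"# netfrail {__version__}", f"# config sha1={digest}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    for k, v in items:
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"
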