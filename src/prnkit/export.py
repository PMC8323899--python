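"""Graph serialization (GEXF / GraphML) and deterministic TSV reports."""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = ["write_graph", "read_graph", "write_tsv"]

_WRITERS = {
    "gexf": nx.write_gexf,
    "graphml": nx.write_graphml,
}
_READERS = {
    "gexf": nx.read_gexf,
    "graphml": nx.read_graphml,
}


def write_graph(g: nx.Graph, format: str, path: str | Path) -> Path:
    """Serialize a residue network with all node/edge attributes.

    Supported formats: ``gexf`` and ``graphml``.  Reading the file back with
    :func:`read_graph` reconstructs an isomorphic graph with equal attribute
    values (up to float round-trip formatting).
    """
    if format not in _WRITERS:
        raise ValueError(f"unknown format {format!r}; choose from {sorted(_WRITERS)}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _WRITERS[format](g, str(path))
    return path


def read_graph(path: str | Path, format: str | None = None) -> nx.Graph:
    """Read a graph written by :func:`write_graph` (format from the suffix)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".")
    if fmt not in _READERS:
        raise ValueError(f"unknown format {fmt!r}; choose from {sorted(_READERS)}")
    g = _READERS[fmt](str(path))
    if isinstance(g, (nx.DiGraph, nx.MultiGraph)):
        g = nx.Graph(g)
    return g


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a report table with fixed %.6f float formatting (stable diffs)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path
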