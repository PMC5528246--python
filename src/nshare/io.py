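"""Readers and writers for the plain-text network formats the tool touches.

Formats
-------
edgelist
    Two-column delimited text, one edge per line, ``#`` comments.  Directed
    unimode only; the stored orientation is resource→consumer (first column
    eaten by second).  Isolated nodes survive round-trips through a
    ``#%nodes=`` directive line (a plain comment to other tools).
adjacency
    Labeled square CSV over all nodes; cell (r, c) = 1 means r is a resource
    of c.  Directed unimode only.
incidence
    Labeled rectangular CSV; rows and columns become the two bipartite sides.

An ``orientation`` flag flips edge direction on read/write for sources that
store consumer→resource matrices — published food-web files disagree on the
convention, so it must be explicit and overridable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ModeError, ParameterError
from .network import Network, PermittedInteractions, TraitTable
from .overlap import OverlapSummary

FORMATS = ("edgelist", "adjacency", "incidence")
ORIENTATIONS = ("resource-to-consumer", "consumer-to-resource")
_NODES_DIRECTIVE = "#%nodes="


@dataclass(frozen=True)
class NetworkFileSpec:
    """Where and how a network lives on disk."""

    path: str | Path
    format: str = "edgelist"
    orientation: str = "resource-to-consumer"
    delimiter: str = ","

    def __post_init__(self):
        if self.format not in FORMATS:
            raise ParameterError(f"unknown format {self.format!r}; expected one of {FORMATS}")
        if self.orientation not in ORIENTATIONS:
            raise ParameterError(
                f"unknown orientation {self.orientation!r}; expected one of {ORIENTATIONS}"
            )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_network(spec: NetworkFileSpec) -> Network:
    """Read a network file according to its spec; see module docstring."""
    path = Path(spec.path)
    if spec.format == "edgelist":
        return _read_edgelist(path, spec)
    if spec.format == "adjacency":
        return _read_adjacency(path, spec)
    return _read_incidence(path)


def _read_edgelist(path: Path, spec: NetworkFileSpec) -> Network:
    edges: list[tuple[str, str]] = []
    declared: list[str] | None = None
    seen = set()
    dup = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line.startswith(_NODES_DIRECTIVE):
            declared = [v for v in line[len(_NODES_DIRECTIVE):].split(spec.delimiter) if v]
            continue
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(spec.delimiter)]
        if len(parts) != 2 or not all(parts):
            raise FormatError(f"{path}:{lineno}: expected two delimited fields, got {raw!r}")
        u, v = parts
        if spec.orientation == "consumer-to-resource":
            u, v = v, u
        if (u, v) in seen:
            dup += 1
            continue
        seen.add((u, v))
        edges.append((u, v))
    if dup:
        warnings.warn(f"{path}: collapsed {dup} duplicate edge(s)", stacklevel=2)
    if declared is None:
        declared = sorted({x for e in edges for x in e})
    return Network(nodes=declared, edges=edges, directed=True)


def _read_labeled_csv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse labeled CSV: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    arr = df.to_numpy()
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-binary cell at row {df.index[r]!r}, column {df.columns[c]!r} "
            f"(line {r + 2})"
        )
    return df


def _read_adjacency(path: Path, spec: NetworkFileSpec) -> Network:
    df = _read_labeled_csv(path)
    if df.shape[0] != df.shape[1] or sorted(df.index) != sorted(df.columns):
        raise FormatError(f"{path}: adjacency matrix must be square with matching labels")
    vals = df.to_numpy().astype(bool)
    if spec.orientation == "consumer-to-resource":
        vals = vals.T
        df = pd.DataFrame(vals, index=df.columns, columns=df.index)
    edges = [
        (str(df.index[a]), str(df.columns[b])) for a, b in zip(*np.nonzero(df.to_numpy()))
    ]
    return Network(nodes=sorted(df.index), edges=edges, directed=True)


def _read_incidence(path: Path) -> Network:
    df = _read_labeled_csv(path)
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if set(rows) & set(cols):
        raise FormatError(f"{path}: incidence row and column labels overlap")
    edges = [(rows[a], cols[b]) for a, b in zip(*np.nonzero(df.to_numpy()))]
    return Network(
        nodes=rows + cols, edges=edges, directed=False, bipartite_sides=(rows, cols)
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_network(net: Network, spec: NetworkFileSpec) -> Path:
    """Write a network with deterministic (lexicographic) ordering.

    Round-trips exactly with :func:`read_network`; writing the same network
    twice yields byte-identical files.
    """
    path = Path(spec.path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if spec.format == "edgelist":
        if net.is_bipartite:
            raise ModeError("bipartite network to edgelist: use the incidence format")
        if not net.directed:
            raise ModeError("edgelist format stores directed unimode networks")
        d = spec.delimiter
        lines = [_NODES_DIRECTIVE + d.join(sorted(net.nodes))]
        for u, v in sorted(net.edges):
            if spec.orientation == "consumer-to-resource":
                u, v = v, u
            lines.append(f"{u}{d}{v}")
        path.write_text("\n".join(lines) + "\n")
        return path
    if spec.format == "adjacency":
        if net.is_bipartite:
            raise ModeError("bipartite network to adjacency: use the incidence format")
        nodes = sorted(net.nodes)
        A = np.zeros((len(nodes), len(nodes)), dtype=int)
        idx = {v: k for k, v in enumerate(nodes)}
        for u, v in net.edges:
            if spec.orientation == "consumer-to-resource":
                u, v = v, u
            A[idx[u], idx[v]] = 1
        pd.DataFrame(A, index=nodes, columns=nodes).to_csv(path)
        return path
    if not net.is_bipartite:
        raise ModeError("unimode network to incidence: use edgelist or adjacency")
    rows = sorted(net.bipartite_sides[0])
    cols = sorted(net.bipartite_sides[1])
    M = np.zeros((len(rows), len(cols)), dtype=int)
    ridx = {v: k for k, v in enumerate(rows)}
    cidx = {v: k for k, v in enumerate(cols)}
    for u, v in net.edges:
        if u in cidx:
            u, v = v, u
        M[ridx[u], cidx[v]] = 1
    pd.DataFrame(M, index=rows, columns=cols).to_csv(path)
    return path


# ---------------------------------------------------------------------------
# trait tables & permitted matrices
# ---------------------------------------------------------------------------

def read_trait_table(path: str | Path) -> TraitTable:
    """Two-column TSV: node_id <TAB> comma-separated trait tokens (may be empty)."""
    traits: dict[str, frozenset[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'node<TAB>tokens', got {raw!r}")
        node, toks = parts[0].strip(), parts[1].strip()
        traits[node] = frozenset(t.strip() for t in toks.split(",") if t.strip())
    return TraitTable(traits)


def write_trait_table(traits: TraitTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        f"{node}\t{','.join(sorted(traits[node]))}" for node in sorted(traits.traits)
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_permitted_matrix(path: str | Path) -> pd.DataFrame:
    """Labeled 0/1 CSV; rows = partners, columns = actors."""
    return _read_labeled_csv(Path(path))


def write_permitted_matrix(perm: PermittedInteractions, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nodes = sorted(perm.nodes)
    idx = [perm.index(v) for v in nodes]
    m = perm.matrix[np.ix_(idx, idx)].astype(int)
    pd.DataFrame(m, index=nodes, columns=nodes).to_csv(path)
    return path


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

def summary_to_json(
    summary: OverlapSummary,
    direction: str,
    constraint: str,
    per_pair: bool = False,
    extra: dict | None = None,
) -> dict:
    """The per-network result record (validates against the shipped schema)."""
    out = summary.to_dict(per_pair=per_pair, constraint=constraint)
    out["direction"] = direction
    if extra:
        out.update(extra)
    return out


def write_summary_json(path: str | Path, record: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return path
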