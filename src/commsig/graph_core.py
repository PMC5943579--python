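"""Graph and partition data model plus edge-list / membership file I/O.

The package works on undirected, unweighted, simple graphs.  Input edges are
canonicalized on construction: directions are ignored, duplicate edges are
collapsed and self-loops are dropped.  Nodes are indexed 0..N-1 internally;
the original labels (arbitrary strings or integers) are preserved in a
bidirectional map so that file output round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "Network",
    "Partition",
    "ParseError",
    "read_edge_list",
    "write_edge_list",
    "read_membership",
    "write_membership",
    "read_graphml",
    "read_gml",
    "community_sizes",
]


class ParseError(ValueError):
    """Raised for malformed edge-list or membership files."""


@dataclass(frozen=True)
class Network:
    """An undirected simple graph.

    Attributes
    ----------
    edges : (M, 2) int array with edges as index pairs u < v, lexicographically
        sorted (the canonical edge set).
    node_labels : original node labels, position i holds the label of node i.
    """

    edges: np.ndarray
    node_labels: tuple
    n_nodes: int

    def __post_init__(self):
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=np.int64).reshape(-1, 2))

    @property
    def N(self) -> int:
        return self.n_nodes

    @property
    def M(self) -> int:
        return int(self.edges.shape[0])

    @property
    def degrees(self) -> np.ndarray:
        d = np.bincount(self.edges.ravel(), minlength=self.n_nodes)
        return d.astype(np.int64)

    @property
    def label_to_index(self) -> dict:
        return {lab: i for i, lab in enumerate(self.node_labels)}

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 adjacency in CSR form (A_ii = 0)."""
        u, v = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * self.M, dtype=np.int64)
        A = sparse.coo_matrix(
            (data, (np.concatenate([u, v]), np.concatenate([v, u]))),
            shape=(self.n_nodes, self.n_nodes),
        )
        A = A.tocsr()
        A.sort_indices()
        return A

    @classmethod
    def from_edges(
        cls,
        pairs: Iterable[tuple[Hashable, Hashable]],
        nodes: Sequence[Hashable] | None = None,
    ) -> "Network":
        """Build a canonical Network from (possibly messy) node-label pairs.

        Duplicate edges (in either orientation) are collapsed and self-loops
        dropped.  ``nodes`` may list extra isolated nodes and/or fix the
        label order; otherwise labels are indexed in order of appearance.
        """
        index: dict = {}
        labels: list = []

        def idx(lab):
            i = index.get(lab)
            if i is None:
                i = len(labels)
                index[lab] = i
                labels.append(lab)
            return i

        if nodes is not None:
            for lab in nodes:
                idx(lab)
        raw = []
        for a, b in pairs:
            ia, ib = idx(a), idx(b)
            if ia == ib:
                continue
            raw.append((ia, ib) if ia < ib else (ib, ia))
        if raw:
            E = np.unique(np.asarray(raw, dtype=np.int64), axis=0)
        else:
            E = np.empty((0, 2), dtype=np.int64)
        return cls(edges=E, node_labels=tuple(labels), n_nodes=len(labels))

    @classmethod
    def from_index_edges(cls, edges: np.ndarray, n_nodes: int) -> "Network":
        """Canonicalize integer index pairs on nodes 0..n_nodes-1."""
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        keep = edges[:, 0] != edges[:, 1]
        edges = edges[keep]
        edges = np.sort(edges, axis=1)
        if len(edges):
            edges = np.unique(edges, axis=0)
        return cls(edges=edges, node_labels=tuple(range(n_nodes)), n_nodes=n_nodes)


@dataclass
class Partition:
    """A hard partition of the nodes into C non-overlapping communities.

    ``labels`` holds one community label per node, normalized to contiguous
    integers 1..C in order of first appearance; every community is non-empty.
    """

    labels: np.ndarray
    C: int = field(init=False)

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 1 or lab.size == 0:
            raise ValueError("labels must be a non-empty 1-D sequence")
        uniq, normalized = np.unique(lab, return_inverse=True)
        # renumber in order of first appearance, not sorted order
        first = {}
        out = np.empty(lab.size, dtype=np.int64)
        nxt = 0
        for i, g in enumerate(normalized):
            if g not in first:
                first[g] = nxt
                nxt += 1
            out[i] = first[g]
        self.labels = out + 1
        self.C = nxt

    @property
    def membership(self) -> np.ndarray:
        """0-based membership array (labels - 1)."""
        return self.labels - 1

    def members(self, c: int) -> np.ndarray:
        """Node indices of community c (1-based community id)."""
        return np.flatnonzero(self.labels == c)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.membership, minlength=self.C)

    def volumes(self, network: Network) -> np.ndarray:
        return np.bincount(self.membership, weights=network.degrees, minlength=self.C).astype(np.int64)


def _split_row(row: str, delimiter: str | None):
    if delimiter is None:
        # whitespace or comma dialect
        return row.replace(",", " ").split()
    return [t.strip() for t in row.split(delimiter)]


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_edge_list(
    path: str | Path,
    delimiter: str | None = None,
    has_header: bool | None = None,
) -> Network:
    """Read a 2-column edge list (TSV/CSV/whitespace) into a Network.

    Directions are ignored, duplicate edges collapsed, self-loops dropped.
    A header row is auto-detected when the first row's tokens are
    non-numeric (override with ``has_header``).  Lines starting with '#'
    are treated as comments.  Blank or 1-token lines are parse errors.
    """
    path = Path(path)
    text = path.read_text()
    rows: list[tuple[int, str]] = [
        (ln, line) for ln, line in enumerate(text.splitlines(), start=1) if not line.lstrip().startswith("#")
    ]
    if not rows:
        raise ParseError(f"{path}: empty edge-list file")
    pairs = []
    first_data = True
    for ln, line in rows:
        toks = _split_row(line, delimiter)
        if first_data:
            first_data = False
            header = has_header
            if header is None:
                header = len(toks) >= 2 and not any(_is_number(t) for t in toks)
            if header:
                continue
        if len(toks) < 2:
            raise ParseError(f"{path}: line {ln}: expected at least 2 columns, got {len(toks)}")
        pairs.append((toks[0], toks[1]))
    if not pairs:
        raise ParseError(f"{path}: no edges found")
    return Network.from_edges(pairs)


def write_edge_list(network: Network, path: str | Path, delimiter: str = "\t") -> None:
    """Write the canonical edge set with original node labels, one edge per line."""
    with open(path, "w") as fh:
        for u, v in network.edges:
            fh.write(f"{network.node_labels[u]}{delimiter}{network.node_labels[v]}\n")


def read_membership(path: str | Path, network: Network, delimiter: str | None = None) -> Partition:
    """Read a 2-column (node, community) file covering every network node exactly once."""
    path = Path(path)
    text = path.read_text()
    lut = network.label_to_index
    # tolerate both str and int label spellings for numeric node ids
    seen: dict[int, object] = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        toks = _split_row(line, delimiter)
        if len(toks) < 2:
            raise ParseError(f"{path}: line {ln}: expected 2 columns")
        node_tok, com = toks[0], toks[1]
        idx = lut.get(node_tok)
        if idx is None:
            try:
                idx = lut.get(int(node_tok))
            except ValueError:
                idx = None
        if idx is None:
            raise ParseError(f"{path}: line {ln}: unknown node {node_tok!r}")
        if idx in seen:
            raise ParseError(f"{path}: line {ln}: node {node_tok!r} listed more than once")
        seen[idx] = com
    missing = [network.node_labels[i] for i in range(network.N) if i not in seen]
    if missing:
        raise ParseError(f"{path}: missing membership for nodes: {missing[:10]}")
    return Partition(np.array([seen[i] for i in range(network.N)], dtype=object))


def write_membership(network: Network, partition: Partition, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for i in range(network.N):
            fh.write(f"{network.node_labels[i]}{delimiter}{partition.labels[i]}\n")


def _from_networkx(G) -> Network:
    nodes = list(G.nodes())
    return Network.from_edges(G.edges(), nodes=nodes)


def read_graphml(path: str | Path) -> Network:
    """Convenience GraphML reader (via networkx); weights/directions ignored."""
    import networkx as nx

    return _from_networkx(nx.read_graphml(path))


def read_gml(path: str | Path) -> Network:
    """Convenience GML reader (via networkx); weights/directions ignored."""
    import networkx as nx

    return _from_networkx(nx.read_gml(path, label="id"))


def community_sizes(network: Network, partition: Partition) -> list[tuple[int, int]]:
    """Per-community (n_c, vol_c): node count and degree sum, c = 1..C."""
    if partition.labels.size != network.N:
        raise ValueError("partition does not cover the network")
    n = partition.sizes()
    vol = partition.volumes(network)
    return [(int(a), int(b)) for a, b in zip(n, vol)]
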