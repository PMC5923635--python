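"""Areal contiguity structures for intrinsic-CAR disease mapping.

The neighbourhood lattice is represented as a symmetric 0-1 contiguity
matrix W: w_ij = 1 when areas i and j share a border, w_ii = 0, and
m_i = sum_j w_ij is the number of neighbours of area i.  Every ICAR
computation downstream (pairwise prior density, full conditionals,
precision Gibbs steps, exact field sampling) works off this structure.

Area order is fixed at construction time and is the canonical vector
index for all downstream fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = ["ArealGraph", "build_graph", "grid_graph", "read_adjacency", "write_adjacency"]


@dataclass(frozen=True)
class ArealGraph:
    """Immutable contiguity structure over ``n`` areas.

    Attributes
    ----------
    area_ids : tuple of str
        Canonical area order; index ``i`` everywhere downstream.
    edges : tuple of (int, int)
        Unordered, deduplicated index pairs with ``i < j``.
    m : ndarray of int
        Neighbour counts per area.
    component_labels : ndarray of int
        Connected-component label per area (0-based, by first appearance).
    """

    area_ids: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    m: np.ndarray
    component_labels: np.ndarray

    @property
    def n(self) -> int:
        return len(self.area_ids)

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if self.n else 0

    @property
    def islands(self) -> np.ndarray:
        """Indices of areas with no neighbours (spatial effect pinned to 0)."""
        return np.flatnonzero(self.m == 0)

    def index_of(self, area_id: str) -> int:
        return self.area_ids.index(area_id)

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Sparse symmetric 0-1 contiguity matrix W."""
        if not self.edges:
            return sp.csr_matrix((self.n, self.n))
        ei, ej = np.array(self.edges).T
        rows = np.concatenate([ei, ej])
        cols = np.concatenate([ej, ei])
        data = np.ones(rows.size)
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian Q = diag(m) - W (the ICAR structure matrix)."""
        W = self.adjacency_matrix().toarray()
        return np.diag(self.m.astype(float)) - W

    def neighbor_lists(self) -> list[np.ndarray]:
        out: list[list[int]] = [[] for _ in range(self.n)]
        for i, j in self.edges:
            out[i].append(j)
            out[j].append(i)
        return [np.array(sorted(v), dtype=np.intp) for v in out]

    def coloring(self) -> list[np.ndarray]:
        """Partition areas into colour classes with no within-class edge.

        Greedy colouring over the canonical order; deterministic.  Used by
        the sampler to run single-site updates of one colour in parallel.
        """
        g = self._nx()
        colors = nx.greedy_color(g, strategy="largest_first")
        k = max(colors.values(), default=0) + 1
        return [
            np.array([i for i in range(self.n) if colors[i] == c], dtype=np.intp)
            for c in range(k)
        ]

    def _nx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g


def build_graph(area_ids: Sequence[str], edges: Iterable[tuple[str, str]]) -> ArealGraph:
    """Build a validated :class:`ArealGraph` from id pairs.

    Edges are symmetrised and deduplicated.  Self-loops and edges naming
    unknown areas are rejected.
    """
    ids = tuple(str(a) for a in area_ids)
    if len(set(ids)) != len(ids):
        dup = [a for a in ids if ids.count(a) > 1][0]
        raise ValueError(f"duplicate area id {dup!r}")
    index = {a: i for i, a in enumerate(ids)}
    edge_set: set[tuple[int, int]] = set()
    for a, b in edges:
        a, b = str(a), str(b)
        for x in (a, b):
            if x not in index:
                raise ValueError(f"edge ({a!r}, {b!r}) names unknown area {x!r}")
        if a == b:
            raise ValueError(f"self-loop on area {a!r}")
        i, j = index[a], index[b]
        edge_set.add((min(i, j), max(i, j)))
    edge_tup = tuple(sorted(edge_set))
    n = len(ids)
    m = np.zeros(n, dtype=np.intp)
    for i, j in edge_tup:
        m[i] += 1
        m[j] += 1
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edge_tup)
    labels = np.empty(n, dtype=np.intp)
    labels.fill(-1)
    next_label = 0
    for i in range(n):
        if labels[i] == -1:
            members = nx.node_connected_component(g, i)
            for v in members:
                labels[v] = next_label
            next_label += 1
    return ArealGraph(ids, edge_tup, m, labels)


def grid_graph(rows: int, cols: int, contiguity: str = "rook") -> ArealGraph:
    """Regular ``rows x cols`` lattice with rook or queen contiguity.

    Rook joins orthogonal neighbours; queen adds the diagonals.  Area ids
    are ``"r{r}c{c}"`` in row-major order.  A stand-in for an irregular
    city lattice in simulations and tests.
    """
    if rows < 1 or cols < 1:
        raise ValueError(f"grid dimensions must be positive, got {rows}x{cols}")
    if rows * cols < 2:
        raise ValueError("grid must contain at least 2 areas")
    if contiguity not in ("rook", "queen"):
        raise ValueError(f"contiguity must be 'rook' or 'queen', got {contiguity!r}")
    ids = [f"r{r}c{c}" for r in range(rows) for c in range(cols)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append((f"r{r}c{c}", f"r{r}c{c + 1}"))
            if r + 1 < rows:
                edges.append((f"r{r}c{c}", f"r{r + 1}c{c}"))
            if contiguity == "queen" and r + 1 < rows:
                if c + 1 < cols:
                    edges.append((f"r{r}c{c}", f"r{r + 1}c{c + 1}"))
                if c - 1 >= 0:
                    edges.append((f"r{r}c{c}", f"r{r + 1}c{c - 1}"))
    return build_graph(ids, edges)


# ---------------------------------------------------------------------------
# File dialects: GAL, plain edge list, WinBUGS-style adjacency vectors.
# ---------------------------------------------------------------------------

_DIALECTS = ("gal", "edge_list", "winbugs_adj")


def read_adjacency(path: str | Path, dialect: str) -> ArealGraph:
    """Read a contiguity file in one of three text dialects.

    ``gal``: header line with the area count, then per area a line
    ``<id> <n_neighbours>`` followed by a line listing the neighbour ids.
    ``edge_list``: a ``nodes:`` header naming every area in order, then one
    ``<id> <id>`` pair per line.
    ``winbugs_adj``: ``num=c(...)``, ``adj=c(...)`` vectors with 1-based
    indices; areas are unnamed and get ids ``"1"``..``"n"``.

    GAL and winbugs_adj listings must be symmetric; an edge listed from
    only one side is rejected naming both areas.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    text = Path(path).read_text()
    if dialect == "gal":
        return _read_gal(text)
    if dialect == "edge_list":
        return _read_edge_list(text)
    return _read_winbugs(text)


def write_adjacency(graph: ArealGraph, path: str | Path, dialect: str) -> None:
    """Write ``graph`` in the named dialect (see :func:`read_adjacency`)."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    nbrs = graph.neighbor_lists()
    lines: list[str] = []
    if dialect == "gal":
        lines.append(str(graph.n))
        for i, a in enumerate(graph.area_ids):
            lines.append(f"{a} {graph.m[i]}")
            lines.append(" ".join(graph.area_ids[j] for j in nbrs[i]))
    elif dialect == "edge_list":
        lines.append("nodes: " + " ".join(graph.area_ids))
        for i, j in graph.edges:
            lines.append(f"{graph.area_ids[i]} {graph.area_ids[j]}")
    else:  # winbugs_adj: 1-based index vectors, ids dropped
        num = ", ".join(str(k) for k in graph.m)
        adj = ", ".join(str(j + 1) for i in range(graph.n) for j in nbrs[i])
        lines.append(f"num=c({num})")
        lines.append(f"adj=c({adj})")
        lines.append(f"sumNumNeigh={int(graph.m.sum())}")
    Path(path).write_text("\n".join(lines) + "\n")


def _check_symmetry(nbrs: dict[str, list[str]], what: str) -> None:
    for a, targets in nbrs.items():
        for b in targets:
            if b not in nbrs:
                raise ValueError(f"{what}: neighbour {b!r} of {a!r} is not a listed area")
            if a not in nbrs[b]:
                raise ValueError(
                    f"{what}: asymmetric listing — {a!r} lists {b!r} "
                    f"but {b!r} does not list {a!r}"
                )


def _read_gal(text: str) -> ArealGraph:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("GAL: empty file")
    # legacy headers may be "n" or "0 n <shapefile> <var>"
    head = lines[0].split()
    n = int(head[1]) if len(head) > 1 else int(head[0])
    ids: list[str] = []
    nbrs: dict[str, list[str]] = {}
    pos = 1
    for _ in range(n):
        if pos + 1 > len(lines):
            raise ValueError("GAL: truncated file")
        area, k = lines[pos].split()
        k = int(k)
        neigh = lines[pos + 1].split() if k > 0 else []
        if k > 0:
            pos += 2
        else:
            # zero-neighbour areas may omit the (empty) neighbour line
            if pos + 1 < len(lines) and len(lines[pos + 1].split()) == 0:
                pos += 2
            else:
                pos += 1
        if len(neigh) != k:
            raise ValueError(f"GAL: area {area!r} declares {k} neighbours, lists {len(neigh)}")
        ids.append(area)
        nbrs[area] = neigh
    _check_symmetry(nbrs, "GAL")
    edges = [(a, b) for a in ids for b in nbrs[a]]
    return build_graph(ids, edges)


def _read_edge_list(text: str) -> ArealGraph:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines or not lines[0].startswith("nodes:"):
        raise ValueError("edge_list: missing 'nodes:' header naming the areas in order")
    ids = lines[0].split()[1:]
    edges = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != 2:
            raise ValueError(f"edge_list: malformed line {ln!r}")
        edges.append((parts[0], parts[1]))
    return build_graph(ids, edges)


def _read_winbugs(text: str) -> ArealGraph:
    import re

    def vector(name: str) -> list[int]:
        mobj = re.search(rf"{name}\s*=\s*c\(([^)]*)\)", text, flags=re.S)
        if mobj is None:
            raise ValueError(f"winbugs_adj: missing {name}=c(...) vector")
        body = mobj.group(1).strip()
        return [int(tok) for tok in re.split(r"[,\s]+", body) if tok] if body else []

    num = vector("num")
    adj = vector("adj")
    if sum(num) != len(adj):
        raise ValueError(f"winbugs_adj: sum(num)={sum(num)} but adj has {len(adj)} entries")
    n = len(num)
    ids = [str(i + 1) for i in range(n)]
    nbrs: dict[str, list[str]] = {}
    pos = 0
    for i in range(n):
        nbrs[ids[i]] = [str(j) for j in adj[pos : pos + num[i]]]
        pos += num[i]
    _check_symmetry(nbrs, "winbugs_adj")
    edges = [(a, b) for a in ids for b in nbrs[a]]
    return build_graph(ids, edges)
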