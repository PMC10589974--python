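"""District adjacency graphs and the matrices derived from them.

Areal models on administrative units (districts) need three structures that
all derive from the same neighbourhood graph:

* the intrinsic-CAR precision ``K = diag(deg) - A`` (the graph Laplacian),
  which is the prior precision pattern of the spatially *structured* random
  effect;
* spatial weight matrices (binary or row-standardised) for Moran statistics;
* plain adjacency for bookkeeping.

Two text dialects are supported for interchange:

* **edge_list** — one whitespace-separated label pair per line, ``#`` starts a
  comment; a line with a single label declares a district without adding an
  edge (this is how isolated districts are represented, and how the writer
  pins down label order).
* **gra** — an areal-model neighbours file: line 1 holds the number of
  districts ``n``; then for every district three lines follow — its label,
  its neighbour count, and the 0-based indices of its neighbours (the third
  line is empty when the count is 0). Adjacency must be declared
  symmetrically; an asymmetric file is rejected. Several .gra variants exist
  in the wild; this is the one documented in the README.

Writing either dialect is canonical (labels sorted, neighbour lists sorted),
so graphs whose labels are already in sorted order round-trip identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GraphFormatError",
    "DistrictGraph",
    "read_graph",
    "write_graph",
    "make_lattice",
    "car_precision",
    "moran_weights",
]


class GraphFormatError(ValueError):
    """Raised when a neighbours file violates the declared dialect."""


@dataclass(frozen=True)
class DistrictGraph:
    """An undirected simple graph over labelled districts.

    Parameters
    ----------
    labels : tuple of str
        District identifiers, order defines the 0-based index of each unit.
    edges : frozenset of (int, int)
        Unordered adjacency pairs, stored with the smaller index first.
    """

    labels: tuple
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        if len(set(labels)) != len(labels):
            raise GraphFormatError("duplicate district labels")
        norm = set()
        for e in self.edges:
            i, j = int(e[0]), int(e[1])
            if i == j:
                raise GraphFormatError(f"self-loop on index {i}")
            if not (0 <= i < len(labels) and 0 <= j < len(labels)):
                raise GraphFormatError(f"edge ({i},{j}) out of range")
            norm.add((min(i, j), max(i, j)))
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "edges", frozenset(norm))

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix."""
        a = np.zeros((self.n, self.n))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=1)

    def neighbors(self, i: int) -> list:
        return sorted(j for a, b in self.edges for j in ((b,) if a == i else (a,) if b == i else ()))

    def n_components(self) -> int:
        ncomp, _ = connected_components(csr_matrix(self.adjacency()), directed=False)
        return int(ncomp)


def make_lattice(rows: int, cols: int) -> DistrictGraph:
    """Rook-adjacency grid graph with labels ``r{i}c{j}`` (row-major).

    A 5x6 lattice is the stand-in map used throughout for a country of 30
    districts.
    """
    rows, cols = int(rows), int(cols)
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise ValueError("lattice needs rows*cols >= 2")
    labels = tuple(f"r{i}c{j}" for i in range(rows) for j in range(cols))
    edges = set()
    for i in range(rows):
        for j in range(cols):
            k = i * cols + j
            if j + 1 < cols:
                edges.add((k, k + 1))
            if i + 1 < rows:
                edges.add((k, k + cols))
    return DistrictGraph(labels, frozenset(edges))


def car_precision(graph: DistrictGraph) -> np.ndarray:
    """Intrinsic-CAR prior precision structure ``K = diag(degrees) - A``.

    ``K`` is the graph Laplacian: symmetric positive semidefinite with rank
    ``n - (number of connected components)`` and row sums exactly zero.
    Isolated districts yield an all-zero row/column — the CAR prior is flat
    for them and their spatial effect is carried by the unstructured term.
    """
    if graph.n < 2:
        raise ValueError("CAR precision needs at least 2 districts")
    a = graph.adjacency()
    return np.diag(a.sum(axis=1)) - a


def moran_weights(graph: DistrictGraph, style: str = "row_standardized") -> np.ndarray:
    """Spatial weight matrix for Moran statistics.

    ``binary`` returns the adjacency itself; ``row_standardized`` divides each
    nonzero row by its degree. Isolated districts get an all-zero row in
    either style (zero-lag convention, no error).
    """
    if graph.n < 2:
        raise ValueError("need at least 2 districts")
    a = graph.adjacency()
    if style == "binary":
        return a
    if style == "row_standardized":
        deg = a.sum(axis=1)
        w = a.copy()
        nz = deg > 0
        w[nz] /= deg[nz, None]
        return w
    raise ValueError(f"unknown weight style {style!r}")


def read_graph(path, dialect: str = "edge_list") -> DistrictGraph:
    """Read a district graph from ``path`` in the named dialect."""
    with open(path) as fh:
        text = fh.read()
    if dialect == "edge_list":
        return _parse_edge_list(text)
    if dialect == "gra":
        return _parse_gra(text)
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_edge_list(text: str) -> DistrictGraph:
    labels: list = []
    seen = {}
    pairs = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        toks = line.split()
        if len(toks) > 2:
            raise GraphFormatError(f"line {lineno}: expected 1 or 2 labels, got {len(toks)}")
        for t in toks:
            if t not in seen:
                seen[t] = len(labels)
                labels.append(t)
        if len(toks) == 2:
            a, b = toks
            if a == b:
                raise GraphFormatError(f"line {lineno}: self-loop on {a!r}")
            pairs.append((seen[a], seen[b]))
    if len(labels) < 1:
        raise GraphFormatError("empty edge-list file")
    return DistrictGraph(tuple(labels), frozenset((min(i, j), max(i, j)) for i, j in pairs))


def _parse_gra(text: str) -> DistrictGraph:
    lines = text.splitlines()
    if not lines:
        raise GraphFormatError("empty gra file")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise GraphFormatError("gra line 1 must be the district count") from None
    labels = []
    nbrs = []
    pos = 1
    for k in range(n):
        try:
            label = lines[pos].strip()
            count = int(lines[pos + 1].strip())
        except (IndexError, ValueError):
            raise GraphFormatError(f"malformed or truncated entry for district {k}") from None
        pos += 2
        if count < 0:
            raise GraphFormatError(f"negative neighbour count for {label!r}")
        if count == 0:
            idx = []
            # the empty neighbour line is optional for degree-0 districts
            if pos < len(lines) and not lines[pos].strip():
                pos += 1
        else:
            try:
                idx = [int(t) for t in lines[pos].split()]
            except (IndexError, ValueError):
                raise GraphFormatError(f"malformed neighbour line for {label!r}") from None
            pos += 1
        if len(idx) != count:
            raise GraphFormatError(f"{label!r}: declared {count} neighbours, listed {len(idx)}")
        labels.append(label)
        nbrs.append(idx)
    if len(set(labels)) != len(labels):
        raise GraphFormatError("duplicate labels in gra file")
    edges = set()
    for i, idx in enumerate(nbrs):
        for j in idx:
            if not 0 <= j < n:
                raise GraphFormatError(f"{labels[i]!r}: neighbour index {j} out of range")
            if j == i:
                raise GraphFormatError(f"{labels[i]!r}: self-loop")
            if i not in nbrs[j]:
                raise GraphFormatError(
                    f"asymmetric adjacency: {labels[i]!r} lists {labels[j]!r} but not conversely"
                )
            edges.add((min(i, j), max(i, j)))
    return DistrictGraph(tuple(labels), frozenset(edges))


def write_graph(graph: DistrictGraph, path, dialect: str = "edge_list") -> None:
    """Write ``graph`` canonically (sorted labels, sorted neighbour lists)."""
    order = sorted(range(graph.n), key=lambda i: graph.labels[i])
    rank = {old: new for new, old in enumerate(order)}
    labels = [graph.labels[i] for i in order]
    nbrs = [sorted(rank[j] for j in graph.neighbors(i)) for i in order]
    lines = []
    if dialect == "edge_list":
        lines.extend(labels)
        edge_lines = set()
        for i, lab in enumerate(labels):
            for j in nbrs[i]:
                a, b = sorted((lab, labels[j]))
                edge_lines.add(f"{a} {b}")
        lines.extend(sorted(edge_lines))
    elif dialect == "gra":
        lines.append(str(graph.n))
        for lab, idx in zip(labels, nbrs):
            lines.append(lab)
            lines.append(str(len(idx)))
            lines.append(" ".join(str(j) for j in idx))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
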