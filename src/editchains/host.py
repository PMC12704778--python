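"""Host graphs, canonical edge indexing, and bitmask edge subsets.

The state space of every graph edit process is the set of edge subsets of a
fixed simple undirected host graph ``H = (V, E)`` with ``n`` vertices and
``m`` edges.  Each subset is encoded as an ``m``-bit integer: bit ``i`` is
set exactly when edge ``i`` (in the canonical edge order) is present.  The
canonical order sorts edges by ``(min endpoint index, max endpoint index)``
under the vertex ordering, so bitmask state indices are reproducible across
runs and platforms.

Vertex ordering: labels consisting only of digits sort numerically and come
first; all other labels sort lexicographically after them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "EdgeSubset",
    "HostGraph",
    "build_host",
    "fixture_host",
    "read_host",
    "write_host",
    "subgraph_is_forest",
]


def _vertex_sort_key(label: str):
    if label.isdigit():
        return (0, int(label), label)
    return (1, 0, label)


@dataclass(frozen=True)
class EdgeSubset:
    """A subset of the host's edges encoded as a bitmask.

    ``bits`` must satisfy ``0 <= bits < 2**m``.  Character ``i`` of
    :meth:`bitstring` (left to right) corresponds to edge index ``i``.
    """

    bits: int
    m: int

    def __post_init__(self) -> None:
        if not (0 <= self.bits < (1 << self.m)):
            raise ValueError(f"bits {self.bits} out of range for m={self.m}")

    # -- set algebra ----------------------------------------------------
    def _check(self, other: "EdgeSubset") -> None:
        if self.m != other.m:
            raise ValueError("edge subsets belong to different hosts")

    def __or__(self, other: "EdgeSubset") -> "EdgeSubset":
        self._check(other)
        return EdgeSubset(self.bits | other.bits, self.m)

    def __and__(self, other: "EdgeSubset") -> "EdgeSubset":
        self._check(other)
        return EdgeSubset(self.bits & other.bits, self.m)

    def __xor__(self, other: "EdgeSubset") -> "EdgeSubset":
        self._check(other)
        return EdgeSubset(self.bits ^ other.bits, self.m)

    def __le__(self, other: "EdgeSubset") -> bool:
        self._check(other)
        return self.bits & ~other.bits == 0

    def __contains__(self, edge_index: int) -> bool:
        return bool((self.bits >> edge_index) & 1)

    def __iter__(self):
        return iter(self.edge_indices())

    def __len__(self) -> int:
        return self.cardinality

    @property
    def cardinality(self) -> int:
        return self.bits.bit_count()

    def edge_indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.m) if (self.bits >> i) & 1)

    # -- encodings ------------------------------------------------------
    def bitstring(self) -> str:
        return "".join("1" if (self.bits >> i) & 1 else "0" for i in range(self.m))

    @classmethod
    def from_bitstring(cls, s: str) -> "EdgeSubset":
        if set(s) - {"0", "1"}:
            raise ValueError(f"not a bitstring: {s!r}")
        bits = 0
        for i, ch in enumerate(s):
            if ch == "1":
                bits |= 1 << i
        return cls(bits, len(s))


class HostGraph:
    """A simple undirected host graph with a fixed canonical edge order.

    Construct via :func:`build_host` or :func:`fixture_host`.
    """

    def __init__(
        self,
        vertices: Sequence[str],
        edges: Sequence[tuple[int, int]],
        bipartition: Optional[tuple[frozenset, frozenset]] = None,
    ) -> None:
        self.vertices: tuple[str, ...] = tuple(vertices)
        self.edges: tuple[tuple[int, int], ...] = tuple(edges)
        self.n = len(self.vertices)
        self.m = len(self.edges)
        self.vertex_index = {v: i for i, v in enumerate(self.vertices)}
        self.bipartition = bipartition
        self._edge_index = {e: k for k, e in enumerate(self.edges)}
        self._degrees = np.zeros(self.n, dtype=int)
        self._nbhd_bits = [0] * self.n
        for k, (i, j) in enumerate(self.edges):
            self._degrees[i] += 1
            self._degrees[j] += 1
            self._nbhd_bits[i] |= 1 << k
            self._nbhd_bits[j] |= 1 << k

    # -- basic queries --------------------------------------------------
    def degree(self, v: str) -> int:
        return int(self._degrees[self.vertex_index[str(v)]])

    @property
    def degrees(self) -> np.ndarray:
        """Vertex degrees in vertex order."""
        return self._degrees.copy()

    @property
    def min_degree(self) -> int:
        """Minimum vertex degree delta(H)."""
        return int(self._degrees.min()) if self.n else 0

    def neighborhood(self, v: str) -> EdgeSubset:
        """N(v): the subset of edges incident to vertex ``v``."""
        return EdgeSubset(self._nbhd_bits[self.vertex_index[str(v)]], self.m)

    def edge_index(self, u, v) -> int:
        i, j = self.vertex_index[str(u)], self.vertex_index[str(v)]
        key = (min(i, j), max(i, j))
        if key not in self._edge_index:
            raise KeyError(f"no edge {{{u},{v}}} in host")
        return self._edge_index[key]

    def edge_label(self, k: int) -> tuple[str, str]:
        i, j = self.edges[k]
        return (self.vertices[i], self.vertices[j])

    # -- subsets ----------------------------------------------------------
    @property
    def empty_subset(self) -> EdgeSubset:
        return EdgeSubset(0, self.m)

    @property
    def full_subset(self) -> EdgeSubset:
        return EdgeSubset((1 << self.m) - 1, self.m)

    def subset(self, edges: Iterable) -> EdgeSubset:
        """Build an EdgeSubset from vertex-label pairs or edge indices."""
        bits = 0
        for e in edges:
            if isinstance(e, int):
                k = e
            else:
                k = self.edge_index(*e)
            bits |= 1 << k
        return EdgeSubset(bits, self.m)

    def as_subset(self, value) -> EdgeSubset:
        """Coerce an int bitmask, bitstring, or EdgeSubset to an EdgeSubset."""
        if isinstance(value, EdgeSubset):
            if value.m != self.m:
                raise ValueError("edge subset belongs to a different host")
            return value
        if isinstance(value, (int, np.integer)):
            return EdgeSubset(int(value), self.m)
        if isinstance(value, str):
            s = EdgeSubset.from_bitstring(value)
            if s.m != self.m:
                raise ValueError("bitstring length does not match edge count")
            return s
        raise TypeError(f"cannot interpret {value!r} as an edge subset")

    # -- identity ---------------------------------------------------------
    def __eq__(self, other) -> bool:
        return (
            isinstance(other, HostGraph)
            and self.vertices == other.vertices
            and self.edges == other.edges
        )

    def __hash__(self) -> int:
        return hash((self.vertices, self.edges))

    def __repr__(self) -> str:
        return f"HostGraph(n={self.n}, m={self.m})"


def build_host(
    edge_list: Iterable[tuple],
    bipartition: Optional[tuple[Iterable, Iterable]] = None,
) -> HostGraph:
    """Build a host graph from vertex-label pairs.

    Self-loops and duplicate (unordered) edges are rejected.  The vertex and
    edge orderings are canonical and stable across runs.
    """
    pairs = []
    labels = set()
    for u, v in edge_list:
        u, v = str(u), str(v)
        if u == v:
            raise ValueError(f"invalid edge: self-loop at {u!r}")
        pairs.append((u, v))
        labels.update((u, v))
    vertices = sorted(labels, key=_vertex_sort_key)
    index = {v: i for i, v in enumerate(vertices)}
    seen = set()
    edges = []
    for u, v in pairs:
        i, j = index[u], index[v]
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"duplicate edge {{{u},{v}}}")
        seen.add(key)
        edges.append(key)
    edges.sort()
    bip = None
    if bipartition is not None:
        left = frozenset(str(x) for x in bipartition[0])
        right = frozenset(str(x) for x in bipartition[1])
        bip = (left, right)
    return HostGraph(vertices, edges, bipartition=bip)


def fixture_host(name: str) -> HostGraph:
    """Named small hosts: ``p3``, ``c5``, ``k4``, ``kn:n``, ``knn:n,N``.

    ``p3`` is the path on three vertices (two edges); ``c5`` the cycle on
    five vertices; ``kn:n`` the complete graph; ``knn:n,N`` the complete
    bipartite graph (with the bipartition recorded on the host).
    """
    name = name.strip().lower()
    if name == "p3":
        return build_host([(1, 2), (2, 3)])
    if name == "c5":
        return build_host([(i, i % 5 + 1) for i in range(1, 6)])
    if name == "k4":
        return fixture_host("kn:4")
    if name.startswith("kn:"):
        n = int(name.split(":", 1)[1])
        if n < 2:
            raise ValueError("kn requires n >= 2")
        return build_host(
            [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]
        )
    if name.startswith("knn:"):
        parts = name.split(":", 1)[1].split(",")
        if len(parts) != 2:
            raise ValueError("knn requires two part sizes, e.g. knn:2,3")
        n, N = int(parts[0]), int(parts[1])
        if n < 1 or N < 1:
            raise ValueError("knn part sizes must be positive")
        left = [f"a{i}" for i in range(1, n + 1)]
        right = [f"b{j}" for j in range(1, N + 1)]
        return build_host(
            [(u, v) for u in left for v in right], bipartition=(left, right)
        )
    raise ValueError(f"unknown fixture name: {name!r}")


def read_host(path) -> tuple[HostGraph, Optional[np.ndarray]]:
    """Read an edge-list TSV (``u<TAB>v[<TAB>p]``).

    Returns the host and, when a third column is present, the per-edge
    probability vector aligned to the canonical edge order.
    """
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"malformed row at line {lineno}: {line!r}")
            u, v = fields[0].strip(), fields[1].strip()
            if u == v:
                raise ValueError(f"invalid edge: self-loop at line {lineno}")
            pe = None
            if len(fields) >= 3 and fields[2].strip():
                try:
                    pe = float(fields[2])
                except ValueError as exc:
                    raise ValueError(
                        f"malformed probability at line {lineno}: {fields[2]!r}"
                    ) from exc
                if not (0.0 < pe < 1.0):
                    raise ValueError(
                        f"edge probability out of (0,1) at line {lineno}: {pe}"
                    )
            rows.append((u, v, pe))
    host = build_host([(u, v) for u, v, _ in rows])
    has_p = [pe is not None for _, _, pe in rows]
    if any(has_p):
        if not all(has_p):
            raise ValueError("probability column present on some rows but not all")
        p = np.empty(host.m)
        for u, v, pe in rows:
            p[host.edge_index(u, v)] = pe
        return host, p
    return host, None


def write_host(host: HostGraph, path, p: Optional[Sequence[float]] = None) -> None:
    """Write the host as an edge-list TSV in canonical edge order."""
    if p is not None and len(p) != host.m:
        raise ValueError("probability vector length does not match edge count")
    with open(path, "w", encoding="utf-8") as fh:
        for k in range(host.m):
            u, v = host.edge_label(k)
            if p is None:
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\t{p[k]!r}\n")


def subgraph_is_forest(host: HostGraph, subset) -> bool:
    """True when the edge subset induces an acyclic subgraph of the host."""
    bits = host.as_subset(subset).bits
    parent = list(range(host.n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for k in range(host.m):
        if (bits >> k) & 1:
            i, j = host.edges[k]
            ri, rj = find(i), find(j)
            if ri == rj:
                return False
            parent[ri] = rj
    return True
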