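"""Areal adjacency structures for conditional-autoregressive modelling.

A :class:`RegionGraph` is the backbone of every spatial prior in this
package: a set of labelled areal units with a symmetric binary contiguity
matrix ``W`` and the neighbour-count vector ``D`` (row sums of ``W``).
Intrinsic CAR/MCAR priors use the combinatorial Laplacian ``D - W``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = ["RegionGraph", "read_adjacency", "study7_graph", "STUDY7_PROVINCES"]

#: The seven provinces surveyed in every CHNS wave, west to east.
STUDY7_PROVINCES = (
    "Jiangsu",
    "Shandong",
    "Henan",
    "Hubei",
    "Hunan",
    "Guangxi",
    "Guizhou",
)

# First-order contiguity among the seven study provinces only (pairs sharing a
# land border on the administrative map, restricted to surveyed provinces).
_STUDY7_EDGES = (
    ("Shandong", "Jiangsu"),
    ("Shandong", "Henan"),
    ("Henan", "Hubei"),
    ("Hubei", "Hunan"),
    ("Hunan", "Guangxi"),
    ("Hunan", "Guizhou"),
    ("Guangxi", "Guizhou"),
)


@dataclass(frozen=True)
class RegionGraph:
    """Labelled areal units with a symmetric binary adjacency matrix.

    Parameters
    ----------
    region_ids
        Ordered unique labels of the ``N`` areal units.
    W
        ``N x N`` symmetric 0/1 matrix with a zero diagonal; ``W[i, j] = 1``
        iff regions ``i`` and ``j`` are neighbours.
    """

    region_ids: tuple[str, ...]
    W: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ids = tuple(str(r) for r in self.region_ids)
        object.__setattr__(self, "region_ids", ids)
        W = np.asarray(self.W)
        if len(set(ids)) != len(ids):
            raise ValueError("region_ids must be unique")
        n = len(ids)
        if W.shape != (n, n):
            raise ValueError(f"W must be {n}x{n}, got {W.shape}")
        if not np.isin(W, (0, 1)).all():
            raise ValueError("W entries must be 0 or 1")
        if np.any(np.diag(W) != 0):
            raise ValueError("W must have a zero diagonal (no self-loops)")
        if not np.array_equal(W, W.T):
            raise ValueError("W must be symmetric")
        object.__setattr__(self, "W", W.astype(np.int64))

    # -- basic derived quantities -------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def D(self) -> np.ndarray:
        """Neighbour counts, ``D_i = sum_j W_ij``."""
        return self.W.sum(axis=1)

    @property
    def laplacian(self) -> np.ndarray:
        """Combinatorial Laplacian ``D - W`` (precision kernel of the ICAR)."""
        return np.diag(self.D) - self.W

    @property
    def edges(self) -> list[tuple[int, int]]:
        """Unique undirected edges as index pairs ``(i, j)`` with ``i < j``."""
        ii, jj = np.nonzero(np.triu(self.W))
        return list(zip(ii.tolist(), jj.tolist()))

    def index_of(self, region: str) -> int:
        return self.region_ids.index(str(region))

    def degree_of(self, region: str) -> int:
        return int(self.D[self.index_of(region)])

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())

    def validate_for_car(self) -> None:
        """Reject graphs unusable under an intrinsic CAR prior."""
        if self.n_regions < 2:
            raise ValueError("CAR prior needs at least 2 regions")
        isolated = [r for r, d in zip(self.region_ids, self.D) if d == 0]
        if isolated:
            raise ValueError(f"isolated region(s) not allowed in a CAR prior: {isolated}")
        if not self.is_connected():
            raise ValueError("graph must be connected for the intrinsic CAR prior")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.region_ids)
        for i, j in self.edges:
            g.add_edge(self.region_ids[i], self.region_ids[j])
        return g

    def coloring(self) -> list[np.ndarray]:
        """Partition region indices into independent sets (greedy colouring).

        Within one colour class no two regions are neighbours, so single-site
        Metropolis updates of a Markov random field can be proposed and
        accepted in parallel across the class.
        """
        colors = nx.greedy_color(self.to_networkx(), strategy="largest_first")
        k = max(colors.values()) + 1 if colors else 0
        out = []
        for c in range(k):
            members = [i for i, r in enumerate(self.region_ids) if colors[r] == c]
            out.append(np.asarray(members, dtype=np.int64))
        return out

    # -- interchange formats -------------------------------------------------
    def to_geobugs(self) -> dict[str, list[int]]:
        """Adjacency in the BUGS-era triple (num, adj, sumNumNeigh).

        ``num`` holds the neighbour count per region (in ``region_ids``
        order), ``adj`` the concatenated 1-based neighbour indices, and
        ``sumNumNeigh`` the total length of ``adj``.
        """
        num = [int(d) for d in self.D]
        adj: list[int] = []
        for i in range(self.n_regions):
            adj.extend((np.nonzero(self.W[i])[0] + 1).tolist())
        return {"num": num, "adj": adj, "sumNumNeigh": [int(sum(num))]}

    def write_edge_list(self, path: str | Path) -> None:
        """Write the whitespace-separated edge-list format read back by
        :func:`read_adjacency`."""
        lines = [f"{self.region_ids[i]} {self.region_ids[j]}" for i, j in self.edges]
        Path(path).write_text("\n".join(lines) + "\n")


def read_adjacency(path: str | Path) -> RegionGraph:
    """Read an edge list ("regionA regionB" per line) into a RegionGraph.

    Region labels are collected in first-appearance order; duplicate edges
    collapse; blank lines are ignored.  A self-loop line is an error.
    """
    path = Path(path)
    text = path.read_text()
    order: list[str] = []
    seen: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise ValueError(f"{path}:{lineno}: expected two region labels, got {raw!r}")
        a, b = tokens
        if a == b:
            raise ValueError(f"{path}:{lineno}: self-loop {a!r}-{b!r} is not allowed")
        for r in (a, b):
            if r not in seen:
                seen.add(r)
                order.append(r)
        pairs.append((a, b))
    if not order:
        raise ValueError(f"{path}: no edges found")
    idx = {r: i for i, r in enumerate(order)}
    W = np.zeros((len(order), len(order)), dtype=np.int64)
    for a, b in pairs:
        W[idx[a], idx[b]] = 1
        W[idx[b], idx[a]] = 1
    return RegionGraph(tuple(order), W)


def study7_graph() -> RegionGraph:
    """Contiguity graph of the seven CHNS study provinces.

    Edges are land borders between surveyed provinces only; borders with
    non-surveyed provinces are not represented.
    """
    idx = {r: i for i, r in enumerate(STUDY7_PROVINCES)}
    W = np.zeros((7, 7), dtype=np.int64)
    for a, b in _STUDY7_EDGES:
        W[idx[a], idx[b]] = 1
        W[idx[b], idx[a]] = 1
    return RegionGraph(STUDY7_PROVINCES, W)
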