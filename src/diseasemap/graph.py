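"""Binary first-order contiguity structure for areal models.

The same graph object feeds both the intrinsic CAR (ICAR) prior and the
global Moran's I statistic: weights are strictly binary (w_ij = 1 iff
regions i and j share a boundary), never row-standardised, and the
aggregate weight S0 = sum_ij w_ij equals twice the number of undirected
edges.  Region order is fixed at construction; every downstream vector
(counts, covariates, latent fields) is aligned by position against
``region_ids``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc


class GraphInputError(ValueError):
    """Raised for malformed adjacency input (self-loop, unknown/duplicate id)."""


@dataclass(frozen=True)
class RegionGraph:
    """Undirected binary contiguity graph over an ordered set of regions.

    Parameters
    ----------
    region_ids
        Ordered unique region identifiers; defines the index space shared
        with all aligned vectors.
    edge_i, edge_j
        Integer position arrays of equal length, one undirected edge per
        entry, with ``edge_i[k] < edge_j[k]`` and no duplicates.
    """

    region_ids: tuple
    edge_i: np.ndarray
    edge_j: np.ndarray
    _index: dict = field(repr=False, default=None)
    _cache: dict = field(repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "_index", {r: k for k, r in enumerate(self.region_ids)})
        object.__setattr__(self, "_cache", {})

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_i)

    @property
    def s0(self) -> int:
        """Aggregate weight sum_i sum_j w_ij (binary symmetric => 2 |E|)."""
        return 2 * self.n_edges

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_regions, dtype=int)
        np.add.at(deg, self.edge_i, 1)
        np.add.at(deg, self.edge_j, 1)
        return deg

    @property
    def islands(self) -> np.ndarray:
        """Positions of degree-0 regions (no CAR conditional is defined for them)."""
        return np.flatnonzero(self.degrees == 0)

    def neighbor_sets(self) -> list[set]:
        out = [set() for _ in range(self.n_regions)]
        for a, b in zip(self.edge_i, self.edge_j):
            out[a].add(int(b))
            out[b].add(int(a))
        return out

    def index_of(self, region_id) -> int:
        try:
            return self._index[region_id]
        except KeyError:
            raise GraphInputError(f"unknown region id: {region_id!r}") from None

    def adjacency_matrix(self) -> csr_matrix:
        n = self.n_regions
        rows = np.concatenate([self.edge_i, self.edge_j])
        cols = np.concatenate([self.edge_j, self.edge_i])
        return csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))

    def connected_components(self) -> np.ndarray:
        """Component label per region (0..c-1); isolated regions get their own label."""
        if "components" not in self._cache:
            n_comp, labels = _cc(self.adjacency_matrix(), directed=False)
            self._cache["components"] = labels
        return self._cache["components"]

    @property
    def n_components(self) -> int:
        return int(self.connected_components().max()) + 1 if self.n_regions else 0

    def validate(self) -> None:
        """Check structural invariants; raise GraphInputError on violation."""
        if len(set(self.region_ids)) != len(self.region_ids):
            raise GraphInputError("duplicate region ids")
        if len(self.edge_i) != len(self.edge_j):
            raise GraphInputError("edge arrays of unequal length")
        if np.any(self.edge_i == self.edge_j):
            raise GraphInputError("self-loop present")
        if self.n_edges:
            if self.edge_i.min() < 0 or self.edge_j.max() >= self.n_regions:
                raise GraphInputError("edge endpoint outside region index range")
            pairs = set(zip(self.edge_i.tolist(), self.edge_j.tolist()))
            if len(pairs) != self.n_edges:
                raise GraphInputError("duplicate edges")
            if any(a >= b for a, b in pairs):
                raise GraphInputError("edges not stored in canonical (i < j) order")
        if self.s0 != 2 * self.n_edges:
            raise GraphInputError("s0 inconsistent with edge count")

    def greedy_coloring(self) -> np.ndarray:
        """Proper vertex colouring (neighbors never share a colour).

        Used to group regions into blocks whose ICAR full conditionals are
        mutually independent, so single-site updates can run vectorised.
        """
        nbrs = self.neighbor_sets()
        order = np.argsort(-self.degrees, kind="stable")
        color = np.full(self.n_regions, -1, dtype=int)
        for i in order:
            used = {color[j] for j in nbrs[i] if color[j] >= 0}
            c = 0
            while c in used:
                c += 1
            color[i] = c
        return color


def build_adjacency(edge_records, region_ids) -> RegionGraph:
    """Build a validated RegionGraph from an undirected edge list.

    Parameters
    ----------
    edge_records
        Iterable of (id_a, id_b) pairs; duplicates and reversed duplicates
        are merged.  Self-loops are rejected.
    region_ids
        Ordered unique identifiers; every edge endpoint must be among them.
        Regions appearing in no edge are kept as islands.
    """
    region_ids = tuple(region_ids)
    if not region_ids:
        raise GraphInputError("region_ids is empty")
    if len(set(region_ids)) != len(region_ids):
        dupes = pd.Series(region_ids).value_counts()
        dupes = dupes[dupes > 1].index.tolist()
        raise GraphInputError(f"duplicate region ids: {dupes}")
    index = {r: k for k, r in enumerate(region_ids)}
    pairs = set()
    for a, b in edge_records:
        if a not in index:
            raise GraphInputError(f"unknown region id in edge: {a!r}")
        if b not in index:
            raise GraphInputError(f"unknown region id in edge: {b!r}")
        ia, ib = index[a], index[b]
        if ia == ib:
            raise GraphInputError(f"self-loop on region {a!r}")
        pairs.add((min(ia, ib), max(ia, ib)))
    if pairs:
        arr = np.array(sorted(pairs), dtype=int)
        ei, ej = arr[:, 0], arr[:, 1]
    else:
        ei = ej = np.zeros(0, dtype=int)
    g = RegionGraph(region_ids, ei, ej)
    g.validate()
    return g


def make_lattice(nrows: int, ncols: int) -> RegionGraph:
    """Rook-contiguity grid graph with nrows x ncols regions (ids 1..n)."""
    if nrows < 1 or ncols < 1:
        raise GraphInputError("lattice dimensions must be >= 1")
    ids = tuple(range(1, nrows * ncols + 1))
    edges = []
    for r in range(nrows):
        for c in range(ncols):
            i = r * ncols + c + 1
            if c + 1 < ncols:
                edges.append((i, i + 1))
            if r + 1 < nrows:
                edges.append((i, i + ncols))
    return build_adjacency(edges, ids)


def read_edge_csv(path, region_ids=None) -> RegionGraph:
    """Read an undirected edge-list CSV with columns ``region_i,region_j``.

    When ``region_ids`` is None, the region set is the sorted union of the
    endpoints (islands cannot be represented without an explicit id list).
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("region_i", "region_j"):
        if col not in df.columns:
            raise GraphInputError(f"edge CSV missing column {col!r}")
    records = list(zip(df["region_i"], df["region_j"]))
    if region_ids is None:
        region_ids = sorted(set(df["region_i"]) | set(df["region_j"]))
    else:
        # CSV endpoints are text; map them back onto the caller's id type
        back = {str(r): r for r in region_ids}
        try:
            records = [(back[a], back[b]) for a, b in records]
        except KeyError as missing:
            raise GraphInputError(f"unknown region id in edge CSV: {missing.args[0]!r}") from None
    return build_adjacency(records, region_ids)


def write_edge_csv(graph: RegionGraph, path) -> None:
    ids = graph.region_ids
    pd.DataFrame(
        {"region_i": [ids[a] for a in graph.edge_i],
         "region_j": [ids[b] for b in graph.edge_j]}
    ).to_csv(path, index=False)


def read_gal(path) -> RegionGraph:
    """Read a GAL-format spatial-weights file.

    Layout: a header line whose last token is the region count n, then for
    each region a line ``id k`` followed by a line of k neighbor ids.
    """
    with open(path) as fh:
        tokens_by_line = [line.split() for line in fh if line.strip()]
    header = tokens_by_line[0]
    n = int(header[-1]) if len(header) == 1 else int(header[1])
    region_ids, edges = [], []
    pos = 1
    for _ in range(n):
        rid, k = tokens_by_line[pos][0], int(tokens_by_line[pos][1])
        region_ids.append(rid)
        nbrs = tokens_by_line[pos + 1] if k > 0 else []
        if len(nbrs) != k:
            raise GraphInputError(f"GAL record for {rid!r}: expected {k} neighbors, got {len(nbrs)}")
        edges.extend((rid, nb) for nb in nbrs)
        pos += 2 if k > 0 else 1
        # a region with 0 neighbors may or may not carry an (empty) neighbor line
        if k == 0 and pos < len(tokens_by_line) and len(tokens_by_line[pos]) == 0:
            pos += 1
    return build_adjacency(edges, region_ids)
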