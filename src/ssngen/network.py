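"""Dendritic stream networks: topology, hydrologic distances and flow weights.

A stream network is a forest of rooted trees: every segment drains into at
most one downstream segment, and each basin has a single outlet segment.
Two quantities drive the spatial weighting used by tail-up covariance
models:

* the *proportional influence* (PI) of a segment at its confluence — its
  share of cumulative drainage area among the segments converging there;
* the *additive function value* (AFV) — the product of PIs encountered on
  the way down to the outlet, so ``afv(outlet) = 1`` and
  ``afv(s) = pi(s) * afv(downstream(s))``.

Tail-up weights between flow-connected points are ``sqrt(afv_up/afv_down)``.

Hydrologic (in-stream) distances between two points decompose into the two
downstream legs to their common junction: for flow-connected pairs one leg
is zero and the total stream distance is ``h``; for flow-unconnected pairs
both legs ``a <= b`` are positive.  Points in different basins are at
infinite hydrologic distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NetworkValidationError",
    "Segment",
    "StreamNetwork",
    "NetworkPoint",
    "DistanceSet",
    "build_network",
    "read_network_csv",
    "read_sites_csv",
    "points_from_sites",
    "hydrologic_distances",
    "hydrologic_index",
]


class NetworkValidationError(ValueError):
    """Raised when an edge table violates the dendritic-network contract."""


@dataclass
class Segment:
    segment_id: str
    downstream_id: str | None
    length: float
    area: float
    precip: float
    pi: float = 1.0
    afv: float = 1.0


@dataclass
class StreamNetwork:
    """Validated rooted forest of stream segments with flow weights."""

    segments: dict[str, Segment]
    # derived topology, filled by build_network
    children: dict[str, list[str]] = field(default_factory=dict)
    root_of: dict[str, str] = field(default_factory=dict)      # segment -> outlet id
    depth: dict[str, float] = field(default_factory=dict)      # m from seg's downstream end to outlet
    cum_area: dict[str, float] = field(default_factory=dict)   # km², segment + all ancestors
    _path_cache: dict[str, tuple[str, ...]] = field(default_factory=dict, repr=False)

    @property
    def roots(self) -> list[str]:
        return sorted({r for r in self.root_of.values()})

    def path_to_root(self, segment_id: str) -> tuple[str, ...]:
        """Segment ids from ``segment_id`` (inclusive) down to the outlet."""
        cached = self._path_cache.get(segment_id)
        if cached is not None:
            return cached
        path = []
        s = segment_id
        while s is not None:
            path.append(s)
            s = self.segments[s].downstream_id
        out = tuple(path)
        self._path_cache[segment_id] = out
        return out

    def upstream_set(self, segment_id: str) -> set[str]:
        """All segments draining through ``segment_id``, itself included."""
        out, stack = set(), [segment_id]
        while stack:
            s = stack.pop()
            if s not in out:
                out.add(s)
                stack.extend(self.children.get(s, ()))
        return out

    def diameter(self) -> float:
        """Largest in-stream distance between two points of one basin (m)."""
        # two deepest leaf tips joined at the outlet bounds it; exact enough
        # for range bounds: use the two largest tip depths per basin.
        best = 0.0
        tips: dict[str, list[float]] = {}
        for sid, seg in self.segments.items():
            d = self.depth[sid] + seg.length
            tips.setdefault(self.root_of[sid], []).append(d)
        for ds in tips.values():
            ds.sort(reverse=True)
            best = max(best, ds[0] + (ds[1] if len(ds) > 1 else 0.0))
        return best

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "segment_id": s.segment_id,
                "downstream_id": s.downstream_id if s.downstream_id is not None else "",
                "length_m": s.length,
                "area_km2": s.area,
                "precip_mm": s.precip,
                "pi": s.pi,
                "afv": s.afv,
            }
            for s in self.segments.values()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class NetworkPoint:
    """A georeferenced observation located on a stream segment.

    ``offset`` is measured upstream from the segment's downstream end, so
    offset 0 is the segment mouth and offset == length is its upstream tip.
    """

    point_id: str
    segment_id: str
    offset: float
    x: float
    y: float
    level: str = "population"


@dataclass
class DistanceSet:
    """Pairwise hydrologic/Euclidean structure for a set of network points.

    ``D[i, j]`` is the downstream-only distance from point *i* to the first
    point of *j*'s downstream path (their common junction); it is 0 when
    *j* lies downstream of *i* and ``inf`` across basins.  Total stream
    distance is ``D + D.T``; the flow-unconnected legs are
    ``a = min(D[i,j], D[j,i])`` and ``b = max(...)``.
    """

    ids: list[str]
    D: np.ndarray
    E: np.ndarray
    connected: np.ndarray
    same_basin: np.ndarray
    W: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def h(self) -> np.ndarray:
        """Total stream distance (inf across basins)."""
        return self.D + self.D.T

    @property
    def a(self) -> np.ndarray:
        return np.minimum(self.D, self.D.T)

    @property
    def b(self) -> np.ndarray:
        return np.maximum(self.D, self.D.T)

    def subset(self, idx: np.ndarray) -> "DistanceSet":
        ix = np.asarray(idx)
        return DistanceSet(
            ids=[self.ids[i] for i in ix],
            D=self.D[np.ix_(ix, ix)],
            E=self.E[np.ix_(ix, ix)],
            connected=self.connected[np.ix_(ix, ix)],
            same_basin=self.same_basin[np.ix_(ix, ix)],
            W=self.W[np.ix_(ix, ix)],
        )

    def write_tsv(self, prefix) -> None:
        """Write D, E and W as labelled TSV matrices ``<prefix>_{D,E,W}.tsv``."""
        for name, m in (("D", self.D), ("E", self.E), ("W", self.W)):
            pd.DataFrame(m, index=self.ids, columns=self.ids).to_csv(
                f"{prefix}_{name}.tsv", sep="\t"
            )


def build_network(edge_table: pd.DataFrame) -> StreamNetwork:
    """Validate an edge table and compute PI and AFV flow weights.

    Expects columns ``segment_id, downstream_id, length, area, precip``
    (the ``_m/_km2/_mm`` suffixed aliases of the CSV layout are accepted).
    Outlets carry an empty/NaN downstream id.
    """
    tab = edge_table.rename(
        columns={"length_m": "length", "area_km2": "area", "precip_mm": "precip"}
    )
    required = ["segment_id", "downstream_id", "length", "area", "precip"]
    missing = [c for c in required if c not in tab.columns]
    if missing:
        raise NetworkValidationError(f"edge table missing columns: {missing}")

    segs: dict[str, Segment] = {}
    for _, row in tab.iterrows():
        sid = str(row["segment_id"])
        if sid in segs:
            raise NetworkValidationError(f"duplicate segment id: {sid!r}")
        did = row["downstream_id"]
        did = None if (pd.isna(did) or str(did) == "") else str(did)
        length = float(row["length"])
        if not length > 0:
            raise NetworkValidationError(f"non-positive length on segment {sid!r}")
        area = float(row["area"])
        precip = float(row["precip"])
        if area < 0 or precip < 0:
            raise NetworkValidationError(f"negative area/precip on segment {sid!r}")
        segs[sid] = Segment(sid, did, length, area, precip)

    for s in segs.values():
        if s.downstream_id is not None and s.downstream_id not in segs:
            raise NetworkValidationError(
                f"segment {s.segment_id!r} drains to unknown segment {s.downstream_id!r}"
            )

    g = nx.DiGraph()
    g.add_nodes_from(segs)
    g.add_edges_from(
        (s.segment_id, s.downstream_id) for s in segs.values() if s.downstream_id
    )
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        raise NetworkValidationError(f"cycle detected through segment {cyc[0][0]!r}")

    net = StreamNetwork(segments=segs)
    net.children = {sid: [] for sid in segs}
    for s in segs.values():
        if s.downstream_id is not None:
            net.children[s.downstream_id].append(s.segment_id)

    # upstream-to-downstream order: reversed flow direction topological sort
    order = list(nx.topological_sort(g))  # upstream before downstream

    cum = {}
    for sid in order:
        cum[sid] = segs[sid].area + sum(cum[c] for c in net.children[sid])
    net.cum_area = cum

    # PI: share of cumulative area among segments converging at a confluence
    for sid, kids in net.children.items():
        total = sum(cum[c] for c in kids)
        for c in kids:
            segs[c].pi = cum[c] / total if total > 0 else 1.0 / len(kids)
    for s in segs.values():
        if s.downstream_id is None:
            s.pi = 1.0

    # AFV and depth by downstream->upstream recursion from each outlet
    for sid in reversed(order):
        s = segs[sid]
        if s.downstream_id is None:
            s.afv = 1.0
            net.depth[sid] = 0.0
            net.root_of[sid] = sid
        else:
            down = segs[s.downstream_id]
            s.afv = s.pi * down.afv
            net.depth[sid] = net.depth[down.segment_id] + down.length
            net.root_of[sid] = net.root_of[down.segment_id]
    return net


def read_network_csv(path) -> StreamNetwork:
    """Read ``segment_id,downstream_id,length_m,area_km2,precip_mm`` CSV."""
    tab = pd.read_csv(path, dtype={"segment_id": str, "downstream_id": str})
    return build_network(tab)


def read_sites_csv(path) -> pd.DataFrame:
    """Read a sites table: ``point_id,segment_id,offset_m,x,y,population[,covariates]``."""
    sites = pd.read_csv(path, dtype={"point_id": str, "segment_id": str, "population": str})
    required = ["point_id", "segment_id", "offset_m", "x", "y"]
    missing = [c for c in required if c not in sites.columns]
    if missing:
        raise ValueError(f"sites file missing columns: {missing}")
    return sites


def points_from_sites(sites: pd.DataFrame, level: str = "population") -> list[NetworkPoint]:
    return [
        NetworkPoint(
            point_id=str(r["point_id"]),
            segment_id=str(r["segment_id"]),
            offset=float(r["offset_m"]),
            x=float(r["x"]),
            y=float(r["y"]),
            level=level,
        )
        for _, r in sites.iterrows()
    ]


def _locate(net: StreamNetwork, p: NetworkPoint) -> None:
    seg = net.segments.get(p.segment_id)
    if seg is None:
        raise NetworkValidationError(
            f"point {p.point_id!r} references unknown segment {p.segment_id!r}"
        )
    if not (0.0 <= p.offset <= seg.length + 1e-9):
        raise NetworkValidationError(
            f"point {p.point_id!r} offset {p.offset} outside segment "
            f"{p.segment_id!r} of length {seg.length}"
        )


def hydrologic_distances(net: StreamNetwork, points: list[NetworkPoint]) -> DistanceSet:
    """Pairwise hydrologic and Euclidean structure for ``points``.

    For each ordered pair, ``D[i, j]`` is the distance from *i* downstream
    to the common junction with *j* (0 when *j* is downstream of *i*); the
    pair is flow-connected iff one of the two legs is 0.  Tail-up weights
    are ``sqrt(afv_upstream / afv_downstream)`` for flow-connected pairs,
    1 on the diagonal and 0 elsewhere.
    """
    for p in points:
        _locate(net, p)
    n = len(points)
    D = np.zeros((n, n))
    E = np.zeros((n, n))
    connected = np.zeros((n, n), dtype=bool)
    same_basin = np.zeros((n, n), dtype=bool)
    W = np.zeros((n, n))

    dtr = np.array([net.depth[p.segment_id] + p.offset for p in points])
    paths = [net.path_to_root(p.segment_id) for p in points]
    path_sets = [set(pth) for pth in paths]
    roots = [net.root_of[p.segment_id] for p in points]
    afv = np.array([net.segments[p.segment_id].afv for p in points])
    xy = np.array([[p.x, p.y] for p in points])

    dxy = xy[:, None, :] - xy[None, :, :]
    E[:] = np.sqrt((dxy**2).sum(axis=-1))

    np.fill_diagonal(connected, True)
    np.fill_diagonal(same_basin, True)
    np.fill_diagonal(W, 1.0)

    for i in range(n):
        for j in range(i + 1, n):
            if roots[i] != roots[j]:
                D[i, j] = D[j, i] = math.inf
                continue
            same_basin[i, j] = same_basin[j, i] = True
            si, sj = points[i].segment_id, points[j].segment_id
            if si == sj:
                dij, dji = max(0.0, dtr[i] - dtr[j]), max(0.0, dtr[j] - dtr[i])
            elif sj in path_sets[i]:   # j's segment strictly downstream of i's
                dij, dji = dtr[i] - dtr[j], 0.0
            elif si in path_sets[j]:
                dij, dji = 0.0, dtr[j] - dtr[i]
            else:
                # first common segment on i's downstream path; junction at its top
                c = next(s for s in paths[i] if s in path_sets[j])
                jun = net.depth[c] + net.segments[c].length
                dij, dji = dtr[i] - jun, dtr[j] - jun
            D[i, j], D[j, i] = dij, dji
            if min(dij, dji) <= 0.0:
                connected[i, j] = connected[j, i] = True
                lo, hi = min(afv[i], afv[j]), max(afv[i], afv[j])
                W[i, j] = W[j, i] = math.sqrt(lo / hi) if hi > 0 else 0.0
    return DistanceSet(
        ids=[p.point_id for p in points],
        D=D, E=E, connected=connected, same_basin=same_basin, W=W,
    )


def hydrologic_index(net: StreamNetwork, point: NetworkPoint) -> float:
    """Precipitation-weighted drainage area DA at ``point`` (km²·m).

    Sums ``area × precip`` over the point's segment and every upstream
    segment, with precipitation converted from mm to m so the index stays
    O(1–10³).  DA is non-decreasing downstream along any flow path and is
    a surrogate for total discharge.
    """
    _locate(net, point)
    up = net.upstream_set(point.segment_id)
    return sum(net.segments[s].area * net.segments[s].precip / 1000.0 for s in up)
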