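"""Queen-contiguity neighbor structure over areal units.

Two areal units (counties, tracts, ...) are *queen* neighbors when their
boundaries share at least one point — an edge or a single corner — regardless
of the length of the shared border.  The graph is undirected, has no
self-loops, and by default every unit must have at least one neighbor,
because the downstream pairwise-difference model is defined only for units
with non-empty neighbor sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

try:
    import shapely
    from shapely.geometry import shape as _geojson_shape
    from shapely.geometry.base import BaseGeometry
    from shapely.strtree import STRtree
except ImportError:  # pragma: no cover - shapely is a hard dependency
    shapely = None


class IsolatedUnitError(ValueError):
    """A unit has zero neighbors, which the difference model cannot accept."""


@dataclass(frozen=True)
class AreaUnit:
    """One areal unit (e.g. a county)."""

    id: str
    name: str = ""
    geometry_ref: object | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("unit id must be non-empty")


@dataclass
class AdjacencyGraph:
    """Symmetric neighbor structure over areal units.

    ``neighbors[s]`` is the neighbor set omega_s of unit ``s``; its size is
    N_s, the neighbor count entering the conditional-autoregressive prior.
    """

    units: tuple[AreaUnit, ...]
    neighbors: dict[str, frozenset[str]] = field(repr=False)

    def __post_init__(self) -> None:
        ids = [u.id for u in self.units]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate unit ids: {dup}")
        idset = set(ids)
        if set(self.neighbors) != idset:
            raise ValueError("neighbor mapping keys must equal the unit id set")
        for s, nbrs in self.neighbors.items():
            if s in nbrs:
                raise ValueError(f"self-loop at unit {s!r}")
            for t in nbrs:
                if t not in idset:
                    raise ValueError(f"neighbor {t!r} of {s!r} is not a unit")
                if s not in self.neighbors[t]:
                    raise ValueError(f"asymmetric edge {s!r} -> {t!r}")

    # -- basic accessors ---------------------------------------------------
    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(u.id for u in self.units)

    def __len__(self) -> int:
        return len(self.units)

    def degree(self, unit_id: str) -> int:
        return len(self.neighbors[unit_id])

    def edges(self) -> list[tuple[str, str]]:
        """Canonical sorted list of undirected edges (a < b)."""
        out = set()
        for s, nbrs in self.neighbors.items():
            for t in nbrs:
                out.add((s, t) if s < t else (t, s))
        return sorted(out)

    def ordered_pairs(self) -> list[tuple[str, str]]:
        """All ordered adjacent pairs (index, neighbor), one row each."""
        order = {u.id: k for k, u in enumerate(self.units)}
        return [
            (s, t)
            for s in self.ids
            for t in sorted(self.neighbors[s], key=order.__getitem__)
        ]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.ids)
        g.add_edges_from(self.edges())
        return g

    def n_components(self) -> int:
        return nx.number_connected_components(self.to_networkx())

    def validate_min_degree(self) -> None:
        isolated = sorted(s for s, nbrs in self.neighbors.items() if not nbrs)
        if isolated:
            raise IsolatedUnitError(
                f"units with zero neighbors: {isolated}; the pairwise model "
                "requires every unit to have at least one neighbor "
                "(pass allow_isolates=True to keep them)"
            )

    def write_edge_list(self, path) -> None:
        """Write the canonical sorted edge list (reproducible output)."""
        with open(path, "w") as fh:
            fh.write("# adjdiff edge list: one undirected edge per line\n")
            for a, b in self.edges():
                fh.write(f"{a} {b}\n")


def _build(units: Sequence[AreaUnit], edge_iter: Iterable[tuple[str, str]],
           allow_isolates: bool) -> AdjacencyGraph:
    nbrs: dict[str, set[str]] = {u.id: set() for u in units}
    for a, b in edge_iter:
        nbrs[a].add(b)
        nbrs[b].add(a)
    g = AdjacencyGraph(
        units=tuple(units),
        neighbors={s: frozenset(v) for s, v in nbrs.items()},
    )
    if not allow_isolates:
        g.validate_min_degree()
    return g


# ---------------------------------------------------------------------------
# construction from polygons
# ---------------------------------------------------------------------------

def build_from_polygons(
    polygons: Mapping[str, "BaseGeometry"],
    names: Mapping[str, str] | None = None,
    *,
    snap_tolerance: float = 0.0,
    allow_isolates: bool = False,
) -> AdjacencyGraph:
    """Queen-contiguity graph from per-unit boundary polygons.

    Parameters
    ----------
    polygons
        Mapping unit id -> shapely geometry.  Two units are neighbors iff
        their geometries intersect in at least one point (queen rule).
    snap_tolerance
        If > 0, boundaries within this distance are treated as touching,
        for noisy digitized boundaries.  Default 0 (exact coordinates).
    allow_isolates
        Keep units with zero neighbors instead of rejecting them.
    """
    if not polygons:
        raise ValueError("no polygons supplied")
    ids = list(polygons)
    geoms = []
    for uid in ids:
        geom = polygons[uid]
        if geom is None or geom.is_empty:
            raise ValueError(f"empty geometry for unit {uid!r}")
        if not geom.is_valid:
            raise ValueError(f"invalid geometry for unit {uid!r}")
        geoms.append(geom)

    tree = STRtree(geoms)
    if snap_tolerance > 0:
        pairs = tree.query(geoms, predicate="dwithin", distance=snap_tolerance)
    else:
        pairs = tree.query(geoms, predicate="intersects")
    edges = [
        (ids[int(i)], ids[int(j)]) for i, j in zip(*pairs) if int(i) != int(j)
    ]
    units = [
        AreaUnit(uid, (names or {}).get(uid, uid), geometry_ref=polygons[uid])
        for uid in ids
    ]
    return _build(units, edges, allow_isolates)


def read_geojson(path, id_property: str = "id", name_property: str | None = None):
    """Read a GeoJSON FeatureCollection into an ``{id: geometry}`` mapping.

    Returns ``(polygons, names)`` suitable for :func:`build_from_polygons`.
    The unit id is taken from ``properties[id_property]`` (or the feature
    ``id`` member when the property is absent).
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    polygons: dict[str, BaseGeometry] = {}
    names: dict[str, str] = {}
    for feat in doc["features"]:
        props = feat.get("properties") or {}
        uid = props.get(id_property, feat.get("id"))
        if uid is None:
            raise ValueError(f"feature without {id_property!r} property")
        uid = str(uid)
        if uid in polygons:
            raise ValueError(f"duplicate unit id {uid!r} in GeoJSON")
        polygons[uid] = _geojson_shape(feat["geometry"])
        if name_property and name_property in props:
            names[uid] = str(props[name_property])
    return polygons, names


# ---------------------------------------------------------------------------
# construction from edge lists
# ---------------------------------------------------------------------------

def read_edge_list(
    path,
    roster: Sequence[str] | None = None,
    *,
    allow_isolates: bool = False,
) -> AdjacencyGraph:
    """Read a plain-text edge list into an :class:`AdjacencyGraph`.

    Dialect: two ids per line, whitespace- or comma-separated; lines starting
    with ``#`` are comments.  Edges are symmetrized and duplicates collapsed.
    When ``roster`` is given it fixes the unit set (and ordering); ids in the
    file but absent from the roster are an error.  Without a roster the unit
    set is the union of ids seen, in first-appearance order.
    """
    edges: list[tuple[str, str]] = []
    seen: dict[str, None] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected two ids, got {line!r}")
            a, b = parts
            if a == b:
                raise ValueError(f"line {lineno}: self-loop on {a!r}")
            seen.setdefault(a)
            seen.setdefault(b)
            edges.append((a, b))
    if roster is not None:
        roster_set = set(roster)
        stray = sorted(set(seen) - roster_set)
        if stray:
            raise ValueError(f"edge-list ids not in roster: {stray}")
        ids: Sequence[str] = roster
    else:
        ids = list(seen)
    units = [AreaUnit(uid, uid) for uid in ids]
    return _build(units, edges, allow_isolates)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def neighbor_stats(graph: AdjacencyGraph) -> dict[str, float]:
    """Mean / min / max neighbor counts over units (plus totals)."""
    if len(graph) == 0:
        raise ValueError("empty graph")
    deg = np.array([graph.degree(s) for s in graph.ids], dtype=float)
    return {
        "n_units": int(len(graph)),
        "n_edges": int(deg.sum() // 2),
        "mean": float(deg.mean()),
        "min": int(deg.min()),
        "max": int(deg.max()),
    }
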