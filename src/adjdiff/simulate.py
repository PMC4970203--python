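"""Synthetic county systems, covariates, and outcomes.

Two generators on purpose:

* :func:`simulate_county_table` builds a per-unit table whose between-neighbor
  differences have realistic spreads; it feeds the differencing pipeline and
  exercises the antisymmetry invariants end to end.
* :func:`simulate_pair_outcomes` generates ordered-pair responses directly
  from the difference model's own equation (random intercepts, slopes,
  spatial term), which is what parameter-recovery and sampler-correctness
  tests need — the model's intercept and spatial terms depend only on the
  index unit, so its draws deliberately do *not* satisfy cross-row
  antisymmetry, and conflating the two generators would make recovery tests
  ill-posed.

Defaults emulate the motivating application: ~115 areal units with 1–8
neighbors each (mean near 5), covariate difference spreads on the scale of
county-level percentage and per-100,000 rates, and true coefficients near
the magnitudes a county mortality-difference analysis reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.spatial

from .graph import AdjacencyGraph, AreaUnit
from .model import LatentState, ModelSpec, PairModelData, linear_predictor
from .pairs import CountyTable

#: true fixed effects, scaled like a county mortality-difference analysis
DEFAULT_TRUE_BETA: dict[str, float] = {
    "cost_barrier_pct": 2.60,
    "hospital_discharge_rate": 1.03,
    "fair_poor_health_pct": 2.93,
    "hypertension_pct": 4.75,
    "poverty_pct": 6.08,
}

#: between-neighbor difference SDs, percentage points / per-100,000 rates
DEFAULT_COVARIATE_DIFF_SD: dict[str, float] = {
    "cost_barrier_pct": 3.68,
    "hospital_discharge_rate": 25.55,
    "fair_poor_health_pct": 4.91,
    "hypertension_pct": 3.99,
    "poverty_pct": 4.15,
}


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of both synthetic generators.

    ``resid_sd`` is the SD of pair-level noise on the outcome difference;
    ``intercept_sd``/``slope_sd``/``spatial_sd`` scale the per-unit random
    effects.  Defaults put roughly half of the outcome-difference variance
    into the structured part, matching the spread a county mortality
    application shows (difference SD near 95 per 100,000).
    """

    n_units: int = 115
    graph_kind: str = "random_planar"   # or "grid_queen"
    true_intercept: float = 0.0
    true_beta: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    covariate_diff_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_DIFF_SD))
    intercept_sd: float = 10.0
    slope_sd: float = 0.3
    spatial_sd: float = 15.0
    resid_sd: float = 80.0
    outcome_level: float = 850.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ValueError("need at least 2 units")
        if self.graph_kind not in ("grid_queen", "random_planar"):
            raise ValueError(f"unknown graph kind {self.graph_kind!r}")
        for nm in ("intercept_sd", "slope_sd", "spatial_sd", "resid_sd"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be non-negative")
        if set(self.true_beta) != set(self.covariate_diff_sd):
            raise ValueError("true_beta and covariate_diff_sd must name the "
                             "same covariates")

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(self.true_beta)


def _unit_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"u{str(k).zfill(width)}" for k in range(n)]


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

def _grid_queen(n: int) -> AdjacencyGraph:
    rows = int(round(math.sqrt(n)))
    cols = math.ceil(n / rows)
    cells = [(r, c) for r in range(rows) for c in range(cols)][:n]
    ids = _unit_ids(n)
    pos = {cell: ids[k] for k, cell in enumerate(cells)}
    nbrs = {i: set() for i in ids}
    for (r, c), s in pos.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                t = pos.get((r + dr, c + dc))
                if t is not None:
                    nbrs[s].add(t)
    units = tuple(AreaUnit(i, i) for i in ids)
    return AdjacencyGraph(units, {s: frozenset(v) for s, v in nbrs.items()})


def _random_planar(n: int, rng: np.random.Generator,
                   target_mean_degree: float = 5.1,
                   max_degree: int = 8) -> AdjacencyGraph:
    """Delaunay triangulation of random points, pruned to county-like degrees.

    Longest edges are removed (connectivity preserved) until the mean degree
    reaches the target and no unit exceeds ``max_degree``; finally the
    weakest unit is pared to a single neighbor so the degree range spans
    down to 1, as state county maps do.
    """
    pts = rng.random((n, 2))
    tri = scipy.spatial.Delaunay(pts)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            g.add_edge(i, j, length=float(np.linalg.norm(pts[i] - pts[j])))

    def _removable(u, v):
        if g.degree(u) <= 1 or g.degree(v) <= 1:
            return False
        g.remove_edge(u, v)
        ok = nx.is_connected(g)
        g.add_edge(u, v)
        return ok

    edges_by_len = sorted(g.edges(data="length"), key=lambda e: -e[2])
    for u, v, _ in edges_by_len:
        over_cap = g.degree(u) > max_degree or g.degree(v) > max_degree
        over_mean = 2 * g.number_of_edges() / n > target_mean_degree
        if (over_cap or over_mean) and g.has_edge(u, v) and _removable(u, v):
            g.remove_edge(u, v)

    # pare one peripheral unit down to a single neighbor
    leaf = min(g.nodes, key=lambda s: (g.degree(s), s))
    nbrs = sorted(g[leaf], key=lambda t: g[leaf][t]["length"])
    for t in nbrs[1:]:
        if _removable(leaf, t):
            g.remove_edge(leaf, t)

    ids = _unit_ids(n)
    units = tuple(AreaUnit(i, i) for i in ids)
    neighbors = {ids[s]: frozenset(ids[t] for t in g[s]) for s in range(n)}
    return AdjacencyGraph(units, neighbors)


def synthetic_boundary_map(n: int, seed: int = 0) -> dict[str, object]:
    """Synthetic unit boundary polygons: a clipped Voronoi tessellation.

    A stand-in geography (labelled synthetic on purpose) for exercising the
    polygon -> queen-contiguity path at realistic scale; cells of a Voronoi
    diagram share edges the way counties on a state map do.  Returns
    ``{unit_id: shapely Polygon}`` with ids matching :func:`_unit_ids`.
    """
    import shapely
    from shapely.geometry import MultiPoint, Point, box
    from shapely.ops import voronoi_diagram

    rng = np.random.default_rng(seed)
    pts = rng.random((n, 2))
    frame = box(0.0, 0.0, 1.0, 1.0)
    cells = voronoi_diagram(MultiPoint([Point(p) for p in pts]), envelope=frame)
    clipped = [c.intersection(frame) for c in cells.geoms]
    ids = _unit_ids(n)
    out: dict[str, object] = {}
    for k, p in enumerate(pts):      # voronoi output order is not input order
        pt = Point(p)
        for c in clipped:
            if c.contains(pt):
                out[ids[k]] = c
                break
    if len(out) != n:
        raise RuntimeError("failed to match every seed point to a cell")
    return out


def make_graph(params: GeneratorParams) -> AdjacencyGraph:
    """Connected unit graph; deterministic per ``params.seed``."""
    if params.graph_kind == "grid_queen":
        return _grid_queen(params.n_units)
    rng = np.random.default_rng(params.seed)
    return _random_planar(params.n_units, rng)


# ---------------------------------------------------------------------------
# county-level generator
# ---------------------------------------------------------------------------

def _smooth_field(graph: AdjacencyGraph, rng: np.random.Generator) -> np.ndarray:
    """Neighbor-averaged white noise: a simple spatially smooth field."""
    n = len(graph)
    pos = {s: k for k, s in enumerate(graph.ids)}
    z = rng.standard_normal(n)
    out = np.empty(n)
    for s in graph.ids:
        k = pos[s]
        nb = [pos[t] for t in graph.neighbors[s]]
        out[k] = 0.5 * z[k] + 0.5 * np.mean(z[nb]) if nb else z[k]
    return out


def _neighbor_diff_sd(x: np.ndarray, graph: AdjacencyGraph) -> float:
    pos = {s: k for k, s in enumerate(graph.ids)}
    d = np.array([x[pos[j]] - x[pos[i]] for j, i in graph.ordered_pairs()])
    return float(d.std(ddof=1))


def simulate_county_table(graph: AdjacencyGraph,
                          params: GeneratorParams) -> CountyTable:
    """Per-unit outcome and covariates with calibrated neighbor-difference SDs.

    Covariates are spatially smooth fields rescaled so the SD of their
    between-neighbor differences matches ``covariate_diff_sd`` exactly on the
    realized graph; the outcome is the linear combination with ``true_beta``
    plus a smooth field (scaled to ``spatial_sd``) and white noise with
    per-unit SD ``resid_sd / sqrt(2)``, so pair differences of the noise have
    SD near ``resid_sd``.
    """
    rng = np.random.default_rng(params.seed + 1)
    n = len(graph)
    cols: dict[str, np.ndarray] = {}
    for name in params.covariate_names:
        target = params.covariate_diff_sd[name]
        level = 10.0 if name.endswith("pct") else 100.0
        if target == 0.0:
            cols[name] = np.full(n, level)
            continue
        f = _smooth_field(graph, rng)
        sd = _neighbor_diff_sd(f, graph)
        cols[name] = level + f * (target / sd)
    y = np.full(n, params.outcome_level)
    for name in params.covariate_names:
        y = y + params.true_beta[name] * (cols[name] - cols[name].mean())
    if params.spatial_sd > 0:
        f = _smooth_field(graph, rng)
        y = y + params.spatial_sd * (f - f.mean()) / f.std()
    if params.resid_sd > 0:
        y = y + rng.standard_normal(n) * params.resid_sd / math.sqrt(2.0)
    df = pd.DataFrame({"outcome": y, **cols},
                      index=pd.Index(graph.ids, name="id"))
    meta = {name: {"source": "synthetic", "units": "percent"
                   if name.endswith("pct") else "per 100,000"}
            for name in params.covariate_names}
    return CountyTable(df, outcome_col="outcome",
                       covariate_cols=params.covariate_names, metadata=meta)


# ---------------------------------------------------------------------------
# model-faithful pair generator
# ---------------------------------------------------------------------------

def draw_truth(spec: ModelSpec, graph: AdjacencyGraph,
               params: GeneratorParams,
               rng: np.random.Generator) -> LatentState:
    """Draw true latent effects for a recovery experiment.

    Fixed effects come from ``params.true_beta`` (intercept from
    ``true_intercept``; modifier coefficient 0); random-effect families are
    centered normals at their configured SDs; the spatial truth is a smooth
    field centered and scaled to ``spatial_sd``.
    """
    n = len(graph)
    beta = [params.true_intercept]
    beta += [params.true_beta.get(c, 0.0) for c in spec.covariate_names]
    if spec.include_modifier:
        beta.append(0.0)

    def _centered(sd: float) -> np.ndarray:
        if sd == 0:
            return np.zeros(n)
        v = rng.standard_normal(n) * sd
        return v - v.mean()

    fspat = np.zeros(n)
    if spec.include_spatial and params.spatial_sd > 0:
        f = _smooth_field(graph, rng)
        f = f - f.mean()
        fspat = params.spatial_sd * f / f.std()
    return LatentState(
        beta=np.array(beta),
        b0=_centered(params.intercept_sd if spec.include_random_intercept else 0.0),
        bk={k: _centered(params.slope_sd) for k in spec.random_slope_names},
        fspat=fspat,
        var_b0=max(params.intercept_sd**2, 1e-12),
        var_bk={k: max(params.slope_sd**2, 1e-12)
                for k in spec.random_slope_names},
        var_spat=max(params.spatial_sd**2, 1e-12),
        var_resid=max(params.resid_sd**2, 1e-12),
    )


def simulate_pair_outcomes(graph: AdjacencyGraph, spec: ModelSpec,
                           truth: LatentState, params: GeneratorParams,
                           rng: np.random.Generator | None = None
                           ) -> PairModelData:
    """Ordered-pair data drawn from the difference model's own equation.

    dX columns are independent normals at the configured difference SDs and
    dY = linear predictor at ``truth`` plus N(0, resid_sd^2) noise.  Because
    the model's intercept, slope, and spatial terms attach to the index unit
    only, reversed rows are *not* negations of each other here — matching
    the model, not the county-differencing construction.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    pairs = graph.ordered_pairs()
    n_rows = len(pairs)
    pos = {s: k for k, s in enumerate(graph.ids)}
    X = np.column_stack([
        rng.standard_normal(n_rows) * params.covariate_diff_sd.get(c, 1.0)
        for c in spec.covariate_names
    ]) if spec.covariate_names else np.empty((n_rows, 0))
    data = PairModelData(
        y=np.zeros(n_rows),
        X=X,
        modifier=np.array([1.0 if j < i else 0.0 for j, i in pairs]),
        group=np.array([pos[j] for j, _ in pairs]),
        covariate_names=tuple(spec.covariate_names),
        graph=graph,
    )
    eta = linear_predictor(truth, data, spec)
    noise = rng.standard_normal(n_rows) * params.resid_sd if params.resid_sd > 0 \
        else np.zeros(n_rows)
    data.y = eta + noise
    return data


def truth_frame(truth: LatentState, spec: ModelSpec) -> pd.DataFrame:
    """Flat truth table (one row per fixed effect) for test harness CSVs."""
    return pd.DataFrame({
        "parameter": [f"beta_{n}" for n in spec.fixed_names],
        "value": list(truth.beta),
    })
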