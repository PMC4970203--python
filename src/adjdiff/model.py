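"""Multilevel Gaussian model on neighbor differences with an intrinsic CAR term.

The response is the ordered-pair outcome difference dY_ij; for the row with
index unit j,

    dY_ij = (b0 + u0_j) + sum_k (bk + uk_j) * dX_k,ij + gamma * modifier
            + f_spat(j) + eps,        eps ~ N(0, sigma2_resid)

with fixed effects (b0, bk, gamma) under vague zero-mean normal priors,
per-unit random intercepts u0_j and random slopes uk_j as independent
zero-mean normal effects with component variances, and f_spat an intrinsic
conditional-autoregressive (Markov random field) effect: conditionally,
f_spat(s) | rest ~ N(mean of neighbors' values, sigma2_spat / N_s).  All
variance components carry inverse-gamma(a, b) priors, default a = b = 0.001.
Sum-to-zero constraints on every random-effect family (re-centering after
each update) fix the identifiability of the intercept against the improper
CAR prior.

Everything here is a *single-sweep* building block; the MCMC schedule and
posterior summaries live in :mod:`adjdiff.inference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .graph import AdjacencyGraph
from .pairs import delta_columns


# ---------------------------------------------------------------------------
# specifications and priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Structural switches of the difference model."""

    covariate_names: tuple[str, ...] = ()
    include_random_intercept: bool = True
    random_slope_names: tuple[str, ...] = ()
    include_spatial: bool = True
    include_modifier: bool = True
    #: residual variance held fixed (known-variance reduction) when not None
    fixed_resid_variance: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        object.__setattr__(self, "random_slope_names", tuple(self.random_slope_names))
        extra = set(self.random_slope_names) - set(self.covariate_names)
        if extra:
            raise ValueError(f"random slopes for unknown covariates: {sorted(extra)}")
        if self.fixed_resid_variance is not None and self.fixed_resid_variance <= 0:
            raise ValueError("fixed residual variance must be positive")

    @property
    def n_fixed(self) -> int:
        return 1 + len(self.covariate_names) + int(self.include_modifier)

    @property
    def fixed_names(self) -> tuple[str, ...]:
        names = ["intercept", *self.covariate_names]
        if self.include_modifier:
            names.append("modifier")
        return tuple(names)

    def to_yaml(self, path) -> None:
        doc = {
            "covariates": list(self.covariate_names),
            "random_intercept": self.include_random_intercept,
            "random_slopes": list(self.random_slope_names),
            "spatial": self.include_spatial,
            "modifier": self.include_modifier,
        }
        if self.fixed_resid_variance is not None:
            doc["fixed_resid_variance"] = self.fixed_resid_variance
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            covariate_names=tuple(doc.get("covariates", ())),
            include_random_intercept=bool(doc.get("random_intercept", True)),
            random_slope_names=tuple(doc.get("random_slopes", ())),
            include_spatial=bool(doc.get("spatial", True)),
            include_modifier=bool(doc.get("modifier", True)),
            fixed_resid_variance=doc.get("fixed_resid_variance"),
        )


@dataclass(frozen=True)
class Priors:
    """Inverse-gamma variance hyperparameters and the vague fixed-effect prior.

    ``a``/``b`` apply to every variance component (random intercept, each
    random-slope family, spatial, residual); fixed effects are zero-mean
    normal with variance ``fixed_prior_variance`` — proper but diffuse, so
    every full conditional stays proper.
    """

    a: float = 0.001
    b: float = 0.001
    fixed_prior_variance: float = 1e6

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("inverse-gamma hyperparameters must be positive")
        if self.fixed_prior_variance <= 0:
            raise ValueError("fixed-effect prior variance must be positive")


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclass
class PairModelData:
    """Design view of a pair dataset, aligned to a graph.

    ``group`` maps each row to the position of its index unit in
    ``graph.units``; the CAR structure, colorings, and per-unit bincounts all
    use that positional indexing.
    """

    y: np.ndarray
    X: np.ndarray
    modifier: np.ndarray
    group: np.ndarray
    covariate_names: tuple[str, ...]
    graph: AdjacencyGraph
    # precomputed structure
    adjacency: sp.csr_matrix = field(repr=False, default=None)
    degrees: np.ndarray = field(repr=False, default=None)
    coloring: tuple[np.ndarray, ...] = field(repr=False, default=None)
    car_rank: int = field(repr=False, default=0)

    def __post_init__(self) -> None:
        n = len(self.y)
        if self.X.shape != (n, len(self.covariate_names)):
            raise ValueError("design matrix shape does not match covariate names")
        if len(self.modifier) != n or len(self.group) != n:
            raise ValueError("row-aligned arrays have inconsistent lengths")
        nunits = len(self.graph)
        if self.group.min() < 0 or self.group.max() >= nunits:
            raise ValueError("group indices outside the graph's unit range")
        if self.adjacency is None:
            g = self.graph.to_networkx()
            self.adjacency = nx.to_scipy_sparse_array(
                g, nodelist=list(self.graph.ids), format="csr"
            ).astype(float)
            self.degrees = np.asarray(self.adjacency.sum(axis=1)).ravel()
            colors = nx.greedy_color(g, strategy="largest_first")
            ncol = max(colors.values()) + 1
            order = {s: k for k, s in enumerate(self.graph.ids)}
            self.coloring = tuple(
                np.array(sorted(order[s] for s, c in colors.items() if c == cc))
                for cc in range(ncol)
            )
            self.car_rank = nunits - nx.number_connected_components(g)

    @property
    def n_rows(self) -> int:
        return len(self.y)

    @property
    def n_units(self) -> int:
        return len(self.graph)

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame, graph: AdjacencyGraph,
                   covariate_names: Sequence[str] | None = None,
                   outcome_col: str = "delta_outcome") -> "PairModelData":
        if covariate_names is None:
            covariate_names = [
                c.removeprefix("delta_") for c in delta_columns(pairs)
                if c != outcome_col
            ]
        pos = {s: k for k, s in enumerate(graph.ids)}
        unknown = sorted(set(map(str, pairs["index_id"])) - set(graph.ids))
        if unknown:
            raise ValueError(f"pair rows reference units outside the graph: {unknown}")
        cols = [f"delta_{c}" for c in covariate_names]
        missing = [c for c in cols if c not in pairs.columns]
        if missing:
            raise ValueError(f"pair dataset lacks columns {missing}")
        return cls(
            y=pairs[outcome_col].to_numpy(float),
            X=pairs[cols].to_numpy(float) if cols else np.empty((len(pairs), 0)),
            modifier=pairs["modifier"].to_numpy(float),
            group=np.array([pos[str(j)] for j in pairs["index_id"]]),
            covariate_names=tuple(covariate_names),
            graph=graph,
        )

    def fixed_design(self, spec: ModelSpec) -> np.ndarray:
        """Columns [1, dX_1..dX_p (, modifier)] in ``spec.fixed_names`` order."""
        if spec.covariate_names != self.covariate_names:
            raise ValueError("spec covariates do not match the data's covariates")
        cols = [np.ones(self.n_rows), *self.X.T]
        if spec.include_modifier:
            cols.append(self.modifier)
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# latent state
# ---------------------------------------------------------------------------

@dataclass
class LatentState:
    """All model unknowns at one MCMC iteration."""

    beta: np.ndarray
    b0: np.ndarray
    bk: dict[str, np.ndarray]
    fspat: np.ndarray
    var_b0: float
    var_bk: dict[str, float]
    var_spat: float
    var_resid: float

    @classmethod
    def initial(cls, spec: ModelSpec, data: PairModelData) -> "LatentState":
        n_units = data.n_units
        return cls(
            beta=np.zeros(spec.n_fixed),
            b0=np.zeros(n_units),
            bk={k: np.zeros(n_units) for k in spec.random_slope_names},
            fspat=np.zeros(n_units),
            var_b0=1.0,
            var_bk={k: 1.0 for k in spec.random_slope_names},
            var_spat=1.0,
            var_resid=(spec.fixed_resid_variance
                       if spec.fixed_resid_variance is not None
                       else max(float(np.var(data.y)), 1.0)),
        )

    def copy(self) -> "LatentState":
        return replace(
            self,
            beta=self.beta.copy(),
            b0=self.b0.copy(),
            bk={k: v.copy() for k, v in self.bk.items()},
            fspat=self.fspat.copy(),
            var_bk=dict(self.var_bk),
        )


def linear_predictor(state: LatentState, data: PairModelData,
                     spec: ModelSpec) -> np.ndarray:
    """Per-row mean eta_r of the Gaussian difference model."""
    F = data.fixed_design(spec)
    if len(state.beta) != F.shape[1]:
        raise ValueError("beta length does not match the fixed design")
    eta = F @ state.beta
    if spec.include_random_intercept:
        eta = eta + state.b0[data.group]
    for k, u in state.bk.items():
        eta = eta + u[data.group] * data.X[:, data.covariate_names.index(k)]
    if spec.include_spatial:
        eta = eta + state.fspat[data.group]
    return eta


def log_likelihood(state: LatentState, data: PairModelData,
                   spec: ModelSpec) -> float:
    """Gaussian log likelihood of the outcome differences."""
    if state.var_resid <= 0:
        raise ValueError("residual variance must be positive")
    res = data.y - linear_predictor(state, data, spec)
    n = data.n_rows
    return float(
        -0.5 * n * np.log(2 * np.pi * state.var_resid)
        - 0.5 * np.dot(res, res) / state.var_resid
    )


def car_conditional(fspat: np.ndarray | dict[str, float], unit: str,
                    graph: AdjacencyGraph, var_spat: float) -> tuple[float, float]:
    """Intrinsic-CAR prior conditional for one unit's spatial effect.

    mean = average of the neighbors' current values; variance = var_spat/N_s.
    """
    nbrs = graph.neighbors[unit]
    if not nbrs:
        raise ValueError(f"unit {unit!r} has no neighbors; CAR conditional undefined")
    if isinstance(fspat, dict):
        vals = np.array([fspat[t] for t in nbrs])
    else:
        pos = {s: k for k, s in enumerate(graph.ids)}
        vals = np.array([fspat[pos[t]] for t in nbrs])
    return float(vals.mean()), float(var_spat / len(nbrs))


# ---------------------------------------------------------------------------
# full conditionals (used by the sweep and grid-checkable in tests)
# ---------------------------------------------------------------------------

def _partial_residual(state, data, spec, *, skip: str,
                      skip_slope: str | None = None) -> np.ndarray:
    """y minus every model term except the one named by ``skip``."""
    F = data.fixed_design(spec)
    res = data.y.astype(float).copy()
    if skip != "fixed":
        res -= F @ state.beta
    if spec.include_random_intercept and skip != "b0":
        res -= state.b0[data.group]
    for k, u in state.bk.items():
        if skip == "bk" and k == skip_slope:
            continue
        res -= u[data.group] * data.X[:, data.covariate_names.index(k)]
    if spec.include_spatial and skip != "fspat":
        res -= state.fspat[data.group]
    return res


def fixed_effects_conditional(state: LatentState, data: PairModelData,
                              spec: ModelSpec, priors: Priors):
    """Mean vector and precision matrix of the fixed-effect block."""
    F = data.fixed_design(spec)
    r = _partial_residual(state, data, spec, skip="fixed")
    prec = F.T @ F / state.var_resid + np.eye(F.shape[1]) / priors.fixed_prior_variance
    mean = np.linalg.solve(prec, F.T @ r / state.var_resid)
    return mean, prec


def random_intercept_conditional(state, data, spec, priors):
    """Per-unit (mean, variance) arrays for the random intercepts (pre-centering)."""
    r = _partial_residual(state, data, spec, skip="b0")
    n_j = np.bincount(data.group, minlength=data.n_units).astype(float)
    s_j = np.bincount(data.group, weights=r, minlength=data.n_units)
    prec = n_j / state.var_resid + 1.0 / state.var_b0
    return s_j / state.var_resid / prec, 1.0 / prec


def random_slope_conditional(state, data, spec, priors, name: str):
    """Per-unit (mean, variance) arrays for one random-slope family."""
    x = data.X[:, data.covariate_names.index(name)]
    r = _partial_residual(state, data, spec, skip="bk", skip_slope=name)
    sxx = np.bincount(data.group, weights=x * x, minlength=data.n_units)
    sxr = np.bincount(data.group, weights=x * r, minlength=data.n_units)
    prec = sxx / state.var_resid + 1.0 / state.var_bk[name]
    return sxr / state.var_resid / prec, 1.0 / prec


def spatial_site_conditional(state, data, spec, priors, unit_pos: int):
    """Likelihood x CAR conditional for one unit's spatial effect.

    Combines the Gaussian likelihood of the unit's rows with the intrinsic
    CAR conditional given the *current* values at all other sites.
    """
    r = _partial_residual(state, data, spec, skip="fspat")
    rows = data.group == unit_pos
    n_s = data.degrees[unit_pos]
    nbr_mean = (data.adjacency[[unit_pos], :] @ state.fspat)[0] / n_s
    prec = rows.sum() / state.var_resid + n_s / state.var_spat
    mean = (r[rows].sum() / state.var_resid + n_s * nbr_mean / state.var_spat) / prec
    return float(mean), float(1.0 / prec)


def car_pairwise_ss(fspat: np.ndarray, data: PairModelData) -> float:
    """Sum over undirected edges of (f_s - f_s')^2 — the CAR kernel quadratic."""
    A = data.adjacency
    # sum_s d_s f_s^2 - f' A f  equals the edge sum of squared differences
    return float(np.dot(data.degrees * fspat, fspat) - fspat @ (A @ fspat))


def sample_variance(rng: np.random.Generator, a: float, b: float,
                    m: float, ss: float) -> float:
    """One inverse-gamma(a + m/2, b + ss/2) draw (shape/rate convention)."""
    shape = a + 0.5 * m
    rate = b + 0.5 * ss
    return float(rate / rng.gamma(shape))


# ---------------------------------------------------------------------------
# the Gibbs sweep
# ---------------------------------------------------------------------------

DEFAULT_BLOCK_ORDER = ("fixed", "b0", "bk", "fspat", "variances")


def gibbs_sweep(state: LatentState, data: PairModelData, spec: ModelSpec,
                priors: Priors, rng: np.random.Generator,
                block_order: Sequence[str] = DEFAULT_BLOCK_ORDER) -> LatentState:
    """One full Gibbs update of every unknown; returns a new state.

    Blocks: multivariate-normal fixed effects; per-unit normal random
    intercepts and slopes (re-centered to sum to zero); spatial effects by a
    chromatic scan — units of the same graph color share no edge, so they are
    conditionally independent and can be drawn jointly, which leaves the
    stationary distribution identical to a site-by-site scan — then
    re-centered; finally each variance from its conjugate inverse-gamma full
    conditional.
    """
    st = state.copy()
    for block in block_order:
        if block == "fixed":
            mean, prec = fixed_effects_conditional(st, data, spec, priors)
            try:
                L = np.linalg.cholesky(prec)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    "singular full-conditional precision for block 'fixed'"
                ) from exc
            z = rng.standard_normal(len(mean))
            st.beta = mean + np.linalg.solve(L.T, z)
        elif block == "b0" and spec.include_random_intercept:
            mean, var = random_intercept_conditional(st, data, spec, priors)
            st.b0 = mean + rng.standard_normal(data.n_units) * np.sqrt(var)
            st.b0 -= st.b0.mean()
        elif block == "bk":
            for k in spec.random_slope_names:
                mean, var = random_slope_conditional(st, data, spec, priors, k)
                st.bk[k] = mean + rng.standard_normal(data.n_units) * np.sqrt(var)
                st.bk[k] -= st.bk[k].mean()
        elif block == "fspat" and spec.include_spatial:
            r = _partial_residual(st, data, spec, skip="fspat")
            n_j = np.bincount(data.group, minlength=data.n_units).astype(float)
            s_j = np.bincount(data.group, weights=r, minlength=data.n_units)
            for color in data.coloring:
                nbr_sum = (data.adjacency @ st.fspat)[color]
                prec = n_j[color] / st.var_resid + data.degrees[color] / st.var_spat
                mean = (s_j[color] / st.var_resid + nbr_sum / st.var_spat) / prec
                st.fspat[color] = mean + rng.standard_normal(len(color)) / np.sqrt(prec)
            st.fspat -= st.fspat.mean()
        elif block == "variances":
            if spec.include_random_intercept:
                st.var_b0 = sample_variance(
                    rng, priors.a, priors.b, data.n_units, float(st.b0 @ st.b0))
            for k in spec.random_slope_names:
                st.var_bk[k] = sample_variance(
                    rng, priors.a, priors.b, data.n_units,
                    float(st.bk[k] @ st.bk[k]))
            if spec.include_spatial:
                st.var_spat = sample_variance(
                    rng, priors.a, priors.b, data.car_rank,
                    car_pairwise_ss(st.fspat, data))
            if spec.fixed_resid_variance is None:
                res = data.y - linear_predictor(st, data, spec)
                st.var_resid = sample_variance(
                    rng, priors.a, priors.b, data.n_rows, float(res @ res))
    return st


# ---------------------------------------------------------------------------
# joint density (for validating conditionals on tiny instances)
# ---------------------------------------------------------------------------

def log_joint(state: LatentState, data: PairModelData, spec: ModelSpec,
              priors: Priors) -> float:
    """log( likelihood x all priors ), up to constants that do not involve
    any sampled parameter's *value* given the rest (the intrinsic CAR kernel
    is improper; its pairwise-difference form is used, which is exactly what
    every conditional is proportional to)."""
    lp = log_likelihood(state, data, spec)
    lp += float(
        -0.5 * np.dot(state.beta, state.beta) / priors.fixed_prior_variance
        - 0.5 * len(state.beta) * np.log(2 * np.pi * priors.fixed_prior_variance)
    )

    def _iid_normal(v: np.ndarray, var: float) -> float:
        return float(-0.5 * len(v) * np.log(2 * np.pi * var)
                     - 0.5 * np.dot(v, v) / var)

    def _ig(var: float) -> float:
        return float(-(priors.a + 1) * np.log(var) - priors.b / var)

    if spec.include_random_intercept:
        lp += _iid_normal(state.b0, state.var_b0) + _ig(state.var_b0)
    for k in spec.random_slope_names:
        lp += _iid_normal(state.bk[k], state.var_bk[k]) + _ig(state.var_bk[k])
    if spec.include_spatial:
        lp += float(
            -0.5 * data.car_rank * np.log(state.var_spat)
            - 0.5 * car_pairwise_ss(state.fspat, data) / state.var_spat
        ) + _ig(state.var_spat)
    if spec.fixed_resid_variance is None:
        lp += _ig(state.var_resid)
    return lp
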