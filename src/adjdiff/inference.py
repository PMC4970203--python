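"""MCMC driver, posterior summaries, DIC, model selection, sensitivity scan.

A single chain is run under a (total, burn-in, thin) schedule — the default
25,000 / 5,000 / 20 stores exactly 1,000 draws — and every summary (posterior
means, 95% credible intervals, DIC) is a pure function of the stored draws,
so recomputing from a saved draw file reproduces the fit summary exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    LatentState,
    ModelSpec,
    PairModelData,
    Priors,
    gibbs_sweep,
    linear_predictor,
    log_likelihood,
)

logger = logging.getLogger("adjdiff")


@dataclass(frozen=True)
class McmcSchedule:
    """Single-chain iteration plan."""

    total_iterations: int = 25_000
    burn_in: int = 5_000
    thin: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_iterations <= 0 or self.thin <= 0 or self.burn_in < 0:
            raise ValueError("schedule fields must be positive (burn-in >= 0)")
        if self.burn_in >= self.total_iterations:
            raise ValueError("burn-in must be smaller than total iterations")

    @property
    def stored_count(self) -> int:
        """Number of stored draws: floor((total - burn_in)/thin)."""
        return (self.total_iterations - self.burn_in) // self.thin

    def stored_iterations(self) -> list[int]:
        """1-based iteration numbers whose states are stored."""
        return [
            t for t in range(1, self.total_iterations + 1)
            if t > self.burn_in and (t - self.burn_in) % self.thin == 0
        ]


@dataclass
class PosteriorSamples:
    """Stored draws of every model unknown, one column per parameter.

    Fixed effects are named ``beta_<name>``, variance components ``var_*``,
    and per-unit effects ``b0_<id>``, ``slope_<cov>_<id>``, ``fspat_<id>``.
    """

    draws: pd.DataFrame
    spec: ModelSpec
    schedule: McmcSchedule
    unit_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        var_cols = [c for c in self.draws.columns if c.startswith("var_")]
        if (self.draws[var_cols] <= 0).any().any():
            raise ValueError("variance draws must be strictly positive")

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    @property
    def fixed_names(self) -> tuple[str, ...]:
        return tuple(f"beta_{n}" for n in self.spec.fixed_names)

    def state_at(self, i: int) -> LatentState:
        return self._row_to_state(self.draws.iloc[i])

    def mean_state(self) -> LatentState:
        """Plug-in state at the posterior mean of every parameter."""
        return self._row_to_state(self.draws.mean(axis=0))

    def _row_to_state(self, row: pd.Series) -> LatentState:
        ids = self.unit_ids
        spec = self.spec
        return LatentState(
            beta=row[list(self.fixed_names)].to_numpy(float),
            b0=(row[[f"b0_{s}" for s in ids]].to_numpy(float)
                if spec.include_random_intercept else np.zeros(len(ids))),
            bk={k: row[[f"slope_{k}_{s}" for s in ids]].to_numpy(float)
                for k in spec.random_slope_names},
            fspat=(row[[f"fspat_{s}" for s in ids]].to_numpy(float)
                   if spec.include_spatial else np.zeros(len(ids))),
            var_b0=float(row.get("var_b0", 1.0)),
            var_bk={k: float(row[f"var_slope_{k}"])
                    for k in spec.random_slope_names},
            var_spat=float(row.get("var_spat", 1.0)),
            var_resid=(spec.fixed_resid_variance
                       if spec.fixed_resid_variance is not None
                       else float(row["var_resid"])),
        )

    def to_csv(self, path) -> None:
        self.draws.to_csv(path, index=False)


def _state_to_row(state: LatentState, spec: ModelSpec,
                  unit_ids: Sequence[str]) -> dict[str, float]:
    row: dict[str, float] = {
        f"beta_{n}": v for n, v in zip(spec.fixed_names, state.beta)
    }
    if spec.include_random_intercept:
        row["var_b0"] = state.var_b0
        row.update({f"b0_{s}": v for s, v in zip(unit_ids, state.b0)})
    for k in spec.random_slope_names:
        row[f"var_slope_{k}"] = state.var_bk[k]
        row.update({f"slope_{k}_{s}": v for s, v in zip(unit_ids, state.bk[k])})
    if spec.include_spatial:
        row["var_spat"] = state.var_spat
        row.update({f"fspat_{s}": v for s, v in zip(unit_ids, state.fspat)})
    if spec.fixed_resid_variance is None:
        row["var_resid"] = state.var_resid
    return row


def run_chain(spec: ModelSpec, data: PairModelData, priors: Priors,
              schedule: McmcSchedule, *, initial: LatentState | None = None,
              log_every: int = 1000) -> PosteriorSamples:
    """Run one Gibbs chain and return the stored (post-burn-in, thinned) draws.

    A fixed ``schedule.seed`` makes the output bit-identical across runs on
    the same platform.  Aborts with the iteration number if the state turns
    non-finite.
    """
    rng = np.random.default_rng(schedule.seed)
    state = initial.copy() if initial is not None else LatentState.initial(spec, data)
    unit_ids = data.graph.ids
    rows: list[dict[str, float]] = []
    for t in range(1, schedule.total_iterations + 1):
        state = gibbs_sweep(state, data, spec, priors, rng)
        if not np.isfinite(state.beta).all() or not np.isfinite(state.var_resid):
            raise FloatingPointError(f"chain diverged at iteration {t}")
        if t > schedule.burn_in and (t - schedule.burn_in) % schedule.thin == 0:
            rows.append(_state_to_row(state, spec, unit_ids))
        if log_every and t % log_every == 0:
            logger.info("iteration %d/%d", t, schedule.total_iterations)
    draws = pd.DataFrame(rows)
    assert len(draws) == schedule.stored_count
    return PosteriorSamples(draws=draws, spec=spec, schedule=schedule,
                            unit_ids=tuple(unit_ids))


def credible_interval(samples: PosteriorSamples, parameter: str,
                      level: float = 0.95) -> tuple[float, float]:
    """Empirical equal-tail interval of a stored parameter's draws.

    Quantiles use linear interpolation between order statistics.
    """
    if parameter not in samples.draws.columns:
        raise KeyError(f"unknown parameter {parameter!r}")
    x = samples.draws[parameter].to_numpy(float)
    if len(x) < 2:
        raise ValueError("need at least 2 draws")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------

def _deviance_per_draw(samples: PosteriorSamples,
                       data: PairModelData) -> np.ndarray:
    """-2 log L for every stored draw, computed with matrix operations.

    Equivalent to reconstructing each draw's state and calling
    :func:`adjdiff.model.log_likelihood` (a unit test holds the two paths
    together), but one matrix product instead of a python loop per draw.
    """
    spec = samples.spec
    draws = samples.draws
    ids = samples.unit_ids
    F = data.fixed_design(spec)
    B = draws[list(samples.fixed_names)].to_numpy(float)
    eta = B @ F.T                                       # (n_draws, n_rows)
    if spec.include_random_intercept:
        b0 = draws[[f"b0_{s}" for s in ids]].to_numpy(float)
        eta += b0[:, data.group]
    for k in spec.random_slope_names:
        u = draws[[f"slope_{k}_{s}" for s in ids]].to_numpy(float)
        eta += u[:, data.group] * data.X[:, data.covariate_names.index(k)]
    if spec.include_spatial:
        f = draws[[f"fspat_{s}" for s in ids]].to_numpy(float)
        eta += f[:, data.group]
    if spec.fixed_resid_variance is not None:
        var = np.full(len(draws), spec.fixed_resid_variance)
    else:
        var = draws["var_resid"].to_numpy(float)
    rss = ((data.y[None, :] - eta) ** 2).sum(axis=1)
    return data.n_rows * np.log(2 * np.pi * var) + rss / var


def compute_dic(samples: PosteriorSamples,
                data: PairModelData) -> tuple[float, float, float]:
    """(dbar, pd, dic) from stored draws.

    Deviance D(theta) = -2 log L; dbar is its posterior mean, the plug-in
    deviance is evaluated at the posterior mean of *all* parameters
    (variance components included), pd = dbar - D(mean), dic = dbar + pd.
    """
    spec = samples.spec
    devs = _deviance_per_draw(samples, data)
    bad = np.flatnonzero(~np.isfinite(devs))
    if bad.size:
        raise ValueError(f"non-finite deviance at draw {bad[0]}")
    dbar = float(devs.mean())
    d_hat = -2.0 * log_likelihood(samples.mean_state(), data, spec)
    p_d = dbar - d_hat
    return dbar, p_d, dbar + p_d


# ---------------------------------------------------------------------------
# fit summaries
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Posterior summary of one fitted model."""

    summary: pd.DataFrame          # parameter, mean, ci_lower, ci_upper
    dbar: float
    pd: float
    dic: float
    schedule: McmcSchedule
    spec: ModelSpec

    def estimate(self, name: str) -> float:
        return float(self.summary.set_index("parameter").loc[name, "mean"])

    def interval(self, name: str) -> tuple[float, float]:
        row = self.summary.set_index("parameter").loc[name]
        return float(row["ci_lower"]), float(row["ci_upper"])


def summarize(samples: PosteriorSamples, data: PairModelData,
              level: float = 0.95) -> FitResult:
    """FitResult from stored draws: means, credible intervals, DIC."""
    params = list(samples.fixed_names) + [
        c for c in samples.draws.columns if c.startswith("var_")
    ]
    rows = []
    for p in params:
        lo, hi = credible_interval(samples, p, level)
        rows.append({
            "parameter": p,
            "mean": float(samples.draws[p].mean()),
            "ci_lower": lo,
            "ci_upper": hi,
        })
    dbar, p_d, dic = compute_dic(samples, data)
    return FitResult(summary=pd.DataFrame(rows), dbar=dbar, pd=p_d, dic=dic,
                     schedule=samples.schedule, spec=samples.spec)


def fit_model(spec: ModelSpec, data: PairModelData, priors: Priors,
              schedule: McmcSchedule) -> tuple[FitResult, PosteriorSamples]:
    samples = run_chain(spec, data, priors, schedule)
    return summarize(samples, data), samples


# ---------------------------------------------------------------------------
# model selection and sensitivity
# ---------------------------------------------------------------------------

def select_model(candidates: Sequence[ModelSpec], pairs: pd.DataFrame, graph,
                 priors: Priors, schedule: McmcSchedule
                 ) -> tuple[FitResult, pd.DataFrame]:
    """Fit every candidate and return the minimum-DIC fit plus a DIC table.

    Each candidate runs an independent chain seeded ``schedule.seed + index``
    (recorded in the table).  Ties on DIC break toward fewer covariates.
    A candidate whose chain aborts is recorded and skipped; if all abort the
    selection fails.
    """
    if not candidates:
        raise ValueError("no candidate models supplied")
    records, fits = [], {}
    for idx, cand in enumerate(candidates):
        sched = replace(schedule, seed=schedule.seed + idx)
        try:
            data = PairModelData.from_pairs(pairs, graph,
                                            covariate_names=cand.covariate_names)
            fit, _ = fit_model(cand, data, priors, sched)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("candidate %d failed: %s", idx, exc)
            records.append({"candidate": idx,
                            "covariates": "+".join(cand.covariate_names),
                            "n_covariates": len(cand.covariate_names),
                            "seed": sched.seed, "dic": np.nan,
                            "status": f"failed: {exc}"})
            continue
        fits[idx] = fit
        records.append({"candidate": idx,
                        "covariates": "+".join(cand.covariate_names),
                        "n_covariates": len(cand.covariate_names),
                        "seed": sched.seed, "dic": fit.dic, "status": "ok"})
    table = pd.DataFrame(records)
    if not fits:
        raise RuntimeError("all candidate fits failed")
    ok = table[table["status"] == "ok"]
    best_idx = int(ok.sort_values(["dic", "n_covariates", "candidate"]).iloc[0]["candidate"])
    return fits[best_idx], table


DEFAULT_SENSITIVITY_GRID: tuple[tuple[float, float], ...] = (
    (0.1, 0.1), (0.01, 0.01), (0.001, 0.001), (0.0001, 0.0001),
)


def sensitivity_scan(spec: ModelSpec, data: PairModelData,
                     grid: Sequence[tuple[float, float]],
                     schedule: McmcSchedule,
                     fixed_prior_variance: float = 1e6) -> pd.DataFrame:
    """Refit under each (a, b) variance hyperprior; common seed across fits.

    Returns one row per fixed effect per grid point with the posterior mean
    and 95% interval, for judging robustness of the fixed effects to the
    variance hyperprior.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    rows = []
    for a, b in grid:
        priors = Priors(a=a, b=b, fixed_prior_variance=fixed_prior_variance)
        fit, _ = fit_model(spec, data, priors, schedule)
        for name in fit.summary["parameter"]:
            if not name.startswith("beta_"):
                continue
            lo, hi = fit.interval(name)
            rows.append({"a": a, "b": b, "parameter": name,
                         "estimate": fit.estimate(name),
                         "ci_lower": lo, "ci_upper": hi,
                         "seed": schedule.seed})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def convergence_check(samples: PosteriorSamples,
                      parameters: Sequence[str] | None = None) -> pd.DataFrame:
    """Quantitative stand-in for trace-plot inspection.

    Per parameter: a Geweke-style z comparing the mean of the first 10% of
    stored draws against the last 50%, and the lag-1 autocorrelation.
    ``flagged`` marks |z| > 2; constant series are reported as ``degenerate``
    (no variability to diagnose) and never flagged.
    """
    if samples.n_draws < 20:
        raise ValueError("need at least 20 stored draws for diagnostics")
    cols = list(parameters) if parameters is not None else [
        c for c in samples.draws.columns
        if c.startswith(("beta_", "var_"))
    ]
    n = samples.n_draws
    a_end = max(int(np.ceil(0.1 * n)), 2)
    b_start = n // 2
    rows = []
    for c in cols:
        x = samples.draws[c].to_numpy(float)
        xa, xb = x[:a_end], x[b_start:]
        va, vb = xa.var(ddof=1), xb.var(ddof=1)
        if np.ptp(x) == 0.0:
            rows.append({"parameter": c, "geweke_z": np.nan, "lag1_acf": np.nan,
                         "degenerate": True, "flagged": False})
            continue
        denom = np.sqrt(va / len(xa) + vb / len(xb))
        z = (xa.mean() - xb.mean()) / denom if denom > 0 else np.inf
        xc = x - x.mean()
        acf1 = float(np.dot(xc[:-1], xc[1:]) / np.dot(xc, xc))
        rows.append({"parameter": c, "geweke_z": float(z), "lag1_acf": acf1,
                     "degenerate": False, "flagged": bool(abs(z) > 2)})
    return pd.DataFrame(rows)


def save_trace_plots(samples: PosteriorSamples, path,
                     parameters: Sequence[str] | None = None) -> None:
    """Write a PNG grid of sampling traces for human review."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = list(parameters) if parameters is not None else list(samples.fixed_names)
    fig, axes = plt.subplots(len(cols), 1, figsize=(7, 1.8 * len(cols)),
                             squeeze=False, sharex=True)
    for ax, c in zip(axes[:, 0], cols):
        ax.plot(samples.draws[c].to_numpy(), lw=0.6)
        ax.set_ylabel(c, fontsize=7)
    axes[-1, 0].set_xlabel("stored draw")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
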