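"""scikit-learn style front end to the Gibbs-sampled difference model."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .graph import AdjacencyGraph
from .inference import (
    McmcSchedule,
    convergence_check,
    fit_model,
    summarize,
)
from .model import ModelSpec, PairModelData, Priors, linear_predictor


class CARMultilevelRegressor(RegressorMixin, BaseEstimator):
    """Bayesian multilevel regression of neighbor differences with a CAR term.

    Fits, by single-chain Gibbs sampling, the Gaussian model

        dY = (b0 + u0_j) + sum_k (bk + uk_j) dX_k + gamma*modifier
             + f_spat(j) + eps

    on an ordered-pair difference dataset (see
    :class:`adjdiff.pairs.NeighborDifferencer`), where j indexes the pair's
    index unit on a supplied adjacency graph.

    Parameters
    ----------
    graph
        Adjacency structure of the areal units; drives both the random-effect
        grouping and the intrinsic-CAR spatial prior.
    covariates
        Covariate names (column ``delta_<name>`` must exist in the pair
        dataset).  ``None`` uses every delta column.
    random_intercept, random_slopes, spatial, modifier
        Structural switches: per-unit intercepts, per-unit slopes for the
        named covariates, the CAR spatial effect, and the 0/1 direction flag.
    a, b
        Inverse-gamma hyperparameters shared by all variance components.
    fixed_prior_variance
        Variance of the vague zero-mean normal prior on fixed effects.
    iterations, burn_in, thin
        MCMC schedule; the defaults store exactly 1,000 draws.
    random_state
        Chain seed; a fixed seed reproduces the fit bit-for-bit.
    fixed_resid_variance
        Hold the residual variance at a known value instead of sampling it.

    Attributes
    ----------
    coef_ : ndarray
        Posterior means of the covariate coefficients, in ``covariates`` order.
    intercept_ : float
        Posterior mean of the fixed intercept.
    samples_ : PosteriorSamples
        All stored draws.
    result_ : FitResult
        Posterior means, 95% credible intervals, DIC components.
    dic_, dbar_, pd_ : float
        Deviance information criterion and its pieces.

    Examples
    --------
    >>> est = CARMultilevelRegressor(graph, covariates=["poverty_pct"],
    ...                              iterations=2000, burn_in=500, thin=5)
    >>> est.fit(pairs)                          # doctest: +SKIP
    >>> est.coef_, est.dic_                     # doctest: +SKIP
    """

    def __init__(self, graph: AdjacencyGraph = None, covariates=None, *,
                 random_intercept: bool = True, random_slopes=(),
                 spatial: bool = True, modifier: bool = True,
                 a: float = 0.001, b: float = 0.001,
                 fixed_prior_variance: float = 1e6,
                 iterations: int = 25_000, burn_in: int = 5_000,
                 thin: int = 20, random_state: int = 0,
                 fixed_resid_variance: float | None = None):
        self.graph = graph
        self.covariates = covariates
        self.random_intercept = random_intercept
        self.random_slopes = random_slopes
        self.spatial = spatial
        self.modifier = modifier
        self.a = a
        self.b = b
        self.fixed_prior_variance = fixed_prior_variance
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.random_state = random_state
        self.fixed_resid_variance = fixed_resid_variance

    # -- internal assembly -------------------------------------------------
    def _spec(self, data_covariates) -> ModelSpec:
        names = tuple(self.covariates) if self.covariates is not None \
            else tuple(data_covariates)
        return ModelSpec(
            covariate_names=names,
            include_random_intercept=self.random_intercept,
            random_slope_names=tuple(self.random_slopes),
            include_spatial=self.spatial,
            include_modifier=self.modifier,
            fixed_resid_variance=self.fixed_resid_variance,
        )

    def _build_data(self, X: pd.DataFrame | PairModelData) -> PairModelData:
        if isinstance(X, PairModelData):
            return X
        if self.graph is None:
            raise ValueError("graph must be set to fit from a pair DataFrame")
        names = tuple(self.covariates) if self.covariates is not None else None
        return PairModelData.from_pairs(X, self.graph, covariate_names=names)

    # -- sklearn API -------------------------------------------------------
    def fit(self, X: pd.DataFrame | PairModelData, y=None) -> "CARMultilevelRegressor":
        """Run the Gibbs chain on an ordered-pair dataset.

        ``X`` is the pair DataFrame produced by ``NeighborDifferencer``
        (``y`` is taken from its ``delta_outcome`` column) or a prebuilt
        :class:`PairModelData`.
        """
        data = self._build_data(X)
        spec = self._spec(data.covariate_names)
        priors = Priors(a=self.a, b=self.b,
                        fixed_prior_variance=self.fixed_prior_variance)
        schedule = McmcSchedule(total_iterations=self.iterations,
                                burn_in=self.burn_in, thin=self.thin,
                                seed=self.random_state)
        result, samples = fit_model(spec, data, priors, schedule)
        self.spec_ = spec
        self.data_ = data
        self.samples_ = samples
        self.result_ = result
        self.n_draws_ = samples.n_draws
        means = samples.draws[list(samples.fixed_names)].mean()
        self.intercept_ = float(means["beta_intercept"])
        self.coef_ = np.array([means[f"beta_{c}"] for c in spec.covariate_names])
        self.coef_names_ = spec.covariate_names
        self.dbar_, self.pd_, self.dic_ = result.dbar, result.pd, result.dic
        return self

    def predict(self, X: pd.DataFrame | PairModelData) -> np.ndarray:
        """Posterior-mean linear predictor for ordered-pair rows."""
        if not hasattr(self, "samples_"):
            raise AttributeError("estimator is not fitted")
        data = self._build_data(X)
        return linear_predictor(self.samples_.mean_state(), data, self.spec_)

    # -- conveniences ------------------------------------------------------
    def credible_intervals(self, level: float = 0.95) -> pd.DataFrame:
        return summarize(self.samples_, self.data_, level=level).summary

    def diagnostics(self) -> pd.DataFrame:
        return convergence_check(self.samples_)

    def _more_tags(self):  # pragma: no cover
        return {"non_deterministic": False, "X_types": ["dataframe"]}
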