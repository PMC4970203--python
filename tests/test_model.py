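"""Likelihood, CAR conditional, and Gibbs-sweep mechanics."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from adjdiff import (
    CountyTable,
    LatentState,
    ModelSpec,
    PairModelData,
    Priors,
    build_pairs,
    car_conditional,
    gibbs_sweep,
    linear_predictor,
    log_likelihood,
)
from adjdiff.model import car_pairwise_ss, sample_variance

from conftest import graph_from_edges


def make_data(graph, outcome, covs, spec_kwargs=None):
    df = pd.DataFrame({"outcome": outcome, **covs},
                      index=pd.Index(graph.ids, name="id"))
    pairs = build_pairs(CountyTable(df), graph)
    data = PairModelData.from_pairs(pairs, graph)
    spec = ModelSpec(covariate_names=data.covariate_names, **(spec_kwargs or {}))
    return data, spec


@pytest.fixture
def toy(cycle4):
    return make_data(cycle4, [3.0, 1.0, 4.0, 1.5], {"x": [0.2, -1.0, 0.5, 2.0]})


class TestLinearPredictor:
    def test_intercept_only(self, toy):
        data, spec = toy
        st = LatentState.initial(spec, data)
        st.beta[0] = 7.5
        assert np.allclose(linear_predictor(st, data, spec), 7.5)

    def test_unit_covariate_times_coefficient(self, cycle4):
        """With dX = 1 and a coefficient of 2.60 everything else zero, the
        predictor is 2.60 on every row."""
        data, spec = make_data(cycle4, [0.0] * 4, {"x": [0.0] * 4})
        data.X[:] = 1.0
        st = LatentState.initial(spec, data)
        st.beta[1] = 2.60
        assert np.allclose(linear_predictor(st, data, spec), 2.60)

    def test_random_slope_cancellation(self, cycle4):
        data, spec = make_data(cycle4, [0.0] * 4, {"x": [1.0, 2.0, 3.0, 4.0]},
                               {"random_slope_names": ("x",)})
        st = LatentState.initial(spec, data)
        st.beta[1] = 2.0
        st.bk["x"] = np.full(4, -2.0)   # slope effect cancels the fixed slope
        eta = linear_predictor(st, data, spec)
        assert np.allclose(eta, 0.0)

    def test_dimension_mismatch_rejected(self, toy):
        data, spec = toy
        st = LatentState.initial(spec, data)
        st.beta = np.zeros(2)
        with pytest.raises(ValueError):
            linear_predictor(st, data, spec)


class TestLogLikelihood:
    def test_zero_residuals_unit_variance(self, toy):
        data, spec0 = toy
        spec = ModelSpec(covariate_names=spec0.covariate_names,
                         fixed_resid_variance=1.0)
        st = LatentState.initial(spec, data)
        st.var_resid = 1.0
        data = PairModelData(y=np.zeros(data.n_rows), X=data.X,
                             modifier=data.modifier, group=data.group,
                             covariate_names=data.covariate_names,
                             graph=data.graph)
        n = data.n_rows
        assert log_likelihood(st, data, spec) == pytest.approx(
            -0.5 * n * np.log(2 * np.pi))

    def test_matches_independent_density_sum(self, toy, rng):
        """Oracle: sum of scipy.stats.norm log densities at the same means."""
        data, spec = toy
        st = LatentState.initial(spec, data)
        st.beta = rng.normal(size=len(st.beta))
        st.b0 = rng.normal(size=4); st.b0 -= st.b0.mean()
        st.fspat = rng.normal(size=4); st.fspat -= st.fspat.mean()
        st.var_resid = 2.7
        eta = linear_predictor(st, data, spec)
        oracle = scipy.stats.norm.logpdf(data.y, eta, np.sqrt(2.7)).sum()
        assert log_likelihood(st, data, spec) == pytest.approx(oracle, abs=1e-12)

    def test_nonpositive_variance_rejected(self, toy):
        data, spec = toy
        st = LatentState.initial(spec, data)
        st.var_resid = 0.0
        with pytest.raises(ValueError):
            log_likelihood(st, data, spec)


class TestCarConditional:
    def test_two_neighbors_arithmetic(self, path3):
        """Neighbors at 2 and 4 with unit variance: mean 3, variance 1/2."""
        f = {"A": 2.0, "B": 0.0, "C": 4.0}
        mean, var = car_conditional(f, "B", path3, var_spat=1.0)
        assert (mean, var) == (3.0, 0.5)

    def test_all_neighbors_zero(self, cycle4):
        mean, _ = car_conditional(np.zeros(4), "A", cycle4, var_spat=5.0)
        assert mean == 0.0

    def test_four_cycle_hand_average(self, cycle4):
        """Unit A's neighbors on the 4-cycle are B and D; values (1,2,3,4)
        by unit order give mean (2+4)/2 = 3."""
        mean, var = car_conditional(np.array([1.0, 2.0, 3.0, 4.0]), "A",
                                    cycle4, var_spat=2.0)
        assert mean == 3.0
        assert var == 1.0

    def test_isolated_unit_rejected(self):
        from adjdiff.graph import AdjacencyGraph, AreaUnit
        g = AdjacencyGraph((AreaUnit("A"), AreaUnit("B"), AreaUnit("C")),
                           {"A": frozenset({"B"}), "B": frozenset({"A"}),
                            "C": frozenset()})
        with pytest.raises(ValueError, match="no neighbors"):
            car_conditional(np.zeros(3), "C", g, 1.0)


class TestGibbsSweep:
    def test_deterministic_given_seed(self, toy):
        data, spec0 = toy
        spec = ModelSpec(covariate_names=spec0.covariate_names,
                         random_slope_names=("x",))
        st0 = LatentState.initial(spec, data)
        a = gibbs_sweep(st0, data, spec, Priors(),
                        np.random.default_rng(42))
        b = gibbs_sweep(st0, data, spec, Priors(),
                        np.random.default_rng(42))
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.fspat, b.fspat)
        assert a.var_resid == b.var_resid

    def test_sum_to_zero_after_sweep(self, toy, rng):
        data, spec0 = toy
        spec = ModelSpec(covariate_names=spec0.covariate_names,
                         random_slope_names=("x",))
        st = LatentState.initial(spec, data)
        for _ in range(5):
            st = gibbs_sweep(st, data, spec, Priors(), rng)
        assert abs(st.b0.sum()) < 1e-10
        assert abs(st.bk["x"].sum()) < 1e-10
        assert abs(st.fspat.sum()) < 1e-10

    def test_input_state_unchanged(self, toy, rng):
        data, spec = toy
        st = LatentState.initial(spec, data)
        beta_before = st.beta.copy()
        gibbs_sweep(st, data, spec, Priors(), rng)
        assert np.array_equal(st.beta, beta_before)


class TestVarianceUpdate:
    def test_zero_ss_is_inverse_gamma_a_plus_half_m_b(self):
        """With SS = 0 the draw is IG(a + m/2, b); its mean b/(a + m/2 - 1)
        is checked by Monte Carlo."""
        rng = np.random.default_rng(7)
        a, b, m = 3.0, 2.0, 4.0
        draws = np.array([sample_variance(rng, a, b, m, 0.0)
                          for _ in range(40_000)])
        assert draws.mean() == pytest.approx(b / (a + m / 2 - 1), rel=0.03)

    def test_car_pairwise_ss_by_hand(self, cycle4, toy):
        """Edge sum of squared differences on the 4-cycle with f=(1,2,3,4):
        (1-2)^2+(2-3)^2+(3-4)^2+(4-1)^2 = 12."""
        data, _ = toy
        assert car_pairwise_ss(np.array([1.0, 2.0, 3.0, 4.0]), data) == 12.0


class TestModelSpecConfig:
    def test_yaml_roundtrip(self, tmp_path):
        spec = ModelSpec(covariate_names=("a", "b"), random_slope_names=("a",),
                         include_spatial=False, fixed_resid_variance=2.5)
        p = tmp_path / "model.yaml"
        spec.to_yaml(p)
        assert ModelSpec.from_yaml(p) == spec

    def test_unknown_slope_rejected(self):
        with pytest.raises(ValueError, match="random slopes"):
            ModelSpec(covariate_names=("a",), random_slope_names=("z",))


class TestOlsLimit:
    def test_flat_prior_posterior_mean_approaches_ols(self, rng):
        """With random effects and the spatial term off and a huge fixed-effect
        prior variance, the posterior mean of beta matches ordinary least
        squares on the pair rows within Monte-Carlo error."""
        g = graph_from_edges([(f"u{i}", f"u{j}")
                              for i, j in [(0, 1), (1, 2), (2, 3), (3, 4),
                                           (4, 0), (0, 2)]])
        df = pd.DataFrame({"outcome": rng.normal(size=5) * 10,
                           "x": rng.normal(size=5) * 3},
                          index=pd.Index(g.ids, name="id"))
        pairs = build_pairs(CountyTable(df), g)
        data = PairModelData.from_pairs(pairs, g)
        spec = ModelSpec(covariate_names=("x",), include_random_intercept=False,
                         include_spatial=False, include_modifier=False,
                         fixed_resid_variance=4.0)
        priors = Priors(fixed_prior_variance=1e10)
        st = LatentState.initial(spec, data)
        rng2 = np.random.default_rng(3)
        draws = []
        for _ in range(4000):
            st = gibbs_sweep(st, data, spec, priors, rng2)
            draws.append(st.beta.copy())
        draws = np.array(draws[500:])
        F = data.fixed_design(spec)
        ols = np.linalg.lstsq(F, data.y, rcond=None)[0]
        mcse = draws.std(axis=0) / np.sqrt(len(draws) / 10)
        assert np.all(np.abs(draws.mean(axis=0) - ols) < 4 * mcse + 1e-8)


class TestCarStationaryStructure:
    def test_adjacent_differences_tighter_than_distant(self):
        """Long-run CAR draws on a path: variance of f differences between
        adjacent units is smaller than between the two path endpoints."""
        g = graph_from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
        df = pd.DataFrame({"outcome": np.zeros(5)},
                          index=pd.Index(g.ids, name="id"))
        pairs = build_pairs(CountyTable(df), g)
        data = PairModelData.from_pairs(pairs, g, covariate_names=[])
        spec = ModelSpec(covariate_names=(), include_random_intercept=False,
                         include_modifier=False,
                         fixed_resid_variance=1e8)  # likelihood ~ flat
        st = LatentState.initial(spec, data)
        st.var_spat = 1.0
        rng = np.random.default_rng(21)
        fs = []
        for _ in range(6000):
            st = gibbs_sweep(st, data, spec, Priors(), rng,
                             block_order=("fspat",))
            fs.append(st.fspat.copy())
        fs = np.array(fs[1000:])
        var_adjacent = np.var(fs[:, 0] - fs[:, 1])
        var_distant = np.var(fs[:, 0] - fs[:, 4])
        assert var_adjacent < var_distant
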