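"""Regression initialisation, objectives and bounded refinement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnode import (
    Dataset,
    ExperimentData,
    InferenceConfig,
    PriorKnowledge,
    UnidentifiableStructureError,
    higher_order_init,
    numeric_derivative,
    objective_output,
    objective_total,
    regress_init,
)
from grnode.identify import (
    RegressionDesign,
    SubmodelProblem,
    SubmodelStructure,
    fit_submodel,
)

from conftest import TIMES6, single_gene_dataset


class TestNumericDerivative:
    def test_linear_slope(self):
        t = np.array([0.0, 1.0, 2.0])
        assert np.allclose(numeric_derivative(3 * t, t), [3, 3, 3])

    def test_constant_is_zero(self):
        t = np.linspace(0, 5, 7)
        assert np.allclose(numeric_derivative(np.full(7, 2.5), t), 0.0)

    def test_quadratic_one_sided_boundaries(self):
        t = np.array([0.0, 1.0, 2.0])
        assert np.allclose(numeric_derivative(t ** 2, t), [1.0, 2.0, 3.0])

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            numeric_derivative([1.0, 2.0, 3.0], [0.0, 1.0, 1.0])


class TestRegressInit:
    def test_generative_recovery_exact_derivatives(self):
        # dx = -x + u with exact values and derivatives: theta = (1, -1)
        t = np.linspace(0, 8, 33)
        x = 1 - np.exp(-t)
        design = RegressionDesign(
            U=np.ones((len(t), 1)), X=x[:, None],
            weights=np.ones(len(t)), dxdt=np.exp(-t),
        )
        theta = regress_init(design)
        assert np.allclose(theta, [1.0, -1.0], atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_weighted_pseudoinverse_oracle(self, seed):
        """theta must match the brute-force (G' W G)^-1 G' W y formula."""
        rng = np.random.default_rng(seed)
        rows, pu, px = rng.integers(10, 40), rng.integers(1, 3), rng.integers(1, 4)
        U = rng.normal(size=(rows, pu))
        X = rng.normal(size=(rows, px))
        w = rng.uniform(0.1, 2.0, rows)
        y = rng.normal(size=rows)
        theta = regress_init(RegressionDesign(U=U, X=X, weights=w, dxdt=y))
        G = np.hstack([U, X])
        W = np.diag(w)
        oracle = np.linalg.pinv(G.T @ W @ G) @ G.T @ W @ y
        assert np.allclose(theta, oracle, atol=1e-8)

    def test_unweighted_equals_ols(self, rng):
        G = rng.normal(size=(25, 4))
        y = rng.normal(size=25)
        theta = regress_init(RegressionDesign(
            U=G[:, :2], X=G[:, 2:], weights=np.ones(25), dxdt=y))
        assert np.allclose(theta, np.linalg.pinv(G) @ y, atol=1e-8)

    def test_collinear_columns_unidentifiable(self, rng):
        col = rng.normal(size=20)
        with pytest.raises(UnidentifiableStructureError):
            regress_init(RegressionDesign(
                U=col[:, None], X=col[:, None],
                weights=np.ones(20), dxdt=rng.normal(size=20)))


class TestObjectives:
    def _dataset(self):
        ds, _ = single_gene_dataset()
        return ds

    def test_perfect_fit_is_zero(self):
        ds = self._dataset()
        sims = [ds.experiments[0].Y[:, 0]]
        assert objective_output(ds, 0, sims) == 0.0

    def test_single_deviation_weighted(self):
        ds = self._dataset()
        ds.experiments[0].weights[:] = 0.5
        sim = ds.experiments[0].Y[:, 0].copy()
        sim[3] += 0.2
        assert objective_output(ds, 0, [sim]) == pytest.approx(0.5 * 0.04)

    def test_additive_over_experiments(self, rng):
        e1 = ExperimentData(TIMES6, rng.normal(size=(6, 1)), np.ones((6, 1)),
                            ["G1"], ["u1"])
        e2 = ExperimentData(TIMES6, rng.normal(size=(6, 1)), np.ones((6, 1)),
                            ["G1"], ["u1"])
        sims = [rng.normal(size=6), rng.normal(size=6)]
        both = objective_output(Dataset([e1, e2]), 0, sims)
        j1 = objective_output(Dataset([e1]), 0, sims[:1])
        j2 = objective_output(Dataset([e2]), 0, sims[1:])
        assert both == pytest.approx(j1 + j2)

    def test_invariant_under_experiment_reordering(self, rng):
        e1 = ExperimentData(TIMES6, rng.normal(size=(6, 1)), np.ones((6, 1)),
                            ["G1"], ["u1"])
        e2 = ExperimentData(TIMES6, rng.normal(size=(6, 1)), np.ones((6, 1)),
                            ["G1"], ["u1"])
        sims = [rng.normal(size=6), rng.normal(size=6)]
        a = objective_output(Dataset([e1, e2]), 0, sims)
        b = objective_output(Dataset([e2, e1]), 0, sims[::-1])
        assert a == pytest.approx(b)

    def test_penalty_zero_lambda_and_agreement(self):
        prior = PriorKnowledge.empty(["G1", "G2"], ["u1"])
        prior.A_flex[0, 1] = 10.0
        prior.S_A[0, 1] = 1.0
        j = objective_total(0.3, 0, {1: 0.7}, {}, prior, lam=0.0)
        assert j == 0.3
        j = objective_total(0.3, 0, {1: 0.7}, {}, prior, lam=0.5)
        assert j == pytest.approx(0.3)  # edge agrees, d = 0

    def test_single_violated_edge_adds_lambda(self):
        prior = PriorKnowledge.empty(["G1", "G2"], ["u1"])
        prior.A_flex[0, 1] = 10.0
        prior.S_A[0, 1] = 1.0
        # edge absent from the model: d = 1, contributes s * lambda
        j = objective_total(0.3, 0, {}, {}, prior, lam=0.5)
        assert j == pytest.approx(0.8)


class TestHigherOrderInit:
    def test_order_one_is_identity(self):
        s = SubmodelStructure(0, (0,), (0,))
        theta = np.array([1.0, -1.0])
        assert np.array_equal(higher_order_init(theta, s, 1), theta)

    @given(a=st.floats(-5.0, -0.1), b=st.floats(-3.0, 3.0),
           r=st.integers(1, 4))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_gain_and_time_constant_preserved(self, a, b, r):
        """Static gain b/(-a)·(1/(-a))^{r-1} and total time constant r/(-a)
        must be invariant under the order adaptation (checked to 1e-10)."""
        s = SubmodelStructure(0, (0,), (0,))
        theta = np.array([b, a])
        out = higher_order_init(theta, s, r)
        b_r, a_r = out[0], out[1]
        gain = lambda bb, aa, rr: bb / (-aa) * (1.0 / (-aa)) ** (rr - 1)
        assert gain(b_r, a_r, r) == pytest.approx(gain(b, a, 1), abs=1e-10,
                                                  rel=1e-10)
        assert r / (-a_r) == pytest.approx(1 / (-a), abs=1e-10, rel=1e-10)


def _problem(ds, structure, config=None, prior=None, lam=0.0):
    lookup = lambda j, e: ds.experiments[e].Y[:, j]
    return SubmodelProblem(structure, ds, lookup,
                           config or InferenceConfig(), prior, lam)


class TestFitSubmodel:
    def test_noise_free_recovery_dense_grid(self):
        ds, _ = single_gene_dataset(times=np.linspace(0, 8, 21))
        problem = _problem(ds, SubmodelStructure(0, (0,), (0,)))
        fit = fit_submodel(problem)
        assert np.allclose(fit.theta, [1.0, -1.0], atol=1e-3)
        assert fit.j_total < 1e-8

    def test_start_at_truth_stays_at_truth(self):
        ds, _ = single_gene_dataset(times=np.linspace(0, 8, 21))
        problem = _problem(ds, SubmodelStructure(0, (0,), (0,)))
        truth = np.array([1.0, -1.0])
        fit = fit_submodel(problem, truth)
        assert fit.j_total <= problem.j_total(truth) + 1e-12

    def test_noisy_two_experiment_recovery(self):
        # sigma = 0.05 noise, two experiments: (b, a) within 0.15 of truth
        rng = np.random.default_rng(3)
        times = np.linspace(0, 8, 17)
        exps = []
        for _ in range(2):
            x = 1 - np.exp(-times)
            y = x + rng.normal(0, 0.05, len(times))
            y -= y[0]
            exps.append(ExperimentData(times, y[:, None],
                                       np.ones((len(times), 1)), ["G1"], ["u1"]))
        ds = Dataset(exps)
        fit = fit_submodel(_problem(ds, SubmodelStructure(0, (0,), (0,))))
        assert abs(fit.theta[0] - 1.0) < 0.15
        assert abs(fit.theta[1] + 1.0) < 0.15

    def test_bounds_are_respected(self):
        ds, _ = single_gene_dataset(times=np.linspace(0, 8, 21))
        cfg = InferenceConfig(coeff_bound=0.5)  # excludes the true b = 1
        problem = _problem(ds, SubmodelStructure(0, (0,), (0,)), cfg)
        fit = fit_submodel(problem)
        assert fit.theta[0] == pytest.approx(0.5)  # lands on the bound
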