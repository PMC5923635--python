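"""Model-layer checks: risks, likelihood, ICAR densities, priors.

The ICAR checks compare the pairwise-difference form and the area-level
full conditionals against dense graph-Laplacian oracles, including an
exhaustive sweep over every labeled graph on up to six areas.
"""

import itertools

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist, norm, poisson

from scsmap.areal_graph import build_graph, grid_graph
from scsmap.model import (
    ModelState,
    PriorSpec,
    icar_full_conditional,
    icar_pairwise_log_density,
    log_likelihood,
    log_posterior,
    log_prior,
    relative_risks,
)
from scsmap.outcome_data import ExpectedCounts, OutcomeTable


def state_for(n, **kw):
    return ModelState.zeros(n, **kw)


def table_for(O, N):
    return OutcomeTable(
        area_ids=tuple(f"a{i}" for i in range(len(N))),
        O=np.asarray(O, dtype=float),
        N=np.asarray(N, dtype=float),
    )


class TestRelativeRisks:
    def test_null_state_gives_unit_risks(self):
        r1, r2 = relative_risks(state_for(4))
        assert np.allclose(r1, 1) and np.allclose(r2, 1)

    def test_asymmetric_scaling_of_shared_surface(self):
        st = state_for(3, log_delta=np.log(0.5))
        st.theta = np.array([0.1, 0.1, 0.1])
        r1, r2 = relative_risks(st)
        assert np.allclose(r1, np.exp(0.05))
        assert np.allclose(r2, np.exp(0.2))

    def test_unit_delta_symmetry(self):
        st = state_for(5)
        st.theta = np.linspace(-0.2, 0.2, 5)
        r1, r2 = relative_risks(st)
        assert np.allclose(r1, r2)

    def test_gradient_asymmetry_for_small_delta(self):
        # for delta < 1 the shared surface is steeper on outcome 2
        st = state_for(6, log_delta=np.log(0.5))
        st.theta = np.sin(np.arange(6))
        d = st.delta
        assert np.var(d * st.theta) < np.var(st.theta / d)


class TestLogLikelihood:
    def test_single_area_zero_count(self):
        t = table_for([[0, 0]], [100])
        e = ExpectedCounts(e=np.array([[1.0, 1.0]]))
        # each cell contributes -lambda = -1
        assert log_likelihood(state_for(1), t, e) == pytest.approx(-2.0)

    def test_matches_scipy_poisson_oracle(self):
        rng = np.random.default_rng(0)
        n = 8
        O = rng.integers(0, 40, size=(n, 2)).astype(float)
        e = ExpectedCounts(e=rng.uniform(5, 30, size=(n, 2)))
        st = state_for(n, log_delta=np.log(0.7))
        st.theta = rng.normal(0, 0.2, n)
        st.u1 = rng.normal(0, 0.1, n)
        r1, r2 = relative_risks(st)
        lam = e.e * np.column_stack([r1, r2])
        oracle = poisson.logpmf(O, lam).sum()
        t = table_for(O, np.full(n, 1000.0))
        assert log_likelihood(st, t, e) == pytest.approx(oracle, abs=1e-9)

    def test_invariant_to_e_r_rebalancing(self):
        t = table_for([[3, 1], [4, 2]], [100, 100])
        e1 = ExpectedCounts(e=np.full((2, 2), 2.0))
        e2 = ExpectedCounts(e=np.full((2, 2), 4.0))
        st1 = state_for(2)
        st2 = state_for(2, alpha=np.log([0.5, 0.5]))
        assert log_likelihood(st1, t, e1) == pytest.approx(log_likelihood(st2, t, e2))

    def test_fractional_counts_accepted(self):
        t = table_for([[3.5, 1.5]], [100])
        e = ExpectedCounts(e=np.array([[3.5, 1.5]]))
        assert np.isfinite(log_likelihood(state_for(1), t, e))


def all_labeled_graphs(n):
    pairs = list(itertools.combinations(range(n), 2))
    for mask in range(2 ** len(pairs)):
        yield [pairs[b] for b in range(len(pairs)) if mask >> b & 1]


class TestICARDensity:
    def test_constant_field_has_zero_quadratic_term(self):
        g = grid_graph(3, 3, "rook")
        val_c = icar_pairwise_log_density(np.full(9, 3.7), g, tau=2.0)
        val_0 = icar_pairwise_log_density(np.zeros(9), g, tau=2.0)
        assert val_c == pytest.approx(val_0)  # translation invariance at work

    def test_two_node_quadratic(self):
        g = build_graph(["a", "b"], [("a", "b")])
        base = icar_pairwise_log_density(np.zeros(2), g, tau=1.0)
        val = icar_pairwise_log_density(np.array([0.0, 2.0]), g, tau=1.0)
        assert val - base == pytest.approx(-2.0)

    def test_matches_laplacian_quadratic_form(self):
        rng = np.random.default_rng(5)
        ids = list("abcde")
        g = build_graph(ids, [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("a", "e")])
        x = rng.normal(size=5)
        tau = 1.7
        Q = g.laplacian()
        oracle = 0.5 * (g.n - g.n_components) * np.log(tau) - 0.5 * tau * x @ Q @ x
        assert icar_pairwise_log_density(x, g, tau) == pytest.approx(oracle, abs=1e-12)

    def test_translation_invariance(self):
        g = grid_graph(2, 3, "queen")
        x = np.arange(6, dtype=float)
        a = icar_pairwise_log_density(x, g, 0.8)
        b = icar_pairwise_log_density(x + 11.3, g, 0.8)
        assert a == b


class TestICARFullConditional:
    def test_single_neighbour(self):
        g = build_graph(["a", "b"], [("a", "b")])
        mean, var = icar_full_conditional(0, np.array([0.0, 2.0]), g, tau=1.0)
        assert mean == 2.0 and var == 1.0

    def test_interior_grid_node(self):
        g = grid_graph(3, 3, "rook")
        x = np.zeros(9)
        centre = g.index_of("r1c1")
        for aid, v in (("r0c1", 1.0), ("r1c0", 2.0), ("r1c2", 3.0), ("r2c1", 4.0)):
            x[g.index_of(aid)] = v
        mean, var = icar_full_conditional(centre, x, g, tau=2.0)
        assert mean == pytest.approx(2.5)
        assert var == pytest.approx(1 / 8)

    def test_island_rejected(self):
        g = build_graph(["a", "b", "c"], [("a", "b")])
        with pytest.raises(ValueError, match="'c'"):
            icar_full_conditional(2, np.zeros(3), g, tau=1.0)

    def test_exhaustive_agreement_with_laplacian_oracle(self):
        """Conditional mean/variance from the joint Laplacian form, every
        labeled graph on 2..6 nodes."""
        rng = np.random.default_rng(123)
        worst = 0.0
        for n in range(2, 7):
            x = rng.normal(size=n)
            tau = 0.9
            for edges in all_labeled_graphs(n):
                if not edges:
                    continue
                g = build_graph([str(i) for i in range(n)], [(str(i), str(j)) for i, j in edges])
                Q = g.laplacian()
                for i in range(n):
                    if g.m[i] == 0:
                        continue
                    mean, var = icar_full_conditional(i, x, g, tau)
                    # complete the square in exp(-tau/2 x^T Q x)
                    mean_oracle = -(Q[i] @ x - Q[i, i] * x[i]) / Q[i, i]
                    var_oracle = 1.0 / (tau * Q[i, i])
                    worst = max(worst, abs(mean - mean_oracle), abs(var - var_oracle))
        assert worst < 1e-8


class TestPriors:
    def test_preset_values(self):
        held = PriorSpec.held()
        assert all(v == (1.0, 0.01) for v in held.precision_priors.values())
        anc = PriorSpec.ancelet()
        assert anc.precision_priors["tau_theta"] == (0.1, 0.1)
        assert anc.precision_priors["tau_u1"] == (0.01, 0.01)
        assert held.log_delta_precision == 5.9
        with pytest.raises(ValueError):
            PriorSpec.preset("jeffreys")

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "priors.yaml"
        PriorSpec.ancelet().save(p)
        back = PriorSpec.load(p)
        assert back.precision_priors == PriorSpec.ancelet().precision_priors
        assert back.name == "ancelet"

    def test_log_prior_matches_per_term_oracle(self):
        g = grid_graph(2, 2, "rook")
        priors = PriorSpec.held()
        st = state_for(4, tau_theta=2.0, tau_s1=3.0, tau_s2=4.0, tau_u1=5.0, tau_u2=6.0)
        st.u1 = np.array([0.1, -0.1, 0.2, 0.0])
        val = log_prior(st, priors, g)
        oracle = 2 * norm.logpdf(0.0, 0, priors.alpha_prior_sd)
        oracle += norm.logpdf(0.0, 0, 1 / np.sqrt(5.9))
        for tau in (2.0, 3.0, 4.0):  # ICAR terms: rank/2 log tau, zero quad
            oracle += 0.5 * (4 - 1) * np.log(tau)
        oracle += norm.logpdf(st.u1, 0, 1 / np.sqrt(5.0)).sum()
        oracle += norm.logpdf(np.zeros(4), 0, 1 / np.sqrt(6.0)).sum()
        for tau in (2.0, 3.0, 4.0, 5.0, 6.0):
            oracle += gamma_dist.logpdf(tau, 1.0, scale=1 / 0.01)
        assert val == pytest.approx(oracle, abs=1e-9)

    def test_delta_term_peaks_at_prior_mean(self):
        g = grid_graph(2, 2, "rook")
        priors = PriorSpec.held()
        vals = []
        for ld in (0.0, 0.4, 0.9):
            st = state_for(4, log_delta=ld)
            vals.append(log_prior(st, priors, g))
        assert vals[0] > vals[1] > vals[2]


class TestLogPosterior:
    def test_composition(self):
        rng = np.random.default_rng(1)
        g = grid_graph(2, 3, "rook")
        t = table_for(rng.integers(1, 30, size=(6, 2)), np.full(6, 500.0))
        e = ExpectedCounts(e=rng.uniform(2, 20, size=(6, 2)))
        priors = PriorSpec.held()
        st = state_for(6)
        st.theta = rng.normal(0, 0.1, 6)
        assert log_posterior(st, t, e, priors, g) == pytest.approx(
            log_likelihood(st, t, e) + log_prior(st, priors, g)
        )

    def test_outcome_relabelling_symmetry(self):
        """Swapping the two outcomes while mapping delta to 1/delta (and
        exchanging the outcome-specific terms) leaves the posterior density
        unchanged under the symmetric default priors."""
        rng = np.random.default_rng(6)
        g = grid_graph(2, 3, "rook")
        O = rng.integers(1, 30, size=(6, 2)).astype(float)
        e_vals = rng.uniform(2, 20, size=(6, 2))
        priors = PriorSpec.held()
        st = state_for(6, log_delta=np.log(0.6), tau_s1=2.0, tau_s2=3.0)
        st.theta = rng.normal(0, 0.1, 6)
        st.s1 = rng.normal(0, 0.1, 6)
        st.u2 = rng.normal(0, 0.1, 6)
        swapped = state_for(
            6, log_delta=-st.log_delta, tau_s1=st.tau_s2, tau_s2=st.tau_s1
        )
        swapped.alpha = st.alpha[::-1].copy()
        swapped.theta = st.theta.copy()
        swapped.s1, swapped.s2 = st.s2.copy(), st.s1.copy()
        swapped.u1, swapped.u2 = st.u2.copy(), st.u1.copy()
        lp = log_posterior(
            st, table_for(O, np.full(6, 500.0)), ExpectedCounts(e=e_vals), priors, g
        )
        lp_swapped = log_posterior(
            swapped,
            table_for(O[:, ::-1], np.full(6, 500.0)),
            ExpectedCounts(e=e_vals[:, ::-1]),
            priors,
            g,
        )
        assert lp_swapped == pytest.approx(lp, abs=1e-9)

    def test_identifiability_translation(self):
        """Shifting theta by c while absorbing delta*c and c/delta into the
        intercepts changes the likelihood not at all."""
        rng = np.random.default_rng(2)
        g = grid_graph(2, 3, "rook")
        t = table_for(rng.integers(1, 30, size=(6, 2)), np.full(6, 500.0))
        e = ExpectedCounts(e=rng.uniform(2, 20, size=(6, 2)))
        st = state_for(6, log_delta=np.log(0.6))
        st.theta = rng.normal(0, 0.1, 6)
        c = 0.37
        shifted = st.copy()
        shifted.theta = st.theta + c
        shifted.alpha = st.alpha - np.array([st.delta * c, c / st.delta])
        assert log_likelihood(shifted, t, e) == pytest.approx(
            log_likelihood(st, t, e), abs=1e-8
        )
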