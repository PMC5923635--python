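"""Sampler checks: single steps against conjugate/closed-form oracles,
determinism, recentring, prior recovery, and agreement between the
accelerated sampler and the plain single-site reference."""

import numpy as np
import pytest

from scsmap.areal_graph import build_graph, grid_graph
from scsmap.mcmc import (
    MCMCConfig,
    PosteriorSamples,
    gibbs_update_precision,
    mh_update_field,
    mh_update_scalars,
    recenter,
    run_mcmc,
)
from scsmap.model import ModelState, PriorSpec, relative_risks
from scsmap.outcome_data import ExpectedCounts, OutcomeTable, compute_expected
from scsmap.synthetic import generate_dataset, sample_icar_field


class TestGibbsPrecision:
    def test_zero_unstructured_field_closed_form(self):
        rng = np.random.default_rng(0)
        field = np.zeros(30)
        draws = [gibbs_update_precision(field, None, (1.0, 0.01), rng) for _ in range(4000)]
        # posterior is Gamma(1 + 15, 0.01); check the sample mean
        target = (1 + 15) / 0.01
        se = np.sqrt(16) / 0.01 / np.sqrt(len(draws))
        assert abs(np.mean(draws) - target) < 3 * se

    def test_two_node_icar_rate(self):
        g = build_graph(["a", "b"], [("a", "b")])
        rng = np.random.default_rng(1)
        x = np.array([0.0, 2.0])
        # rate = b + (1/2)(0-2)^2 = b + 2; shape = a + (2-1)/2
        draws = np.array(
            [gibbs_update_precision(x, g, (1.0, 0.01), rng) for _ in range(20000)]
        )
        shape, rate = 1.5, 2.01
        se = np.sqrt(shape) / rate / np.sqrt(draws.size)
        assert abs(draws.mean() - shape / rate) < 3 * se

    def test_nonzero_field_monte_carlo_moments(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.5, size=40)
        a, b = 1.0, 0.01
        shape = a + 20
        rate = b + 0.5 * np.sum(x**2)
        draws = np.array(
            [gibbs_update_precision(x, None, (a, b), rng) for _ in range(100_000)]
        )
        se = np.sqrt(shape) / rate / np.sqrt(draws.size)
        assert abs(draws.mean() - shape / rate) < 3 * se

    def test_degenerate_icar_field_is_valid(self):
        g = grid_graph(2, 2, "rook")
        rng = np.random.default_rng(3)
        val = gibbs_update_precision(np.full(4, 1.3), g, (1.0, 0.01), rng)
        assert val > 0  # rate collapses to b, still a proper draw


class TestFieldUpdate:
    def test_tiny_scale_keeps_state(self):
        g = grid_graph(3, 3, "rook")
        st = ModelState.zeros(9)
        st.u1 = np.full(9, 0.05)
        rng = np.random.default_rng(4)
        before = st.u1.copy()
        acc = mh_update_field("u1", st, None, None, g, 1e-9, rng)
        assert acc.mean() > 0.95
        assert np.allclose(st.u1, before, atol=1e-6)

    def test_prior_only_field_matches_direct_icar_sampler(self):
        """Pairwise-difference energy of MH draws matches the exact sampler's
        trace identity E[sum (x_i - x_j)^2] = (n - c)/tau."""
        g = grid_graph(3, 3, "rook")
        tau = 4.0
        rng = np.random.default_rng(5)
        st = ModelState.zeros(9, tau_s1=tau)
        energies = []
        for sweep in range(4000):
            mh_update_field("s1", st, None, None, g, 0.5, rng)
            st.s1 -= st.s1.mean()
            if sweep >= 500 and sweep % 5 == 0:
                d = st.s1
                ei = np.array([i for i, j in g.edges])
                ej = np.array([j for i, j in g.edges])
                energies.append(np.sum((d[ei] - d[ej]) ** 2))
        expected = (9 - 1) / tau
        direct = []
        rng2 = np.random.default_rng(6)
        for _ in range(2000):
            x = sample_icar_field(g, tau, rng2)
            ei = np.array([i for i, j in g.edges])
            ej = np.array([j for i, j in g.edges])
            direct.append(np.sum((x[ei] - x[ej]) ** 2))
        # both estimates near the analytic value, generous MC tolerance
        assert np.mean(energies) == pytest.approx(expected, rel=0.15)
        assert np.mean(direct) == pytest.approx(expected, rel=0.15)

    def test_invalid_inputs(self):
        g = grid_graph(2, 2, "rook")
        st = ModelState.zeros(4)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="scale"):
            mh_update_field("u1", st, None, None, g, -1.0, rng)
        with pytest.raises(ValueError, match="unknown field"):
            mh_update_field("phi", st, None, None, g, 0.1, rng)


class TestScalarUpdate:
    def test_intercept_concentrates_at_inflation_factor(self):
        """O = 2e with everything else null pins alpha_1 near log 2."""
        g = grid_graph(4, 4, "rook")
        n = 16
        e = ExpectedCounts(e=np.full((n, 2), 50.0))
        table = OutcomeTable(
            area_ids=g.area_ids,
            O=np.column_stack([np.full(n, 100.0), np.full(n, 50.0)]),
            N=np.full(n, 1000.0),
        )
        cfg = MCMCConfig(chains=2, iterations=1500, burn_in=500, thinning=2, seed=8)
        s = run_mcmc(cfg, table, e, PriorSpec.held(), g)
        a1 = s.stacked("alpha1")
        assert abs(a1.mean() - np.log(2)) < 0.05
        assert abs(s.stacked("alpha2").mean()) < 0.05


class TestRecenter:
    def test_centered_state_unchanged(self):
        st = ModelState.zeros(4)
        st.theta = np.array([0.2, -0.2, 0.1, -0.1])
        before = st.theta.copy()
        recenter(st)
        assert np.allclose(st.theta, before)

    def test_shift_absorbed_without_changing_risks(self):
        st = ModelState.zeros(4, log_delta=np.log(0.5))
        st.theta = np.array([0.2, -0.2, 0.1, -0.1]) + 1.0
        st.s1 = np.array([0.3, 0.3, 0.3, 0.3])
        r_before = relative_risks(st)
        a1_before = st.alpha[0]
        recenter(st)
        r_after = relative_risks(st)
        assert abs(st.theta.mean()) < 1e-12
        assert np.allclose(r_before[0], r_after[0], rtol=1e-12)
        assert np.allclose(r_before[1], r_after[1], rtol=1e-12)
        # mean(s1)=0.3 flows into alpha_1, plus delta * mean(theta)
        assert st.alpha[0] == pytest.approx(a1_before + 0.3 + 0.5 * 1.0)


class TestRunMCMC:
    def test_determinism_and_draw_counts(self, small_grid, small_dataset):
        table, expected, _ = small_dataset
        cfg = MCMCConfig(chains=2, iterations=1000, burn_in=500, thinning=5, seed=21)
        assert cfg.kept_per_chain == 100
        s1 = run_mcmc(cfg, table, expected, PriorSpec.held(), small_grid)
        s2 = run_mcmc(cfg, table, expected, PriorSpec.held(), small_grid)
        assert s1.n_draws == 100
        for key in s1.scalars:
            assert np.array_equal(s1.scalars[key], s2.scalars[key])
        for key in s1.fields:
            assert np.array_equal(s1.fields[key], s2.fields[key])

    def test_adapted_acceptance_rates_reasonable(self, small_grid, small_dataset):
        table, expected, _ = small_dataset
        cfg = MCMCConfig(chains=1, iterations=3000, burn_in=1500, thinning=5, seed=22)
        s = run_mcmc(cfg, table, expected, PriorSpec.held(), small_grid)
        for block in ("theta", "s1", "s2", "u1", "u2", "alpha1", "alpha2", "log_delta"):
            assert 0.1 <= s.acceptance[0][block] <= 0.6, block

    def test_risks_invariant_spotcheck_via_deviance_finite(self, small_grid, small_dataset):
        table, expected, _ = small_dataset
        cfg = MCMCConfig(chains=1, iterations=600, burn_in=300, thinning=3, seed=23)
        s = run_mcmc(cfg, table, expected, PriorSpec.held(), small_grid)
        assert np.all(np.isfinite(s.stacked("deviance")))
        # spatial fields stored post-recentring: sum-to-zero holds per draw
        assert np.allclose(s.fields["theta"].sum(axis=-1), 0, atol=1e-9)
        assert np.allclose(s.fields["s1"].sum(axis=-1), 0, atol=1e-9)

    def test_prior_recovery_of_log_delta(self, small_grid):
        """Likelihood off: sampled log delta reproduces its Normal(0, 1/5.9)
        prior in mean and precision."""
        cfg = MCMCConfig(chains=2, iterations=30000, burn_in=3000, thinning=10, seed=24)
        s = run_mcmc(cfg, None, None, PriorSpec.held(), small_grid, prior_only=True)
        ld = s.stacked("log_delta")
        n_eff = ld.size / 10  # crude IACT allowance for the thinned RW chain
        se_mean = (1 / np.sqrt(5.9)) / np.sqrt(n_eff)
        assert abs(ld.mean()) < 3 * se_mean
        assert 1.0 / np.var(ld) == pytest.approx(5.9, rel=0.10)

    def test_accelerated_and_single_site_samplers_agree(self, small_grid):
        """The Laplace-refresh/joint blocks must leave the posterior
        untouched: medians match a plain single-site run on a small case."""
        table, truth = generate_dataset("shared_dominant", small_grid, seed=9)
        expected = compute_expected(table)
        pr = PriorSpec.held()
        fancy = run_mcmc(
            MCMCConfig(chains=2, iterations=8000, burn_in=2000, thinning=5, seed=31),
            table, expected, pr, small_grid,
        )
        plain = run_mcmc(
            MCMCConfig(
                chains=2, iterations=30000, burn_in=6000, thinning=10, seed=32,
                simple_updates=True,
            ),
            table, expected, pr, small_grid,
        )
        assert np.median(fancy.stacked("log_delta")) == pytest.approx(
            np.median(plain.stacked("log_delta")), abs=0.12
        )
        assert np.median(fancy.stacked("alpha1")) == pytest.approx(
            np.median(plain.stacked("alpha1")), abs=0.02
        )
        th_f = fancy.fields["theta"].reshape(-1, small_grid.n).mean(axis=0)
        th_p = plain.fields["theta"].reshape(-1, small_grid.n).mean(axis=0)
        assert np.corrcoef(th_f, th_p)[0, 1] > 0.98

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(chains=0, iterations=10, burn_in=1)
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, burn_in=10, thinning=0)

    def test_samples_round_trip_npz(self, tmp_path, small_grid, small_dataset):
        table, expected, _ = small_dataset
        cfg = MCMCConfig(chains=2, iterations=400, burn_in=200, thinning=2, seed=25)
        s = run_mcmc(cfg, table, expected, PriorSpec.held(), small_grid)
        path = tmp_path / "draws.npz"
        s.save(path)
        back = PosteriorSamples.load(path)
        assert np.array_equal(back.scalars["log_delta"], s.scalars["log_delta"])
        assert back.area_ids == s.area_ids
        assert back.config.iterations == 400
        df = back.to_long_dataframe()
        assert set(df.columns) == {"chain", "iteration", "parameter", "value"}
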