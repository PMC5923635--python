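"""Shared fixtures.

The expensive multi-replicate MCMC experiments are session-scoped so the
recovery/diagnostics/model-comparison tests all read from one set of runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from scsmap.areal_graph import grid_graph
from scsmap.diagnostics import _pooled_mc_error, dic_from_samples, gelman_rubin
from scsmap.mcmc import MCMCConfig, run_mcmc
from scsmap.model import PriorSpec
from scsmap.outcome_data import compute_expected
from scsmap.synthetic import default_graph, generate_dataset

N_RECOVERY_REPLICATES = 5
N_DIC_REPLICATES = 10


@pytest.fixture(scope="session")
def queen_grid():
    return default_graph()


@pytest.fixture(scope="session")
def small_grid():
    return grid_graph(4, 4, "rook")


@pytest.fixture(scope="session")
def small_dataset(small_grid):
    table, truth = generate_dataset("shared_dominant", small_grid, seed=11)
    return table, compute_expected(table), truth


@pytest.fixture(scope="session")
def recovery_results(queen_grid):
    """Parameter-recovery experiment: shared-surface data with true delta 0.5.

    Each replicate simulates fresh data on the 140-area lattice and fits
    with the desk-scale protocol (2 chains x 5,000 iterations, 2,000
    burn-in, thinning 5).  Returns per-replicate summaries consumed by
    the recovery and diagnostics tests.
    """
    results = []
    for rep in range(N_RECOVERY_REPLICATES):
        table, truth = generate_dataset("shared_dominant", queen_grid, seed=rep + 1)
        expected = compute_expected(table)
        cfg = MCMCConfig.reduced(seed=500 + rep)
        samples = run_mcmc(cfg, table, expected, PriorSpec.held(), queen_grid)
        d = samples.get("log_delta")
        delta = np.exp(d.reshape(-1))
        lo, hi = np.quantile(delta, [0.025, 0.975])
        psrf = {
            name: gelman_rubin(samples.get(name))
            for name in (
                "log_delta",
                "alpha1",
                "alpha2",
                "tau_theta",
                "tau_s1",
                "tau_s2",
                "tau_u1",
                "tau_u2",
            )
        }
        results.append(
            {
                "true_delta": truth.state.delta,
                "median": float(np.median(delta)),
                "ci": (float(lo), float(hi)),
                "mc_error_ratio": _pooled_mc_error(d) / float(d.reshape(-1).std(ddof=1)),
                "psrf": psrf,
                "samples": samples,
                "table": table,
                "expected": expected,
            }
        )
    return results


@pytest.fixture(scope="session")
def dic_comparison_results(queen_grid):
    """DIC of the shared-component fit vs the independent-surfaces variant.

    Ten seeded replicates of shared-surface data, each fitted with and
    without the shared component under a shortened protocol (the DIC
    direction is a coarse signal and stabilizes quickly).
    """
    out = []
    for rep in range(N_DIC_REPLICATES):
        table, _ = generate_dataset("shared_dominant", queen_grid, seed=100 + rep)
        expected = compute_expected(table)
        base = dict(chains=2, iterations=1200, burn_in=400, thinning=4)
        full = run_mcmc(
            MCMCConfig(**base, seed=700 + rep), table, expected, PriorSpec.held(), queen_grid
        )
        novar = run_mcmc(
            MCMCConfig(**base, seed=900 + rep, shared=False),
            table,
            expected,
            PriorSpec.held(),
            queen_grid,
        )
        dic_full = dic_from_samples(full, table, expected)[2]
        dic_indep = dic_from_samples(novar, table, expected)[2]
        out.append({"dic_shared": dic_full, "dic_independent": dic_indep})
    return out
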