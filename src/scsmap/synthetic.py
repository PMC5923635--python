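"""Synthetic areal datasets from the shared-component generative model.

The motivating study's neighbourhood counts are not deposited, so
recovery and calibration experiments run on data generated forward from
the model itself, at the study's scale: 140 areas (a 14x10 lattice
standing in for the city's neighbourhood map), populations uniform on
7,000-10,000, counts Poisson around expected values modulated by a
shared ICAR surface, outcome-specific ICAR surfaces and unstructured
noise, with every area holding at least five counts.

ICAR fields are sampled exactly by eigendecomposition of the component
Laplacian — deliberately independent of the MCMC engine so that
prior-equivalence tests of the sampler mean something.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .areal_graph import ArealGraph, grid_graph
from .model import ModelState, relative_risks
from .outcome_data import ExpectedCounts, OutcomeTable

__all__ = [
    "Scenario",
    "TruthRecord",
    "SCENARIOS",
    "sample_icar_field",
    "generate_populations",
    "generate_dataset",
    "default_graph",
]


@dataclass(frozen=True)
class Scenario:
    """Generating parameters for one synthetic study condition.

    Precisions are on the generating fields; ``None`` pins a field to
    zero.  ``rate1``/``rate2`` are region-wide baseline event rates per
    person-year; with populations of 7,000-10,000 the defaults give
    expected counts of roughly 210-300 (a frequent outcome such as
    doctor visits) and 10-15 (a rare one such as hospital admissions).
    """

    name: str
    delta: float = 0.5
    tau_theta: float | None = 10.0
    tau_s: float | None = 100.0
    tau_u: float | None = 400.0
    rate1: float = 0.03
    rate2: float = 0.0015
    min_count: int | None = 5  # regenerate areas until every O_ik >= this


SCENARIOS: dict[str, Scenario] = {
    # strong shared surface, weak outcome-specific structure
    "shared_dominant": Scenario(name="shared_dominant"),
    # weak shared surface, strong outcome-specific structure
    "discrepant": Scenario(name="discrepant", delta=1.0, tau_theta=200.0, tau_s=10.0),
    # no spatial structure at all: O ~ Poisson(e)
    "null": Scenario(name="null", delta=1.0, tau_theta=None, tau_s=None, tau_u=None),
}


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth behind one generated dataset."""

    scenario: str
    seed: int
    state: ModelState
    graph: ArealGraph
    populations: np.ndarray
    expected: ExpectedCounts

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scenario": self.scenario,
            "seed": self.seed,
            "delta": self.state.delta,
            "alpha": self.state.alpha.tolist(),
            "theta": self.state.theta.tolist(),
            "s1": self.state.s1.tolist(),
            "s2": self.state.s2.tolist(),
            "u1": self.state.u1.tolist(),
            "u2": self.state.u2.tolist(),
            "populations": self.populations.tolist(),
            "area_ids": list(self.graph.area_ids),
        }
        Path(path).write_text(json.dumps(payload))


def default_graph() -> ArealGraph:
    """The 14x10 queen lattice used as the 140-area study stand-in."""
    return grid_graph(14, 10, "queen")


def sample_icar_field(
    graph: ArealGraph, tau: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact draw from the ICAR prior on the sum-to-zero subspace.

    Per connected component, the Laplacian Q is eigendecomposed and the
    draw is sum_j z_j v_j / sqrt(tau lambda_j) over the non-null
    eigenpairs, which realizes N(0, (tau Q)^+) restricted to the
    component's sum-to-zero subspace.  Singleton components (islands)
    get a zero entry.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    x = np.zeros(graph.n)
    Q = graph.laplacian()
    for label in range(graph.n_components):
        members = np.flatnonzero(graph.component_labels == label)
        if members.size == 1:
            continue
        sub = Q[np.ix_(members, members)]
        evals, evecs = np.linalg.eigh(sub)
        keep = evals > 1e-10 * evals.max()
        z = rng.standard_normal(int(keep.sum()))
        x[members] = evecs[:, keep] @ (z / np.sqrt(tau * evals[keep]))
        x[members] -= x[members].mean()  # kill residual null-space round-off
    return x


def generate_populations(
    n: int, rng: np.random.Generator, low: int = 7000, high: int = 10000
) -> np.ndarray:
    """Integer at-risk populations uniform on [low, high] (inclusive)."""
    if not 0 < low <= high:
        raise ValueError("need 0 < low <= high")
    return rng.integers(low, high + 1, size=n)


def generate_dataset(
    scenario: str | Scenario,
    graph: ArealGraph | None = None,
    seed: int = 0,
) -> tuple[OutcomeTable, TruthRecord]:
    """Generate one synthetic dataset with known truth.

    ``scenario`` is one of the named presets (``shared_dominant``,
    ``discrepant``, ``null``) or a custom :class:`Scenario`.  Counts are
    Poisson(e_ik * r_ki) with the risks built from exact ICAR and normal
    field draws; when the scenario sets ``min_count``, any area with a
    count below it is redrawn (count only) until the floor holds,
    emulating the study's every-area-has-at-least-five property.
    Deterministic in (scenario, graph, seed).
    """
    if isinstance(scenario, str):
        try:
            scenario = SCENARIOS[scenario]
        except KeyError:
            raise ValueError(
                f"unknown scenario {scenario!r}; expected one of {sorted(SCENARIOS)}"
            ) from None
    if graph is None:
        graph = default_graph()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2018]))
    n = graph.n

    N = generate_populations(n, rng)
    e = np.outer(N, [scenario.rate1, scenario.rate2])

    theta = (
        sample_icar_field(graph, scenario.tau_theta, rng)
        if scenario.tau_theta
        else np.zeros(n)
    )
    s1 = sample_icar_field(graph, scenario.tau_s, rng) if scenario.tau_s else np.zeros(n)
    s2 = sample_icar_field(graph, scenario.tau_s, rng) if scenario.tau_s else np.zeros(n)
    if scenario.tau_u:
        u1 = rng.standard_normal(n) / np.sqrt(scenario.tau_u)
        u2 = rng.standard_normal(n) / np.sqrt(scenario.tau_u)
    else:
        u1 = np.zeros(n)
        u2 = np.zeros(n)

    state = ModelState.zeros(
        n,
        log_delta=float(np.log(scenario.delta)),
        theta=theta,
        s1=s1,
        s2=s2,
        u1=u1,
        u2=u2,
        tau_theta=scenario.tau_theta or 1.0,
        tau_s1=scenario.tau_s or 1.0,
        tau_s2=scenario.tau_s or 1.0,
        tau_u1=scenario.tau_u or 1.0,
        tau_u2=scenario.tau_u or 1.0,
    )
    r1, r2 = relative_risks(state)
    lam = e * np.column_stack([r1, r2])
    O = rng.poisson(lam).astype(float)
    if scenario.min_count is not None:
        for _ in range(1000):
            low_mask = O < scenario.min_count
            if not low_mask.any():
                break
            O[low_mask] = rng.poisson(lam[low_mask])
        else:
            raise RuntimeError(
                "could not satisfy the minimum-count floor; "
                "expected counts are too small for the requested floor"
            )

    table = OutcomeTable(
        area_ids=graph.area_ids, O=O, N=N.astype(float), period_years=(1.0, 1.0)
    )
    truth = TruthRecord(
        scenario=scenario.name,
        seed=seed,
        state=state,
        graph=graph,
        populations=N,
        expected=ExpectedCounts(e=e),
    )
    return table, truth
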