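"""The shared-component spatial model (SCSM) for two areal outcomes.

Counts O_ik for outcomes k=1,2 in area i are conditionally independent
Poisson with mean lambda_ik = e_ik * r_ki, where e_ik is the expected
count under internal standardization and the relative risks are

    r_1i = exp(alpha_1 + delta * theta_i + s_1i + u_1i)
    r_2i = exp(alpha_2 + (1/delta) * theta_i + s_2i + u_2i)

theta is a latent spatial surface shared by both outcomes; the scaling
parameter delta > 0 lets the shared surface carry a different risk
gradient for each outcome (delta^2 is the ratio of the two gradients,
and delta = 1 means the surfaces contribute symmetrically).  s_1, s_2
are outcome-specific spatial residual surfaces and u_1, u_2 unstructured
(exchangeable normal) residuals.

theta, s_1 and s_2 carry intrinsic conditional autoregressive (ICAR)
priors on the contiguity graph: conditionally, a component is normal
around the mean of its neighbours with variance 1/(tau * m_i).  The
improper joint density, up to a constant, is

    ((n - c)/2) log tau - (tau/2) * sum_{i~j} (x_i - x_j)^2

with c the number of connected components (the rank deficiency).

Everything here is a pure function of a ModelState; the sampler in
:mod:`scsmap.mcmc` mutates copies of the state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.special import gammaln

from .areal_graph import ArealGraph
from .outcome_data import ExpectedCounts, OutcomeTable

__all__ = [
    "ModelState",
    "PriorSpec",
    "relative_risks",
    "log_likelihood",
    "icar_pairwise_log_density",
    "icar_full_conditional",
    "log_prior",
    "log_posterior",
]

PRECISION_NAMES = ("tau_theta", "tau_s1", "tau_s2", "tau_u1", "tau_u2")


@dataclass
class ModelState:
    """All latent quantities of the SCSM at one point of the chain."""

    alpha: np.ndarray  # (2,) log-baseline risks
    log_delta: float
    theta: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    u1: np.ndarray
    u2: np.ndarray
    tau_theta: float
    tau_s1: float
    tau_s2: float
    tau_u1: float
    tau_u2: float

    @property
    def delta(self) -> float:
        return float(np.exp(self.log_delta))

    @property
    def n(self) -> int:
        return self.theta.size

    def precisions(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PRECISION_NAMES}

    def copy(self) -> "ModelState":
        return replace(
            self,
            alpha=self.alpha.copy(),
            theta=self.theta.copy(),
            s1=self.s1.copy(),
            s2=self.s2.copy(),
            u1=self.u1.copy(),
            u2=self.u2.copy(),
        )

    def validate(self) -> None:
        for name in PRECISION_NAMES:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n = self.n
        for name in ("s1", "s2", "u1", "u2"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"field {name} has wrong length")

    @classmethod
    def zeros(cls, n: int, **kwargs) -> "ModelState":
        defaults = dict(
            alpha=np.zeros(2),
            log_delta=0.0,
            theta=np.zeros(n),
            s1=np.zeros(n),
            s2=np.zeros(n),
            u1=np.zeros(n),
            u2=np.zeros(n),
            tau_theta=1.0,
            tau_s1=1.0,
            tau_s2=1.0,
            tau_u1=1.0,
            tau_u2=1.0,
        )
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass(frozen=True)
class PriorSpec:
    """Prior settings for the SCSM.

    ``alpha_prior_sd`` realizes the "flat" normal prior on the intercepts
    as Normal(0, sd=1000): proper and numerically safe but flat at the
    data's scale.  ``log_delta_precision`` defaults to 5.9 (= 1/0.17),
    i.e. a prior median of 1 for delta and 95% prior probability that the
    gradient ratio delta^2 lies between 1/5 and 5.  Gamma hyperpriors on
    the five precisions are in shape/rate parameterization; the default
    "held" preset Gamma(1.0, 0.01) puts the mode of the implied variance
    at 0.005, and the "ancelet" sensitivity preset uses Gamma(0.1, 0.1)
    for the spatial and Gamma(0.01, 0.01) for the unstructured terms.
    """

    alpha_prior_sd: float = 1000.0
    log_delta_mean: float = 0.0
    log_delta_precision: float = 5.9
    precision_priors: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {name: (1.0, 0.01) for name in PRECISION_NAMES}
    )
    name: str = "held"

    def __post_init__(self) -> None:
        if self.alpha_prior_sd <= 0 or self.log_delta_precision <= 0:
            raise ValueError("prior scales must be positive")
        for key, (a, b) in self.precision_priors.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"gamma hyperprior for {key} must have positive shape/rate")

    @classmethod
    def held(cls) -> "PriorSpec":
        return cls()

    @classmethod
    def ancelet(cls) -> "PriorSpec":
        pp = {
            "tau_theta": (0.1, 0.1),
            "tau_s1": (0.1, 0.1),
            "tau_s2": (0.1, 0.1),
            "tau_u1": (0.01, 0.01),
            "tau_u2": (0.01, 0.01),
        }
        return cls(precision_priors=pp, name="ancelet")

    @classmethod
    def preset(cls, name: str) -> "PriorSpec":
        if name == "held":
            return cls.held()
        if name == "ancelet":
            return cls.ancelet()
        raise ValueError(f"unknown prior preset {name!r}; expected 'held' or 'ancelet'")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "alpha_prior_sd": self.alpha_prior_sd,
            "log_delta_mean": self.log_delta_mean,
            "log_delta_precision": self.log_delta_precision,
            "precision_priors": {k: list(v) for k, v in self.precision_priors.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PriorSpec":
        return cls(
            alpha_prior_sd=d.get("alpha_prior_sd", 1000.0),
            log_delta_mean=d.get("log_delta_mean", 0.0),
            log_delta_precision=d.get("log_delta_precision", 5.9),
            precision_priors={k: tuple(v) for k, v in d["precision_priors"].items()},
            name=d.get("name", "custom"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PriorSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def relative_risks(state: ModelState) -> tuple[np.ndarray, np.ndarray]:
    """Per-area relative risks (r_1, r_2) for the two outcomes."""
    d = state.delta
    r1 = np.exp(state.alpha[0] + d * state.theta + state.s1 + state.u1)
    r2 = np.exp(state.alpha[1] + state.theta / d + state.s2 + state.u2)
    return r1, r2


def log_likelihood(state: ModelState, table: OutcomeTable, expected: ExpectedCounts) -> float:
    """Poisson log likelihood sum_ik [O log(lambda) - lambda - lgamma(O+1)].

    The log-gamma term makes the density well defined for the fractional
    counts produced by annual averaging.
    """
    r1, r2 = relative_risks(state)
    lam = expected.e * np.column_stack([r1, r2])
    if not np.all(np.isfinite(lam)):
        i, k = np.argwhere(~np.isfinite(lam))[0]
        raise FloatingPointError(
            f"non-finite Poisson mean for area {table.area_ids[i]!r}, outcome {k + 1}"
        )
    O = table.O
    return float(np.sum(O * np.log(lam) - lam - gammaln(O + 1.0)))


def deviance(state: ModelState, table: OutcomeTable, expected: ExpectedCounts) -> float:
    """-2 * log likelihood, the quantity monitored for DIC."""
    return -2.0 * log_likelihood(state, table, expected)


def icar_pairwise_log_density(field: np.ndarray, graph: ArealGraph, tau: float) -> float:
    """Improper ICAR log density up to an additive constant.

    ((n - c)/2) log tau - (tau/2) sum over unordered neighbour pairs of
    the squared difference; c is the number of connected components.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if field.shape != (graph.n,):
        raise ValueError(f"field length {field.size} does not match n={graph.n}")
    quad = 0.0
    if graph.edges:
        ei, ej = np.array(graph.edges).T
        quad = float(np.sum((field[ei] - field[ej]) ** 2))
    rank = graph.n - graph.n_components
    return 0.5 * rank * np.log(tau) - 0.5 * tau * quad


def icar_full_conditional(
    i: int, field: np.ndarray, graph: ArealGraph, tau: float
) -> tuple[float, float]:
    """Mean and variance of x_i given its neighbours under the ICAR prior.

    mean is the neighbour average, variance 1/(tau * m_i).  Undefined for
    islands (m_i = 0), whose spatial effect is pinned to zero upstream.
    """
    mi = int(graph.m[i])
    if mi == 0:
        raise ValueError(
            f"area {graph.area_ids[i]!r} has no neighbours; its ICAR conditional is undefined"
        )
    nbr = [j for a, b in graph.edges for j in ((b,) if a == i else (a,) if b == i else ())]
    mean = float(np.mean(field[list(nbr)]))
    return mean, 1.0 / (tau * mi)


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


def _normal_logpdf(x: np.ndarray | float, mean: float, precision: float):
    return 0.5 * np.log(precision / (2.0 * np.pi)) - 0.5 * precision * (x - mean) ** 2


def log_prior(state: ModelState, priors: PriorSpec, graph: ArealGraph) -> float:
    """Joint log prior density of the state (improper ICAR terms included)."""
    state.validate()
    total = float(np.sum(_normal_logpdf(state.alpha, 0.0, 1.0 / priors.alpha_prior_sd**2)))
    total += float(
        _normal_logpdf(state.log_delta, priors.log_delta_mean, priors.log_delta_precision)
    )
    total += icar_pairwise_log_density(state.theta, graph, state.tau_theta)
    total += icar_pairwise_log_density(state.s1, graph, state.tau_s1)
    total += icar_pairwise_log_density(state.s2, graph, state.tau_s2)
    total += float(np.sum(_normal_logpdf(state.u1, 0.0, state.tau_u1)))
    total += float(np.sum(_normal_logpdf(state.u2, 0.0, state.tau_u2)))
    for name in PRECISION_NAMES:
        a, b = priors.precision_priors[name]
        total += _gamma_logpdf(getattr(state, name), a, b)
    return total


def log_posterior(
    state: ModelState,
    table: OutcomeTable,
    expected: ExpectedCounts,
    priors: PriorSpec,
    graph: ArealGraph,
) -> float:
    """Unnormalized log posterior: log likelihood + log prior."""
    return log_likelihood(state, table, expected) + log_prior(state, priors, graph)
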