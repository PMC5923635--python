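"""Metropolis-within-Gibbs sampler for the shared-component model.

Latent fields (theta, s1, s2, u1, u2) are updated by single-site
random-walk Metropolis.  Sites are grouped by a graph colouring: within
one colour class no two areas are neighbours, so their full conditionals
are mutually independent and a whole colour class can be proposed and
accepted in one vectorized step — the result is distributionally
identical to a site-by-site sweep.  Unstructured fields have no spatial
coupling and are updated in a single batch.

Scalars (alpha_1, alpha_2, log delta) get scalar random-walk Metropolis
steps; the five precisions have conjugate Gamma full conditionals and
are drawn exactly by Gibbs.  After every sweep the spatial fields are
recentred to sum to zero with the means absorbed into the intercepts,
which leaves all relative risks unchanged and fixes the ICAR/intercept
identifiability.

Proposal scales adapt by Robbins-Monro toward a target acceptance rate
during burn-in only, then freeze, so the post-burn-in chain has the
correct stationary distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .areal_graph import ArealGraph
from .model import (
    PRECISION_NAMES,
    ModelState,
    PriorSpec,
    log_likelihood,
    log_posterior,
)
from .outcome_data import ExpectedCounts, OutcomeTable

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "gibbs_update_precision",
    "mh_update_field",
    "mh_update_scalars",
    "recenter",
    "run_mcmc",
]

_FIELD_NAMES = ("theta", "s1", "s2", "u1", "u2")
_SCALAR_BLOCKS = ("alpha1", "alpha2", "log_delta")
_NC_BLOCKS = tuple(f"nc_{f}" for f in _FIELD_NAMES)
_JOINT_BLOCK = "delta_theta"
_DEFAULT_SCALES = {
    "theta": 0.2,
    "s1": 0.2,
    "s2": 0.2,
    "u1": 0.2,
    "u2": 0.2,
    "alpha1": 0.05,
    "alpha2": 0.05,
    "log_delta": 0.2,
    "nc_theta": 0.8,
    "nc_s1": 0.8,
    "nc_s2": 0.8,
    "nc_u1": 0.8,
    "nc_u2": 0.8,
    "delta_theta": 0.3,
    "joint_s1": 0.6,
    "joint_s2": 0.6,
    "joint_u1": 0.6,
    "joint_u2": 0.6,
}
# per-iteration repeats of the joint (log delta, theta) block; the joint
# blocks adapt toward a lower acceptance target than plain RW blocks
# because the field refresh multiplies a mismatch factor into their
# acceptance rates
_JOINT_REPEATS = 3
_JOINT_TARGET = 0.25


@dataclass(frozen=True)
class MCMCConfig:
    """Run protocol for the sampler.

    The defaults mirror the study protocol (2 chains, 20,000 burn-in
    iterations, thinning of 100, 20,000 kept draws per chain); use
    :meth:`reduced` or explicit values for desk-scale runs.
    """

    chains: int = 2
    iterations: int = 2_020_000
    burn_in: int = 20_000
    thinning: int = 100
    seed: int = 0
    adapt_window: int = 50
    target_acceptance: float = 0.44
    scales: Mapping[str, float] = dc_field(default_factory=lambda: dict(_DEFAULT_SCALES))
    shared: bool = True  # False removes delta and theta (independent-surfaces variant)
    # True restricts the sampler to single-site MH + conjugate Gibbs only
    # (no Laplace refresh, joint or non-centered blocks); slower mixing but
    # a useful reference for validating the accelerated moves
    simple_updates: bool = False

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        merged = dict(_DEFAULT_SCALES)
        merged.update(self.scales)
        object.__setattr__(self, "scales", merged)

    @classmethod
    def reduced(cls, **kwargs) -> "MCMCConfig":
        """Desk-scale protocol: 2 chains x 5,000 iterations, 2,000 burn-in, thin 5."""
        base = dict(chains=2, iterations=5000, burn_in=2000, thinning=5)
        base.update(kwargs)
        return cls(**base)

    @property
    def kept_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning

    def to_dict(self) -> dict:
        return {
            "chains": self.chains,
            "iterations": self.iterations,
            "burn_in": self.burn_in,
            "thinning": self.thinning,
            "seed": self.seed,
            "adapt_window": self.adapt_window,
            "target_acceptance": self.target_acceptance,
            "scales": dict(self.scales),
            "shared": self.shared,
            "simple_updates": self.simple_updates,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MCMCConfig":
        return cls(**dict(d))


@dataclass
class PosteriorSamples:
    """Thinned multi-chain draws of all monitored quantities.

    ``scalars[name]`` has shape (chains, draws); ``fields[name]`` has
    shape (chains, draws, n).  ``iterations`` holds the original
    iteration index of each kept draw.
    """

    scalars: dict[str, np.ndarray]
    fields: dict[str, np.ndarray]
    iterations: np.ndarray
    area_ids: tuple[str, ...]
    acceptance: list[dict[str, float]]
    config: MCMCConfig

    @property
    def n_chains(self) -> int:
        return next(iter(self.scalars.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.scalars.values())).shape[1]

    def get(self, name: str) -> np.ndarray:
        """Per-chain draws of a scalar; ``"delta"`` is derived from log delta."""
        if name == "delta":
            return np.exp(self.scalars["log_delta"])
        return self.scalars[name]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated into one vector."""
        return self.get(name).reshape(-1)

    def risk_draws(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-draw relative risks r_1, r_2, shape (chains, draws, n)."""
        d = np.exp(self.scalars["log_delta"])[..., None]
        a1 = self.scalars["alpha1"][..., None]
        a2 = self.scalars["alpha2"][..., None]
        r1 = np.exp(a1 + d * self.fields["theta"] + self.fields["s1"] + self.fields["u1"])
        r2 = np.exp(a2 + self.fields["theta"] / d + self.fields["s2"] + self.fields["u2"])
        return r1, r2

    def exp_theta_draws(self) -> np.ndarray:
        return np.exp(self.fields["theta"])

    def to_long_dataframe(self) -> pd.DataFrame:
        """Long-format (chain, iteration, parameter, value) table."""
        rows = []
        for name, arr in self.scalars.items():
            for c in range(arr.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": self.iterations,
                            "parameter": name,
                            "value": arr[c],
                        }
                    )
                )
        for name, arr in self.fields.items():
            for c in range(arr.shape[0]):
                for i, aid in enumerate(self.area_ids):
                    rows.append(
                        pd.DataFrame(
                            {
                                "chain": c,
                                "iteration": self.iterations,
                                "parameter": f"{name}[{aid}]",
                                "value": arr[c, :, i],
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)

    def save(self, path: str | Path) -> None:
        """Binary cache (npz) of all draws plus the run configuration."""
        path = Path(path)
        payload = {f"scalar_{k}": v for k, v in self.scalars.items()}
        payload.update({f"field_{k}": v for k, v in self.fields.items()})
        payload["iterations"] = self.iterations
        payload["area_ids"] = np.array(self.area_ids)
        payload["config_yaml"] = np.array(yaml.safe_dump(self.config.to_dict()))
        payload["acceptance_yaml"] = np.array(yaml.safe_dump(self.acceptance))
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorSamples":
        with np.load(path, allow_pickle=False) as z:
            scalars = {k[7:]: z[k] for k in z.files if k.startswith("scalar_")}
            fields = {k[6:]: z[k] for k in z.files if k.startswith("field_")}
            config = MCMCConfig.from_dict(yaml.safe_load(str(z["config_yaml"])))
            acceptance = yaml.safe_load(str(z["acceptance_yaml"]))
            return cls(
                scalars=scalars,
                fields=fields,
                iterations=z["iterations"],
                area_ids=tuple(str(a) for a in z["area_ids"]),
                acceptance=acceptance,
                config=config,
            )


# ---------------------------------------------------------------------------
# Sampler context: everything precomputable from graph + data.
# ---------------------------------------------------------------------------


class _Context:
    def __init__(
        self,
        graph: ArealGraph,
        table: OutcomeTable | None,
        expected: ExpectedCounts | None,
        prior_only: bool,
    ):
        self.graph = graph
        self.n = graph.n
        self.m = graph.m.astype(float)
        self.W = graph.adjacency_matrix()
        if graph.edges:
            eidx = np.array(graph.edges)
            self.ei, self.ej = eidx[:, 0], eidx[:, 1]
        else:
            self.ei = self.ej = np.array([], dtype=np.intp)
        active = graph.m > 0  # islands excluded from spatial updates
        self.colors_spatial = [
            idx[active[idx]] for idx in graph.coloring() if idx[active[idx]].size
        ]
        self.all_idx = np.arange(self.n)
        self.prior_only = prior_only
        self.laplacian = graph.laplacian()
        self.diag_idx = np.diag_indices(self.n)
        # free (non-island) coordinates and non-singleton components, for the
        # Jacobians of non-centered precision moves
        self.n_free = int(np.sum(active))
        labels = graph.component_labels
        sizes = np.bincount(labels)
        self.n_big_components = int(np.sum(sizes > 1))
        if prior_only:
            self.O = self.e = None
        else:
            assert table is not None and expected is not None
            self.O = table.O
            self.e = expected.e

    def lam(self, state: ModelState, k: int, idx) -> np.ndarray:
        d = state.delta
        c = d if k == 0 else 1.0 / d
        sk = state.s1 if k == 0 else state.s2
        uk = state.u1 if k == 0 else state.u2
        eta = state.alpha[k] + c * state.theta[idx] + sk[idx] + uk[idx]
        return self.e[idx, k] * np.exp(eta)


def _field_blocks(name: str, state: ModelState):
    """(outcome index, coefficient on the field) pairs entering the likelihood."""
    if name == "theta":
        d = state.delta
        return [(0, d), (1, 1.0 / d)]
    if name in ("s1", "u1"):
        return [(0, 1.0)]
    return [(1, 1.0)]


def _mh_field_ctx(
    ctx: _Context, state: ModelState, name: str, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """One sweep of single-site MH over field ``name``; returns accept mask."""
    x = getattr(state, name)
    spatial = name in ("theta", "s1", "s2")
    tau = getattr(state, f"tau_{name}")
    accepted = np.zeros(ctx.n, dtype=bool)
    color_sets = ctx.colors_spatial if spatial else [ctx.all_idx]
    for idx in color_sets:
        cur = x[idx]
        dx = scale * rng.standard_normal(idx.size)
        prop = cur + dx
        if spatial:
            nbrsum = (ctx.W @ x)[idx]
            dlp = -0.5 * tau * (ctx.m[idx] * (prop**2 - cur**2) - 2.0 * nbrsum * dx)
        else:
            dlp = -0.5 * tau * (prop**2 - cur**2)
        if not ctx.prior_only:
            with np.errstate(over="ignore"):
                for k, coeff in _field_blocks(name, state):
                    lam = ctx.lam(state, k, idx)
                    dlp = dlp + ctx.O[idx, k] * coeff * dx - lam * np.expm1(coeff * dx)
        logu = np.log(rng.random(idx.size))
        acc = logu < np.nan_to_num(dlp, nan=-np.inf)
        x[idx[acc]] = prop[acc]
        accepted[idx[acc]] = True
    return accepted


def _mh_scalar_ctx(
    ctx: _Context,
    state: ModelState,
    priors: PriorSpec,
    block: str,
    scale: float,
    rng: np.random.Generator,
) -> bool:
    """Scalar random-walk MH step for alpha1, alpha2 or log_delta."""
    z = scale * rng.standard_normal()
    logu = np.log(rng.random())
    with np.errstate(over="ignore"):
        if block in ("alpha1", "alpha2"):
            k = 0 if block == "alpha1" else 1
            cur = state.alpha[k]
            prop = cur + z
            prec = 1.0 / priors.alpha_prior_sd**2
            dlp = -0.5 * prec * (prop**2 - cur**2)
            if not ctx.prior_only:
                lam_sum = ctx.lam(state, k, ctx.all_idx).sum()
                dlp += ctx.O[:, k].sum() * z - lam_sum * np.expm1(z)
            if logu < np.nan_to_num(dlp, nan=-np.inf):
                state.alpha[k] = prop
                return True
            return False
        # log delta
        cur = state.log_delta
        prop = cur + z
        q = priors.log_delta_precision
        mu = priors.log_delta_mean
        dlp = -0.5 * q * ((prop - mu) ** 2 - (cur - mu) ** 2)
        if not ctx.prior_only:
            d0, d1 = np.exp(cur), np.exp(prop)
            t = state.theta
            lam1 = ctx.lam(state, 0, ctx.all_idx)
            lam2 = ctx.lam(state, 1, ctx.all_idx)
            c1 = (d1 - d0) * t
            c2 = (1.0 / d1 - 1.0 / d0) * t
            dlp += float(np.sum(ctx.O[:, 0] * c1 - lam1 * np.expm1(c1)))
            dlp += float(np.sum(ctx.O[:, 1] * c2 - lam2 * np.expm1(c2)))
    if logu < np.nan_to_num(dlp, nan=-np.inf):
        state.log_delta = prop
        return True
    return False


def _nc_precision_move(
    ctx: _Context,
    state: ModelState,
    priors: PriorSpec,
    field_name: str,
    scale: float,
    rng: np.random.Generator,
) -> bool:
    """Non-centered (interweaved) precision update for one field.

    In the non-centered parameterization phi = sqrt(tau) * x the field's
    prior no longer depends on tau, so a random-walk move on log tau
    with phi held fixed rescales the field x by sqrt(tau_old/tau_new)
    against the likelihood.  Alternating this with the centered conjugate
    Gibbs draw (ASIS interweaving) breaks the slow random walk that the
    centered step alone produces when the field amplitude is
    data-constrained.

    The Metropolis ratio: likelihood change under the rescaled field,
    Gamma prior terms, and the reparameterization exponent — for ICAR
    fields tau^{(rank - n_free)/2} = tau^{-c/2} with c the number of
    non-singleton components; for unstructured fields the exponent
    vanishes.
    """
    tau = getattr(state, f"tau_{field_name}")
    fieldv = getattr(state, field_name)
    a, b = priors.precision_priors[f"tau_{field_name}"]
    z = scale * rng.standard_normal()
    logu = np.log(rng.random())
    tau_new = tau * np.exp(z)
    shrink = np.sqrt(tau / tau_new)
    spatial = field_name in ("theta", "s1", "s2")
    comp_correction = 0.5 * ctx.n_big_components if spatial else 0.0
    with np.errstate(over="ignore"):
        dlp = (a - comp_correction) * z - b * (tau_new - tau)
        if not ctx.prior_only:
            for k, coeff in _field_blocks(field_name, state):
                lam = ctx.lam(state, k, ctx.all_idx)
                deta = coeff * fieldv * (shrink - 1.0)
                dlp += float(np.sum(ctx.O[:, k] * deta - lam * np.expm1(deta)))
    if logu < np.nan_to_num(dlp, nan=-np.inf):
        setattr(state, f"tau_{field_name}", tau_new)
        setattr(state, field_name, fieldv * shrink)
        return True
    return False


def _laplace_theta(ctx: _Context, state: ModelState, delta: float, tau: float, base_lam):
    """Gaussian (Laplace) approximation of theta's full conditional.

    Newton iterations on the log-concave conditional under scaling
    ``delta`` and ICAR precision ``tau``; returns (mode, precision H,
    Cholesky factor, log det H).  ``base_lam`` holds the two
    Poisson-mean vectors with the current theta contribution removed.
    """
    import scipy.linalg as sla

    coeffs = (delta, 1.0 / delta)
    Ld = ctx.laplacian
    x = state.theta.copy()
    w = np.zeros(ctx.n)
    for _ in range(2):
        grad = -tau * (Ld @ x)
        w[:] = 0.0
        for k in (0, 1):
            lam = base_lam[k] * np.exp(coeffs[k] * x)
            grad += (ctx.O[:, k] - lam) * coeffs[k]
            w += lam * coeffs[k] ** 2
        H = tau * Ld.copy()
        H[ctx.diag_idx] += w
        chol, _ = sla.cho_factor(H, lower=True)
        x = x + sla.cho_solve((chol, True), grad)
    w[:] = 0.0
    for k in (0, 1):
        w += base_lam[k] * np.exp(coeffs[k] * x) * coeffs[k] ** 2
    H = tau * Ld.copy()
    H[ctx.diag_idx] += w
    chol, _ = sla.cho_factor(H, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return x, H, chol, logdet


def _theta_cond_logpost(ctx, state, base_lam, x, delta, tau) -> float:
    """log p(theta=x, delta, tau_theta | rest) up to free terms.

    Includes the ICAR normalizing power of tau_theta and its Gamma
    prior so the joint hyperparameter block can move tau_theta.
    """
    rank = ctx.n_free - ctx.n_big_components
    val = 0.5 * rank * np.log(tau) - 0.5 * tau * float(x @ (ctx.laplacian @ x))
    for k, coeff in ((0, delta), (1, 1.0 / delta)):
        lam = base_lam[k] * np.exp(coeff * x)
        val += float(np.sum(ctx.O[:, k] * coeff * x - lam))
    return val


# fixed scale of the log tau_theta step inside the joint block (0 keeps
# tau_theta out of the block; its mixing is handled by the non-centered move)
_JOINT_TAU_SCALE = 0.0


def _joint_tau_spatial_move(
    ctx: _Context,
    state: ModelState,
    priors: PriorSpec,
    field_name: str,
    tau_scale: float,
    rng: np.random.Generator,
) -> bool:
    """One-block (log tau, field) update for a spatial (ICAR) field.

    Propose log tau by random walk (skipped when ``tau_scale`` is 0) and
    the field from the Laplace approximation of its log-concave full
    conditional under the proposed tau; accept or reject jointly with
    the approximation densities of both directions in the ratio.  With
    ``tau_scale`` = 0 this is a pure independence-MH field refresh; with
    a positive scale it traverses the precision/amplitude funnel that
    the centered Gibbs draw and single-site moves random-walk through
    only slowly.
    """
    import scipy.linalg as sla

    cur = getattr(state, field_name)
    tau_cur = getattr(state, f"tau_{field_name}")
    a, b = priors.precision_priors[f"tau_{field_name}"]
    zt = tau_scale * rng.standard_normal() if tau_scale > 0 else 0.0
    tau_new = tau_cur * float(np.exp(zt))
    blocks = _field_blocks(field_name, state)
    Ld = ctx.laplacian
    rank = ctx.n_free - ctx.n_big_components
    # Poisson means with this field's contribution removed
    base_lam = [ctx.lam(state, k, ctx.all_idx) * np.exp(-coeff * cur) for k, coeff in blocks]

    def cond_logpost(v: np.ndarray, tau: float) -> float:
        # ICAR term with its tau-power, Gamma prior (+ log-RW Jacobian),
        # and the Poisson likelihood channels touching this field
        val = (0.5 * rank + a) * np.log(tau) - b * tau - 0.5 * tau * float(v @ (Ld @ v))
        for (k, coeff), lam0 in zip(blocks, base_lam):
            val += float(np.sum(ctx.O[:, k] * coeff * v - lam0 * np.exp(coeff * v)))
        return val

    def laplace(tau: float):
        x = cur.copy()
        w = np.zeros(ctx.n)
        for _ in range(2):
            grad = -tau * (Ld @ x)
            w[:] = 0.0
            for (k, coeff), lam0 in zip(blocks, base_lam):
                lam = lam0 * np.exp(coeff * x)
                grad += (ctx.O[:, k] - lam) * coeff
                w += lam * coeff**2
            H = tau * Ld.copy()
            H[ctx.diag_idx] += w
            chol, _ = sla.cho_factor(H, lower=True)
            x = x + sla.cho_solve((chol, True), grad)
        w[:] = 0.0
        for (k, coeff), lam0 in zip(blocks, base_lam):
            w += lam0 * np.exp(coeff * x) * coeff**2
        H = tau * Ld.copy()
        H[ctx.diag_idx] += w
        chol, _ = sla.cho_factor(H, lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        return x, H, chol, logdet

    with np.errstate(over="ignore", invalid="ignore"):
        try:
            m1, H1, chol1, logdet1 = laplace(tau_new)
            prop = m1 + sla.solve_triangular(
                chol1, rng.standard_normal(ctx.n), lower=True, trans="T"
            )
            if zt == 0.0:
                m0, H0, logdet0 = m1, H1, logdet1
            else:
                m0, H0, _, logdet0 = laplace(tau_cur)
        except (np.linalg.LinAlgError, ValueError):
            return False

        def logq(v, m, H, logdet):
            dv = v - m
            return 0.5 * logdet - 0.5 * float(dv @ (H @ dv))

        ratio = cond_logpost(prop, tau_new) - cond_logpost(cur, tau_cur)
        ratio += logq(cur, m0, H0, logdet0) - logq(prop, m1, H1, logdet1)
    if np.isfinite(ratio) and np.log(rng.random()) < ratio:
        setattr(state, field_name, prop)
        setattr(state, f"tau_{field_name}", tau_new)
        return True
    return False


def _joint_tau_unstructured_move(
    ctx: _Context,
    state: ModelState,
    priors: PriorSpec,
    field_name: str,
    tau_scale: float,
    rng: np.random.Generator,
) -> bool:
    """One-block (log tau, field) update for an unstructured field.

    Same construction as the spatial version, but the conditional
    factorizes over areas, so the Laplace fit is a vectorized per-site
    Newton iteration and the proposal covariance is diagonal.
    """
    cur = getattr(state, field_name)
    tau_cur = getattr(state, f"tau_{field_name}")
    a, b = priors.precision_priors[f"tau_{field_name}"]
    zt = tau_scale * rng.standard_normal() if tau_scale > 0 else 0.0
    tau_new = tau_cur * float(np.exp(zt))
    ((k, _),) = _field_blocks(field_name, state)
    lam0 = ctx.lam(state, k, ctx.all_idx) * np.exp(-cur)
    O = ctx.O[:, k]

    def cond_logpost(v: np.ndarray, tau: float) -> float:
        val = (0.5 * ctx.n + a) * np.log(tau) - b * tau - 0.5 * tau * float(np.sum(v**2))
        return val + float(np.sum(O * v - lam0 * np.exp(v)))

    def laplace(tau: float):
        x = cur.copy()
        for _ in range(2):
            lam = lam0 * np.exp(x)
            x = x + (O - lam - tau * x) / (tau + lam)
        h = tau + lam0 * np.exp(x)
        return x, h

    with np.errstate(over="ignore", invalid="ignore"):
        m1, h1 = laplace(tau_new)
        if not (np.all(np.isfinite(m1)) and np.all(h1 > 0)):
            return False
        prop = m1 + rng.standard_normal(ctx.n) / np.sqrt(h1)
        m0, h0 = (m1, h1) if zt == 0.0 else laplace(tau_cur)

        def logq(v, m, h):
            return 0.5 * float(np.sum(np.log(h))) - 0.5 * float(np.sum(h * (v - m) ** 2))

        ratio = cond_logpost(prop, tau_new) - cond_logpost(cur, tau_cur)
        ratio += logq(cur, m0, h0) - logq(prop, m1, h1)
    if np.isfinite(ratio) and np.log(rng.random()) < ratio:
        setattr(state, field_name, prop)
        setattr(state, f"tau_{field_name}", tau_new)
        return True
    return False


def _joint_delta_theta_move(
    ctx: _Context,
    state: ModelState,
    priors: PriorSpec,
    scale: float,
    rng: np.random.Generator,
) -> bool:
    """One-block update of (log delta, log tau_theta, theta).

    delta and tau_theta given the field are tight while their marginals
    are wide, so scalar steps with theta fixed random-walk slowly along
    the ridge.  Following the one-block strategy for hyperparameters of
    Gaussian Markov random fields, propose both hyperparameters by
    random walk and theta from the Laplace approximation of its full
    conditional under the proposed values, then accept or reject the
    triple jointly — the approximation densities of both directions
    enter the ratio, so the update targets the exact posterior.
    """
    import scipy.linalg as sla

    z = scale * rng.standard_normal()
    zt = _JOINT_TAU_SCALE * rng.standard_normal()
    logu = np.log(rng.random())
    ld_new = state.log_delta + z
    d_new = float(np.exp(ld_new))
    d_cur = state.delta
    tau_cur = state.tau_theta
    tau_new = tau_cur * float(np.exp(zt))
    base_lam = (
        ctx.lam(state, 0, ctx.all_idx) * np.exp(-d_cur * state.theta),
        ctx.lam(state, 1, ctx.all_idx) * np.exp(-state.theta / d_cur),
    )
    with np.errstate(over="ignore", invalid="ignore"):
        try:
            m1, H1, chol1, logdet1 = _laplace_theta(ctx, state, d_new, tau_new, base_lam)
            prop = m1 + sla.solve_triangular(
                chol1, rng.standard_normal(ctx.n), lower=True, trans="T"
            )
            m0, H0, chol0, logdet0 = _laplace_theta(ctx, state, d_cur, tau_cur, base_lam)
        except (np.linalg.LinAlgError, ValueError):
            return False

        def logq(x, m, H, logdet):
            dv = x - m
            return 0.5 * logdet - 0.5 * float(dv @ (H @ dv))

        q, mu = priors.log_delta_precision, priors.log_delta_mean
        a, b = priors.precision_priors["tau_theta"]
        num = _theta_cond_logpost(ctx, state, base_lam, prop, d_new, tau_new)
        num += logq(state.theta, m0, H0, logdet0) - 0.5 * q * (ld_new - mu) ** 2
        num += a * np.log(tau_new) - b * tau_new  # Gamma prior + log-RW Jacobian
        den = _theta_cond_logpost(ctx, state, base_lam, state.theta, d_cur, tau_cur)
        den += logq(prop, m1, H1, logdet1) - 0.5 * q * (state.log_delta - mu) ** 2
        den += a * np.log(tau_cur) - b * tau_cur
        ratio = num - den
    if np.isfinite(ratio) and logu < ratio:
        state.log_delta = ld_new
        state.tau_theta = tau_new
        state.theta = prop
        return True
    return False


# ---------------------------------------------------------------------------
# Public single-step operations (thin wrappers over the context versions).
# ---------------------------------------------------------------------------


def mh_update_field(
    field_name: str,
    state: ModelState,
    table: OutcomeTable | None,
    expected: ExpectedCounts | None,
    graph: ArealGraph,
    scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single-site random-walk Metropolis sweep over one latent field.

    Mutates ``state`` in place and returns the per-area acceptance mask.
    Pass ``table=None, expected=None`` for a prior-only (likelihood-off)
    update.
    """
    if scale <= 0:
        raise ValueError("proposal scale must be positive")
    if field_name not in _FIELD_NAMES:
        raise ValueError(f"unknown field {field_name!r}")
    prior_only = table is None
    ctx = _Context(graph, table, expected, prior_only)
    return _mh_field_ctx(ctx, state, field_name, scale, rng)


def mh_update_scalars(
    state: ModelState,
    table: OutcomeTable | None,
    expected: ExpectedCounts | None,
    graph: ArealGraph,
    priors: PriorSpec,
    scales: Mapping[str, float],
    rng: np.random.Generator,
) -> dict[str, bool]:
    """Random-walk MH updates of alpha_1, alpha_2 and log delta."""
    prior_only = table is None
    ctx = _Context(graph, table, expected, prior_only)
    return {
        block: _mh_scalar_ctx(ctx, state, priors, block, scales[block], rng)
        for block in _SCALAR_BLOCKS
    }


def gibbs_update_precision(
    field: np.ndarray,
    graph: ArealGraph | None,
    hyperprior: tuple[float, float],
    rng: np.random.Generator,
    edge_index: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Exact conjugate Gamma draw for a field precision.

    ICAR fields (``graph`` given): Gamma(a + (n-c)/2, b + half the sum of
    squared neighbour differences).  Unstructured fields (``graph`` is
    None): Gamma(a + n/2, b + half the sum of squares).
    """
    a, b = hyperprior
    if a <= 0 or b <= 0:
        raise ValueError("gamma hyperprior must have positive shape and rate")
    if graph is None:
        shape = a + field.size / 2.0
        rate = b + 0.5 * float(np.sum(field**2))
    else:
        if edge_index is None:
            if graph.edges:
                eidx = np.array(graph.edges)
                ei, ej = eidx[:, 0], eidx[:, 1]
            else:
                ei = ej = np.array([], dtype=np.intp)
        else:
            ei, ej = edge_index
        quad = float(np.sum((field[ei] - field[ej]) ** 2)) if ei.size else 0.0
        shape = a + (graph.n - graph.n_components) / 2.0
        rate = b + 0.5 * quad
    return float(rng.gamma(shape, 1.0 / rate))


def recenter(state: ModelState) -> ModelState:
    """Impose sum-to-zero on theta, s1, s2, absorbing the means into alpha.

    alpha_1 gains delta*mean(theta) + mean(s1), alpha_2 gains
    mean(theta)/delta + mean(s2); relative risks are unchanged.
    Mutates and returns ``state``.
    """
    d = state.delta
    mt = float(state.theta.mean())
    m1 = float(state.s1.mean())
    m2 = float(state.s2.mean())
    state.theta -= mt
    state.s1 -= m1
    state.s2 -= m2
    state.alpha[0] += d * mt + m1
    state.alpha[1] += mt / d + m2
    return state


# ---------------------------------------------------------------------------
# Full sampler.
# ---------------------------------------------------------------------------


def _initial_state(ctx: _Context, priors: PriorSpec) -> ModelState:
    n = ctx.n
    if ctx.prior_only:
        alpha = np.zeros(2)
    else:
        alpha = np.log(ctx.O.sum(axis=0) / ctx.e.sum(axis=0))
    taus = {
        name: priors.precision_priors[name][0] / priors.precision_priors[name][1]
        for name in PRECISION_NAMES
    }
    return ModelState(
        alpha=alpha,
        log_delta=0.0,
        theta=np.zeros(n),
        s1=np.zeros(n),
        s2=np.zeros(n),
        u1=np.zeros(n),
        u2=np.zeros(n),
        **taus,
    )


def run_mcmc(
    config: MCMCConfig,
    table: OutcomeTable | None,
    expected: ExpectedCounts | None,
    priors: PriorSpec,
    graph: ArealGraph,
    prior_only: bool = False,
) -> PosteriorSamples:
    """Run the full Metropolis-within-Gibbs sampler.

    Sweep order per iteration is fixed for reproducibility: theta, s1,
    s2, u1, u2, scalars (alpha_1, alpha_2, log delta), precisions, then
    recentring.  Chain seeds derive deterministically from
    ``config.seed``; identical inputs give bit-identical draws.

    ``prior_only=True`` switches the likelihood off (used for prior
    calibration checks); the stored deviance is then zero by convention.
    With ``config.shared=False`` the shared surface and delta are removed
    (theta pinned at 0, delta at 1), giving the independent-surfaces
    comparison model.
    """
    if prior_only:
        table = expected = None
    ctx = _Context(graph, table, expected, prior_only)
    if not prior_only:
        if len(table.area_ids) != graph.n:
            raise ValueError(
                f"counts table has {len(table.area_ids)} areas but graph has {graph.n}"
            )
        if tuple(table.area_ids) != tuple(graph.area_ids):
            raise ValueError("counts table area order does not match the graph")
    seed_seq = np.random.SeedSequence(config.seed)
    chain_seeds = seed_seq.spawn(config.chains)

    n_kept = config.kept_per_chain
    scalar_names = ["alpha1", "alpha2", "log_delta", *PRECISION_NAMES, "deviance"]
    scalars = {k: np.empty((config.chains, n_kept)) for k in scalar_names}
    fields = {k: np.empty((config.chains, n_kept, ctx.n)) for k in _FIELD_NAMES}
    kept_iters = np.array(
        [config.burn_in + (j + 1) * config.thinning for j in range(n_kept)], dtype=np.intp
    )
    acceptance_all: list[dict[str, float]] = []

    update_blocks = list(_FIELD_NAMES) + list(_SCALAR_BLOCKS)
    # Laplace-based blocks assume every area joins the ICAR structure;
    # with islands present only the single-site machinery runs
    no_islands = graph.islands.size == 0
    fancy = not config.simple_updates
    use_joint = fancy and config.shared and not prior_only and no_islands
    use_refresh = fancy and not prior_only and no_islands
    use_nc = fancy and not prior_only
    if use_joint:
        update_blocks.append(_JOINT_BLOCK)
    refresh_fields = []
    if use_refresh:
        refresh_fields = ["theta", "s1", "s2", "u1", "u2"] if config.shared else [
            "s1",
            "s2",
            "u1",
            "u2",
        ]
        for f in refresh_fields:
            if f in ("theta", "s1", "s2"):
                update_blocks.append(f"refresh_{f}")
            if f != "theta":
                update_blocks.append(f"joint_{f}")
    if use_nc:
        update_blocks += [
            b for b in _NC_BLOCKS if config.shared or b != "nc_theta"
        ]
    if not config.shared:
        update_blocks = [b for b in update_blocks if b not in ("theta", "log_delta")]

    for c in range(config.chains):
        rng = np.random.default_rng(chain_seeds[c])
        state = _initial_state(ctx, priors)
        check = log_posterior(state, table, expected, priors, graph) if not prior_only else 0.0
        if not np.isfinite(check):
            raise FloatingPointError("non-finite log posterior at initialization")
        scales = dict(config.scales)
        window_acc = {b: 0.0 for b in update_blocks}
        window_n = {b: 0.0 for b in update_blocks}
        post_acc = {b: 0.0 for b in update_blocks}
        post_n = {b: 0.0 for b in update_blocks}
        adapt_round = 0
        kept = 0
        for t in range(1, config.iterations + 1):
            adapting = t <= config.burn_in
            for name in _FIELD_NAMES:
                if name == "theta" and not config.shared:
                    continue
                mask = _mh_field_ctx(ctx, state, name, scales[name], rng)
                tgt = (window_acc, window_n) if adapting else (post_acc, post_n)
                tgt[0][name] += float(mask.sum())
                tgt[1][name] += float(mask.size)
            for block in _SCALAR_BLOCKS:
                if block == "log_delta" and not config.shared:
                    continue
                ok = _mh_scalar_ctx(ctx, state, priors, block, scales[block], rng)
                tgt = (window_acc, window_n) if adapting else (post_acc, post_n)
                tgt[0][block] += float(ok)
                tgt[1][block] += 1.0
            if use_joint:
                for _ in range(_JOINT_REPEATS):
                    ok = _joint_delta_theta_move(
                        ctx, state, priors, scales[_JOINT_BLOCK], rng
                    )
                    tgt = (window_acc, window_n) if adapting else (post_acc, post_n)
                    tgt[0][_JOINT_BLOCK] += float(ok)
                    tgt[1][_JOINT_BLOCK] += 1.0
            for fname in refresh_fields:
                tgt = (window_acc, window_n) if adapting else (post_acc, post_n)
                if fname in ("theta", "s1", "s2"):
                    # pure conditional refresh (high acceptance) renews the
                    # surface shape; tau_theta's scale moves are handled by
                    # the non-centered step and the delta_theta block
                    block = f"refresh_{fname}"
                    ok = _joint_tau_spatial_move(ctx, state, priors, fname, 0.0, rng)
                    tgt[0][block] += float(ok)
                    tgt[1][block] += 1.0
                if fname == "theta":
                    continue
                # joint (log tau, field) move traverses the amplitude funnel
                block = f"joint_{fname}"
                if fname in ("s1", "s2"):
                    ok = _joint_tau_spatial_move(
                        ctx, state, priors, fname, scales[block], rng
                    )
                else:
                    ok = _joint_tau_unstructured_move(
                        ctx, state, priors, fname, scales[block], rng
                    )
                tgt[0][block] += float(ok)
                tgt[1][block] += 1.0
            # conjugate precision draws
            eidx = (ctx.ei, ctx.ej)
            if config.shared:
                state.tau_theta = gibbs_update_precision(
                    state.theta, graph, priors.precision_priors["tau_theta"], rng, eidx
                )
            state.tau_s1 = gibbs_update_precision(
                state.s1, graph, priors.precision_priors["tau_s1"], rng, eidx
            )
            state.tau_s2 = gibbs_update_precision(
                state.s2, graph, priors.precision_priors["tau_s2"], rng, eidx
            )
            state.tau_u1 = gibbs_update_precision(
                state.u1, None, priors.precision_priors["tau_u1"], rng
            )
            state.tau_u2 = gibbs_update_precision(
                state.u2, None, priors.precision_priors["tau_u2"], rng
            )
            if use_nc:
                for fname in _FIELD_NAMES:
                    if fname == "theta" and not config.shared:
                        continue
                    block = f"nc_{fname}"
                    ok = _nc_precision_move(ctx, state, priors, fname, scales[block], rng)
                    tgt = (window_acc, window_n) if adapting else (post_acc, post_n)
                    tgt[0][block] += float(ok)
                    tgt[1][block] += 1.0
            recenter(state)
            if not config.shared:
                state.log_delta = 0.0
            if adapting and t % config.adapt_window == 0:
                adapt_round += 1
                step = 1.0 / np.sqrt(adapt_round)
                for b in update_blocks:
                    # pure refresh blocks have no tunable scale
                    if b.startswith("refresh_"):
                        window_acc[b] = window_n[b] = 0.0
                        continue
                    # joint blocks carry a field-refresh mismatch factor on
                    # top of the hyperparameter step, so they are tuned to a
                    # lower target than the plain random-walk blocks
                    is_joint = b == _JOINT_BLOCK or b.startswith("joint_")
                    target = _JOINT_TARGET if is_joint else config.target_acceptance
                    if window_n[b] > 0:
                        rate = window_acc[b] / window_n[b]
                        scales[b] = float(
                            np.clip(
                                scales[b] * np.exp(step * (rate - target)),
                                1e-4,
                                10.0,
                            )
                        )
                    window_acc[b] = window_n[b] = 0.0
            if t > config.burn_in and (t - config.burn_in) % config.thinning == 0:
                scalars["alpha1"][c, kept] = state.alpha[0]
                scalars["alpha2"][c, kept] = state.alpha[1]
                scalars["log_delta"][c, kept] = state.log_delta
                for name in PRECISION_NAMES:
                    scalars[name][c, kept] = getattr(state, name)
                dev = 0.0 if prior_only else -2.0 * log_likelihood(state, table, expected)
                scalars["deviance"][c, kept] = dev
                for name in _FIELD_NAMES:
                    fields[name][c, kept] = getattr(state, name)
                kept += 1
        rates = {
            b: (post_acc[b] / post_n[b]) if post_n[b] else float("nan") for b in update_blocks
        }
        rates["_scales"] = {b: scales[b] for b in update_blocks if b in scales}
        acceptance_all.append(rates)

    return PosteriorSamples(
        scalars=scalars,
        fields=fields,
        iterations=kept_iters,
        area_ids=graph.area_ids,
        acceptance=acceptance_all,
        config=config,
    )
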