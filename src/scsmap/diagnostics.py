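"""Convergence and fit diagnostics for the sampler output.

Implements the monitoring protocol used in applied disease-mapping work:
the Gelman-Rubin potential scale reduction factor (plain variance-ratio
convention), sample autocorrelation, batch-means Monte Carlo error with
the "MC error below 5% of the posterior sd" rule, and the Deviance
Information Criterion with the plug-in deviance evaluated at the
posterior means of the Poisson means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .mcmc import PosteriorSamples
from .outcome_data import ExpectedCounts, OutcomeTable

__all__ = [
    "gelman_rubin",
    "autocorrelation",
    "mc_error",
    "dic",
    "dic_from_samples",
    "DiagnosticsReport",
    "diagnostics_report",
]

MC_ERROR_FRACTION = 0.05  # MC error must be below this fraction of the posterior sd


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor from >= 2 equal-length chains.

    ``chains`` has shape (n_chains, n_draws).  With W the mean
    within-chain variance, B the between-chain variance (n_draws times
    the variance of the chain means), and m the draws per chain:

        PSRF = sqrt( (W (m - 1)/m + B/m) / W )

    Values near 1 indicate the chains have mixed over a common
    distribution.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("gelman_rubin needs at least two chains of equal length")
    m = chains.shape[1]
    if m < 10:
        raise ValueError("chains too short for a meaningful PSRF (need >= 10 draws)")
    within = float(np.mean(np.var(chains, axis=1, ddof=1)))
    means = chains.mean(axis=1)
    between = m * float(np.var(means, ddof=1))
    if within == 0.0:
        return 1.0 if between == 0.0 else float("inf")
    var_plus = within * (m - 1) / m + between / m
    return float(np.sqrt(var_plus / within))


def autocorrelation(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation at lags 0..max_lag (lag 0 is 1).

    NaN for a constant series, whose autocorrelation is undefined.
    """
    x = np.asarray(series, dtype=float)
    if x.size <= max_lag:
        raise ValueError(f"series of length {x.size} too short for max_lag={max_lag}")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return np.full(max_lag + 1, np.nan)
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    for lag in range(1, max_lag + 1):
        out[lag] = float(np.dot(x[:-lag], x[lag:])) / denom
    return out


def mc_error(series: np.ndarray, n_batches: int = 50) -> float:
    """Batch-means Monte Carlo standard error of the posterior mean.

    The series is split into ``n_batches`` consecutive batches (trailing
    remainder dropped); the error is the standard deviation of the batch
    means divided by sqrt(n_batches).  Autocorrelation inflates the
    spread of batch means, so this tracks the effective (not nominal)
    sample size.
    """
    x = np.asarray(series, dtype=float)
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    batch_len = x.size // n_batches
    if batch_len < 1:
        raise ValueError(f"series of length {x.size} too short for {n_batches} batches")
    trimmed = x[: batch_len * n_batches].reshape(n_batches, batch_len)
    batch_means = trimmed.mean(axis=1)
    return float(np.std(batch_means, ddof=1) / np.sqrt(n_batches))


def _pooled_mc_error(per_chain: np.ndarray, n_batches: int = 50) -> float:
    """MC error of the all-chain posterior mean: batch means within chains."""
    ses = [mc_error(row, n_batches) for row in per_chain]
    c = len(ses)
    return float(np.sqrt(np.sum(np.square(ses))) / c)


def dic(deviance_draws: np.ndarray, plug_in_deviance: float) -> tuple[float, float, float]:
    """Deviance Information Criterion (Dbar, pD, DIC).

    Dbar is the posterior mean deviance; pD = Dbar - D(lambda-bar) is the
    effective number of parameters with the plug-in deviance evaluated at
    the posterior means of the Poisson means; DIC = Dbar + pD.  Smaller
    DIC indicates better fit.
    """
    dev = np.asarray(deviance_draws, dtype=float)
    if not np.all(np.isfinite(dev)):
        raise ValueError("non-finite deviance draws")
    dbar = float(dev.mean())
    pd_ = dbar - float(plug_in_deviance)
    return dbar, pd_, dbar + pd_


def _poisson_deviance(O: np.ndarray, lam: np.ndarray) -> float:
    return -2.0 * float(np.sum(O * np.log(lam) - lam - gammaln(O + 1.0)))


def dic_from_samples(
    samples: PosteriorSamples, table: OutcomeTable, expected: ExpectedCounts
) -> tuple[float, float, float]:
    """DIC of a fitted model, with lambda-bar averaged over all kept draws."""
    r1, r2 = samples.risk_draws()
    lam1 = expected.e[:, 0] * r1
    lam2 = expected.e[:, 1] * r2
    lam_bar = np.stack(
        [lam1.reshape(-1, lam1.shape[-1]).mean(axis=0), lam2.reshape(-1, lam2.shape[-1]).mean(axis=0)],
        axis=1,
    )
    plug_in = _poisson_deviance(table.O, lam_bar)
    return dic(samples.stacked("deviance"), plug_in)


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence table plus DIC and pass/fail flags."""

    table: pd.DataFrame  # parameter, psrf, mean, sd, mc_error, mc_error_ok, acf_lag1
    dic: tuple[float, float, float] | None
    psrf_threshold: float
    all_psrf_ok: bool
    all_mc_ok: bool

    @property
    def passed(self) -> bool:
        return self.all_psrf_ok and self.all_mc_ok

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_text(self) -> str:
        lines = [self.table.to_string(index=False)]
        if self.dic is not None:
            dbar, pd_, d = self.dic
            lines.append(f"DIC: Dbar={dbar:.2f}  pD={pd_:.2f}  DIC={d:.2f}")
            if pd_ < 0:
                lines.append("warning: negative pD (known DIC pathology)")
        lines.append(
            f"PSRF <= {self.psrf_threshold}: {'PASS' if self.all_psrf_ok else 'FAIL'}; "
            f"MC error < {MC_ERROR_FRACTION:.0%} of sd: {'PASS' if self.all_mc_ok else 'FAIL'}"
        )
        return "\n".join(lines)


def diagnostics_report(
    samples: PosteriorSamples,
    table: OutcomeTable | None = None,
    expected: ExpectedCounts | None = None,
    psrf_threshold: float = 1.1,
    acf_lag: int = 1,
    n_batches: int = 50,
) -> DiagnosticsReport:
    """Build the full monitoring report.

    PSRF, posterior sd, batch-means MC error and lag-1 autocorrelation
    are reported for every scalar parameter and the deviance; latent
    fields are summarized by the maximum PSRF across areas.  The MC-error
    flag per parameter is true iff the error is below 5% of the posterior
    sd, the monitoring rule used in the motivating study.
    """
    rows = []
    multi = samples.n_chains >= 2
    scalar_names = [k for k in samples.scalars if k != "deviance"]
    if not samples.config.shared:
        scalar_names = [k for k in scalar_names if k not in ("log_delta", "tau_theta")]
    watch = scalar_names + ["deviance"]
    for name in watch:
        draws = samples.get(name)
        merged = draws.reshape(-1)
        sd = float(np.std(merged, ddof=1))
        err = _pooled_mc_error(draws, n_batches)
        psrf = gelman_rubin(draws) if multi else float("nan")
        const = sd == 0.0
        rows.append(
            {
                "parameter": name,
                "psrf": psrf,
                "mean": float(merged.mean()),
                "sd": sd,
                "mc_error": err,
                "mc_error_ok": bool(const or err < MC_ERROR_FRACTION * sd),
                "acf_lag1": float("nan")
                if const
                else float(autocorrelation(draws[0], acf_lag)[acf_lag]),
            }
        )
    for fname, arr in samples.fields.items():
        if not samples.config.shared and fname == "theta":
            continue
        if multi:
            psrf_max = max(
                gelman_rubin(arr[:, :, i])
                for i in range(arr.shape[2])
                if np.std(arr[:, :, i]) > 0
            )
        else:
            psrf_max = float("nan")
        rows.append(
            {
                "parameter": f"max[{fname}]",
                "psrf": psrf_max,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)),
                "mc_error": float("nan"),
                "mc_error_ok": True,
                "acf_lag1": float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    dic_triple = None
    if table is not None and expected is not None:
        dic_triple = dic_from_samples(samples, table, expected)
    psrf_ok = bool(np.all(np.nan_to_num(df["psrf"], nan=1.0) <= psrf_threshold))
    mc_ok = bool(df["mc_error_ok"].all())
    return DiagnosticsReport(
        table=df,
        dic=dic_triple,
        psrf_threshold=psrf_threshold,
        all_psrf_ok=psrf_ok,
        all_mc_ok=mc_ok,
    )
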