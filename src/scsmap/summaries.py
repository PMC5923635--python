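"""Posterior summaries: risk surfaces, exceedance, shared-component scale.

Turns thinned draws into the quantities a disease-mapping analysis
reports: per-area posterior medians and credible intervals of the two
relative-risk surfaces and of the shared surface exp(theta), exceedance
probabilities P(exp(theta) > 1) flagging hotspots, the scaling parameter
delta with its risk-gradient ratio delta^2, the fraction of log-risk
variation explained by the shared component, and equal-count quantile
classes for choropleth mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mcmc import PosteriorSamples

__all__ = [
    "SharedSummary",
    "summarize_areas",
    "exceedance_probability",
    "risk_gradient_ratio",
    "variance_fractions",
    "shared_summary",
    "quantile_classes",
    "merge_geojson_properties",
]

_DEFAULT_LEVELS = (0.025, 0.5, 0.975)


def _quantiles(draws: np.ndarray, levels) -> np.ndarray:
    """Quantiles over all chains/draws; draws shape (..., n) -> (len(levels), n)."""
    flat = draws.reshape(-1, draws.shape[-1])
    return np.quantile(flat, levels, axis=0)


def summarize_areas(
    samples: PosteriorSamples, levels: tuple[float, float, float] = _DEFAULT_LEVELS
) -> pd.DataFrame:
    """Per-area posterior summary table.

    Columns: median and credible bounds of r1, r2 and exp(theta); the
    exceedance probability P(exp(theta) > 1); and quintile class labels
    of the three median surfaces.
    """
    if samples.n_draws == 0:
        raise ValueError("empty samples")
    lo, med, hi = sorted(levels)
    r1, r2 = samples.risk_draws()
    et = samples.exp_theta_draws()
    out = {"area_id": list(samples.area_ids)}
    for name, draws in (("r1", r1), ("r2", r2), ("exp_theta", et)):
        q = _quantiles(draws, (lo, med, hi))
        out[f"{name}_lo"] = q[0]
        out[f"{name}_median"] = q[1]
        out[f"{name}_hi"] = q[2]
    out["p_exceed"] = exceedance_probability(et)
    df = pd.DataFrame(out)
    k = min(5, samples.fields["theta"].shape[-1])
    for name in ("r1", "r2", "exp_theta"):
        df[f"{name}_class"] = quantile_classes(df[f"{name}_median"].to_numpy(), k)
    return df


def exceedance_probability(draws: np.ndarray, threshold: float = 1.0) -> np.ndarray:
    """Fraction of draws strictly greater than ``threshold``, per area.

    ``draws`` has shape (..., n); the leading axes index draws.
    """
    flat = np.asarray(draws, dtype=float).reshape(-1, draws.shape[-1])
    if flat.shape[0] == 0:
        raise ValueError("need at least one draw")
    return (flat > threshold).mean(axis=0)


def risk_gradient_ratio(delta):
    """Ratio of the two risk gradients, delta / (1/delta) = delta**2.

    Accepts a scalar delta (returns a scalar) or an array of posterior
    draws (returns per-draw ratios).  A delta of 0.48 gives 0.23 to two
    decimals: the shared surface carries a steeper gradient for the
    second outcome.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0):
        raise ValueError("delta must be positive")
    out = delta**2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SharedSummary:
    """Posterior summary of the shared-component scale and its reach."""

    delta_median: float
    delta_ci: tuple[float, float]
    gradient_ratio_median: float
    gradient_ratio_ci: tuple[float, float]
    variance_fraction_1: tuple[float, float, float]  # (lo, median, hi)
    variance_fraction_2: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {
            "delta_median": self.delta_median,
            "delta_ci_low": self.delta_ci[0],
            "delta_ci_high": self.delta_ci[1],
            "gradient_ratio_median": self.gradient_ratio_median,
            "gradient_ratio_ci_low": self.gradient_ratio_ci[0],
            "gradient_ratio_ci_high": self.gradient_ratio_ci[1],
            "variance_fraction_1_median": self.variance_fraction_1[1],
            "variance_fraction_1_ci_low": self.variance_fraction_1[0],
            "variance_fraction_1_ci_high": self.variance_fraction_1[2],
            "variance_fraction_2_median": self.variance_fraction_2[1],
            "variance_fraction_2_ci_low": self.variance_fraction_2[0],
            "variance_fraction_2_ci_high": self.variance_fraction_2[2],
        }

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([self.to_dict()]).to_csv(path, index=False)


def variance_fractions(samples: PosteriorSamples) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw fraction of log-risk variation explained by the shared surface.

    For outcome 1 each draw contributes
    Var(delta*theta) / [Var(delta*theta) + Var(s1) + Var(u1)], with Var
    the empirical variance across areas; outcome 2 uses theta/delta, s2,
    u2.  Draws whose denominator is zero yield NaN (no variation to
    attribute).
    """
    d = np.exp(samples.scalars["log_delta"])[..., None]
    shared1 = (d * samples.fields["theta"]).var(axis=-1)
    shared2 = (samples.fields["theta"] / d).var(axis=-1)
    v_s1 = samples.fields["s1"].var(axis=-1)
    v_s2 = samples.fields["s2"].var(axis=-1)
    v_u1 = samples.fields["u1"].var(axis=-1)
    v_u2 = samples.fields["u2"].var(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(
            shared1 + v_s1 + v_u1 > 0, shared1 / (shared1 + v_s1 + v_u1), np.nan
        )
        f2 = np.where(
            shared2 + v_s2 + v_u2 > 0, shared2 / (shared2 + v_s2 + v_u2), np.nan
        )
    return f1.reshape(-1), f2.reshape(-1)


def shared_summary(samples: PosteriorSamples, levels=_DEFAULT_LEVELS) -> SharedSummary:
    """Summarize delta, the gradient ratio delta^2 and the variance fractions."""
    lo, med, hi = sorted(levels)
    delta_draws = samples.stacked("delta")
    ratio_draws = risk_gradient_ratio(delta_draws)
    f1, f2 = variance_fractions(samples)
    q = lambda x: tuple(float(v) for v in np.nanquantile(x, (lo, med, hi)))
    dq = q(delta_draws)
    rq = q(ratio_draws)
    return SharedSummary(
        delta_median=dq[1],
        delta_ci=(dq[0], dq[2]),
        gradient_ratio_median=rq[1],
        gradient_ratio_ci=(rq[0], rq[2]),
        variance_fraction_1=q(f1),
        variance_fraction_2=q(f2),
    )


def quantile_classes(values: np.ndarray, k: int) -> np.ndarray:
    """Equal-count class labels 1..k from quantile break points.

    Classes are bounded by the (1/k, 2/k, ...) sample quantiles, so with
    n divisible by k and no ties every class holds exactly n/k areas —
    the convention behind quantile choropleth maps.  Tied values share a
    class (all-equal input is all class 1), which keeps the labelling a
    function of the values alone.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of areas n={n}")
    breaks = np.quantile(values, np.arange(1, k) / k)
    return np.searchsorted(breaks, values, side="left").astype(np.intp) + 1


def merge_geojson_properties(
    geojson_path: str | Path,
    table: pd.DataFrame,
    out_path: str | Path,
    key: str = "area_id",
) -> None:
    """Join summary columns onto GeoJSON feature properties by area id."""
    gj = json.loads(Path(geojson_path).read_text())
    rows = {str(r[key]): r for r in table.to_dict(orient="records")}
    for feat in gj.get("features", []):
        aid = str(feat.get("properties", {}).get(key))
        if aid in rows:
            feat["properties"].update(
                {c: v for c, v in rows[aid].items() if c != key}
            )
    Path(out_path).write_text(json.dumps(gj))
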