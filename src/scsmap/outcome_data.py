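"""Per-area counts, populations, expected counts, and prevalence ratios.

Two outcomes are carried side by side (k=1, k=2; in the motivating study
doctor visits and hospital admissions for mental-health conditions).
Counts observed over multi-year windows are converted to annual averages
by dividing by the span in years; fractional averaged counts are retained
unrounded, and the model likelihood evaluates them with a continuous
log-density (log-gamma in place of the factorial).

Expected counts use internal standardization: the region-wide rate of
each outcome times the area population, so that sum(e) = sum(O) per
outcome by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .areal_graph import ArealGraph

__all__ = [
    "OutcomeTable",
    "ExpectedCounts",
    "read_counts",
    "write_counts",
    "annualize_counts",
    "compute_expected",
    "standardized_prevalence_ratio",
]


@dataclass(frozen=True)
class OutcomeTable:
    """Observed counts for two outcomes and the at-risk population.

    ``O`` has shape (n, 2); column k-1 holds outcome-k counts.
    ``period_years`` is per outcome: the observation span the raw counts
    cover (the two outcomes may cover different windows).
    """

    area_ids: tuple[str, ...]
    O: np.ndarray
    N: np.ndarray
    period_years: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        O = np.asarray(self.O, dtype=float)
        N = np.asarray(self.N, dtype=float)
        if O.shape != (len(self.area_ids), 2):
            raise ValueError(f"O must have shape (n, 2), got {O.shape}")
        if N.shape != (len(self.area_ids),):
            raise ValueError(f"N must have shape (n,), got {N.shape}")
        if (O < 0).any():
            i = int(np.argwhere(O < 0)[0][0])
            raise ValueError(f"negative count for area {self.area_ids[i]!r}")
        if (N <= 0).any():
            i = int(np.argwhere(N <= 0)[0][0])
            raise ValueError(f"non-positive population for area {self.area_ids[i]!r}")
        object.__setattr__(self, "O", O)
        object.__setattr__(self, "N", N)

    @property
    def n(self) -> int:
        return len(self.area_ids)


@dataclass(frozen=True)
class ExpectedCounts:
    """Expected events per area and outcome under internal standardization."""

    e: np.ndarray  # shape (n, 2), strictly positive

    def __post_init__(self) -> None:
        e = np.asarray(self.e, dtype=float)
        if (e <= 0).any():
            raise ValueError("expected counts must be strictly positive")
        object.__setattr__(self, "e", e)


def read_counts(
    path: str | Path,
    graph: ArealGraph | None = None,
    period_years: tuple[float, float] = (1.0, 1.0),
) -> OutcomeTable:
    """Read a per-area counts CSV with columns area_id, O1, O2, N.

    If ``graph`` is given, rows are reordered to the graph's canonical
    area order; areas missing from the CSV (or unknown to the graph) are
    an error.  Malformed rows are rejected naming the 1-based data row.
    """
    df = pd.read_csv(path, dtype={"area_id": str})
    required = {"area_id", "O1", "O2", "N"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts CSV missing columns: {sorted(missing)}")
    seen: dict[str, int] = {}
    for row, aid in enumerate(df["area_id"], start=1):
        if aid in seen:
            raise ValueError(f"duplicate area_id {aid!r} at row {row} (first at row {seen[aid]})")
        seen[aid] = row
    for row, (o1, o2, nn) in enumerate(zip(df["O1"], df["O2"], df["N"]), start=1):
        if o1 < 0 or o2 < 0:
            raise ValueError(f"negative count at row {row}")
        if nn <= 0:
            raise ValueError(f"non-positive population at row {row}")
    if graph is not None:
        missing_areas = set(graph.area_ids) - set(df["area_id"])
        if missing_areas:
            raise ValueError(f"counts CSV missing areas: {sorted(missing_areas)[:5]}")
        extra = set(df["area_id"]) - set(graph.area_ids)
        if extra:
            raise ValueError(f"counts CSV has areas unknown to the graph: {sorted(extra)[:5]}")
        df = df.set_index("area_id").loc[list(graph.area_ids)].reset_index()
    return OutcomeTable(
        area_ids=tuple(df["area_id"]),
        O=df[["O1", "O2"]].to_numpy(dtype=float),
        N=df["N"].to_numpy(dtype=float),
        period_years=period_years,
    )


def write_counts(
    table: OutcomeTable, path: str | Path, expected: ExpectedCounts | None = None
) -> None:
    """Write the per-area table as CSV.

    With ``expected`` given, expected counts and standardized prevalence
    ratios are appended (columns e1, e2, spr1, spr2).
    """
    cols = {
        "area_id": table.area_ids,
        "O1": table.O[:, 0],
        "O2": table.O[:, 1],
        "N": table.N.astype(int),
    }
    if expected is not None:
        spr = standardized_prevalence_ratio(table, expected)
        cols.update(
            {
                "e1": expected.e[:, 0],
                "e2": expected.e[:, 1],
                "spr1": spr[:, 0],
                "spr2": spr[:, 1],
            }
        )
    pd.DataFrame(cols).to_csv(path, index=False)


def annualize_counts(table: OutcomeTable) -> OutcomeTable:
    """Convert multi-year counts to annual averages (O / period_years).

    Idempotent once both periods are 1.  Averaged counts may be
    non-integral and are kept unrounded.
    """
    p1, p2 = table.period_years
    if p1 <= 0 or p2 <= 0:
        raise ValueError(f"period_years must be positive, got {table.period_years}")
    O = table.O / np.array([p1, p2])
    return replace(table, O=O, period_years=(1.0, 1.0))


def compute_expected(table: OutcomeTable) -> ExpectedCounts:
    """Internal standardization: e_ik = (sum_j O_jk / sum_j N_j) * N_i."""
    totals = table.O.sum(axis=0)
    for k in range(2):
        if totals[k] == 0:
            raise ValueError(f"outcome {k + 1} has all-zero counts; overall rate undefined")
    rate = totals / table.N.sum()
    e = np.outer(table.N, rate)
    return ExpectedCounts(e=e)


def standardized_prevalence_ratio(table: OutcomeTable, expected: ExpectedCounts) -> np.ndarray:
    """Observed/expected ratio per area and outcome, shape (n, 2).

    The raw-map analogue of the model's relative risk; its
    expected-count-weighted mean is 1 under internal standardization.
    """
    if expected.e.shape != table.O.shape:
        raise ValueError("expected counts do not match table dimensions")
    return table.O / expected.e
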