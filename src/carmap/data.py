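"""Count panels, internally standardized expected counts and descriptives.

An areal study is an ``areas x periods`` matrix of event counts ``O_it``
together with area populations.  Expected counts use internal
standardization: each area's expectation is its population share of the
global event total (optionally recomputed per period), so that
``sum(E) == sum(O)`` and the ratio ``O/E`` is the standardized incidence
ratio (SMR) familiar from small-area disease mapping.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Literal, Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass
class CountPanel:
    """Observed counts per area and period, with area populations."""

    counts: np.ndarray  # (n_areas, n_periods) nonnegative ints
    populations: np.ndarray  # (n_areas,) positive ints
    period_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim == 1:
            self.counts = self.counts[:, None]
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        self.populations = np.asarray(self.populations, dtype=np.int64)
        if self.populations.shape != (self.counts.shape[0],):
            raise ValueError("populations must have one entry per area")
        if (self.populations < 1).any():
            raise ValueError("populations must be positive")
        if not self.period_labels:
            self.period_labels = tuple(
                str(t + 1) for t in range(self.counts.shape[1])
            )
        elif len(self.period_labels) != self.counts.shape[1]:
            raise ValueError("period_labels length must equal n_periods")

    @property
    def n_areas(self) -> int:
        return self.counts.shape[0]

    @property
    def n_periods(self) -> int:
        return self.counts.shape[1]

    # -- I/O: long-format CSV (area_id, period, count), 1-based on disk ----
    def to_frame(self) -> pd.DataFrame:
        area, period = np.meshgrid(
            np.arange(1, self.n_areas + 1),
            np.arange(1, self.n_periods + 1),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "area_id": area.ravel(),
                "period": period.ravel(),
                "count": self.counts.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, populations: Sequence[int] | np.ndarray
    ) -> "CountPanel":
        areas = np.sort(df["area_id"].unique())
        periods = np.sort(df["period"].unique())
        wide = (
            df.pivot_table(index="area_id", columns="period", values="count")
            .reindex(index=areas, columns=periods)
        )
        if wide.isna().any().any():
            raise ValueError("counts table has missing area/period cells")
        return cls(
            counts=wide.to_numpy().astype(np.int64),
            populations=np.asarray(populations),
            period_labels=tuple(str(p) for p in periods),
        )

    @classmethod
    def read_csv(cls, counts_path, populations_path) -> "CountPanel":
        df = pd.read_csv(counts_path)
        pops = pd.read_csv(populations_path).sort_values("area_id")
        return cls.from_frame(df, pops["population"].to_numpy())


def write_populations(populations: np.ndarray, path) -> None:
    pd.DataFrame(
        {"area_id": np.arange(1, len(populations) + 1), "population": populations}
    ).to_csv(path, index=False)


@dataclasses.dataclass
class ExpectedCounts:
    """Positive expected counts per area x period cell.

    Produced by :func:`expected_counts` (internally standardized, so the
    grand totals of E and O agree) or supplied directly in simulation
    studies where E is an input rather than a derived quantity.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if (self.values <= 0).any():
            raise ValueError("expected counts must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def expected_counts(
    populations: np.ndarray,
    panel: CountPanel | np.ndarray,
    mode: Literal["global", "per_period"] = "global",
) -> ExpectedCounts:
    """Internally standardized expected counts.

    ``global`` (default): E_it = pop_i * total(O) / (total(pop) * n_periods),
    constant over periods.  ``per_period``: each period's column of E is
    standardized against that period's count total, so every E column sums to
    the corresponding O column.  Both modes satisfy sum(E) == sum(O).
    """
    counts = panel.counts if isinstance(panel, CountPanel) else np.asarray(panel)
    if counts.ndim == 1:
        counts = counts[:, None]
    populations = np.asarray(populations, dtype=float)
    if (populations <= 0).any() or populations.sum() <= 0:
        raise ValueError("populations must be positive")
    total_pop = populations.sum()
    n_periods = counts.shape[1]
    if counts.sum() <= 0:
        raise ValueError("total observed count must be positive")
    if mode == "global":
        rate = counts.sum() / (total_pop * n_periods)
        values = np.repeat((populations * rate)[:, None], n_periods, axis=1)
    elif mode == "per_period":
        col_tot = counts.sum(axis=0)
        if (col_tot <= 0).any():
            raise ValueError("per_period standardization needs events in every period")
        values = populations[:, None] * (col_tot[None, :] / total_pop)
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    return ExpectedCounts(values)


def standardized_ratio(
    counts: np.ndarray | CountPanel, expected: ExpectedCounts | np.ndarray
) -> np.ndarray:
    """Elementwise O/E (standardized incidence ratio)."""
    o = counts.counts if isinstance(counts, CountPanel) else np.asarray(counts, float)
    e = expected.values if isinstance(expected, ExpectedCounts) else np.asarray(expected, float)
    if o.ndim == 1:
        o = o[:, None]
    if e.ndim == 1:
        e = e[:, None]
    if (e <= 0).any():
        raise ValueError("expected counts must be positive")
    return o / e


def season_of(t: int | np.ndarray) -> int | np.ndarray:
    """Trimester-of-year map q(t) for 1-based quarterly period indices.

    Period 1 is January-March of the first study year, so
    q(t) = ((t - 1) mod 4) + 1; q is periodic with period 4 and onto
    {1, 2, 3, 4}.
    """
    t_arr = np.asarray(t)
    if (t_arr < 1).any():
        raise ValueError("period index must be >= 1")
    q = (t_arr - 1) % 4 + 1
    return int(q) if np.isscalar(t) or t_arr.ndim == 0 else q


def descriptives(panel: CountPanel) -> dict:
    """Summary statistics of a count panel.

    Returns a dict with global per-area statistics (totals over periods),
    a per-period table, and the fraction of zero area-period cells.
    """
    counts = panel.counts
    if counts.size == 0:
        raise ValueError("empty panel")
    area_totals = counts.sum(axis=1)
    per_period = pd.DataFrame(
        {
            "period": list(panel.period_labels),
            "total": counts.sum(axis=0),
            "min": counts.min(axis=0),
            "max": counts.max(axis=0),
            "mean": counts.mean(axis=0),
        }
    )
    return {
        "global": {
            "total": int(area_totals.sum()),
            "min": int(area_totals.min()),
            "max": int(area_totals.max()),
            "mean": float(area_totals.mean()),
        },
        "per_period": per_period,
        "zero_fraction": float((counts == 0).mean()),
    }


def descriptives_csv(panel: CountPanel) -> str:
    """Per-period descriptives as CSV text (global row appended)."""
    d = descriptives(panel)
    buf = io.StringIO()
    table = d["per_period"].copy()
    table.loc[len(table)] = [
        "global",
        d["global"]["total"],
        d["global"]["min"],
        d["global"]["max"],
        d["global"]["mean"],
    ]
    table.to_csv(buf, index=False)
    return buf.getvalue()
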