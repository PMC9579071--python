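"""Caloric conversion of wet biomass and replicate-level summary tables.

Wet biomass concentrations (g/m^2) of the six dominant benthic prey groups
are converted to energy density (kJ/m^2) with group-specific caloric
multipliers determined by bomb calorimetry.  Summaries (mean, median, min,
max, percent of total, percent zeros) are computed over replicate grab
values, with a total row formed by summing the six groups within each
replicate before summarising.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MULTIPLIERS",
    "PREY_GROUPS",
    "canonical_group",
    "to_energy",
    "total_energy",
    "zero_percentage",
    "summarize",
]

#: kJ per g wet weight for the six dominant prey groups.
DEFAULT_MULTIPLIERS: dict[str, float] = {
    "Actinopterygii": 5.2,
    "Amphipoda": 5.2,
    "Isopoda": 4.0,
    "Bivalvia": 2.3,
    "Cumacea": 4.8,
    "Polychaeta": 4.4,
}

PREY_GROUPS: tuple[str, ...] = tuple(DEFAULT_MULTIPLIERS)

# Variant spelling that occurs in field datasets for ray-finned fishes.
_ALIASES = {"Actinoptygerii": "Actinopterygii"}


def canonical_group(group: str) -> str:
    """Resolve a group label (including known spelling variants)."""
    g = group.strip()
    return _ALIASES.get(g, g)


def to_energy(
    biomass, group: str, multipliers: Mapping[str, float] | None = None
):
    """Convert wet biomass (g/m^2) to energy density (kJ/m^2).

    Parameters
    ----------
    biomass : float or array-like
        Non-negative wet biomass concentration(s).
    group : str
        Prey group label (canonical or known alias).
    multipliers : mapping, optional
        Group -> kJ/g multiplier; defaults to :data:`DEFAULT_MULTIPLIERS`.

    Returns
    -------
    float or ndarray
        ``biomass * multiplier(group)``.
    """
    m = DEFAULT_MULTIPLIERS if multipliers is None else multipliers
    g = canonical_group(group)
    if g not in m:
        raise KeyError(
            f"unknown prey group {group!r}; known groups: {sorted(m)}"
        )
    b = np.asarray(biomass, dtype=float)
    if np.any(b < 0):
        raise ValueError("biomass must be non-negative")
    out = b * m[g]
    return float(out) if out.ndim == 0 else out


def total_energy(
    group_energies: Mapping[str, float],
    groups: Iterable[str] = PREY_GROUPS,
) -> float:
    """Total energy density of one replicate: sum over the six prey groups.

    Raises ``KeyError`` if any required group is missing from the replicate.
    """
    canon = {canonical_group(k): v for k, v in group_energies.items()}
    missing = [g for g in groups if g not in canon]
    if missing:
        raise KeyError(f"incomplete replicate; missing groups: {missing}")
    return float(sum(canon[g] for g in groups))


def zero_percentage(values) -> float:
    """Percentage of exact zeros among ``values``."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("zero_percentage of empty input is undefined")
    if np.any(v < 0):
        raise ValueError("values must be non-negative")
    return 100.0 * float(np.count_nonzero(v == 0)) / v.size


def summarize(
    table: pd.DataFrame,
    value_col: str = "biomass_g_m2",
    group_col: str = "group",
    period: str | None = None,
    multipliers: Mapping[str, float] | None = None,
    convert: bool = False,
) -> pd.DataFrame:
    """Per-group replicate-level summary with a total row.

    Statistics are computed over individual replicate values; the total row
    is built by summing the groups within each replicate (identified by
    ``station_id``/``replicate_id``/``period`` when present) and summarising
    those sums.  ``pct_total`` is 100 x group mean / total mean.

    Parameters
    ----------
    table : DataFrame
        Long-format station table with one row per replicate x group.
    value_col : str
        Column to summarise (wet biomass or energy density).
    period : str, optional
        Restrict to a single sampling period.
    convert : bool
        If True, convert ``value_col`` to energy density per group first.
    """
    if table.empty:
        raise ValueError("cannot summarize an empty table")
    t = table.copy()
    if period is not None:
        t = t[t["period"] == period]
        if t.empty:
            raise ValueError(f"no rows for period {period!r}")
    t[group_col] = t[group_col].map(canonical_group)
    if convert:
        m = DEFAULT_MULTIPLIERS if multipliers is None else multipliers
        t[value_col] = t[value_col].to_numpy(dtype=float) * t[group_col].map(
            m
        ).to_numpy(dtype=float)

    key_cols = [
        c for c in ("station_id", "replicate_id", "period") if c in t.columns
    ]
    rows = []
    for g, sub in t.groupby(group_col, sort=True):
        v = sub[value_col].to_numpy(dtype=float)
        rows.append(_stats_row(g, v))
    if key_cols:
        totals = t.groupby(key_cols, sort=True)[value_col].sum().to_numpy()
    else:
        totals = t.groupby(level=0)[value_col].sum().to_numpy()
    rows.append(_stats_row("Total", totals))
    out = pd.DataFrame(rows)
    total_mean = out.loc[out["group"] == "Total", "mean"].iloc[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["pct_total"] = 100.0 * out["mean"] / total_mean
    out.loc[out["group"] == "Total", "pct_total"] = np.nan
    return out


def _stats_row(group: str, v: np.ndarray) -> dict:
    return {
        "group": group,
        "mean": float(np.mean(v)),
        "median": float(np.median(v)),
        "minimum": float(np.min(v)),
        "maximum": float(np.max(v)),
        "pct_zeros": zero_percentage(v),
    }
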