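"""Apparent membrane tension from static tether forces.

A membrane nanotube (tether) pulled from a cell and held at constant
length settles at a plateau force F0 set by the membrane's in-plane
tension T and its bending rigidity B:

    T = F0**2 / (8 * B * pi**2)

With F0 in newtons and B in N*m, T comes out in N/m; results are
reported in uN/m, the unit conventional for cell-scale tensions.
B is treated as a constant of the cell type (default 2.7e-19 N*m) and
assumed invariant across experimental conditions, so group differences
in T reflect differences in tether force alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Plasma-membrane bending rigidity assumed for all conditions (N*m).
DEFAULT_BENDING_RIGIDITY = 2.7e-19

__all__ = [
    "DEFAULT_BENDING_RIGIDITY",
    "apparent_tension",
    "tension_summary",
    "percent_change",
]


def apparent_tension(force_pN, bending_rigidity: float = DEFAULT_BENDING_RIGIDITY):
    """Convert a static tether force to apparent membrane tension.

    Parameters
    ----------
    force_pN : float or array-like
        Static tether force(s) in piconewtons. Must be positive.
    bending_rigidity : float
        Membrane bending rigidity B in N*m. Must be positive.

    Returns
    -------
    float or ndarray
        Apparent tension T = F0^2 / (8 B pi^2) in uN/m.
    """
    force = np.asarray(force_pN, dtype=float)
    if bending_rigidity <= 0:
        raise ValueError("bending_rigidity must be positive")
    if np.any(~np.isfinite(force)) or np.any(force <= 0):
        raise ValueError("tether forces must be positive and finite")
    force_N = force * 1e-12
    tension_N_per_m = force_N**2 / (8.0 * bending_rigidity * np.pi**2)
    tension = tension_N_per_m * 1e6  # N/m -> uN/m
    if np.isscalar(force_pN):
        return float(tension)
    return tension


def tension_summary(
    records: pd.DataFrame,
    bending_rigidity: float = DEFAULT_BENDING_RIGIDITY,
    mode: str = "mean_force",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell and per-group tension summaries.

    Averaging follows the measurement hierarchy: tether pulls are
    averaged within each cell (>= 3 pulls per cell in practice), cells
    within each group.

    Parameters
    ----------
    records : DataFrame
        Columns ``cell_id``, ``group``, ``force_pN`` (one row per tether).
    mode : {"mean_force", "per_tether"}
        ``mean_force`` converts the mean force of each aggregation level
        (the convention consistent with a printed force/tension pair);
        ``per_tether`` converts every pull and averages tensions upward.

    Returns
    -------
    (per_cell, per_group) : DataFrame pair
        Per-cell means and per-group means of force and tension.
    """
    required = {"cell_id", "group", "force_pN"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if len(records) == 0:
        raise ValueError("no tether records")
    df = records.copy()
    if mode not in ("mean_force", "per_tether"):
        raise ValueError("mode must be 'mean_force' or 'per_tether'")

    df["tension_uN_m"] = apparent_tension(df["force_pN"].to_numpy(), bending_rigidity)
    per_cell = (
        df.groupby(["group", "cell_id"], sort=False)
        .agg(mean_force_pN=("force_pN", "mean"), mean_tether_tension=("tension_uN_m", "mean"))
        .reset_index()
    )
    if mode == "mean_force":
        per_cell["tension_uN_m"] = apparent_tension(
            per_cell["mean_force_pN"].to_numpy(), bending_rigidity
        )
    else:
        per_cell["tension_uN_m"] = per_cell["mean_tether_tension"]
    per_cell = per_cell.drop(columns="mean_tether_tension")

    per_group = (
        per_cell.groupby("group", sort=False)
        .agg(
            mean_force_pN=("mean_force_pN", "mean"),
            mean_cell_tension=("tension_uN_m", "mean"),
            n_cells=("cell_id", "nunique"),
        )
        .reset_index()
    )
    if mode == "mean_force":
        per_group["tension_uN_m"] = apparent_tension(
            per_group["mean_force_pN"].to_numpy(), bending_rigidity
        )
    else:
        per_group["tension_uN_m"] = per_group["mean_cell_tension"]
    per_group = per_group.drop(columns="mean_cell_tension")
    return per_cell, per_group


def percent_change(t_reference: float, t_other: float) -> float:
    """Percent change 100*(T2 - T1)/T1 of tension (or any quantity)."""
    if t_reference == 0:
        raise ValueError("reference tension must be nonzero")
    return 100.0 * (t_other - t_reference) / t_reference
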