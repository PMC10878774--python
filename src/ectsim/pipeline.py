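"""Protocol-grid predictions and reduction of uptake/survival measurements.

The experimental workflow this mirrors: cells are pulsed in medium containing
0-50 uM cisplatin, intracellular platinum is measured ~25 min later by
ICP-MS and converted to molecules per cell (1 mol Pt == 1 mol cisplatin,
blank-subtracted against untreated cells), and the passive no-pulse uptake at
each concentration is subtracted to isolate the electroporative contribution.
Survival comes from a clonogenic assay normalized to control plating
efficiency. Model predictions for the same protocol x concentration grid are
then compared point-by-point.

Measurement tables are long-format :class:`pandas.DataFrame` objects with
columns ``protocol, concentration_uM, replicate, quantity, value`` where
``quantity`` is one of ``pt_pg_per_cell``, ``molecules_per_cell`` or
``survival_fraction``. The no-pulse condition uses protocol name
``"control"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    AVOGADRO,
    ModelParameters,
    SolverConfig,
    equilibration_ceiling,
    molecules_per_cell,
    simulate,
)
from .waveforms import PulseTrain, get_preset

__all__ = [
    "CONTROL_PROTOCOL",
    "MEASUREMENT_COLUMNS",
    "UptakeRecord",
    "run_protocol_grid",
    "grid_to_frame",
    "pt_mass_to_molecules",
    "subtract_baseline",
    "model_vs_measurement",
    "survival_vs_molecules",
]

#: protocol label reserved for the no-pulse condition
CONTROL_PROTOCOL = "control"

#: required columns of a long-format measurement table
MEASUREMENT_COLUMNS = ("protocol", "concentration_uM", "replicate", "quantity", "value")

#: molar mass of platinum, g/mol
M_PT = 195.084


class PairingError(ValueError):
    """Raised when two tables cannot be joined on (protocol, concentration)."""


@dataclass(frozen=True)
class UptakeRecord:
    """Model-predicted uptake for one protocol at one concentration."""

    protocol_name: str
    E_applied: float  # V/m
    X_e_uM: float
    X_final: float
    molecules: float
    t_end_s: float

    def __post_init__(self) -> None:
        if self.X_e_uM == 0.0 and self.molecules != 0.0:
            raise ValueError("zero extracellular concentration must give zero molecules")


def run_protocol_grid(
    presets: Sequence[str | PulseTrain],
    concentrations_uM: Sequence[float],
    p: ModelParameters | None = None,
    solver: SolverConfig | None = None,
    t_end: float = 25 * 60.0,
) -> list[UptakeRecord]:
    """Predict uptake for every protocol x concentration combination.

    The normalized uptake X is independent of the extracellular concentration,
    so each protocol is simulated once and the molecule count scales exactly
    linearly across concentrations.
    """
    p = p or ModelParameters()
    records: list[UptakeRecord] = []
    for preset in presets:
        train = get_preset(preset) if isinstance(preset, str) else preset
        traj = simulate(train, p, t_end=t_end, solver=solver)
        X = traj.final.X
        for c in concentrations_uM:
            records.append(
                UptakeRecord(
                    protocol_name=train.name,
                    E_applied=traj.E_applied,
                    X_e_uM=float(c),
                    X_final=X,
                    molecules=molecules_per_cell(X, c * 1e-6, p.r),
                    t_end_s=t_end,
                )
            )
    return records


def grid_to_frame(records: Iterable[UptakeRecord]) -> pd.DataFrame:
    """Tabulate UptakeRecords (one row per protocol x concentration)."""
    return pd.DataFrame([vars(r) for r in records])


def pt_mass_to_molecules(pt_mass_pg: float, blank_pg: float = 0.0) -> float:
    """Convert a per-cell platinum mass (pg) to cisplatin molecules per cell.

    The instrument blank (Pt measured in untreated, cisplatin-free cells) is
    subtracted first; a net negative mass is floored at zero. One mole of
    platinum is taken as one mole of cisplatin.
    """
    if pt_mass_pg < 0.0 or blank_pg < 0.0:
        raise ValueError("platinum masses must be nonnegative")
    net_g = max(pt_mass_pg - blank_pg, 0.0) * 1e-12
    return net_g / M_PT * AVOGADRO


def _check_measurement_table(df: pd.DataFrame) -> None:
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")


def subtract_baseline(measurements: pd.DataFrame) -> pd.DataFrame:
    """Isolate electroporative uptake by removing the no-pulse baseline.

    For each (protocol, concentration) group of ``molecules_per_cell``
    records, the mean over replicates of the no-pulse (``"control"``) rows at
    the same concentration is subtracted from the treated mean. Differences
    below zero are floored at 0 with a warning.

    Returns a table with one row per treated (protocol, concentration):
    columns ``protocol, concentration_uM, molecules_per_cell, sd, n``, where
    ``sd`` is the replicate standard deviation of the treated group.
    """
    _check_measurement_table(measurements)
    mol = measurements[measurements["quantity"] == "molecules_per_cell"]
    controls = mol[mol["protocol"] == CONTROL_PROTOCOL]
    treated = mol[mol["protocol"] != CONTROL_PROTOCOL]
    baseline = controls.groupby("concentration_uM")["value"].mean()

    rows = []
    for (proto, conc), grp in treated.groupby(["protocol", "concentration_uM"], sort=True):
        if conc not in baseline.index:
            raise PairingError(
                f"no no-pulse (control) records at {conc} uM for baseline subtraction"
            )
        net = grp["value"].mean() - baseline.loc[conc]
        if net < 0.0:
            warnings.warn(
                f"negative baseline-subtracted uptake for {proto} at {conc} uM; "
                "flooring at 0",
                stacklevel=2,
            )
            net = 0.0
        rows.append(
            {
                "protocol": proto,
                "concentration_uM": conc,
                "molecules_per_cell": net,
                "sd": grp["value"].std(ddof=1) if len(grp) > 1 else 0.0,
                "n": len(grp),
            }
        )
    return pd.DataFrame(rows)


def model_vs_measurement(
    model: Iterable[UptakeRecord] | pd.DataFrame,
    measured: pd.DataFrame,
) -> pd.DataFrame:
    """Compare predicted with measured molecules per (protocol, concentration).

    ``measured`` must already be baseline-subtracted (output of
    :func:`subtract_baseline`). The per-cell ratio is model/measured; per
    protocol an aggregate over nonzero concentrations is formed as the
    geometric mean of the ratios (ratios are multiplicative). Grid points with
    zero measured uptake at nonzero concentration are flagged
    (``ratio = NaN``) and excluded from the aggregate.

    Returns a table with columns ``protocol, concentration_uM,
    model_molecules, measured_molecules, ratio, protocol_ratio``.
    """
    mdf = model if isinstance(model, pd.DataFrame) else grid_to_frame(model)
    mdf = mdf.rename(columns={"protocol_name": "protocol", "X_e_uM": "concentration_uM"})
    merged = mdf.merge(measured, on=["protocol", "concentration_uM"], how="inner")
    if merged.empty:
        raise PairingError("model and measurement tables share no (protocol, concentration) keys")

    merged = merged[merged["concentration_uM"] > 0].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = merged["molecules"].to_numpy() / merged["molecules_per_cell"].to_numpy()
    ratio[~np.isfinite(ratio)] = np.nan
    merged["ratio"] = ratio

    out = merged[
        ["protocol", "concentration_uM", "molecules", "molecules_per_cell", "ratio"]
    ].rename(
        columns={"molecules": "model_molecules", "molecules_per_cell": "measured_molecules"}
    )
    geo = (
        out.dropna(subset=["ratio"])
        .groupby("protocol")["ratio"]
        .apply(lambda r: float(np.exp(np.mean(np.log(r)))))
        .rename("protocol_ratio")
    )
    return out.merge(geo, on="protocol", how="left").sort_values(
        ["protocol", "concentration_uM"], ignore_index=True
    )


def survival_vs_molecules(
    uptake: pd.DataFrame, survival: pd.DataFrame
) -> pd.DataFrame:
    """Pair mean molecule counts with mean survival per (protocol, concentration).

    Both inputs are long-format measurement tables; replicates are aggregated
    by arithmetic mean with sample standard deviation. The result is the inner
    join on the (protocol, concentration) keys — the dose-response pairing of
    uptake against clonogenic survival.
    """
    _check_measurement_table(uptake)
    _check_measurement_table(survival)

    def _agg(df: pd.DataFrame, quantity: str, prefix: str) -> pd.DataFrame:
        sub = df[df["quantity"] == quantity]
        g = sub.groupby(["protocol", "concentration_uM"])["value"]
        return pd.DataFrame(
            {
                prefix: g.mean(),
                f"{prefix}_sd": g.std(ddof=1).fillna(0.0),
                f"{prefix}_n": g.size(),
            }
        ).reset_index()

    mol = _agg(uptake, "molecules_per_cell", "molecules")
    sur = _agg(survival, "survival_fraction", "survival")
    paired = mol.merge(sur, on=["protocol", "concentration_uM"], how="inner")
    if paired.empty:
        raise PairingError("uptake and survival tables share no (protocol, concentration) keys")
    return paired.sort_values(["protocol", "concentration_uM"], ignore_index=True)
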