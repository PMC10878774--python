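"""Synthetic replicate-level uptake and clonogenic-survival data.

No public dataset accompanies the uptake/survival measurements this package
analyses, so this module generates statistically realistic stand-ins against
which the reduction pipeline can be exercised and validated end to end:

* **Uptake** (ICP-MS molecules per cell): per-replicate values are the model
  truth for a protocol/concentration, multiplied by an optional per-protocol
  distortion factor (emulating systematic model/experiment mismatch) and by
  multiplicative lognormal noise with a fixed coefficient of variation, plus
  a small passive no-pulse baseline that grows linearly with concentration.
  No-pulse ("control") records carry the baseline alone.

* **Clonogenic survival**: true survival follows a single-hit exponential
  kill model ``S = exp(-k * molecules)``; each well's colony count is a
  binomial draw with ``cells_plated`` trials and success probability
  ``pe0 * S`` (``pe0`` = control plating efficiency). Survival is recovered
  exactly as in the assay: per-well plating efficiency, group means,
  normalization to the control group.

The exponential kill link and the lognormal noise are modelling choices of
this package, not measured facts; they provide a known ground truth for
parameter-recovery tests. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pipeline import CONTROL_PROTOCOL, MEASUREMENT_COLUMNS, UptakeRecord, grid_to_frame

__all__ = [
    "SyntheticConfig",
    "generate_uptake_measurements",
    "generate_clonogenic_counts",
    "clonogenic_survival",
    "fit_kill_rate",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design and noise model for the synthetic experiments.

    Defaults mirror the emulated study: four cisplatin concentrations
    (0/10/30/50 uM), 4 independent experiments, ~100 cells plated per well in
    triplicate wells, and uptake noise of 20% CV typical of per-cell ICP-MS
    quantities. ``kill_rate_k`` (per molecule) is set so that survival drops
    to a few percent at ~5e7 molecules per cell, the observed cytotoxic range.
    """

    protocols: tuple[str, ...] = ("hf_50x50", "mono_8x100us", "mono_8x5ms")
    concentrations_uM: tuple[float, ...] = (0.0, 10.0, 30.0, 50.0)
    n_replicates: int = 4
    uptake_cv: float = 0.2
    baseline_slope: float = 1e5  # passive molecules per uM without pulses
    distortion_factors: Mapping[str, float] = field(default_factory=dict)
    kill_rate_k: float = 7e-8  # per molecule; S = exp(-k * molecules)
    plating_efficiency_pe0: float = 0.8
    cells_plated: int = 100
    wells: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not self.uptake_cv > 0.0:
            raise ValueError("uptake_cv must be > 0")
        if not 0.0 < self.plating_efficiency_pe0 <= 1.0:
            raise ValueError("plating_efficiency_pe0 must lie in (0, 1]")

    def distortion(self, protocol: str) -> float:
        return float(self.distortion_factors.get(protocol, 1.0))


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and coefficient of variation cv."""
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def generate_uptake_measurements(
    cfg: SyntheticConfig,
    model_truth: Sequence[UptakeRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Simulate replicate ICP-MS molecule counts around a model truth grid.

    Replicate value = distortion(protocol) * truth * lognormal(1, cv)
    + baseline_slope * concentration. Control (no-pulse) rows receive the
    noisy baseline only. Returns a long-format measurement table
    (``quantity == "molecules_per_cell"``).
    """
    rng = np.random.default_rng(cfg.seed)
    truth = model_truth if isinstance(model_truth, pd.DataFrame) else grid_to_frame(model_truth)
    truth = truth.set_index(["protocol_name", "X_e_uM"])["molecules"]

    rows = []
    for proto in cfg.protocols:
        for conc in cfg.concentrations_uM:
            try:
                mu = truth.loc[(proto, conc)]
            except KeyError:
                raise KeyError(
                    f"model truth missing grid point ({proto!r}, {conc} uM)"
                ) from None
            noise = _lognormal_factors(rng, cfg.uptake_cv, cfg.n_replicates)
            values = cfg.distortion(proto) * mu * noise + cfg.baseline_slope * conc
            for rep, v in enumerate(values, start=1):
                rows.append((proto, conc, rep, "molecules_per_cell", float(v)))
    for conc in cfg.concentrations_uM:
        noise = _lognormal_factors(rng, cfg.uptake_cv, cfg.n_replicates)
        values = cfg.baseline_slope * conc * noise
        for rep, v in enumerate(values, start=1):
            rows.append((CONTROL_PROTOCOL, conc, rep, "molecules_per_cell", float(v)))
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def generate_clonogenic_counts(
    cfg: SyntheticConfig, molecules_table: pd.DataFrame
) -> pd.DataFrame:
    """Simulate colony counts for each (protocol, concentration) group.

    The mean molecules per cell of each group sets the true survival
    ``S = exp(-k * molecules)``; each well then yields a binomial colony
    count with ``cells_plated`` trials at success probability ``pe0 * S``.
    The control group at 0 uM (no pulses, no drug) has S = 1 by construction
    and anchors the plating-efficiency normalization.

    Returns a table with columns ``protocol, concentration_uM, well,
    cells_plated, colonies``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    mol = molecules_table[molecules_table["quantity"] == "molecules_per_cell"]
    if mol.empty:
        raise ValueError("molecules_table contains no molecules_per_cell records")
    means = mol.groupby(["protocol", "concentration_uM"], sort=True)["value"].mean()

    rows = []
    for (proto, conc), m in means.items():
        S = math.exp(-cfg.kill_rate_k * m)
        p_colony = cfg.plating_efficiency_pe0 * S
        counts = rng.binomial(cfg.cells_plated, p_colony, size=cfg.wells)
        for well, c in enumerate(counts, start=1):
            rows.append((proto, conc, well, cfg.cells_plated, int(c)))
    return pd.DataFrame(
        rows, columns=["protocol", "concentration_uM", "well", "cells_plated", "colonies"]
    )


def clonogenic_survival(counts: pd.DataFrame) -> pd.DataFrame:
    """Reduce colony counts to survival fractions, as in the clonogenic assay.

    Per well, plating efficiency = colonies / cells plated; efficiencies are
    averaged per (protocol, concentration) group and normalized to the control
    group (no pulses at 0 uM). Returns a long-format measurement table with
    one ``survival_fraction`` record per group (replicate 1).
    """
    pe = (counts["colonies"] / counts["cells_plated"]).rename("pe")
    df = pd.concat([counts[["protocol", "concentration_uM"]], pe], axis=1)
    group_pe = df.groupby(["protocol", "concentration_uM"], sort=True)["pe"].mean()

    key = (CONTROL_PROTOCOL, 0.0)
    if key not in group_pe.index:
        raise ValueError("control group (no pulses, 0 uM) required for normalization")
    pe0 = group_pe.loc[key]
    if pe0 <= 0.0:
        raise ZeroDivisionError("control plating efficiency is zero; cannot normalize")

    rows = [
        (proto, conc, 1, "survival_fraction", float(v / pe0))
        for (proto, conc), v in group_pe.items()
    ]
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def fit_kill_rate(
    paired: pd.DataFrame,
    n_bootstrap: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Estimate the per-molecule kill rate from paired (molecules, survival).

    Fits ``log S = -k * molecules`` through the origin by least squares over
    rows with ``survival`` in (0, 1]; a nonparametric bootstrap over rows
    gives the confidence interval. ``paired`` is the output of
    :func:`ectsim.pipeline.survival_vs_molecules` (columns ``molecules`` and
    ``survival``).
    """
    usable = paired[(paired["survival"] > 0.0) & (paired["survival"] <= 1.0)]
    m = usable["molecules"].to_numpy(float)
    logS = np.log(usable["survival"].to_numpy(float))
    if len(m) < 3:
        raise ValueError("need at least 3 paired points with survival in (0, 1]")
    denom = float(m @ m)
    if denom == 0.0 or np.all(logS == 0.0):
        raise ValueError("degenerate fit: all survivals equal 1 or all molecule counts 0")
    k_hat = float(-(m @ logS) / denom)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(m), size=(n_bootstrap, len(m)))
    mb, lb = m[idx], logS[idx]
    db = np.einsum("ij,ij->i", mb, mb)
    ok = db > 0
    ks = -np.einsum("ij,ij->i", mb, lb)[ok] / db[ok]
    lo, hi = np.quantile(ks, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return k_hat, (float(lo), float(hi))
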