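"""Run configuration: validated YAML with unit-tagged keys.

Every numeric key that carries a unit says so in its name (``field_kV_per_cm``,
``t_end_min``, ...) because the protocols mix kV/cm, V, us, ms and ns at the
bench; tagging prevents silent unit mistakes. Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .model import ModelParameters, SolverConfig
from .synthetic import SyntheticConfig
from .waveforms import KV_PER_CM, PRESETS

__all__ = ["RunConfig", "ProtocolSelection", "load_config", "manifest"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolSelection(_Strict):
    """A preset name with an optional field-strength override in kV/cm."""

    name: str
    field_kV_per_cm: Optional[float] = None

    @field_validator("name")
    @classmethod
    def _known(cls, v: str) -> str:
        if v not in PRESETS:
            raise ValueError(f"unknown protocol {v!r}; available: {', '.join(PRESETS)}")
        return v

    @property
    def field_V_per_m(self) -> Optional[float]:
        if self.field_kV_per_cm is None:
            return None
        return self.field_kV_per_cm * KV_PER_CM


class SolverSection(_Strict):
    rtol: float = 1e-8
    atol: float = 1e-12
    gap_switch_threshold_tau: float = 100.0
    t_end_reference: str = "train_end"

    def build(self) -> SolverConfig:
        return SolverConfig(
            rtol=self.rtol,
            atol=self.atol,
            gap_switch_threshold=self.gap_switch_threshold_tau,
            t_end_reference=self.t_end_reference,
        )


class ParameterOverrides(_Strict):
    """Optional overrides of the default model parameters (unit-tagged)."""

    U0_mV: Optional[float] = None
    h_nm: Optional[float] = None
    r_um: Optional[float] = None
    tau_RC_us: Optional[float] = None
    rho_s_nm: Optional[float] = None
    rho_d_nm: Optional[float] = None
    D_m2_per_s: Optional[float] = None
    alpha: Optional[float] = None
    beta: Optional[float] = None
    gamma: Optional[float] = None
    delta: Optional[float] = None
    eta: Optional[float] = None
    xi: Optional[float] = None
    sigma_ext_S_per_m: Optional[float] = None

    def build(self) -> ModelParameters:
        scale = {
            "U0_mV": ("U0", 1e-3), "h_nm": ("h", 1e-9), "r_um": ("r", 1e-6),
            "tau_RC_us": ("tau_RC", 1e-6), "rho_s_nm": ("rho_s", 1e-9),
            "rho_d_nm": ("rho_d", 1e-9), "D_m2_per_s": ("D", 1.0),
            "alpha": ("alpha", 1.0), "beta": ("beta", 1.0), "gamma": ("gamma", 1.0),
            "delta": ("delta", 1.0), "eta": ("eta", 1.0), "xi": ("xi", 1.0),
            "sigma_ext_S_per_m": ("sigma_ext", 1.0),
        }
        kwargs = {}
        for key, (target, factor) in scale.items():
            v = getattr(self, key)
            if v is not None:
                kwargs[target] = v * factor
        return ModelParameters(**kwargs)


class SyntheticSection(_Strict):
    n_replicates: int = 4
    uptake_cv: float = 0.2
    baseline_slope_per_uM: float = 1e5
    distortion_factors: dict[str, float] = Field(default_factory=dict)
    kill_rate_k_per_molecule: float = 7e-8
    plating_efficiency_pe0: float = 0.8
    cells_plated: int = 100
    wells: int = 3

    def build(self, protocols: tuple[str, ...], concentrations: tuple[float, ...],
              seed: int) -> SyntheticConfig:
        return SyntheticConfig(
            protocols=protocols,
            concentrations_uM=concentrations,
            n_replicates=self.n_replicates,
            uptake_cv=self.uptake_cv,
            baseline_slope=self.baseline_slope_per_uM,
            distortion_factors=self.distortion_factors,
            kill_rate_k=self.kill_rate_k_per_molecule,
            plating_efficiency_pe0=self.plating_efficiency_pe0,
            cells_plated=self.cells_plated,
            wells=self.wells,
            seed=seed,
        )


class RunConfig(_Strict):
    """Top-level run configuration (see examples/config.yaml for a template)."""

    protocols: list[ProtocolSelection] = Field(
        default_factory=lambda: [ProtocolSelection(name=n) for n in PRESETS]
    )
    concentrations_uM: list[float] = Field(default_factory=lambda: [0.0, 10.0, 30.0, 50.0])
    t_end_min: float = 25.0
    parameters: ParameterOverrides = Field(default_factory=ParameterOverrides)
    solver: SolverSection = Field(default_factory=SolverSection)
    synthetic: SyntheticSection = Field(default_factory=SyntheticSection)
    output_dir: str = "ectsim_out"
    seed: int = 0
    log_level: str = "INFO"

    @property
    def t_end_s(self) -> float:
        return self.t_end_min * 60.0

    def model_parameters(self) -> ModelParameters:
        return self.parameters.build()

    def solver_config(self) -> SolverConfig:
        return self.solver.build()

    def synthetic_config(self) -> SyntheticConfig:
        return self.synthetic.build(
            tuple(p.name for p in self.protocols),
            tuple(self.concentrations_uM),
            self.seed,
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def manifest(cfg: RunConfig) -> dict:
    """Reproducibility record: config hash, seed and package version."""
    from . import __version__

    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return {
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": cfg.seed,
        "ectsim_version": __version__,
    }
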