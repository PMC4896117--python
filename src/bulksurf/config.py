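"""YAML run configuration with strict validation and table defaults.

Every kinetic symbol of the cell model is a config key with its reference
default; unknown keys are rejected (typos fail loudly, listing every
offending key), and a loaded configuration round-trips through save/load.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class MeinhardtConfig(_Strict):
    ra: float = 2e-2
    ba: float = 1e-1
    sa: float = 5e-4
    Da: float = 4e-7
    rb: float = 3e-2
    Db: float = 4e-5
    bc: float = 7e-3
    rc: float = 1.3e-2
    Dc: float = 2.8e-6
    sc: float = 2e-1

    @field_validator("Da", "Db", "Dc")
    @classmethod
    def _nonneg_diff(cls, v, info):
        if v < 0:
            raise ValueError(f"{info.field_name}: diffusion coefficient must be nonnegative")
        return v


class MotilityConfig(_Strict):
    Kprot: float = 1e-5
    lambda0: float = 2e-6
    beta_tension: float = 2e-2


class LigandConfig(_Strict):
    D: float = 10.0
    Ds: float = 1e-6
    k_minus1: float = 1.0
    Kd: float = 30.0
    k1: float | None = None      # default k_minus1 / Kd
    total_receptors: float = 7e4
    r0: float = 0.1
    rf: float = 0.3
    l0: float = 5.3
    gradient: float = 8.5

    @field_validator("D", "Ds")
    @classmethod
    def _nonneg_diff(cls, v, info):
        if v < 0:
            raise ValueError(f"{info.field_name}: diffusion coefficient must be nonnegative")
        return v


class NoiseConfig(_Strict):
    theta: float = 0.1
    mu: float = 0.0
    sigma: float = float(0.05 * np.sqrt(2 * 0.1))
    enabled: bool = True


class NumericsConfig(_Strict):
    dt: float = 0.1
    n_steps: int = 2000
    ns_membrane: int = 80
    h_far: float = 0.035
    h_membrane: float = 0.012
    tau_bulk: float = 1e-2
    tau_curve: float = 1e-2
    angle_tol: float = 10.0
    picard_tol: float = 1e-9
    newton_tol: float = 1e-10
    record_every: int = 10
    perturbation: float = 0.05

    @field_validator("dt", "tau_bulk", "tau_curve", "picard_tol", "newton_tol")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive")
        return v


class RunConfig(_Strict):
    seed: int = 0
    outdir: str = "runs/out"
    meinhardt: MeinhardtConfig = Field(default_factory=MeinhardtConfig)
    motility: MotilityConfig = Field(default_factory=MotilityConfig)
    ligand: LigandConfig = Field(default_factory=LigandConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    numerics: NumericsConfig = Field(default_factory=NumericsConfig)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (missing keys -> defaults)."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level of the config must be a mapping")
    return RunConfig.model_validate(raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


def to_model_params(cfg: RunConfig):
    """Translate a validated config into the cell-model parameter objects."""
    from . import cellmodel as cm

    mein = cm.MeinhardtParams(**cfg.meinhardt.model_dump())
    mot = cm.MotilityParams(Kprot=cfg.motility.Kprot,
                            lambda0=cfg.motility.lambda0,
                            beta_tension=cfg.motility.beta_tension,
                            A0=float(np.pi * cfg.ligand.r0 ** 2),
                            lam=cfg.motility.lambda0)
    lig = cm.LigandParams(D=cfg.ligand.D, Ds_ligand=cfg.ligand.Ds,
                          k_minus1=cfg.ligand.k_minus1, Kd=cfg.ligand.Kd,
                          k1=cfg.ligand.k1,
                          total_receptors=cfg.ligand.total_receptors,
                          r0=cfg.ligand.r0, rf=cfg.ligand.rf,
                          l0=cfg.ligand.l0, gradient=cfg.ligand.gradient)
    noise = cm.NoiseParams(theta=cfg.noise.theta, mu=cfg.noise.mu,
                           sigma=cfg.noise.sigma)
    run = cm.CellRunConfig(dt=cfg.numerics.dt, n_steps=cfg.numerics.n_steps,
                           seed=cfg.seed,
                           ns_membrane=cfg.numerics.ns_membrane,
                           h_far=cfg.numerics.h_far,
                           h_membrane=cfg.numerics.h_membrane,
                           tau_bulk=cfg.numerics.tau_bulk,
                           tau_curve=cfg.numerics.tau_curve,
                           angle_tol=cfg.numerics.angle_tol,
                           noise=noise, noise_on=cfg.noise.enabled,
                           perturbation=cfg.numerics.perturbation,
                           record_every=cfg.numerics.record_every)
    return lig, mein, mot, run
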