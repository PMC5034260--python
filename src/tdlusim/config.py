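"""Validated run configuration (YAML) and simulation builders.

A :class:`RunConfig` bundles everything one experiment needs -- geometry,
hormone curves, chemokine PDE constants, engine rates, trafficking and
sampling -- and is schema-validated (pydantic) before any run. Every run
writes its resolved configuration next to its outputs so a directory is
self-reproducing.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from . import hormones
from .engine import Simulation
from .geometry import LatticeDomain, build_tdlu
from .params import SimulationParams, TraffickingParams


class GeometryConfig(BaseModel):
    n_acini: int = 12
    lumen_radius: int = 3
    acinus_spacing: int = 13
    grid_size: int = 80
    stromal_margin: int = 3
    jitter: int = 1
    seed: int = 0
    epithelial_band: tuple[int, int] | None = (250, 2500)


class HormoneConfig(BaseModel):
    curve_csv: str | None = None      # columns day,f_pi,f_ai; default packaged curves
    follicular_len: float = 14.0
    theta: float = Field(1.0, gt=0)


class ChemokineConfig(BaseModel):
    d_dam: float = Field(5.0, ge=0)
    d_dying: float = Field(5.0, ge=0)
    lambda_dam: float = Field(0.5, ge=0)
    lambda_dying: float = Field(0.5, ge=0)
    s_dam: float = Field(1.0, ge=0)
    s_dying: float = Field(1.0, ge=0)


class EngineConfig(BaseModel):
    k_pro: float = Field(0.03, ge=0)
    k_apt: float = Field(0.0021, ge=0)
    k_dge: float = Field(0.0, ge=0, le=1)
    k_kill: float = Field(0.10, ge=0)
    k_sup: float = Field(0.05, ge=0)
    c_act: float = Field(0.02, ge=0)
    chi: float = Field(50.0, ge=0)
    m_rate: float = Field(10.0, ge=0)
    tau_lys: float = Field(12.0, ge=0)
    dt: float = Field(1.0, gt=0)


class TraffickingConfig(BaseModel):
    lam0_E: float = Field(3.2, ge=0)
    alpha_E: float = Field(300.0, ge=0)
    beta_E: float = Field(2270.0, ge=0)
    lam0_R: float = Field(5.1, ge=0)
    alpha_R: float = Field(300.0, ge=0)
    lam_out: float = Field(0.2, ge=0)


class SamplingConfig(BaseModel):
    snapshot_days: list[float] = [5.0, 14.0, 25.0]
    rdf_bin_width: float = Field(1.0, gt=0)
    cluster_min: int = Field(3, ge=1)


class RunConfig(BaseModel):
    geometry: GeometryConfig = GeometryConfig()
    hormone: HormoneConfig = HormoneConfig()
    chemokine: ChemokineConfig = ChemokineConfig()
    engine: EngineConfig = EngineConfig()
    trafficking: TraffickingConfig = TraffickingConfig()
    sampling: SamplingConfig = SamplingConfig()
    n_cycles: int = Field(12, ge=1)
    n_reps: int = Field(10, ge=1)
    seed: int = 0

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v):
        if not 0 <= v < 2**31:
            raise ValueError("seed must be a nonnegative 31-bit integer")
        return v

    # -- IO ---------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)

    # -- builders ---------------------------------------------------------
    def build_domain(self) -> LatticeDomain:
        g = self.geometry
        band = tuple(g.epithelial_band) if g.epithelial_band else None
        return build_tdlu(
            n_acini=g.n_acini, lumen_radius=g.lumen_radius,
            acinus_spacing=g.acinus_spacing, grid_size=g.grid_size,
            seed=g.seed, stromal_margin=g.stromal_margin, jitter=g.jitter,
            epithelial_band=band,
        )

    def build_profile(self) -> hormones.HormoneProfile:
        h = self.hormone
        if h.curve_csv:
            prof = hormones.HormoneProfile.from_csv(h.curve_csv, theta=h.theta)
        else:
            prof = hormones.default_profile(theta=h.theta)
        if h.follicular_len != prof.follicular_len:
            prof = hormones.rescale_follicular(prof, h.follicular_len)
        return prof

    def build_params(self) -> SimulationParams:
        return SimulationParams(
            **self.engine.model_dump(),
            **self.chemokine.model_dump(),
            theta=self.hormone.theta,
            trafficking=TraffickingParams(**self.trafficking.model_dump()),
        )

    def build_simulation(self, seed=None, domain: LatticeDomain | None = None) -> Simulation:
        if domain is None:
            domain = self.build_domain()
        return Simulation(
            domain, self.build_params(), self.build_profile(),
            seed=self.seed if seed is None else seed,
        )
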