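"""Declarative run configuration (TOML or JSON) with schema validation.

Blocks mirror the library types: ``model`` (how to obtain E(R) and mu(R)),
``cavity``, ``bath``, ``dynamics``, ``spectrum``, ``scan`` and ``output``.
Unknown keys are rejected.  Config files use presentation units at the
boundary (photon frequencies in meV, friction in cm^-1, times in fs); the
resolvers convert to atomic units.

Every run emits a resolved-config record — all defaults materialized, plus
the package version, a content hash and the master seed — via
:func:`resolved_record`.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict

from . import units
from .cavity import CavityParams
from .dynamics import SimConfig
from .fixtures import QuarticFixtureSpec, table1_model
from .ghrates import BathParams
from .potentials import (PotentialModel, SMParams, build_potential_model,
                         stationary_points)
from .spectrum import SpectrumConfig

__all__ = ["RunConfig", "load_config", "resolved_record"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelBlock(_Block):
    kind: Literal["sm", "tabulated", "quartic", "table1", "serialized"] = "table1"
    # sm
    ion_separation: float = 9.4
    ion_charges: tuple[float, float] = (1.0, 1.0)
    softening_lengths: tuple[float, float, float] = (1.5, 1.5, 1.5)
    softening_kind: Literal["erf", "inverse_square"] = "erf"
    electron_grid: tuple[float, float, int] = (-17.0, 17.0, 401)
    R_grid: tuple[float, float, int] = (-3.6, 3.6, 129)
    # tabulated / serialized
    path: Optional[str] = None
    dipole_path: Optional[str] = None
    mass: Optional[float] = None
    # quartic / table1
    Eb: float = 0.014
    omega_b_mev: Optional[float] = None
    mu_slope: float = 0.0
    mu_quad: float = 0.0
    mu_cubic: float = 0.0

    def build(self) -> PotentialModel:
        if self.kind == "sm":
            params = SMParams(
                ion_separation=self.ion_separation,
                ion_charges=self.ion_charges,
                softening_lengths=self.softening_lengths,
                softening_kind=self.softening_kind,
                electron_grid=self.electron_grid,
                R_grid=self.R_grid,
            )
            return build_potential_model(params)
        if self.kind == "tabulated":
            if self.path is None or self.mass is None:
                raise ValueError("tabulated model needs 'path' and 'mass'")
            return build_potential_model(self.path, mass=self.mass,
                                         dipole_path=self.dipole_path)
        if self.kind == "serialized":
            if self.path is None:
                raise ValueError("serialized model needs 'path'")
            return PotentialModel.from_json(self.path)
        if self.kind == "table1":
            return table1_model(Eb=self.Eb)
        # quartic
        if self.omega_b_mev is None or self.mass is None:
            raise ValueError("quartic model needs 'omega_b_mev' and 'mass'")
        spec = QuarticFixtureSpec(
            Eb=self.Eb,
            omega_b=units.energy(self.omega_b_mev, "mev", "hartree"),
            mass=self.mass, mu_slope=self.mu_slope,
            mu_quad=self.mu_quad, mu_cubic=self.mu_cubic,
        )
        return spec.to_model()


class CavityBlock(_Block):
    omega_c_mev: float = 170.6
    coupling_kind: Literal["chi", "eta", "eta_tilde", "A0"] = "eta"
    value: float = 0.047

    def build(self, model: PotentialModel) -> CavityParams:
        sp = stationary_points(model)
        wc = units.energy(self.omega_c_mev, "mev", "hartree")
        return CavityParams.from_reference(wc, self.coupling_kind, self.value,
                                           sp, model.mass)


class BathBlock(_Block):
    gamma_cm1: float = 400.0
    temperature: float = 300.0
    omega_p_cm1: Optional[float] = None

    def build(self) -> BathParams:
        return BathParams(
            gamma=units.wavenumber_to_angular_frequency(self.gamma_cm1),
            temperature=self.temperature,
            omega_p=(units.wavenumber_to_angular_frequency(self.omega_p_cm1)
                     if self.omega_p_cm1 is not None else None),
        )


class DynamicsBlock(_Block):
    dt: float = 4.0
    t_max_fs: float = 200.0
    n_traj: int = 100_000
    sampling_interval_fs: float = 270.0
    plateau_window: float = 0.25
    save_stride: int = 4
    sampling_mode: Literal["gaussian", "constrained_md"] = "gaussian"
    n_batches: int = 20
    product_side: Literal[1, -1] = 1

    def build(self, bath: BathBlock, seed: int) -> SimConfig:
        return SimConfig(
            dt=self.dt, t_max_fs=self.t_max_fs, n_traj=self.n_traj,
            temperature=bath.temperature,
            gamma=units.wavenumber_to_angular_frequency(bath.gamma_cm1),
            sampling_interval_fs=self.sampling_interval_fs, seed=seed,
            plateau_window=self.plateau_window, save_stride=self.save_stride,
            sampling_mode=self.sampling_mode, n_batches=self.n_batches,
            product_side=self.product_side,
        )


class SpectrumBlock(_Block):
    n_R: int = 64
    n_qc: int = 48
    n_states: int = 16
    epsilon_mev: float = 1.0
    energy_min_mev: Optional[float] = None
    energy_max_mev: Optional[float] = None
    n_energy: int = 4000

    def build(self) -> SpectrumConfig:
        egrid = None
        if self.energy_min_mev is not None and self.energy_max_mev is not None:
            egrid = (units.energy(self.energy_min_mev, "mev", "hartree"),
                     units.energy(self.energy_max_mev, "mev", "hartree"),
                     self.n_energy)
        return SpectrumConfig(
            n_R=self.n_R, n_qc=self.n_qc, n_states=self.n_states,
            epsilon=units.energy(self.epsilon_mev, "mev", "hartree"),
            energy_grid=egrid, n_energy=self.n_energy,
        )


class ScanBlock(_Block):
    omega_c_min_mev: float = 1.0
    omega_c_max_mev: float = 500.0
    n_omega_c: int = 500
    eta_values: tuple[float, ...] = (0.047, 0.094, 0.188)


class OutputBlock(_Block):
    directory: str = "."


class RunConfig(_Block):
    seed: int = 0
    model: ModelBlock = ModelBlock()
    cavity: CavityBlock = CavityBlock()
    bath: BathBlock = BathBlock()
    dynamics: DynamicsBlock = DynamicsBlock()
    spectrum: SpectrumBlock = SpectrumBlock()
    scan: ScanBlock = ScanBlock()
    output: OutputBlock = OutputBlock()


def load_config(path) -> RunConfig:
    """Load and validate a TOML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = tomllib.loads(text)
    return RunConfig.model_validate(data)


def resolved_record(config: RunConfig) -> dict:
    """Fully materialized config with version, content hash and seed."""
    from . import __version__

    payload = config.model_dump()
    canonical = json.dumps(payload, sort_keys=True)
    return {
        "cavikin_version": __version__,
        "config_hash": hashlib.sha256(canonical.encode()).hexdigest()[:16],
        "seed": config.seed,
        "resolved": payload,
    }
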