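"""Ground-state light-matter Hamiltonian of a molecule in a single-mode cavity.

The dipole-gauge (Pauli-Fierz) Hamiltonian projected on the electronic
ground state couples the reaction coordinate R to one photon displacement
coordinate q_c through the permanent dipole mu(R):

    V_CBO(R, q_c) = E(R) + 1/2 omega_c^2 (q_c + sqrt(2/omega_c^3) chi mu(R))^2

(atomic units, hbar = 1; the photon coordinate is mass-weighted so its mass
is 1).  The squared term contains the dipole self-energy
(chi mu)^2 / omega_c, which keeps the barrier along the minimum-energy path
exactly equal to the bare barrier for every coupling and frequency.

Coupling-strength parameterizations
-----------------------------------
Four equivalent parameterizations are interconverted here (refs are the
molecular reference quantities M, omega0, mu0'):

* ``chi`` — the coupling in the displaced-oscillator form above;
* ``A0 = chi / omega_c`` — field amplitude;
* ``eta_tilde = chi / (sqrt(M) omega_c)`` — mass-weighted coupling;
* ``eta = mu0' sqrt(1/(2 M omega0)) chi / omega_c`` — the dimensionless
  normalized coupling; the linear-response Rabi splitting is
  ``2 omega_c eta``.

Scanning omega_c at fixed ``eta`` keeps ``eta_tilde`` constant, i.e. chi is
rescaled proportionally to omega_c.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .potentials import PotentialModel, StationaryPoints

__all__ = [
    "CavityParams",
    "CouplingValues",
    "EffectiveCouplings",
    "convert_coupling",
    "cbo_potential",
    "photon_displacement",
    "effective_couplings",
]


class CouplingValues(NamedTuple):
    chi: float
    eta: float
    eta_tilde: float
    A0: float


@dataclass(frozen=True)
class EffectiveCouplings:
    """Bilinear R--q_c couplings at the well (C0) and barrier (C_ddag)."""

    C0: float
    C_ddag: float


@dataclass(frozen=True)
class CavityParams:
    """Photon frequency and light-matter coupling.

    ``chi`` is the canonical stored coupling; ``eta``, ``eta_tilde`` and
    ``A0`` are derived.  ``mass``, ``omega0`` and ``mu0_prime`` are the
    molecular reference quantities needed for the eta conversions; they may
    be omitted when only chi/A0/eta_tilde are used.
    """

    omega_c: float
    chi: float
    mass: float | None = None
    omega0: float | None = None
    mu0_prime: float | None = None

    def __post_init__(self) -> None:
        if self.omega_c <= 0:
            raise ValueError("omega_c must be positive")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_chi(cls, omega_c: float, chi: float, **refs) -> "CavityParams":
        return cls(omega_c=omega_c, chi=chi, **refs)

    @classmethod
    def from_A0(cls, omega_c: float, A0: float, **refs) -> "CavityParams":
        return cls(omega_c=omega_c, chi=A0 * omega_c, **refs)

    @classmethod
    def from_eta_tilde(cls, omega_c: float, eta_tilde: float, *, mass: float,
                       **refs) -> "CavityParams":
        return cls(omega_c=omega_c, chi=eta_tilde * np.sqrt(mass) * omega_c,
                   mass=mass, **refs)

    @classmethod
    def from_eta(cls, omega_c: float, eta: float, *, mass: float,
                 omega0: float, mu0_prime: float) -> "CavityParams":
        cls._require(mass=mass, omega0=omega0, mu0_prime=mu0_prime)
        eta_tilde = eta * np.sqrt(2.0 * omega0) / mu0_prime
        return cls(omega_c=omega_c, chi=eta_tilde * np.sqrt(mass) * omega_c,
                   mass=mass, omega0=omega0, mu0_prime=mu0_prime)

    @classmethod
    def from_reference(cls, omega_c: float, kind: str, value: float,
                       sp: StationaryPoints, mass: float) -> "CavityParams":
        """Build from a stationary-point analysis (supplies all refs)."""
        refs = dict(mass=mass, omega0=sp.omega0, mu0_prime=sp.mu0_prime)
        ctor = {"chi": cls.from_chi, "A0": cls.from_A0,
                "eta_tilde": cls.from_eta_tilde, "eta": cls.from_eta}
        if kind not in ctor:
            raise ValueError(f"unknown coupling kind {kind!r}")
        if kind in ("chi", "A0"):
            return ctor[kind](omega_c, value, **refs)
        return ctor[kind](omega_c, value, **refs)

    @staticmethod
    def _require(**kwargs) -> None:
        for name, value in kwargs.items():
            if value is None:
                raise ValueError(f"missing reference quantity {name!r}")

    # -- derived parameterizations ----------------------------------------

    @property
    def A0(self) -> float:
        return self.chi / self.omega_c

    @property
    def eta_tilde(self) -> float:
        self._require(mass=self.mass)
        return self.chi / (np.sqrt(self.mass) * self.omega_c)

    @property
    def eta(self) -> float:
        self._require(mass=self.mass, omega0=self.omega0,
                      mu0_prime=self.mu0_prime)
        return self.mu0_prime * np.sqrt(1.0 / (2.0 * self.mass * self.omega0)) \
            * self.chi / self.omega_c

    def with_omega_c(self, omega_c: float, *, hold: str = "eta") -> "CavityParams":
        """Move to a new photon frequency.

        ``hold="eta"`` (equivalently ``"eta_tilde"``) rescales chi
        proportionally to omega_c so the normalized coupling stays fixed —
        the convention used for fixed-eta frequency scans.  ``hold="chi"``
        keeps chi itself.
        """
        if hold in ("eta", "eta_tilde"):
            return replace(self, omega_c=omega_c,
                           chi=self.chi * omega_c / self.omega_c)
        if hold == "chi":
            return replace(self, omega_c=omega_c)
        raise ValueError(f"unknown hold convention {hold!r}")


def convert_coupling(cavity: CavityParams) -> CouplingValues:
    """All four coupling parameterizations of ``cavity``, mutually consistent."""
    return CouplingValues(chi=cavity.chi, eta=float(cavity.eta),
                          eta_tilde=float(cavity.eta_tilde), A0=cavity.A0)


def photon_displacement(model: PotentialModel, cavity: CavityParams, R):
    """Equilibrium photon displacement -sqrt(2/omega_c^3) chi mu(R)."""
    wc = cavity.omega_c
    return -np.sqrt(2.0 / wc**3) * cavity.chi * model.dipole(R)


def cbo_potential(model: PotentialModel, cavity: CavityParams, R, qc):
    """Cavity Born-Oppenheimer surface V_CBO(R, q_c).

    The dipole self-energy is implicit in the completed square, so the
    minimum-energy path q_c(R) = -sqrt(2/omega_c^3) chi mu(R) traces the
    bare E(R) exactly.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < model.R_min) or np.any(R > model.R_max):
        raise ValueError("R outside the model grid range")
    wc = cavity.omega_c
    disp = np.sqrt(2.0 / wc**3) * cavity.chi * model.dipole(R)
    return model.energy(R) + 0.5 * wc**2 * (np.asarray(qc) + disp) ** 2


def effective_couplings(sp: StationaryPoints, cavity: CavityParams,
                        mass: float | None = None) -> EffectiveCouplings:
    """Bilinear couplings C0 = sqrt(2 omega_c / M) chi mu0' and the barrier
    analogue C_ddag with the dipole slope on the dividing surface."""
    M = mass if mass is not None else cavity.mass
    if M is None:
        raise ValueError("missing reference quantity 'mass'")
    pref = np.sqrt(2.0 * cavity.omega_c / M) * cavity.chi
    return EffectiveCouplings(C0=pref * sp.mu0_prime,
                              C_ddag=pref * sp.mu_ddag_prime)
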