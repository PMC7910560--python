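"""Grote-Hynes rate theory for a reaction coordinate coupled to a photon mode.

The photon coordinate acts as a non-Markovian "solvent" degree of freedom.
The rate factorizes as k = kappa_GH * k_TST with

    k_TST   = omega0/(2 pi) exp(-beta Eb)          (cavity independent)
    kappa_GH = lambda / omega_b

where lambda is the unstable (reactive) frequency at the barrier.  For the
isolated two-dimensional model {R, q_c} lambda has a closed form; with an
additional Markovian friction gamma = zeta/M on R (an ohmic phonon bath in
the memoryless limit), lambda is the unique positive real root of the
quartic

    lambda^4 + gamma lambda^3
    + (omega_c^2 - omega_b^2 + C_ddag^2/omega_c^2) lambda^2
    + gamma omega_c^2 lambda - omega_c^2 omega_b^2 = 0.

Tuning omega_c minimizes kappa_GH near the barrier frequency omega_b
(weak coupling) and red-shifts the minimum into the ultra-strong coupling
regime — the frequency-resonant suppression of the rate.

All inputs and outputs are in Hartree atomic units unless noted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import units
from .cavity import CavityParams, effective_couplings
from .potentials import PotentialModel, StationaryPoints, stationary_points

logger = logging.getLogger("cavikin.ghrates")

__all__ = [
    "BathParams",
    "NormalModes",
    "GHResult",
    "normal_modes",
    "kappa_gh_2d",
    "resonance_omega_c",
    "gh_lambda_markovian",
    "k_tst",
    "effective_ddG",
    "scan_frequencies",
    "find_resonance_numeric",
]

#: Default Markovian friction rate gamma = zeta/M: angular-frequency
#: equivalent of 400 cm^-1.
DEFAULT_GAMMA = units.wavenumber_to_angular_frequency(400.0)


@dataclass(frozen=True)
class BathParams:
    """Markovian phonon-bath parameters.

    ``gamma`` is the friction *rate* zeta/M (an angular frequency in a.u.).
    The ohmic spectral density J(omega) = zeta omega exp(-omega/omega_p) is
    represented only through (gamma, omega_p); ``omega_p`` gates a
    Markovianity diagnostic and must be set explicitly to enable it.
    """

    gamma: float = DEFAULT_GAMMA
    temperature: float = 300.0
    omega_p: float | None = None

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.omega_p is not None and self.gamma > 0.5 * self.omega_p:
            logger.warning(
                "friction rate gamma=%.3e comparable to phonon cutoff "
                "omega_p=%.3e; Markovian bath limit may be inaccurate",
                self.gamma, self.omega_p,
            )

    @property
    def beta(self) -> float:
        return units.thermal_beta(self.temperature)


@dataclass(frozen=True)
class NormalModes:
    """Polariton normal modes of the 2D model at the well and the barrier.

    ``Omega_minus_ddag_sq`` is the unstable squared barrier eigenvalue and
    is always negative; -Omega_minus_ddag_sq = lambda^2 of the frictionless
    theory.
    """

    Omega_plus: float
    Omega_minus: float
    Omega_plus_ddag: float
    Omega_minus_ddag_sq: float


@dataclass(frozen=True)
class GHResult:
    """Reactive frequency, transmission coefficient and rates."""

    lam: float
    kappa_gh: float
    k_tst: float
    k: float
    omega_c_star: float | None = None


def normal_modes(omega0: float, omega_b: float, omega_c: float,
                 C0: float, C_ddag: float) -> NormalModes:
    """Polariton normal-mode frequencies at the reactant well and barrier.

    Well branches:
        Omega_pm^2 = 1/2 (omega0^2 + C0^2/omega_c^2 + omega_c^2)
                     +- 1/2 sqrt((...)^2 - 4 omega_c^2 omega0^2)
    Barrier branches use -omega_b^2 in place of omega0^2 (with C_ddag) and a
    plus sign under the square root, so the minus branch squared is negative.
    """
    if min(omega0, omega_b, omega_c) <= 0:
        raise ValueError("frequencies must be positive")
    # minus branches in rationalized form (conjugate product) to avoid
    # catastrophic cancellation at strong coupling / extreme frequency ratios
    s0 = omega0**2 + C0**2 / omega_c**2 + omega_c**2
    disc0 = np.sqrt(s0 * s0 - 4.0 * omega_c**2 * omega0**2)
    Op2 = 0.5 * (s0 + disc0)
    Om2 = 2.0 * omega_c**2 * omega0**2 / (s0 + disc0)
    sb = -(omega_b**2) + C_ddag**2 / omega_c**2 + omega_c**2
    discb = np.sqrt(sb * sb + 4.0 * omega_c**2 * omega_b**2)
    if sb >= 0:
        Opd2 = 0.5 * (sb + discb)
        Omd2 = -2.0 * omega_c**2 * omega_b**2 / (sb + discb)
    else:
        Opd2 = 2.0 * omega_c**2 * omega_b**2 / (discb - sb)
        Omd2 = 0.5 * (sb - discb)
    return NormalModes(
        Omega_plus=float(np.sqrt(Op2)),
        Omega_minus=float(np.sqrt(Om2)),
        Omega_plus_ddag=float(np.sqrt(Opd2)),
        Omega_minus_ddag_sq=float(Omd2),
    )


def kappa_gh_2d(omega_b: float, omega_c: float, C_ddag: float) -> float:
    """Frictionless transmission coefficient of the 2D {R, q_c} model.

    kappa_GH = (1/omega_b) [1/2 (-d + sqrt(d^2 + 4 omega_b^2 omega_c^2))]^{1/2}
    with d = omega_c^2 - omega_b^2 + C_ddag^2/omega_c^2; equals
    sqrt(-Omega_minus_ddag^2)/omega_b and lies in (0, 1].
    """
    if omega_b <= 0 or omega_c <= 0:
        raise ValueError("frequencies must be positive")
    d = omega_c**2 - omega_b**2 + C_ddag**2 / omega_c**2
    disc = np.sqrt(d * d + 4.0 * omega_b**2 * omega_c**2)
    # rationalized for d > 0 to avoid cancellation at strong coupling
    lam2 = (2.0 * omega_b**2 * omega_c**2 / (d + disc) if d >= 0
            else 0.5 * (-d + disc))
    return float(np.sqrt(lam2) / omega_b)


def resonance_omega_c(eta_tilde: float, mu_ddag_prime: float,
                      omega_b: float) -> float:
    """Photon frequency minimizing the 2D kappa_GH at fixed eta_tilde.

        omega_c* = -1/2 eta_tilde^2 mu_ddag'^2
                   + 1/2 sqrt(eta_tilde^4 mu_ddag'^4 + 4 omega_b^2)

    Decreases (red-shifts) as eta_tilde grows; equals omega_b at zero
    coupling.
    """
    a = eta_tilde**2 * mu_ddag_prime**2
    return float(-0.5 * a + 0.5 * np.sqrt(a * a + 4.0 * omega_b**2))


def gh_lambda_markovian(omega_b: float, omega_c: float, C_ddag: float,
                        gamma: float) -> float:
    """Reactive frequency lambda with Markovian friction gamma on R.

    Solves the quartic in the module docstring via companion-matrix
    eigenvalues and returns its unique positive real root.  Raises if no, or
    more than one, positive real root is found (parameter pathology).
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    coeffs = np.array([
        1.0,
        gamma,
        omega_c**2 - omega_b**2 + C_ddag**2 / omega_c**2,
        gamma * omega_c**2,
        -(omega_c**2) * omega_b**2,
    ])
    roots = np.roots(coeffs)
    tol = 1e-10
    pos = [r.real for r in roots
           if abs(r.imag) <= tol * max(abs(r), 1.0) and r.real > 0]
    if len(pos) == 0:
        raise RuntimeError("no positive real root of the reactive-frequency "
                           "quartic; inputs are unphysical")
    if len(pos) > 1:
        raise RuntimeError(
            f"multiple positive real roots {pos}; parameter pathology")
    return float(pos[0])


def k_tst(omega0: float, Eb: float, temperature: float) -> float:
    """Transition-state-theory rate omega0/(2 pi) exp(-beta Eb) in a.u.

    Invariant to all cavity parameters: the dipole self-energy keeps the
    barrier height unchanged for any coupling.
    """
    if Eb < 0:
        raise ValueError("Eb must be non-negative")
    beta = units.thermal_beta(temperature)
    return float(omega0 / (2.0 * np.pi) * np.exp(-beta * Eb))


def effective_ddG(kappa: float, kappa0: float, temperature: float) -> float:
    """Effective activation free-energy change -kB T ln(kappa/kappa0) (Hartree).

    Obtained by pushing the transmission-coefficient change through the
    Eyring equation; positive when the cavity suppresses kappa below the
    bare value kappa0.  Convert with ``units.energy(x, "hartree", "kJ/mol")``
    for presentation.
    """
    if kappa <= 0 or kappa0 <= 0:
        raise ValueError("transmission coefficients must be positive")
    beta = units.thermal_beta(temperature)
    return float(-np.log(kappa / kappa0) / beta)


def _gh_point(sp: StationaryPoints, mass: float, cavity: CavityParams,
              gamma: float, temperature: float) -> GHResult:
    eff = effective_couplings(sp, cavity, mass=mass)
    lam = gh_lambda_markovian(sp.omega_b, cavity.omega_c, eff.C_ddag, gamma)
    kappa = lam / sp.omega_b
    ktst = k_tst(sp.omega0, sp.Eb, temperature)
    return GHResult(lam=lam, kappa_gh=kappa, k_tst=ktst, k=kappa * ktst)


def gh_rate(model: PotentialModel, cavity: CavityParams,
            bath: BathParams | None = None,
            sp: StationaryPoints | None = None) -> GHResult:
    """Full Grote-Hynes rate for a potential model in a cavity."""
    bath = bath or BathParams()
    sp = sp or stationary_points(model)
    return _gh_point(sp, model.mass, cavity, bath.gamma, bath.temperature)


def scan_frequencies(model: PotentialModel, eta: float,
                     omega_c_list, gamma: float = DEFAULT_GAMMA,
                     temperature: float = 300.0,
                     sp: StationaryPoints | None = None) -> pd.DataFrame:
    """kappa(omega_c) at fixed normalized coupling eta.

    chi is rescaled proportionally to omega_c across the scan so eta (and
    eta_tilde) stay constant.  Returns a table with columns
    (omega_c_mev, eta, chi_au, kappa_gh, lambda_au, k_tst_au, k_au); the
    located minimum is available through :func:`find_resonance_numeric` or
    ``df.loc[df.kappa_gh.idxmin()]``.
    """
    sp = sp or stationary_points(model)
    rows = []
    for wc in np.asarray(omega_c_list, dtype=float):
        if eta == 0.0:
            cav = CavityParams(omega_c=wc, chi=0.0, mass=model.mass,
                               omega0=sp.omega0, mu0_prime=sp.mu0_prime)
        else:
            cav = CavityParams.from_eta(wc, eta, mass=model.mass,
                                        omega0=sp.omega0,
                                        mu0_prime=sp.mu0_prime)
        res = _gh_point(sp, model.mass, cav, gamma, temperature)
        rows.append({
            "omega_c_mev": units.energy(wc, "hartree", "mev"),
            "eta": eta,
            "chi_au": cav.chi,
            "kappa_gh": res.kappa_gh,
            "lambda_au": res.lam,
            "k_tst_au": res.k_tst,
            "k_au": res.k,
        })
    return pd.DataFrame(rows)


def find_resonance_numeric(sp: StationaryPoints, mass: float, eta: float,
                           gamma: float = DEFAULT_GAMMA,
                           bracket_mev: tuple[float, float] = (1.0, 1000.0),
                           n_bracket: int = 200) -> tuple[float, float]:
    """Numerically locate the kappa-minimizing omega_c at fixed eta.

    Scans a log-spaced bracket, then refines with bounded scalar
    minimization (golden-section family).  Returns ``(omega_c_star,
    kappa_min)`` in a.u.  Covers the gamma > 0 case where the closed-form
    resonance of the frictionless 2D model no longer applies.
    """
    eta_tilde = eta * np.sqrt(2.0 * sp.omega0) / sp.mu0_prime

    def kappa_of(wc: float) -> float:
        csq_over = 2.0 * wc * eta_tilde**2 * sp.mu_ddag_prime**2
        c_ddag = np.sqrt(csq_over) * wc  # C_ddag^2 = csq_over * wc^2
        return gh_lambda_markovian(sp.omega_b, wc, c_ddag, gamma) / sp.omega_b

    lo = units.energy(bracket_mev[0], "mev", "hartree")
    hi = units.energy(bracket_mev[1], "mev", "hartree")
    grid = np.logspace(np.log10(lo), np.log10(hi), n_bracket)
    vals = np.array([kappa_of(w) for w in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_bracket - 1)]
    res = minimize_scalar(kappa_of, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x), float(res.fun)
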