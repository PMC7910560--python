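"""Ground-state molecular potential E(R) and permanent dipole mu(R).

The reaction coordinate R is a proton-transfer coordinate.  A model of
proton-coupled electron transfer (an electron and a proton shuttling between
two fixed ions, the Shin-Metiu construction) is solved on a real-space grid
to yield the Born-Oppenheimer ground-state surface E(R) and the permanent
dipole mu(R) = <Psi_g| mu_hat |Psi_g>.  Alternatively both curves can be
supplied as tabulated data or generated analytically (see
:mod:`cavikin.fixtures`).

All quantities are in Hartree atomic units.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import eigh_tridiagonal
from scipy.special import erf

from . import units

logger = logging.getLogger("cavikin.potentials")

__all__ = [
    "SMParams",
    "PotentialModel",
    "StationaryPoints",
    "solve_sm_ground_state",
    "build_potential_model",
    "stationary_points",
    "center_at_barrier",
]


# --------------------------------------------------------------------------
# Shin-Metiu-type electronic problem
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SMParams:
    """Parameters of the one-electron proton-transfer model.

    Two ions of charge ``ion_charges`` are held fixed at -L/2 and +L/2
    (L = ``ion_separation``).  A proton (coordinate R, mass ``proton_mass``)
    and one electron (coordinate r, mass ``electron_mass``) move between
    them.  The electron-nucleus attractions are soft Coulomb terms with the
    given ``softening_lengths`` (left ion, right ion, proton); the
    proton-ion repulsions are bare Coulomb.

    ``softening_kind`` selects the regularization: ``"erf"`` uses
    -Z erf(|x|/a)/|x| and ``"inverse_square"`` uses -Z/sqrt(x^2 + a^2).

    The defaults are calibrated so the ground surface is an asymmetric-slope
    double well with hbar*omega0 ~ 172 meV, hbar*omega_b ~ 163 meV,
    mu0' ~ 0.23 a.u. and mu_ddag' ~ -2.1 a.u. — representative
    proton-coupled electron-transfer parameters (see docs/methods.md).
    """

    ion_separation: float = 9.4
    ion_charges: tuple[float, float] = (1.0, 1.0)
    softening_lengths: tuple[float, float, float] = (1.5, 1.5, 1.5)
    softening_kind: str = "erf"
    electron_mass: float = 1.0
    proton_mass: float = units.PROTON_MASS_AU
    electron_grid: tuple[float, float, int] = (-17.0, 17.0, 401)
    R_grid: tuple[float, float, int] = (-3.6, 3.6, 129)
    gap_tol: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("electron_grid", "R_grid"):
            lo, hi, n = getattr(self, name)
            if not (hi > lo and n >= 64):
                raise ValueError(
                    f"{name} must be strictly increasing with >= 64 points"
                )
        if self.electron_mass <= 0 or self.proton_mass <= 0:
            raise ValueError("masses must be positive")
        if any(a <= 0 for a in self.softening_lengths):
            raise ValueError("softening lengths must be positive")
        if self.softening_kind not in ("erf", "inverse_square"):
            raise ValueError("softening_kind must be 'erf' or 'inverse_square'")

    @property
    def ion_positions(self) -> tuple[float, float]:
        L = self.ion_separation
        return (-L / 2.0, L / 2.0)


def _soft_attraction(x: np.ndarray, Z: float, a: float, kind: str) -> np.ndarray:
    """Softened -Z/|x| electron-nucleus attraction."""
    ax = np.abs(x)
    if kind == "erf":
        # erf(|x|/a)/|x| -> 2/(a sqrt(pi)) as x -> 0
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(ax > 1e-12, erf(ax / a) / np.where(ax > 0, ax, 1.0),
                         2.0 / (a * np.sqrt(np.pi)))
        return -Z * v
    return -Z / np.sqrt(x * x + a * a)


def sm_electron_potential(params: SMParams, r: np.ndarray, R: float) -> np.ndarray:
    """Electron potential V_eN(r; R) for fixed proton position R."""
    (z1, z2) = params.ion_charges
    (a1, a2, ap) = params.softening_lengths
    x1, x2 = params.ion_positions
    kind = params.softening_kind
    return (
        _soft_attraction(r - x1, z1, a1, kind)
        + _soft_attraction(r - x2, z2, a2, kind)
        + _soft_attraction(r - R, 1.0, ap, kind)
    )


def sm_nuclear_repulsion(params: SMParams, R: float) -> float:
    """Bare Coulomb repulsion between the proton and the two fixed ions."""
    (z1, z2) = params.ion_charges
    x1, x2 = params.ion_positions
    return z1 / abs(R - x1) + z2 / abs(R - x2)


def solve_sm_ground_state(
    params: SMParams, R: float, *, return_wavefunction: bool = False
):
    """Ground state of the one-electron Hamiltonian at fixed proton R.

    Diagonalizes T_r + V_eN + V_NN discretized with second-order finite
    differences on the electron grid (Dirichlet boundaries) and returns
    ``(energy, dipole)``: the lowest eigenvalue (including the nuclear
    repulsion V_NN) and the ground-state permanent dipole
    <Psi_g| mu_hat |Psi_g> with mu_hat built from all charges about the
    center of the fixed-ion pair.

    A warning is logged when the ground state is separated from the first
    excited state by less than ``params.gap_tol``.
    """
    lo, hi, n = params.electron_grid
    if not (lo < R < hi):
        raise ValueError("proton position R must lie inside the electron grid")
    rmin, rmax = params.R_grid[0], params.R_grid[1]
    if not (rmin <= R <= rmax):
        raise ValueError(f"R = {R} outside the declared R grid [{rmin}, {rmax}]")
    r = np.linspace(lo, hi, n)
    dr = r[1] - r[0]
    v = sm_electron_potential(params, r, R)
    kin = 1.0 / (params.electron_mass * dr * dr)
    diag = kin + v
    offdiag = np.full(n - 1, -0.5 * kin)
    try:
        evals, evecs = eigh_tridiagonal(
            diag, offdiag, select="i", select_range=(0, 1)
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"electronic eigensolve failed at R={R}: {exc}") from exc
    gap = evals[1] - evals[0]
    if gap < params.gap_tol:
        warnings.warn(
            f"electronic gap {gap:.3e} Ha below tolerance at R={R:.3f}; "
            "ground-state surface may be unreliable near an avoided crossing",
            stacklevel=2,
        )
    psi = evecs[:, 0]
    psi = psi / np.sqrt(np.sum(psi * psi) * dr)
    r_mean = float(np.sum(r * psi * psi) * dr)
    (z1, z2) = params.ion_charges
    x1, x2 = params.ion_positions
    # dipole about the ion-pair center (origin 0): ions + proton - electron
    dipole = z1 * x1 + z2 * x2 + 1.0 * R - r_mean
    energy = float(evals[0]) + sm_nuclear_repulsion(params, R)
    if return_wavefunction:
        return energy, dipole, r, psi
    return energy, dipole


# --------------------------------------------------------------------------
# PotentialModel container
# --------------------------------------------------------------------------


@dataclass
class PotentialModel:
    """Grid-defined ground-state surface E(R) and dipole mu(R).

    Cubic-spline interpolants (with analytic first and second derivatives)
    are built at construction and reproduce the grid values exactly at the
    nodes.
    """

    R: np.ndarray
    E: np.ndarray
    mu: np.ndarray
    mass: float
    provenance: str = "tabulated"
    _E_spline: CubicSpline = field(init=False, repr=False, compare=False)
    _mu_spline: CubicSpline = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.R.ndim != 1 or self.R.size < 16:
            raise ValueError("R grid must be 1-D with at least 16 points")
        if np.any(np.diff(self.R) <= 0):
            raise ValueError("R grid must be strictly increasing")
        if self.E.shape != self.R.shape or self.mu.shape != self.R.shape:
            raise ValueError("E and mu must match the R grid length")
        if not (np.all(np.isfinite(self.E)) and np.all(np.isfinite(self.mu))):
            raise ValueError("E and mu must be finite")
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        self._E_spline = CubicSpline(self.R, self.E)
        self._mu_spline = CubicSpline(self.R, self.mu)

    # -- evaluation -------------------------------------------------------

    def energy(self, R):
        return self._E_spline(R)

    def energy_d1(self, R):
        return self._E_spline(R, 1)

    def energy_d2(self, R):
        return self._E_spline(R, 2)

    def dipole(self, R):
        return self._mu_spline(R)

    def dipole_d1(self, R):
        return self._mu_spline(R, 1)

    @property
    def R_min(self) -> float:
        return float(self.R[0])

    @property
    def R_max(self) -> float:
        return float(self.R[-1])

    def shifted(self, offset: float) -> "PotentialModel":
        """Rigidly translate the coordinate by ``offset`` (R -> R + offset)."""
        return PotentialModel(
            self.R + offset, self.E.copy(), self.mu.copy(), self.mass,
            provenance=self.provenance,
        )

    # -- serialization (JSON + arrays) ------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "format": "cavikin-potential-model",
            "version": 1,
            "mass": self.mass,
            "provenance": self.provenance,
            "R": self.R.tolist(),
            "E": self.E.tolist(),
            "mu": self.mu.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "PotentialModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "cavikin-potential-model":
            raise ValueError(f"{path} is not a serialized PotentialModel")
        return cls(
            np.asarray(payload["R"]),
            np.asarray(payload["E"]),
            np.asarray(payload["mu"]),
            float(payload["mass"]),
            provenance=payload.get("provenance", "tabulated"),
        )


# --------------------------------------------------------------------------
# Construction from the various sources
# --------------------------------------------------------------------------


def _read_table(path) -> np.ndarray:
    data = np.loadtxt(path, comments="#", delimiter=None if not str(path).endswith(".csv") else ",", ndmin=2)
    return data


def _table_units(path) -> dict:
    """Parse an optional '# units: R=<u> E=<u> mu=<u>' header line."""
    out = {"R": "au", "E": "hartree", "mu": "au"}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if not line.startswith("#"):
                break
            if "units:" in line:
                for token in line.split("units:", 1)[1].split():
                    if "=" in token:
                        key, val = token.split("=", 1)
                        out[key.strip()] = val.strip().lower()
    return out


_LENGTH_TO_AU = {"au": 1.0, "bohr": 1.0, "angstrom": 1.0 / 0.529177210903}


def build_potential_model(
    source,
    *,
    mass: float | None = None,
    dipole_path=None,
    provenance: str | None = None,
) -> PotentialModel:
    """Construct a :class:`PotentialModel` from any supported source.

    ``source`` may be

    * :class:`SMParams` — solve the electronic problem at every point of the
      declared R grid (``mass`` defaults to the proton mass of the params);
    * a path to a three-column table ``(R, E, mu)`` (``mass`` required), or
      a path to a two-column ``(R, E)`` table with the dipole in a second
      two-column file given as ``dipole_path``;
    * an object exposing ``to_model()`` (analytic fixture specs).

    Tabulated files may declare units in a ``# units: R=au E=ev mu=au``
    header; atomic units are the default.
    """
    if isinstance(source, SMParams):
        lo, hi, n = source.R_grid
        Rg = np.linspace(lo, hi, n)
        E = np.empty(n)
        mu = np.empty(n)
        for i, R in enumerate(Rg):
            E[i], mu[i] = solve_sm_ground_state(source, R)
        return PotentialModel(
            Rg, E, mu, mass if mass is not None else source.proton_mass,
            provenance=provenance or "sm_solver",
        )
    if hasattr(source, "to_model"):
        return source.to_model()
    # tabulated
    path = Path(source)
    data = _read_table(path)
    u = _table_units(path)
    if dipole_path is None:
        if data.shape[1] != 3:
            raise ValueError(
                f"{path}: expected 3 columns (R, E, mu), got {data.shape[1]}"
            )
        Rg, E, mu = data[:, 0], data[:, 1], data[:, 2]
    else:
        if data.shape[1] != 2:
            raise ValueError(f"{path}: expected 2 columns (R, E)")
        dd = _read_table(dipole_path)
        if dd.shape[1] != 2:
            raise ValueError(f"{dipole_path}: expected 2 columns (R, mu)")
        if dd.shape[0] != data.shape[0] or not np.allclose(dd[:, 0], data[:, 0]):
            raise ValueError("energy and dipole tables must share the R column")
        Rg, E, mu = data[:, 0], data[:, 1], dd[:, 1]
    if np.any(~np.isfinite(data)):
        raise ValueError(f"{path}: non-finite entries in table")
    if Rg.size < 16:
        raise ValueError(f"{path}: need at least 16 grid points, got {Rg.size}")
    if np.any(np.diff(Rg) <= 0):
        raise ValueError(f"{path}: R column must be strictly increasing")
    if mass is None:
        raise ValueError("mass is required for tabulated input")
    Rg = Rg * _LENGTH_TO_AU.get(u["R"], 1.0)
    E = units.energy(E, u["E"], "hartree") if u["E"] not in ("au", "hartree") else E
    return PotentialModel(Rg, E, mu, mass, provenance=provenance or "tabulated")


# --------------------------------------------------------------------------
# Stationary-point analysis
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StationaryPoints:
    """Reactant minimum and barrier-top properties of a double-well surface.

    ``omega0`` and ``omega_b`` are the harmonic frequencies
    sqrt(E''(R0)/M) and sqrt(-E''(R_ddag)/M); ``Eb`` is the barrier height
    E(R_ddag) - E(R0).  ``mu0_prime`` and ``mu_ddag_prime`` are the dipole
    slopes at the reactant minimum and at the dividing surface.
    """

    R0: float
    R_ddag: float
    Eb: float
    omega0: float
    omega_b: float
    mu0_prime: float
    mu_ddag_prime: float


def _fd_second_derivative(f: Callable, x: float, h: float) -> float:
    """5-point central finite-difference second derivative."""
    return (
        -f(x - 2 * h) + 16 * f(x - h) - 30 * f(x) + 16 * f(x + h) - f(x + 2 * h)
    ) / (12 * h * h)


def stationary_points(model: PotentialModel, *, fd_check_tol: float = 0.01) -> StationaryPoints:
    """Locate the reactant minimum and barrier of a double-well model.

    The stationary points are roots of the analytic derivative of the cubic
    interpolant; the reactant minimum is the lower-energy of the two minima
    flanking the intervening maximum.  Curvatures come from the interpolant's
    second derivative, cross-checked against a 5-point finite difference
    (disagreement above ``fd_check_tol`` relative emits a warning).

    Raises ``ValueError`` for single-well potentials.
    """
    d1 = model._E_spline.derivative()
    crit = d1.roots(extrapolate=False)
    crit = np.unique(crit[(crit > model.R_min) & (crit < model.R_max)])
    if crit.size == 0:
        raise ValueError("no stationary points found")
    curv = model.energy_d2(crit)
    minima = crit[curv > 0]
    maxima = crit[curv < 0]
    if minima.size < 2 or maxima.size < 1:
        raise ValueError(
            "no barrier: potential must have two minima separated by a maximum"
        )
    # choose the barrier as the maximum lying between a pair of minima,
    # taking the highest such maximum if the surface has extra wiggles
    best = None
    for Rb in maxima:
        left = minima[minima < Rb]
        right = minima[minima > Rb]
        if left.size and right.size:
            Rl = left[np.argmin(model.energy(left))]
            Rr = right[np.argmin(model.energy(right))]
            cand = (Rb, Rl, Rr)
            if best is None or model.energy(Rb) > model.energy(best[0]):
                best = cand
    if best is None:
        raise ValueError("no maximum lies between two minima")
    R_ddag, Rl, Rr = best
    R0 = Rl if model.energy(Rl) <= model.energy(Rr) else Rr
    Eb = float(model.energy(R_ddag) - model.energy(R0))
    if Eb <= 0:
        raise ValueError("non-positive barrier height")
    e2_min = float(model.energy_d2(R0))
    e2_bar = float(model.energy_d2(R_ddag))
    if e2_bar >= 0:
        raise ValueError("second derivative at the barrier must be negative")
    h = 2.0 * float(np.mean(np.diff(model.R)))
    for x, e2 in ((R0, e2_min), (R_ddag, e2_bar)):
        if x - 2 * h > model.R_min and x + 2 * h < model.R_max:
            fd = _fd_second_derivative(model.energy, x, h)
            if abs(fd - e2) > fd_check_tol * abs(e2):
                warnings.warn(
                    f"spline and finite-difference curvatures disagree by "
                    f"{abs(fd - e2) / abs(e2):.1%} at R={x:.4f}",
                    stacklevel=2,
                )
    omega0 = float(np.sqrt(e2_min / model.mass))
    omega_b = float(np.sqrt(-e2_bar / model.mass))
    return StationaryPoints(
        R0=float(R0),
        R_ddag=float(R_ddag),
        Eb=Eb,
        omega0=omega0,
        omega_b=omega_b,
        mu0_prime=float(model.dipole_d1(R0)),
        mu_ddag_prime=float(model.dipole_d1(R_ddag)),
    )


def center_at_barrier(model: PotentialModel) -> PotentialModel:
    """Return a copy of ``model`` translated so the barrier sits at R = 0."""
    sp = stationary_points(model)
    return model.shifted(-sp.R_ddag)
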