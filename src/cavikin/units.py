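"""Hartree atomic units and the conversion registry.

Everything inside the package is in Hartree atomic units (hbar = m_e = e = 1).
Presentation-layer conversions (eV, meV, cm^-1, kJ/mol, fs, K) all go through
the single registry in this module so they compose exactly.
"""

from __future__ import annotations

from scipy import constants as _const

# --- fundamental conversion factors (CODATA via scipy.constants) ---------

#: Hartree energy in eV.
HARTREE_EV: float = _const.physical_constants["Hartree energy in eV"][0]
#: Hartree energy in meV.
HARTREE_MEV: float = HARTREE_EV * 1e3
#: Hartree energy in J.
HARTREE_J: float = _const.physical_constants["Hartree energy"][0]
#: Hartree energy expressed as a wavenumber (cm^-1).
HARTREE_CM1: float = (
    _const.physical_constants["hartree-inverse meter relationship"][0] / 100.0
)
#: Hartree energy in kJ/mol.
HARTREE_KJMOL: float = HARTREE_J * _const.Avogadro / 1e3
#: Boltzmann constant in Hartree / K.
KB_HA: float = _const.k / HARTREE_J
#: Atomic unit of time in fs.
AU_TIME_FS: float = _const.physical_constants["atomic unit of time"][0] * 1e15
#: Proton mass in electron masses (atomic units of mass).
PROTON_MASS_AU: float = _const.m_p / _const.m_e
#: Speed of light in atomic units (1 / fine-structure constant).
C_AU: float = 1.0 / _const.fine_structure

# registry: factor such that (value in unit) = (value in Hartree) * factor
_ENERGY_TO = {
    "hartree": 1.0,
    "au": 1.0,
    "ev": HARTREE_EV,
    "mev": HARTREE_MEV,
    "cm-1": HARTREE_CM1,
    "kj/mol": HARTREE_KJMOL,
}

_TIME_TO = {
    "au": 1.0,
    "fs": AU_TIME_FS,
    "ps": AU_TIME_FS * 1e-3,
}


def energy(value: float, frm: str, to: str = "hartree") -> float:
    """Convert an energy between registry units (case-insensitive names)."""
    f, t = frm.lower(), to.lower()
    if f not in _ENERGY_TO or t not in _ENERGY_TO:
        raise KeyError(f"unknown energy unit in conversion {frm!r} -> {to!r}")
    return value / _ENERGY_TO[f] * _ENERGY_TO[t]


def time(value: float, frm: str, to: str = "au") -> float:
    """Convert a time between registry units."""
    f, t = frm.lower(), to.lower()
    if f not in _TIME_TO or t not in _TIME_TO:
        raise KeyError(f"unknown time unit in conversion {frm!r} -> {to!r}")
    return value / _TIME_TO[f] * _TIME_TO[t]


def wavenumber_to_angular_frequency(value_cm1: float) -> float:
    """Angular frequency (a.u.) equivalent of a wavenumber in cm^-1.

    In atomic units an energy in Hartree and the corresponding angular
    frequency are numerically equal (hbar = 1), so this is the cm^-1 ->
    Hartree energy conversion.
    """
    return energy(value_cm1, "cm-1", "hartree")


def thermal_beta(temperature_K: float) -> float:
    """Inverse temperature beta = 1/(kB T) in 1/Hartree."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return 1.0 / (KB_HA * temperature_K)
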