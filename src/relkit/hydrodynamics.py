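"""Closed-form hydrodynamic calculations: Svedberg molar mass and f/f0.

Bundled data make the computation self-contained: Cohn-Edsall style
residue partial specific volumes for computing vbar from amino-acid
composition, and additive density increments for common buffer components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

R_GAS = 8.314462618          # J / (mol K)
N_AVOGADRO = 6.02214076e23   # 1 / mol
SVEDBERG = 1e-13             # s
WATER20_DENSITY = 0.998203   # g/mL at 20 C
WATER20_VISCOSITY = 1.002e-3  # Pa s at 20 C

#: Residue partial specific volumes (mL/g), Cohn-Edsall style.
RESIDUE_VBAR = {
    "A": 0.74, "R": 0.70, "N": 0.62, "D": 0.60, "C": 0.63,
    "Q": 0.67, "E": 0.66, "G": 0.64, "H": 0.67, "I": 0.90,
    "L": 0.90, "K": 0.82, "M": 0.75, "F": 0.77, "P": 0.76,
    "S": 0.63, "T": 0.70, "W": 0.74, "Y": 0.71, "V": 0.86,
}

#: Monoisotopic-free average residue masses (Da, water already removed).
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "Q": 128.1307, "E": 129.1155, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: Reference amino-acid composition (frequencies from a large protein-db
#: average); used when the exact sequence is unavailable.
REFERENCE_COMPOSITION = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0672, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0661, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0687,
}

#: Solution density increments at 20 C, g/mL per mol/L of solute
#: (molar mass minus apparent molar volume x water density, over 1000;
#: apparent molar volumes taken near the working concentrations).
DENSITY_INCREMENTS = {
    "tris": 0.0320,
    "nacl": 0.0400,
    "mgcl2": 0.0807,
    "edta": 0.1520,
    "kcl": 0.0455,
}

GLYCEROL_DENSITY = 1.261  # g/mL


@dataclass
class HydroSample:
    s: float       # sedimentation coefficient in Svedberg units
    D: float       # diffusion coefficient in um^2/s
    T: float       # K
    vbar: float    # mL/g
    rho: float     # g/mL
    eta: float = WATER20_VISCOSITY  # Pa s

    def __post_init__(self) -> None:
        for name in ("s", "D", "T", "vbar", "rho", "eta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def vbar_from_composition(composition: dict[str, float] | str) -> float:
    """Partial specific volume (mL/g) from residue composition.

    ``composition`` is either a residue string or a mapping residue ->
    count/frequency.  Weight-averaged over residue masses.
    """
    if isinstance(composition, str):
        counts: dict[str, float] = {}
        for ch in composition.upper():
            if ch in RESIDUE_VBAR:
                counts[ch] = counts.get(ch, 0) + 1
        composition = counts
    num = 0.0
    den = 0.0
    for res, cnt in composition.items():
        if res not in RESIDUE_VBAR:
            continue
        w = cnt * RESIDUE_MASS[res]
        num += w * RESIDUE_VBAR[res]
        den += w
    if den == 0:
        raise ValueError("empty composition")
    return num / den


def vbar_at_temperature(vbar25: float, T: float = 293.15) -> float:
    """Temperature-correct a 25 C partial specific volume (mL/g)."""
    return vbar25 + 4.25e-4 * (T - 298.15)


def buffer_density(molar: dict[str, float] | None = None,
                   glycerol_pct_v: float = 0.0,
                   base: float = WATER20_DENSITY) -> float:
    """Solution density (g/mL) from additive component increments.

    ``molar`` maps component name (see DENSITY_INCREMENTS) to mol/L;
    ``glycerol_pct_v`` is percent volume/volume glycerol.
    """
    rho = base
    for comp, conc in (molar or {}).items():
        key = comp.lower()
        if key not in DENSITY_INCREMENTS:
            raise KeyError(f"no density increment for {comp!r}")
        rho += DENSITY_INCREMENTS[key] * conc
    rho += glycerol_pct_v / 100.0 * (GLYCEROL_DENSITY - WATER20_DENSITY)
    return rho


def svedberg_mass(sample: HydroSample) -> float:
    """Molar mass (g/mol) via M = R T s / ((1 - vbar rho) D)."""
    buoyancy = 1.0 - sample.vbar * sample.rho
    if buoyancy <= 0:
        raise ValueError("vbar * rho >= 1: species does not sediment")
    s_si = sample.s * SVEDBERG            # s
    d_si = sample.D * 1e-12               # m^2/s
    m_kg = R_GAS * sample.T * s_si / (buoyancy * d_si)  # kg/mol
    return m_kg * 1e3


def sedimentation_coefficient(M: float, D: float, T: float, vbar: float,
                              rho: float) -> float:
    """Inverse of :func:`svedberg_mass`; returns s in Svedberg units."""
    s_si = (M / 1e3) * (1.0 - vbar * rho) * (D * 1e-12) / (R_GAS * T)
    return s_si / SVEDBERG


def frictional_ratio(M: float, s20w: float, vbar: float,
                     rho_w: float = WATER20_DENSITY,
                     eta_w: float = WATER20_VISCOSITY) -> float:
    """f/f0 from molar mass (g/mol), s20,w (Svedberg) and vbar (mL/g).

    f is the measured frictional coefficient from the Svedberg relation;
    f0 the Stokes coefficient of the anhydrous sphere of equal mass and
    vbar, in water at 20 C.
    """
    if min(M, s20w, vbar) <= 0:
        raise ValueError("inputs must be positive")
    m_kg = M / 1e3
    vbar_si = vbar * 1e-3          # m^3/kg
    rho_si = rho_w * 1e3           # kg/m^3
    f = m_kg * (1.0 - vbar_si * rho_si) / (N_AVOGADRO * s20w * SVEDBERG)
    r0 = (3.0 * m_kg * vbar_si / (4.0 * np.pi * N_AVOGADRO)) ** (1.0 / 3.0)
    f0 = 6.0 * np.pi * eta_w * r0
    return f / f0


def assay_buffer_density() -> float:
    """Density of the sedimentation assay buffer
    (20 mM Tris, 500 mM NaCl, 10 mM MgCl2, 1 mM EDTA, 1 % glycerol)."""
    return buffer_density(
        {"tris": 0.020, "nacl": 0.500, "mgcl2": 0.010, "edta": 0.001},
        glycerol_pct_v=1.0)
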