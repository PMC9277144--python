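"""Concentration unit handling.

The internal canonical unit throughout the package is mg/L; millimolar
values are accepted and produced only at I/O boundaries.  Conversions use
the molar mass of the dissolved anion (sulfate as SO4^2-, sulfide as HS-,
the organic acids as their conjugate bases), which is the basis on which
1.0 g/L sulfate corresponds to ~10.4 mM.
"""

from __future__ import annotations

from typing import Mapping

#: Anion molar masses, g/mol.
MOLAR_MASS_G_MOL: Mapping[str, float] = {
    "sulfate": 96.06,
    "lactate": 89.07,
    "propionate": 73.07,
    "acetate": 59.04,
    "citrate": 189.10,
    "sulfide": 33.07,  # as HS-
}

#: Analytes the observation schema accepts.
ANALYTES = tuple(MOLAR_MASS_G_MOL)


def molar_mass(analyte: str) -> float:
    """Anion molar mass in g/mol for a known analyte."""
    try:
        return MOLAR_MASS_G_MOL[analyte]
    except KeyError:
        raise KeyError(
            f"unknown analyte {analyte!r}; expected one of {sorted(MOLAR_MASS_G_MOL)}"
        ) from None


def mm_to_mg_per_l(value_mm: float, analyte: str) -> float:
    """Convert millimolar to mg/L."""
    return value_mm * molar_mass(analyte)


def mg_per_l_to_mm(value_mg_l: float, analyte: str) -> float:
    """Convert mg/L to millimolar."""
    return value_mg_l / molar_mass(analyte)
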