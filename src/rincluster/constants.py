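"""Physical constants and element tables shared across the package.

All distances are in Å, energies in kcal mol⁻¹ unless stated otherwise.
The van der Waals radii are the Bondi (1964) element-wise set, which is the
single published table bundled with the package; the covalent radii are the
Cordero et al. (2008) single-bond values used only for bond perception.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA-2018 constants, frozen in one place.

    kB and h are in SI units; R is in kcal mol⁻¹ K⁻¹ so that Eyring
    barriers come out directly in kcal mol⁻¹.
    """

    kB: float = 1.380649e-23          # J K⁻¹
    h: float = 6.62607015e-34         # J s
    R: float = 8.31446261815324 / 4184.0  # kcal mol⁻¹ K⁻¹
    hartree_to_kcal: float = 627.5094740631


CONSTANTS = PhysicalConstants()

# Bondi vdW radii, Å.  H uses the Rowland & Taylor revision (1.10) common in
# contact-dot work; elements absent from the table fall back to 1.70.
VDW_RADII: dict[str, float] = {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "Cl": 1.75,
    "Br": 1.85,
}
VDW_DEFAULT = 1.70

# Cordero single-bond covalent radii, Å (bond perception only).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "P": 1.07,
}
COVALENT_DEFAULT = 0.77

# Scale factor applied to the covalent-radius sum when deciding whether two
# atoms are bonded.  1.3 accepts slightly stretched bonds while excluding
# van der Waals contacts (shortest heavy-atom nonbonded approach ~2.4 Å).
BOND_TOLERANCE = 1.3

# Idealized X–H bond lengths, Å, used for added hydrogens and caps.
XH_BOND_LENGTHS: dict[str, float] = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}
XH_DEFAULT = 1.09


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.capitalize(), VDW_DEFAULT)


def covalent_radius(element: str) -> float:
    return COVALENT_RADII.get(element.capitalize(), COVALENT_DEFAULT)


def xh_length(element: str) -> float:
    return XH_BOND_LENGTHS.get(element.capitalize(), XH_DEFAULT)
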