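"""Physical constants and scattering-length tables.

Bound coherent neutron scattering lengths are the Sears (1992) values, in fm
(1 fm = 1e-5 Å).  Deuterium is tabulated under its own symbol ``"D"``.  These
tables are the single source of truth for every neutron computation in the
package; X-ray scattering amplitudes are carried as electron counts (point
scatterers), adequate for the q < ~0.5 Å⁻¹ range of solution scattering.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23

# Sears bound coherent scattering lengths, fm
NEUTRON_B: dict[str, float] = {
    "H": -3.7390,
    "D": 6.671,
    "C": 6.6460,
    "N": 9.36,
    "O": 5.803,
    "Na": 3.63,
    "Mg": 5.375,
    "P": 5.13,
    "S": 2.847,
    "Cl": 9.5770,
    "K": 3.67,
    "Ca": 4.70,
    "Fe": 9.45,
    "Se": 7.970,
    "Zn": 5.680,
}

ATOMIC_NUMBER: dict[str, int] = {
    "H": 1, "D": 1, "C": 6, "N": 7, "O": 8, "Na": 11, "Mg": 12, "P": 15,
    "S": 16, "Cl": 17, "K": 19, "Ca": 20, "Fe": 26, "Se": 34, "Zn": 30,
}

B_H = NEUTRON_B["H"]
B_D = NEUTRON_B["D"]
B_C = NEUTRON_B["C"]
B_O = NEUTRON_B["O"]

# --- solvent -----------------------------------------------------------------
# mass densities at 20 °C, g/cm³; molar masses, g/mol
H2O_DENSITY = 0.9982
D2O_DENSITY = 1.1044
H2O_MOLAR_MASS = 18.015
D2O_MOLAR_MASS = 20.028
# NaCl apparent molar volume in water, cm³/mol (mid-range value for 0-5 M)
NACL_MOLAR_VOLUME = 20.0
NACL_ELECTRONS = 28
NACL_B = NEUTRON_B["Na"] + NEUTRON_B["Cl"]

# --- DDM (n-dodecyl-β-D-maltopyranoside) -------------------------------------
# The detergent is represented by two pseudo-atom species carrying fixed
# electron-count fractions of the tail (C12H25, 97 e) and head (C12H21O11,
# 181 e): a CH3-like 9-electron tail pseudo-atom and an NH3-like 10-electron
# head pseudo-atom.  The maltoside head has 7 hydroxyl hydrogens that exchange
# with solvent deuterium.
DDM_TAIL_FORMULA: dict[str, int] = {"C": 12, "H": 25}
DDM_HEAD_FORMULA: dict[str, int] = {"C": 12, "H": 21, "O": 11}
DDM_TAIL_ELECTRONS = 97
DDM_HEAD_ELECTRONS = 181
DDM_HEAD_EXCHANGEABLE_H = 7
TAIL_PSEUDO_ELECTRONS = 9
HEAD_PSEUDO_ELECTRONS = 10
# molecular volumes of the two moieties, Å³ (detergent volumetry; reproduce
# the belt SLDs −0.388e-6 / 3.92e-6 Å⁻² at full head deuteration)
DDM_TAIL_VOLUME = 354.0
DDM_HEAD_VOLUME = 352.0

# --- average protein residue -------------------------------------------------
# Composition-averaged amino-acid residue for coarse one-bead-per-residue toy
# models (no sequence needed): formula, displaced volume, labile H count.
AVG_RESIDUE_FORMULA: dict[str, float] = {
    "C": 4.86, "H": 7.57, "N": 1.36, "O": 1.48, "S": 0.042,
}
AVG_RESIDUE_VOLUME = 135.0          # Å³
AVG_RESIDUE_EXCHANGEABLE_H = 1.8    # backbone NH + average side-chain OH/NH


def formula_electrons(formula: dict[str, float]) -> float:
    """Total electron count of a chemical formula."""
    try:
        return float(sum(ATOMIC_NUMBER[el] * n for el, n in formula.items()))
    except KeyError as exc:
        raise KeyError(f"unknown element symbol {exc.args[0]!r}") from None


def formula_neutron_b(formula: dict[str, float]) -> float:
    """Total bound coherent scattering length of a formula, fm."""
    try:
        return float(sum(NEUTRON_B[el] * n for el, n in formula.items()))
    except KeyError as exc:
        raise KeyError(f"unknown element symbol {exc.args[0]!r}") from None


AVG_RESIDUE_ELECTRONS = formula_electrons(AVG_RESIDUE_FORMULA)
AVG_RESIDUE_B = formula_neutron_b(AVG_RESIDUE_FORMULA)
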