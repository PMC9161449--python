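"""Physical constants and monosaccharide building-block masses.

All masses are monoisotopic, in daltons. Building-block masses are residue
masses (the mass added to a peptide or glycan chain on condensation), derived
from the atomic monoisotopic masses of the neutral monosaccharide minus water.
"""

from __future__ import annotations

#: Gas constant in kcal·mol⁻¹·K⁻¹.
R_KCAL: float = 1.9872e-3

#: Standard laboratory temperature (25 °C) in kelvin.
T_STANDARD_K: float = 298.15

#: Proton mass used for ESI charge-state arithmetic (Da).
PROTON_MASS: float = 1.0072765

#: Mass of water (Da), added once per free peptide/glycan.
WATER_MASS: float = 18.010565

#: Asn→Asp deamidation mass shift left by PNGase F de-glycosylation (Da).
DEAMIDATION_SHIFT: float = 0.98402

#: Monoisotopic residue masses of the glycan building blocks used in
#: compositional assignment. ``Phospho`` is the HPO3 adduct.
BLOCK_MASSES: dict[str, float] = {
    "Hex": 162.05282,
    "HexNAc": 203.07937,
    "dHex": 146.05791,
    "NeuAc": 291.09542,
    "Phospho": 79.96633,
}

#: Canonical ordering of building blocks for composition vectors and labels.
BLOCK_ORDER: tuple[str, ...] = ("Hex", "HexNAc", "dHex", "NeuAc", "Phospho")

#: Default count bounds per building block for the bounded mass decomposition.
#: These reflect N-glycan biology (up to tetra-antennary, core fucose,
#: sialylation, mannose-6-phosphate) and are configurable.
DEFAULT_BLOCK_BOUNDS: dict[str, int] = {
    "Hex": 9,
    "HexNAc": 7,
    "dHex": 2,
    "NeuAc": 4,
    "Phospho": 2,
}

#: Default enzyme molar mass (g/mol) used to convert Vmax (per mg of enzyme)
#: to kcat (per mole). FUT8 constructs in this size range are ~58 kg/mol;
#: override per experiment.
DEFAULT_ENZYME_MOLAR_MASS: float = 58000.0
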