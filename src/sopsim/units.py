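"""Unit conventions shared package-wide.

Energies are kcal/mol, lengths Å, times ps. Forces are computed in
kcal/(mol·Å) internally and converted to pN wherever they are reported.
"""

#: 1 kcal/(mol·Å) expressed in pN.
KCAL_PER_MOL_ANG_IN_PN = 69.479

#: Thermal energy at ~300 K, kcal/mol.
DEFAULT_KBT = 0.6


def force_to_pn(f_kcal_mol_ang: float) -> float:
    """Convert a force from kcal/(mol·Å) to pN."""
    return f_kcal_mol_ang * KCAL_PER_MOL_ANG_IN_PN


def force_from_pn(f_pn: float) -> float:
    """Convert a force from pN to kcal/(mol·Å)."""
    return f_pn / KCAL_PER_MOL_ANG_IN_PN
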