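"""Monoisotopic masses of the bicyclic thioether peptide and its macrolactam.

Computes the elemental formulas and [M+H]+ values of a bicyclic
Ile3-S-deoxo-amaninamide-type peptide (head-to-tail octapeptide with a
thioether bridge, -H2) and of the macrolactam obtained by desulfurization
(Cys -> Ala), and checks the formula identity bicycle - S + 2H = monocycle.
"""

from ansamer.masses import (
    ElementalFormula,
    ResidueComposition,
    formula_from_residues,
    monoisotopic_mass,
    mz_protonated,
)

bicycle = ResidueComposition(
    residues=("Asn", "Hyp", "Ile", "Trp", "Gly", "Ile", "Gly", "Cys"),
    cyclization="head-to-tail",
    modifications=("thioether_bridge",),
)
monocycle = ResidueComposition(
    residues=("Asn", "Hyp", "Ile", "Trp", "Gly", "Ile", "Gly", "Ala"),
    cyclization="head-to-tail",
)

def hill(formula):
    return "".join(
        f"{el}{formula[el] if formula[el] != 1 else ''}"
        for el in sorted(formula, key=lambda e: (e != "C", e != "H", e))
    )

f_bi = formula_from_residues(bicycle)
f_mono = formula_from_residues(monocycle)
print(f"bicycle   {hill(f_bi)}:  M = {monoisotopic_mass(f_bi):.4f} Da,  "
      f"[M+H]+ = {mz_protonated(f_bi):.4f}")
print(f"monocycle {hill(f_mono)}:  M = {monoisotopic_mass(f_mono):.4f} Da,  "
      f"[M+H]+ = {mz_protonated(f_mono):.4f}")

identity = f_bi - ElementalFormula(S=1) + ElementalFormula(H=2) == f_mono
print(f"bicycle - S + 2H == monocycle: {identity}")

# The desulfurization identity mirrors the Raney-nickel chemistry that turns
# the thioether bicycle into the Cys->Ala macrolactam; it must hold exactly
# at the formula level, not merely to mass precision.
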