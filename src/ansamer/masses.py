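"""Elemental-formula bookkeeping and monoisotopic masses for cyclic peptides.

Residue compositions (the 20 canonical residues plus the modified residues
Hyp, DHIle and OHTrp found in amatoxins) are summed to an elemental
formula; head-to-tail cyclization adds nothing, a linear peptide adds one
water.  Named modification deltas cover the amatoxin chemistry: the
tryptathionine thioether bridge removes H2, sulfoxidation and hydroxylation
each add O, and Raney-nickel desulfurization removes the bridge sulfur
(with the Cys -> Ala change expressed as a residue substitution).

Isotope masses come from the IUPAC table shipped with pyteomics; [M+zH]z+
uses the proton mass 1.007276 Da (not the hydrogen atom mass), per HRMS
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _pt_mass
from pyteomics.auxiliary import PyteomicsError

from .errors import MassError

__all__ = [
    "PROTON_MASS",
    "RESIDUE_FORMULAS",
    "MODIFICATIONS",
    "ElementalFormula",
    "ResidueComposition",
    "parse_formula",
    "formula_from_residues",
    "monoisotopic_mass",
    "mz_protonated",
]

PROTON_MASS = 1.007276

#: element -> count; pyteomics Composition supports +/- arithmetic.
ElementalFormula = _pt_mass.Composition

_ONE_LETTER = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

#: residue name -> elemental formula of the residue (dehydrated) unit.
RESIDUE_FORMULAS: dict[str, ElementalFormula] = {
    name: ElementalFormula(_pt_mass.std_aa_comp[letter])
    for name, letter in _ONE_LETTER.items()
}
# Modified residues of the amatoxin scaffold.
RESIDUE_FORMULAS["Hyp"] = RESIDUE_FORMULAS["Pro"] + ElementalFormula(O=1)
RESIDUE_FORMULAS["DHIle"] = RESIDUE_FORMULAS["Ile"] + ElementalFormula(O=2)
RESIDUE_FORMULAS["OHTrp"] = RESIDUE_FORMULAS["Trp"] + ElementalFormula(O=1)

WATER = ElementalFormula(H=2, O=1)

#: built-in modification deltas (applied to the summed residue formula).
MODIFICATIONS: dict[str, ElementalFormula] = {
    "thioether_bridge": ElementalFormula(H=-2),
    "sulfoxide": ElementalFormula(O=1),
    "hydroxylation": ElementalFormula(O=1),
    "desulfurization": ElementalFormula(S=-1),
}


@dataclass
class ResidueComposition:
    """Residue sequence, cyclization mode and modification list.

    ``modifications`` entries are either names of built-in deltas or
    ``(name, {element: count})`` pairs for ad-hoc deltas.
    """

    residues: tuple
    cyclization: str = "linear"  # or "head-to-tail"
    modifications: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.residues = tuple(self.residues)
        self.modifications = tuple(self.modifications)
        if self.cyclization not in ("linear", "head-to-tail"):
            raise MassError(f"unknown cyclization {self.cyclization!r}")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation formula string such as ``C39H56N10O10``."""
    try:
        comp = ElementalFormula(formula=text)
    except PyteomicsError as exc:
        raise MassError(f"cannot parse formula {text!r}: {exc}") from None
    _check_elements(comp)
    return comp


def _check_elements(formula: ElementalFormula) -> None:
    for element, count in formula.items():
        if element not in _pt_mass.nist_mass:
            raise MassError(f"unknown element {element!r}")
        if count < 0:
            raise MassError(f"negative count for element {element!r}")


def formula_from_residues(composition: ResidueComposition) -> ElementalFormula:
    """Elemental formula of a peptide from its residue composition.

    Residue units are summed; a linear peptide gains H2O, a head-to-tail
    cycle gains nothing; modification deltas are then applied.
    """
    total = ElementalFormula()
    for residue in composition.residues:
        try:
            total += RESIDUE_FORMULAS[residue]
        except KeyError:
            raise MassError(f"unknown residue {residue!r}") from None
    if composition.cyclization == "linear":
        total += WATER
    for mod in composition.modifications:
        if isinstance(mod, str):
            try:
                delta = MODIFICATIONS[mod]
            except KeyError:
                raise MassError(f"unknown modification {mod!r}") from None
        else:
            _name, raw = mod
            delta = ElementalFormula(**dict(raw))
        total += delta
    total = ElementalFormula({k: v for k, v in total.items() if v != 0})
    _check_elements(total)
    return total


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass in Da: sum of most-abundant-isotope masses."""
    _check_elements(formula)
    return float(
        sum(
            count * _pt_mass.nist_mass[element][0][0]
            for element, count in formula.items()
        )
    )


def mz_protonated(formula: ElementalFormula, z: int = 1) -> float:
    """m/z of the [M+zH]z+ ion."""
    if z < 1:
        raise MassError(f"charge must be >= 1, got {z}")
    return (monoisotopic_mass(formula) + z * PROTON_MASS) / z
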