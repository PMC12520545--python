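"""Monoisotopic mass chemistry for (seleno)peptides.

Masses for elements and residues are taken from pyteomics' NIST tables and
exposed through :class:`ResidueTable`. Selenocysteine (``U``) is a
first-class residue: its mass differs from cysteine by exactly the Se-S
monoisotopic element difference (+47.944451 Da), which is the mass shift
exploited by the Cys-to-Sec proxy transform.

Built-in modifications cover the SecMS labeling chemistry:

* ``CAM``            carbamidomethyl (iodoacetic-acid/IAA alkylation), C/U, +57.021464
* ``IodoAPB-CAM``    biotin-labeled carbamidomethyl adduct of the IodoAPB
                     probe, C/U, +414.193691
* ``deSe``           deselenization of Sec, -81.932170
* ``Oxidation``      Met oxidation, +15.994915
* ``Acetyl``         protein N-terminal acetylation, +42.010565
"""

from __future__ import annotations

from typing import Mapping, Optional

import yaml
from pyteomics import mass as _ptmass

from .entities import Modification, Peptide, PrecursorIon

__all__ = [
    "ResidueTable",
    "DEFAULT_TABLE",
    "BUILTIN_MODIFICATIONS",
    "composition_mass",
    "peptide_neutral_mass",
    "fragment_mz",
    "precursor_mz",
    "sec_cys_delta",
    "make_modification",
    "load_modifications",
    "get_modification",
]

_CANONICAL = "ACDEFGHIKLMNPQRSTVWY"


class ResidueTable:
    """Monoisotopic element and residue masses plus the proton/water constants.

    Residues are the 20 canonical amino acids plus ``U`` (Sec). Anything
    else (B, J, O, X, Z, ...) is rejected by mass computations.
    """

    def __init__(self) -> None:
        self.element_mass: dict[str, float] = {
            el: data[0][0] for el, data in _ptmass.nist_mass.items()
        }
        self.residue_mass: dict[str, float] = {
            aa: _ptmass.std_aa_mass[aa] for aa in _CANONICAL
        }
        # Sec = Cys - S + Se, exactly, so the proxy shift is self-consistent.
        self.residue_mass["U"] = (
            self.residue_mass["C"]
            - self.element_mass["S"]
            + self.element_mass["Se"]
        )
        self.proton: float = _ptmass.nist_mass["H+"][0][0]
        self.water: float = _ptmass.calculate_mass(formula="H2O")

    def element(self, symbol: str) -> float:
        try:
            return self.element_mass[symbol]
        except KeyError:
            raise KeyError(f"unknown element symbol {symbol!r}") from None

    def residue(self, letter: str) -> float:
        try:
            return self.residue_mass[letter]
        except KeyError:
            raise KeyError(
                f"unknown or non-canonical residue {letter!r} "
                "(allowed: 20 canonical amino acids + U)"
            ) from None


DEFAULT_TABLE = ResidueTable()


def composition_mass(
    composition: Mapping[str, int], table: ResidueTable = DEFAULT_TABLE
) -> float:
    """Monoisotopic mass of a signed elemental composition, in Da."""
    return sum(count * table.element(sym) for sym, count in composition.items())


def sec_cys_delta(table: ResidueTable = DEFAULT_TABLE) -> float:
    """Mass added by one Cys -> Sec substitution (Se - S), +47.944451 Da."""
    return table.element("Se") - table.element("S")


def make_modification(
    name: str,
    targets,
    composition: Mapping[str, int],
    neutral_loss: bool = False,
    table: ResidueTable = DEFAULT_TABLE,
) -> Modification:
    return Modification(
        name=name,
        targets=frozenset(targets),
        composition=tuple(sorted(composition.items())),
        delta=composition_mass(composition, table),
        neutral_loss=neutral_loss,
    )


BUILTIN_MODIFICATIONS: dict[str, Modification] = {
    m.name: m
    for m in [
        make_modification("CAM", {"C", "U"}, {"C": 2, "H": 3, "N": 1, "O": 1}),
        make_modification(
            "IodoAPB-CAM", {"C", "U"}, {"C": 18, "H": 30, "N": 4, "O": 5, "S": 1}
        ),
        make_modification("deSe", {"U"}, {"H": -2, "Se": -1}),
        make_modification("Oxidation", {"M"}, {"O": 1}),
        make_modification("Acetyl", {"N-term"}, {"C": 2, "H": 2, "O": 1}),
    ]
}


def get_modification(name: str) -> Modification:
    try:
        return BUILTIN_MODIFICATIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown modification {name!r}; built-ins: "
            f"{sorted(BUILTIN_MODIFICATIONS)}"
        ) from None


def load_modifications(path, table: ResidueTable = DEFAULT_TABLE) -> dict[str, Modification]:
    """Load a modification registry from a YAML file and merge with built-ins.

    Schema: a list of ``{name, targets: [..], composition: {El: count},
    neutral_loss: bool}`` entries. User entries override built-ins by name.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    registry = dict(BUILTIN_MODIFICATIONS)
    for item in raw:
        mod = make_modification(
            item["name"],
            item["targets"],
            item["composition"],
            bool(item.get("neutral_loss", False)),
            table,
        )
        registry[mod.name] = mod
    return registry


def _residue_masses(peptide: Peptide, table: ResidueTable) -> list[float]:
    if not peptide.sequence:
        raise ValueError("empty peptide sequence")
    masses = [table.residue(aa) for aa in peptide.sequence]
    for site, mod in peptide.modifications:
        # N-terminal mods ride on the first residue for fragment purposes.
        masses[max(site - 1, 0)] += mod.delta
    return masses


def peptide_neutral_mass(peptide: Peptide, table: ResidueTable = DEFAULT_TABLE) -> float:
    """Neutral monoisotopic mass: residues + water + modification deltas."""
    return sum(_residue_masses(peptide, table)) + table.water


def precursor_mz(
    peptide: Peptide, charge: int, table: ResidueTable = DEFAULT_TABLE
) -> float:
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (peptide_neutral_mass(peptide, table) + charge * table.proton) / charge


def make_precursor(
    peptide: Peptide, charge: int, table: ResidueTable = DEFAULT_TABLE
) -> PrecursorIon:
    return PrecursorIon(peptide, charge, precursor_mz(peptide, charge, table))


def fragment_mz(
    peptide: Peptide,
    ion_type: str,
    series_number: int,
    charge: int,
    table: ResidueTable = DEFAULT_TABLE,
) -> float:
    """m/z of a b or y fragment ion.

    b_k = (sum of the first k residue+mod masses + z protons) / z;
    y_k = (sum of the last k residue+mod masses + water + z protons) / z.
    Modifications belong to the fragment containing their site.
    """
    if ion_type not in ("b", "y"):
        raise ValueError(f"ion_type must be 'b' or 'y', got {ion_type!r}")
    if charge not in (1, 2):
        raise ValueError(f"fragment charge must be 1 or 2, got {charge}")
    n = len(peptide.sequence)
    if not 1 <= series_number <= n - 1:
        raise ValueError(
            f"series number {series_number} out of range 1..{n - 1} "
            f"for peptide {peptide.sequence!r}"
        )
    masses = _residue_masses(peptide, table)
    if ion_type == "b":
        neutral = sum(masses[:series_number])
    else:
        neutral = sum(masses[n - series_number:]) + table.water
    return (neutral + charge * table.proton) / charge


def fragment_ladder(
    peptide: Peptide,
    ion_types=("b", "y"),
    charges=(1, 2),
    table: ResidueTable = DEFAULT_TABLE,
) -> dict[tuple[str, int, int], float]:
    """All (ion_type, series_number, charge) -> m/z for a peptide."""
    n = len(peptide.sequence)
    out = {}
    for t in ion_types:
        for k in range(1, n):
            for z in charges:
                out[(t, k, z)] = fragment_mz(peptide, t, k, z, table)
    return out
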