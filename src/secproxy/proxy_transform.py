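"""The Cys-to-Sec proxy transform ("Cys-S+Se" conversion).

An experimental spectral library of labeled Cys peptides is rewritten into
a pseudo-Sec library: substituted Cys positions become ``U`` keeping their
modification, the precursor m/z shifts by k * (Se - S) / z for k
substituted sites, and each fragment m/z shifts by the number of
substituted sites it spans times (Se - S) / fragment charge. Fragment
intensities, retention time and ion mobility are carried over unchanged —
the proxy assumption, justified by the near-identity of these properties
between Cys- and Sec-substituted peptide twins.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Literal

from . import chem
from .entities import Fragment, LibraryEntry, SpectralLibrary

__all__ = ["cys_to_sec", "transform_library", "eligible_sites"]

Mode = Literal["all_labeled", "all"]

#: the label whose presence marks a Cys as a stand-in for Sec
SEC_MARKER_MOD = "IodoAPB-CAM"


def eligible_sites(entry: LibraryEntry, mode: Mode = "all_labeled") -> list[int]:
    """1-based Cys positions to substitute.

    ``all_labeled`` (default): only Cys carrying the IodoAPB-CAM probe
    adduct — the label that marks the Sec position in real SecMS data;
    CAM-only Cys stay Cys, mirroring real selenopeptides where non-Sec
    Cys are CAM-alkylated. ``all``: every Cys.
    """
    pep = entry.peptide
    sites = []
    for pos, aa in enumerate(pep.sequence, start=1):
        if aa != "C":
            continue
        if mode == "all":
            sites.append(pos)
        else:
            mod = pep.mod_at(pos)
            if mod is not None and mod.name == SEC_MARKER_MOD:
                sites.append(pos)
    return sites


def _fragment_span(ion_type: str, series_number: int, length: int) -> range:
    """1-based residue positions covered by a fragment."""
    if ion_type == "b":
        return range(1, series_number + 1)
    return range(length - series_number + 1, length + 1)


def cys_to_sec(entry: LibraryEntry, mode: Mode = "all_labeled") -> LibraryEntry:
    """Substitute Cys -> Sec in one library entry, adjusting parent and
    product ion masses and keeping intensities/RT/IM as training targets.

    Raises ``ValueError`` if the entry has no eligible Cys.
    """
    sites = eligible_sites(entry, mode)
    if not sites:
        raise ValueError(
            f"entry {entry.peptide.sequence!r} has no eligible Cys to substitute"
        )
    pep = entry.peptide
    delta = chem.sec_cys_delta()
    n = len(pep.sequence)
    seq = "".join(
        "U" if (i in sites) else aa for i, aa in enumerate(pep.sequence, start=1)
    )
    for pos in sites:
        mod = pep.mod_at(pos)
        if mod is not None and "U" not in mod.targets:
            raise ValueError(
                f"modification {mod.name!r} at substituted site {pos} "
                "does not target U; cannot transfer"
            )
    new_pep = pep.with_sequence(seq)

    new_frags = []
    for f in entry.fragments:
        span = _fragment_span(f.ion_type, f.series_number, n)
        k = sum(1 for s in sites if s in span)
        new_frags.append(
            Fragment(f.ion_type, f.series_number, f.charge,
                     f.mz + k * delta / f.charge, f.intensity)
        )
    return replace(
        entry,
        peptide=new_pep,
        precursor_mz=entry.precursor_mz + len(sites) * delta / entry.charge,
        fragments=tuple(new_frags),
        origin="pseudo_sec",
    )


def transform_library(
    lib: SpectralLibrary, mode: Mode = "all_labeled"
) -> SpectralLibrary:
    """Transform every eligible entry; ineligible entries are skipped and
    logged. Collisions (two entries mapping to the same modified sequence
    and charge) keep the higher-total-intensity entry.
    """
    out = SpectralLibrary(provenance=list(lib.provenance))
    by_key: dict = {}
    skipped = 0
    collisions = 0
    for entry in lib:
        if not eligible_sites(entry, mode):
            skipped += 1
            continue
        new = cys_to_sec(entry, mode)
        key = new.key
        if key in by_key:
            collisions += 1
            if new.total_intensity() <= by_key[key].total_intensity():
                continue
        by_key[key] = new
    out.entries = list(by_key.values())
    out.log(
        f"cys_to_sec[{mode}]: {len(lib)} in, {len(out)} out, "
        f"{skipped} skipped (no eligible Cys), {collisions} collisions"
    )
    return out
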