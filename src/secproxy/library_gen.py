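"""Assemble and serialize the final DIA spectral library.

``build_predicted_library`` runs the three predictors over enumerated Sec
precursors and applies the library filters (fragment charge 1-2, b/y ions,
minimum relative intensity, scan range, minimum fragment count);
``add_buffering`` attaches high-intensity experimental Cys precursors at a
configurable Cys:Sec ratio; the TSV dialect is the long-format,
one-row-per-fragment layout consumed by DIA-NN.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import pandas as pd

from . import chem
from .entities import Fragment, LibraryEntry, Modification, Peptide, PrecursorIon, SpectralLibrary
from .mobility import ccs_to_mobility

__all__ = [
    "HybridLibrarySpec",
    "PRESET_RATIOS",
    "parse_ratio",
    "build_predicted_library",
    "add_buffering",
    "write_library_tsv",
    "read_library_tsv",
    "LIBRARY_COLUMNS",
]

PRESET_RATIOS = ("1:10", "1:3", "1:2", "1:1.2", "1:1", "2:1")

LIBRARY_COLUMNS = [
    "ModifiedPeptide",
    "StrippedPeptide",
    "PrecursorCharge",
    "PrecursorMz",
    "Tr_recalibrated",
    "IonMobility",
    "ProteinId",
    "FragmentMz",
    "RelativeIntensity",
    "FragmentType",
    "FragmentCharge",
    "FragmentSeriesNumber",
    "FragmentLossType",
]


def parse_ratio(ratio) -> float:
    """Cys:Sec ratio as a float r = #buffering / #sec, e.g. "2:1" -> 2.0."""
    if isinstance(ratio, (int, float)):
        r = float(ratio)
    else:
        m = re.fullmatch(r"\s*([\d.]+)\s*:\s*([\d.]+)\s*", str(ratio))
        if not m:
            raise ValueError(f"cannot parse ratio {ratio!r}; expected 'a:b'")
        r = float(m.group(1)) / float(m.group(2))
    if r <= 0:
        raise ValueError(f"ratio must be positive, got {r}")
    return r


@dataclass(frozen=True)
class HybridLibrarySpec:
    ratio: str = "2:1"
    selection: str = "top_intensity"

    @property
    def r(self) -> float:
        return parse_ratio(self.ratio)


def build_predicted_library(
    ms2_model,
    rt_model,
    ccs_model,
    precursors: Sequence[PrecursorIon],
    min_rel_intensity: float = 0.01,
    mz_range: tuple[float, float] = (100.0, 1700.0),
    min_fragments: int = 4,
    fragment_charges: tuple[int, ...] = (1, 2),
    ion_types: tuple[str, ...] = ("b", "y"),
) -> SpectralLibrary:
    """One predicted entry per precursor: fragment m/z from the mass
    chemistry, intensities from the MS2 model, iRT from the RT model and
    ion mobility from the CCS model via the Mason-Schamp conversion.

    Fragments below ``min_rel_intensity`` (after max-normalization) or
    outside ``mz_range`` are dropped; entries with fewer than
    ``min_fragments`` surviving fragments are dropped and logged.
    """
    if ms2_model is None or rt_model is None or ccs_model is None:
        raise ValueError("all three models (ms2, rt, ccs) are required")
    precursors = list(precursors)
    lib = SpectralLibrary()
    if not precursors:
        lib.log("build_predicted_library: 0 precursors in")
        return lib
    intensity_maps = ms2_model.predict(precursors)
    irts = rt_model.predict([p.peptide for p in precursors])
    ccss = ccs_model.predict(precursors)
    dropped = 0
    for prec, frag_int, irt, ccs in zip(precursors, intensity_maps, irts, ccss):
        peak = max(frag_int.values(), default=0.0)
        frags = []
        for (ion_type, k, z), inten in sorted(frag_int.items()):
            if ion_type not in ion_types or z not in fragment_charges:
                continue
            rel = inten / peak if peak > 0 else 0.0
            if rel < min_rel_intensity:
                continue
            mz = chem.fragment_mz(prec.peptide, ion_type, k, z)
            if not mz_range[0] <= mz <= mz_range[1]:
                continue
            frags.append(Fragment(ion_type, k, z, mz, rel))
        if len(frags) < min_fragments:
            dropped += 1
            continue
        ccs_val = float(ccs)
        lib.add(
            LibraryEntry(
                peptide=prec.peptide,
                charge=prec.charge,
                precursor_mz=prec.mz,
                irt=float(irt),
                fragments=tuple(frags),
                ccs=ccs_val,
                ion_mobility=float(ccs_to_mobility(ccs_val, prec.mz, prec.charge)),
                origin="predicted",
            )
        )
    lib.log(
        f"build_predicted_library: {len(precursors)} precursors in, "
        f"{len(lib)} entries out, {dropped} dropped (<{min_fragments} fragments)"
    )
    if not lib.entries:
        warnings.warn("predicted library is empty after filtering", stacklevel=2)
    return lib


def _buffering_rank_key(entry: LibraryEntry):
    total = entry.total_intensity()
    score = total * entry.precursor_intensity if entry.precursor_intensity else total
    # descending score; ties by m/z ascending, then sequence lexicographic
    return (-score, entry.precursor_mz, entry.peptide.sequence)


def add_buffering(
    sec_lib: SpectralLibrary,
    cys_lib: SpectralLibrary,
    ratio="2:1",
) -> SpectralLibrary:
    """Merge the top ceil(r * #sec) highest-intensity Cys precursors into a
    Sec library as buffering peptides (origin flag ``buffering``)."""
    r = parse_ratio(ratio)
    n_needed = math.ceil(r * len(sec_lib))
    ranked = sorted(cys_lib.entries, key=_buffering_rank_key)
    if len(ranked) < n_needed:
        warnings.warn(
            f"buffering pool has {len(ranked)} precursors, need {n_needed}; taking all",
            stacklevel=2,
        )
        n_needed = len(ranked)
    out = SpectralLibrary(provenance=list(sec_lib.provenance))
    seen = set()
    for e in sec_lib:
        out.add(e)
        seen.add(e.key)
    n_added = 0
    for e in ranked:
        if n_added >= n_needed:
            break
        if e.key in seen:
            continue
        out.add(replace(e, origin="buffering"))
        seen.add(e.key)
        n_added += 1
    out.log(
        f"add_buffering: ratio={ratio}, {len(sec_lib)} sec + {n_added} buffering"
    )
    return out


def write_library_tsv(lib: SpectralLibrary, path, dialect: str = "diann") -> None:
    """Long-format TSV, one row per fragment, DIA-NN column set."""
    if dialect != "diann":
        raise ValueError(f"unsupported dialect {dialect!r}")
    rows = []
    for e in lib:
        modpep = e.peptide.modified_string()
        prot = ";".join(e.peptide.proteins)
        for f in e.fragments:
            rows.append(
                (
                    modpep,
                    e.peptide.sequence,
                    e.charge,
                    round(e.precursor_mz, 6),
                    round(e.irt, 6),
                    round(e.ion_mobility, 6) if e.ion_mobility is not None else "",
                    prot,
                    round(f.mz, 6),
                    round(f.intensity, 6),
                    f.ion_type,
                    f.charge,
                    f.series_number,
                    "noloss",
                )
            )
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(path, sep="\t", index=False)


_MOD_TOKEN = re.compile(r"([A-Z])?\[([+-][\d.]+)\]")


def _parse_modified_peptide(modpep: str, stripped: str) -> tuple[tuple[int, Modification], ...]:
    """Recover site-localized modifications from bracketed-delta notation,
    matching each delta to the registry within 0.01 Da."""
    mods = []
    pos = 0
    i = 0
    while i < len(modpep):
        ch = modpep[i]
        if ch == "[":
            j = modpep.index("]", i)
            delta = float(modpep[i + 1 : j])
            site = pos  # 0 if before the first residue (N-term)
            mods.append((site, _mod_by_delta(delta, stripped[site - 1] if site else "N-term")))
            i = j + 1
        else:
            pos += 1
            i += 1
    return tuple(mods)


def _mod_by_delta(delta: float, target: str) -> Modification:
    candidates = [
        m
        for m in chem.BUILTIN_MODIFICATIONS.values()
        if abs(m.delta - delta) < 0.01 and (target in m.targets)
    ]
    if not candidates:
        raise ValueError(f"no registered modification with delta {delta:+.4f} on {target}")
    return candidates[0]


PRECURSOR_COLUMNS = [
    "ModifiedPeptide",
    "StrippedPeptide",
    "PrecursorCharge",
    "PrecursorMz",
    "ProteinId",
]


def write_precursor_tsv(precursors: Sequence[PrecursorIon], path) -> None:
    """Enumerated-precursor table (the digest output / prediction input)."""
    rows = [
        (
            p.peptide.modified_string(),
            p.peptide.sequence,
            p.charge,
            round(p.mz, 6),
            ";".join(p.peptide.proteins),
        )
        for p in precursors
    ]
    pd.DataFrame(rows, columns=PRECURSOR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_precursor_tsv(path) -> list[PrecursorIon]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PRECURSOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"precursor table missing columns {missing}")
    out = []
    for r in df.itertuples():
        mods = _parse_modified_peptide(str(r.ModifiedPeptide), str(r.StrippedPeptide))
        pep = Peptide(
            str(r.StrippedPeptide),
            modifications=mods,
            proteins=tuple(str(r.ProteinId).split(";")) if not pd.isna(r.ProteinId) else (),
        )
        out.append(PrecursorIon(pep, int(r.PrecursorCharge), float(r.PrecursorMz)))
    return out


def read_library_tsv(path, dialect: str = "diann") -> SpectralLibrary:
    if dialect != "diann":
        raise ValueError(f"unsupported dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in LIBRARY_COLUMNS]
    if missing or extra:
        raise ValueError(
            f"unexpected library columns: missing={missing}, extra={extra}"
        )
    lib = SpectralLibrary()
    group_cols = ["ModifiedPeptide", "StrippedPeptide", "PrecursorCharge"]
    for (modpep, stripped, charge), grp in df.groupby(group_cols, sort=False):
        mods = _parse_modified_peptide(str(modpep), str(stripped))
        proteins = tuple(str(grp["ProteinId"].iloc[0]).split(";"))
        pep = Peptide(str(stripped), modifications=mods, proteins=proteins)
        frags = tuple(
            Fragment(
                str(r.FragmentType),
                int(r.FragmentSeriesNumber),
                int(r.FragmentCharge),
                float(r.FragmentMz),
                float(r.RelativeIntensity),
            )
            for r in grp.itertuples()
        )
        im = grp["IonMobility"].iloc[0]
        lib.add(
            LibraryEntry(
                peptide=pep,
                charge=int(charge),
                precursor_mz=float(grp["PrecursorMz"].iloc[0]),
                irt=float(grp["Tr_recalibrated"].iloc[0]),
                fragments=frags,
                ion_mobility=None if pd.isna(im) else float(im),
                origin="experimental",
            )
        )
    return lib
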