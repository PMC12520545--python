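"""Sec-aware protein databases: FASTA I/O, UGA-readthrough translation,
tryptic digestion, selenopeptide precursor enumeration and SCoSS filtering.

A "SIS-style" database (SECIS-independent selenoprotein database) is built
by translating through UGA stop codons as Sec (``U``) instead of
terminating, so that in-frame readthrough products become searchable
protein entries. The SCoSS filter then trims such a database to proteins
whose transcripts bind SECISBP2, supplied as a plain identifier list.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Data.CodonTable import standard_dna_table

from . import chem
from .entities import Modification, Peptide, PrecursorIon

__all__ = [
    "ProteinRecord",
    "read_fasta",
    "write_fasta",
    "translate_readthrough",
    "build_sis_database",
    "digest",
    "enumerate_sec_precursors",
    "read_binder_ids",
    "scoss_filter",
]

_ALLOWED = set("ACDEFGHIKLMNPQRSTVWYU")
_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)  # TAA, TAG, TGA


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    description: str = ""
    source: str = "user"  # sis | scoss | user

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.accession!r} has an empty sequence")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(
                f"record {self.accession!r} contains illegal characters "
                f"{sorted(bad)} (allowed: 20 amino acids + U)"
            )


def read_fasta(path, source: str = "user") -> list[ProteinRecord]:
    """Read protein FASTA, preserving ``U``. A single trailing ``*`` per
    record is stripped; any other non-residue character is an error."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(rec.id, seq, desc, source))
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def translate_readthrough(nt_seq: str, frame_offset: int = 0, strict: bool = True) -> str:
    """Translate DNA with UGA (TGA) readthrough as Sec.

    Standard genetic code except every TGA emits ``U`` and translation
    continues; TAA/TAG terminate; a trailing partial codon is ignored.
    Ambiguous bases raise in strict mode.
    """
    if not 0 <= frame_offset <= 2:
        raise ValueError(f"frame_offset must be 0..2, got {frame_offset}")
    seq = nt_seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    if bad:
        if strict:
            raise ValueError(f"ambiguous/illegal nucleotide(s) {sorted(bad)}")
        seq = re.sub("[^ACGT]", "N", seq)
    out = []
    for i in range(frame_offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon == "TGA":
            out.append("U")
        elif codon in _STOP_CODONS:
            break
        elif codon in _CODON_TABLE:
            out.append(_CODON_TABLE[codon])
        else:  # only reachable in non-strict mode
            out.append("X")
    return "".join(out)


def build_sis_database(
    nt_records: Sequence, frame_offset: int = 0, min_length: int = 1
) -> list[ProteinRecord]:
    """Translate nucleotide records (Biopython SeqRecords or (id, seq)
    pairs) with UGA readthrough into a SIS-style protein database."""
    out = []
    for rec in nt_records:
        if hasattr(rec, "seq"):
            acc, seq = rec.id, str(rec.seq)
        else:
            acc, seq = rec
        prot = translate_readthrough(seq, frame_offset)
        if len(prot) >= min_length and prot:
            out.append(ProteinRecord(acc, prot, source="sis"))
    return out


def _tryptic_cut_sites(sequence: str) -> list[int]:
    """0-based positions after which trypsin cleaves: C-terminal to K/R,
    not before P. ``U`` is never a cleavage site."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    record: ProteinRecord,
    max_missed: int = 2,
    min_len: int = 7,
    max_len: int = 50,
    min_mass: float = 500.0,
    max_mass: float = 5000.0,
    mass_on_modified: bool = True,
    cys_mod: Optional[Modification] = None,
    sec_mod: Optional[Modification] = None,
) -> list[Peptide]:
    """Fully tryptic digestion with missed cleavages and length/mass filters.

    The mass window is evaluated on the labeled peptide by default (fixed
    ``cys_mod`` on every C and ``sec_mod`` on every U, defaulting to CAM
    and IodoAPB-CAM), since the searched species carries those labels;
    set ``mass_on_modified=False`` to filter on the stripped mass.
    Returned peptides are unmodified — labels are attached downstream.
    """
    if cys_mod is None:
        cys_mod = chem.get_modification("CAM")
    if sec_mod is None:
        sec_mod = chem.get_modification("IodoAPB-CAM")
    seq = record.sequence
    bounds = [0] + _tryptic_cut_sites(seq) + [len(seq)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + max_missed + 2, len(bounds))):
            sub = seq[bounds[i] : bounds[j]]
            if not min_len <= len(sub) <= max_len:
                continue
            pep = Peptide(
                sub,
                proteins=(record.accession,),
                missed_cleavages=j - i - 1,
            )
            mass_pep = _with_fixed_labels(pep, cys_mod, sec_mod) if mass_on_modified else pep
            mass = chem.peptide_neutral_mass(mass_pep)
            if min_mass <= mass <= max_mass:
                peptides.append(pep)
    return peptides


def _with_fixed_labels(
    peptide: Peptide, cys_mod: Modification, sec_mod: Modification
) -> Peptide:
    mods = list(peptide.modifications)
    occupied = {site for site, _ in mods}
    for pos, aa in enumerate(peptide.sequence, start=1):
        if pos in occupied:
            continue
        if aa == "C":
            mods.append((pos, cys_mod))
        elif aa == "U":
            mods.append((pos, sec_mod))
    return replace(peptide, modifications=tuple(sorted(mods)))


def enumerate_sec_precursors(
    peptides: Iterable[Peptide],
    charges: Sequence[int] = (1, 2, 3, 4),
    sec_mod: Optional[Modification] = None,
    cys_mod: Optional[Modification] = None,
) -> list[PrecursorIon]:
    """One labeled precursor per (Sec peptide, charge).

    Only peptides containing ``U`` are retained; every U carries
    ``sec_mod`` (default IodoAPB-CAM, the SecMS probe adduct) and every
    C the fixed ``cys_mod`` (default CAM).
    """
    if sec_mod is None:
        sec_mod = chem.get_modification("IodoAPB-CAM")
    if cys_mod is None:
        cys_mod = chem.get_modification("CAM")
    if "U" not in sec_mod.targets:
        raise ValueError(f"sec_mod {sec_mod.name!r} does not target U")
    out = []
    for pep in peptides:
        if not pep.is_sec:
            continue
        labeled = _with_fixed_labels(pep, cys_mod, sec_mod)
        for z in charges:
            out.append(chem.make_precursor(labeled, z))
    return out


_VERSION_SUFFIX = re.compile(r"\.\d+$")


def read_binder_ids(path) -> set[str]:
    """Read a one-column identifier list (plain text, or TSV whose first
    column is ``accession``); '#'-comment lines ignored."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        token = line.split("\t")[0].strip()
        if token and token.lower() != "accession":
            ids.add(token)
    return ids


def scoss_filter(
    records: Sequence[ProteinRecord],
    binder_ids: set[str],
    normalize_versions: bool = True,
) -> list[ProteinRecord]:
    """Keep records whose accession is in the SECISBP2-binder list.

    Order is preserved and the source tag is set to ``scoss``. An empty
    binder list is an error so a missing/empty file cannot silently empty
    the library.
    """
    if not binder_ids:
        raise ValueError("binder-ID list is empty; refusing to drop every record")

    def norm(acc: str) -> str:
        return _VERSION_SUFFIX.sub("", acc) if normalize_versions else acc

    wanted = {norm(b) for b in binder_ids}
    return [
        replace(r, source="scoss") for r in records if norm(r.accession) in wanted
    ]
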