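"""Shared in-memory containers for peptides, precursors and spectral libraries.

Conventions used throughout the package:

* Peptide sequences are stripped (no modification notation) and may contain
  ``U`` (selenocysteine) as a first-class residue letter.
* Modification sites are 1-based positions on the stripped sequence;
  position 0 denotes the peptide N-terminus.
* Fragment ions are b/y only, fragment charges 1-2, with relative
  intensities normalized so the base peak of an entry equals 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

__all__ = [
    "Modification",
    "Peptide",
    "PrecursorIon",
    "Fragment",
    "LibraryEntry",
    "SpectralLibrary",
]


@dataclass(frozen=True)
class Modification:
    """A named modification with a signed elemental composition.

    ``delta`` is the monoisotopic mass shift in Da, recomputed from
    ``composition`` at registry-build time; ``targets`` are residue letters
    (or the special token ``"N-term"``).
    """

    name: str
    targets: frozenset[str]
    composition: tuple[tuple[str, int], ...]
    delta: float
    neutral_loss: bool = False

    def composition_dict(self) -> dict[str, int]:
        return dict(self.composition)


@dataclass(frozen=True)
class Peptide:
    """A stripped peptide sequence with site-localized modifications."""

    sequence: str
    modifications: tuple[tuple[int, Modification], ...] = ()
    proteins: tuple[str, ...] = ()
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        for site, mod in self.modifications:
            if not 0 <= site <= len(self.sequence):
                raise ValueError(
                    f"modification site {site} outside peptide "
                    f"{self.sequence!r} (length {len(self.sequence)})"
                )
            if site == 0:
                if "N-term" not in mod.targets:
                    raise ValueError(
                        f"modification {mod.name!r} does not target the N-terminus"
                    )
            elif self.sequence[site - 1] not in mod.targets:
                raise ValueError(
                    f"modification {mod.name!r} targets {sorted(mod.targets)}, "
                    f"not {self.sequence[site - 1]!r} at position {site}"
                )

    @property
    def is_sec(self) -> bool:
        return "U" in self.sequence

    @property
    def is_cys(self) -> bool:
        return "C" in self.sequence

    def mod_at(self, site: int) -> Optional[Modification]:
        for s, mod in self.modifications:
            if s == site:
                return mod
        return None

    def with_sequence(self, sequence: str, modifications=None) -> "Peptide":
        return replace(
            self,
            sequence=sequence,
            modifications=self.modifications if modifications is None else tuple(modifications),
        )

    def modified_string(self, decimals: int = 4) -> str:
        """Bracketed-delta notation, e.g. ``AC[+57.0215]UK[...]``."""
        by_site = dict()
        for site, mod in self.modifications:
            by_site.setdefault(site, 0.0)
            by_site[site] += mod.delta
        out = []
        if 0 in by_site:
            out.append(f"[{by_site[0]:+.{decimals}f}]")
        for i, aa in enumerate(self.sequence, start=1):
            out.append(aa)
            if i in by_site:
                out.append(f"[{by_site[i]:+.{decimals}f}]")
        return "".join(out)


@dataclass(frozen=True)
class PrecursorIon:
    """A peptide at a given positive charge state."""

    peptide: Peptide
    charge: int
    mz: float

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"precursor charge must be >= 1, got {self.charge}")


@dataclass(frozen=True)
class Fragment:
    ion_type: str  # "b" or "y"
    series_number: int
    charge: int
    mz: float
    intensity: float

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.ion_type, self.series_number, self.charge)


@dataclass
class LibraryEntry:
    """A precursor with its annotated fragment ions and predicted/observed
    chromatographic and mobility properties.

    ``irt`` is on a dimensionless 120-min-gradient scale; ``ion_mobility``
    is 1/K0 in Vs cm^-2; ``ccs`` in A^2. ``origin`` is one of
    experimental / pseudo_sec / predicted / buffering.
    """

    peptide: Peptide
    charge: int
    precursor_mz: float
    irt: float
    fragments: tuple[Fragment, ...]
    ion_mobility: Optional[float] = None
    ccs: Optional[float] = None
    origin: str = "experimental"
    precursor_intensity: Optional[float] = None

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.peptide.sequence, self.peptide.modified_string(), self.charge)

    def total_intensity(self) -> float:
        return sum(f.intensity for f in self.fragments)

    def normalized(self) -> "LibraryEntry":
        peak = max((f.intensity for f in self.fragments), default=0.0)
        if peak <= 0:
            return self
        frags = tuple(
            Fragment(f.ion_type, f.series_number, f.charge, f.mz, f.intensity / peak)
            for f in self.fragments
        )
        return replace_entry(self, fragments=frags)


def replace_entry(entry: LibraryEntry, **kw) -> LibraryEntry:
    return field_replace(entry, **kw)


def field_replace(obj, **kw):
    return replace(obj, **kw)


@dataclass
class SpectralLibrary:
    """Ordered collection of LibraryEntry, unique by (sequence, mods, charge)."""

    entries: list[LibraryEntry] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LibraryEntry]:
        return iter(self.entries)

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def add(self, entry: LibraryEntry) -> None:
        self.entries.append(entry)

    def keys(self) -> list[tuple[str, str, int]]:
        return [e.key for e in self.entries]

    def by_key(self) -> dict[tuple[str, str, int], LibraryEntry]:
        return {e.key: e for e in self.entries}

    def validate_unique(self) -> None:
        seen = set()
        for e in self.entries:
            if e.key in seen:
                raise ValueError(f"duplicate library key {e.key}")
            seen.add(e.key)

    @classmethod
    def from_entries(cls, entries: Iterable[LibraryEntry], provenance: Iterable[str] = ()) -> "SpectralLibrary":
        lib = cls(entries=list(entries), provenance=list(provenance))
        lib.validate_unique()
        return lib
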