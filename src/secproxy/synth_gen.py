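"""Seeded synthetic spectral-library generator with known generative truth.

Emulates, at desk scale, an IodoAPB-labeled Cys-peptide DDA library of the
kind used to proxy-train selenopeptide predictors: tryptic-looking random
sequences with at least one labeled Cys, fragment intensity patterns from
a smooth deterministic function of cleavage position / flanking-residue
basicity / precursor charge, retention times from additive residue
coefficients, and CCS from a charge-dependent power law of m/z — each with
configurable noise. The noiseless truth is retained so parameter-recovery
tests can compare model output against an analytically computed noise
ceiling.

The generative functions are deliberately invariant under Cys -> Sec
substitution (U shares the C coefficients), embedding the proxy assumption
that the properties of a peptide and its Sec-substituted twin coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import chem, proxy_transform
from .entities import Fragment, LibraryEntry, Peptide, SpectralLibrary
from .mobility import ccs_to_mobility

__all__ = [
    "SynthConfig",
    "GenerativeTruth",
    "generate_cys_library",
    "generate_sec_holdout",
    "rt_noise_ceiling",
    "scalar_noise_ceiling",
    "ms2_noise_ceiling",
    "RT_COEFFICIENTS",
    "BASICITY",
]

# Hydrophobicity-like retention coefficients on a 120-min-gradient iRT-like
# scale (arbitrary but fixed; W/F/L/I elute late, charged residues early).
RT_COEFFICIENTS: dict[str, float] = {
    "W": 11.0, "F": 10.2, "L": 9.6, "I": 8.4, "M": 5.8, "V": 5.0,
    "Y": 4.1, "C": 2.3, "A": 0.8, "T": 0.4, "P": 0.2, "E": 0.0,
    "D": -0.5, "S": -0.8, "Q": -0.9, "G": -0.9, "N": -1.2, "R": -1.3,
    "H": -1.3, "K": -1.9,
}
RT_INTERCEPT = 12.0

# Gas-phase-basicity-like weights driving fragment intensity.
BASICITY: dict[str, float] = {
    "R": 1.00, "K": 0.85, "H": 0.72, "Q": 0.45, "N": 0.42, "W": 0.40,
    "P": 0.38, "M": 0.32, "F": 0.30, "Y": 0.30, "L": 0.26, "I": 0.26,
    "V": 0.24, "T": 0.20, "S": 0.18, "E": 0.15, "D": 0.14, "A": 0.14,
    "G": 0.12, "C": 0.20,
}
for _tbl in (RT_COEFFICIENTS, BASICITY):
    _tbl["U"] = _tbl["C"]  # proxy assumption: Sec behaves like Cys

# CCS power law ccs = a_z * (m/z)^b, A^2; a grows with charge as multiply
# protonated ions are more extended.
CCS_COEF = {1: 14.0, 2: 15.0, 3: 19.0, 4: 22.0}
CCS_EXP = 0.5

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SynthConfig:
    n_peptides: int = 1000
    min_len: int = 7
    max_len: int = 30
    charges: tuple[int, ...] = (2, 3)
    charge_weights: tuple[float, ...] = (0.65, 0.35)
    sigma_rt: float = 3.0
    sigma_ccs: float = 5.0
    sigma_ms2: float = 0.10
    label: str = "IodoAPB-CAM"  # applied to every Cys
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2")
        if self.max_len < self.min_len:
            raise ValueError("max_len < min_len")
        if min(self.sigma_rt, self.sigma_ccs, self.sigma_ms2) < 0:
            raise ValueError("noise sigmas must be >= 0")
        if len(self.charges) != len(self.charge_weights):
            raise ValueError("charges and charge_weights length mismatch")


@dataclass
class GenerativeTruth:
    """Noiseless values per library key, plus the noise levels used."""

    rt: dict = field(default_factory=dict)       # key -> float
    ccs: dict = field(default_factory=dict)      # key -> float
    ms2: dict = field(default_factory=dict)      # key -> {frag key -> float}
    sigma_rt: float = 0.0
    sigma_ccs: float = 0.0
    sigma_ms2: float = 0.0


def rt_truth(sequence: str) -> float:
    return RT_INTERCEPT + sum(RT_COEFFICIENTS[aa] for aa in sequence)


def ccs_truth(mz: float, charge: int) -> float:
    return CCS_COEF[charge] * mz ** CCS_EXP


def ms2_truth(sequence: str, charge: int) -> dict[tuple[str, int, int], float]:
    """Deterministic smooth fragment-intensity pattern, max-normalized.

    y ions dominate with a broad positional bump modulated by the basicity
    of the C-terminal-side flanking residue; b ions a smaller bump driven
    by the N-terminal side; an N-terminal-side proline boosts y and
    suppresses b; doubly charged fragments scale with fragment length and
    are stronger for 3+ precursors.
    """
    n = len(sequence)
    out: dict[tuple[str, int, int], float] = {}
    z2_factor = 0.55 if charge >= 3 else 0.22
    for i in range(1, n):  # cleavage after residue i
        rel = i / n
        left, right = sequence[i - 1], sequence[i]
        y_base = np.exp(-((rel - 0.45) ** 2) / (2 * 0.30**2)) * (0.5 + BASICITY[right])
        b_base = 0.65 * np.exp(-((rel - 0.60) ** 2) / (2 * 0.25**2)) * (0.5 + BASICITY[left])
        if right == "P":  # classic proline effect
            y_base *= 2.2
            b_base *= 0.35
        y_len, b_len = n - i, i
        out[("y", n - i, 1)] = y_base
        out[("b", i, 1)] = b_base
        out[("y", n - i, 2)] = z2_factor * y_base * (y_len / n)
        out[("b", i, 2)] = z2_factor * b_base * (b_len / n)
    peak = max(out.values())
    return {k: v / peak for k, v in out.items()}


def _random_peptide(rng: np.random.Generator, config: SynthConfig) -> str:
    length = int(rng.integers(config.min_len, config.max_len + 1))
    seq = list(rng.choice(list(_ALPHABET), size=length))
    seq[-1] = str(rng.choice(["K", "R"]))          # tryptic C-terminus
    cys_pos = int(rng.integers(0, length - 1))     # >= 1 Cys, not terminal
    seq[cys_pos] = "C"
    return "".join(seq)


def _observed_entry(
    peptide: Peptide,
    charge: int,
    truth_rt: float,
    truth_ccs: float,
    truth_ms2: dict,
    config: SynthConfig,
    rng: np.random.Generator,
) -> LibraryEntry:
    mz = chem.precursor_mz(peptide, charge)
    obs_rt = truth_rt + rng.normal(0.0, config.sigma_rt)
    obs_ccs = truth_ccs + rng.normal(0.0, config.sigma_ccs)
    frags = []
    for (ion_type, k, z), t in sorted(truth_ms2.items()):
        noisy = max(t * (1.0 + rng.normal(0.0, config.sigma_ms2)), 0.0)
        frags.append(
            Fragment(ion_type, k, z, chem.fragment_mz(peptide, ion_type, k, z), noisy)
        )
    entry = LibraryEntry(
        peptide=peptide,
        charge=charge,
        precursor_mz=mz,
        irt=obs_rt,
        fragments=tuple(frags),
        ccs=obs_ccs,
        ion_mobility=float(ccs_to_mobility(max(obs_ccs, 1.0), mz, charge)),
        origin="experimental",
        precursor_intensity=float(rng.lognormal(mean=10.0, sigma=1.5)),
    )
    return entry.normalized()


def generate_cys_library(
    config: SynthConfig,
) -> tuple[SpectralLibrary, GenerativeTruth]:
    """Generate a labeled Cys library plus its generative truth."""
    rng = np.random.default_rng(config.seed)
    label = chem.get_modification(config.label)
    truth = GenerativeTruth(
        sigma_rt=config.sigma_rt, sigma_ccs=config.sigma_ccs, sigma_ms2=config.sigma_ms2
    )
    lib = SpectralLibrary()
    seen: set = set()
    while len(lib) < config.n_peptides:
        seq = _random_peptide(rng, config)
        charge = int(rng.choice(config.charges, p=np.asarray(config.charge_weights) / sum(config.charge_weights)))
        mods = tuple(
            (pos, label) for pos, aa in enumerate(seq, start=1) if aa == "C"
        )
        pep = Peptide(seq, modifications=mods, proteins=("SYNTH",))
        key = (seq, charge)
        if key in seen:
            continue
        seen.add(key)
        t_rt = rt_truth(seq)
        t_ccs = ccs_truth(chem.precursor_mz(pep, charge), charge)
        t_ms2 = ms2_truth(seq, charge)
        entry = _observed_entry(pep, charge, t_rt, t_ccs, t_ms2, config, rng)
        lib.add(entry)
        truth.rt[entry.key] = t_rt
        truth.ccs[entry.key] = t_ccs
        truth.ms2[entry.key] = t_ms2
    lib.log(f"synth_gen: {len(lib)} Cys entries, seed={config.seed}")
    return lib, truth


def generate_sec_holdout(
    config: SynthConfig,
    cys_library: SpectralLibrary,
    truth: GenerativeTruth,
    noise_seed: Optional[int] = None,
) -> tuple[SpectralLibrary, GenerativeTruth]:
    """Sec-substituted twins of a Cys library with fresh noise draws.

    Twin truth equals source truth (the embedded proxy assumption); the
    observations are independent re-draws, so the twins act as a held-out
    "experimental" selenopeptide library whose noise ceiling is known.
    """
    rng = np.random.default_rng(config.seed + 104729 if noise_seed is None else noise_seed)
    sec_truth = GenerativeTruth(
        sigma_rt=config.sigma_rt, sigma_ccs=config.sigma_ccs, sigma_ms2=config.sigma_ms2
    )
    out = SpectralLibrary()
    for entry in cys_library:
        twin = proxy_transform.cys_to_sec(entry, mode="all_labeled")
        t_rt = truth.rt[entry.key]
        t_ccs_src = truth.ccs[entry.key]
        t_ms2 = truth.ms2[entry.key]
        # CCS truth follows the twin's own (shifted) m/z through the power law
        t_ccs = ccs_truth(twin.precursor_mz, twin.charge)
        fresh = _observed_entry(
            twin.peptide, twin.charge, t_rt, t_ccs, t_ms2, config, rng
        )
        fresh = replace(fresh, origin="pseudo_sec")
        out.add(fresh)
        sec_truth.rt[fresh.key] = t_rt
        sec_truth.ccs[fresh.key] = t_ccs
        sec_truth.ms2[fresh.key] = t_ms2
        del t_ccs_src
    out.log(f"sec_holdout: {len(out)} twins of {len(cys_library)} Cys entries")
    return out, sec_truth


# ---------------------------------------------------------------------------
# Analytic noise ceilings


def scalar_noise_ceiling(truth_values, sigma: float) -> float:
    """Best attainable R^2 against observations y = t + N(0, sigma^2):
    R^2_max = Var(t) / (Var(t) + sigma^2)."""
    v = float(np.var(np.asarray(list(truth_values), dtype=float)))
    if v == 0:
        return 0.0
    return v / (v + sigma**2)


rt_noise_ceiling = scalar_noise_ceiling


def ms2_noise_ceiling(truth_ms2: dict, sigma: float) -> float:
    """Median over spectra of the best attainable fragment PCC against
    observations y = t (1 + eps), eps ~ N(0, sigma^2):
    rho_max = sqrt(Var(t) / (Var(t) + sigma^2 E[t^2])) per spectrum."""
    ceilings = []
    for frag_truth in truth_ms2.values():
        t = np.asarray(list(frag_truth.values()), dtype=float)
        v = t.var()
        m2 = (t**2).mean()
        if v == 0:
            continue
        ceilings.append(np.sqrt(v / (v + sigma**2 * m2)))
    return float(np.median(ceilings))
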