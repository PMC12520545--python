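"""Evaluation suite: matched-fragment Pearson correlation between spectra,
iRT normalization/regression, ion-mobility regression, and library-level
comparison reports.

Fragment pairing is by annotation keys (ion type, series number, fragment
charge) whenever both spectra are annotated — this pairing is invariant
under the Cys->Sec mass shift, so a Cys entry can be compared directly
with its Sec twin. m/z-tolerance pairing (default 15 ppm) is provided for
annotation-free inputs. Unmatched fragments contribute zero intensity on
the missing side by default (the way library search scores missing peaks);
``drop_unmatched=True`` restricts to the shared set instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .entities import LibraryEntry, SpectralLibrary

__all__ = [
    "SpectrumMatchResult",
    "RegressionResult",
    "match_fragments",
    "spectral_pcc",
    "compare_entries",
    "normalize_irt",
    "regress",
    "compare_libraries",
]


@dataclass(frozen=True)
class SpectrumMatchResult:
    key: tuple
    n_matched: int
    pcc: float
    valid: bool


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    pvalue: float
    n: int


def match_fragments(
    a: LibraryEntry,
    b: LibraryEntry,
    tol_ppm: float = 15.0,
    by_annotation: bool = True,
    drop_unmatched: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired intensity vectors for two entries.

    Annotation mode pairs by (ion_type, series_number, fragment_charge);
    m/z mode pairs one-to-one, closest-ppm-first, within ``tol_ppm``.
    """
    if by_annotation:
        ia = {f.key: f.intensity for f in a.fragments}
        ib = {f.key: f.intensity for f in b.fragments}
        keys = sorted(set(ia) & set(ib)) if drop_unmatched else sorted(set(ia) | set(ib))
        x = np.array([ia.get(k, 0.0) for k in keys])
        y = np.array([ib.get(k, 0.0) for k in keys])
        return x, y
    return _match_by_mz(a, b, tol_ppm, drop_unmatched)


def _match_by_mz(a, b, tol_ppm, drop_unmatched):
    fa, fb = list(a.fragments), list(b.fragments)
    pairs = []
    for i, f in enumerate(fa):
        for j, g in enumerate(fb):
            ppm = abs(f.mz - g.mz) / f.mz * 1e6
            if ppm <= tol_ppm:
                pairs.append((ppm, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    x, y = [], []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        x.append(fa[i].intensity)
        y.append(fb[j].intensity)
    if not drop_unmatched:
        for i, f in enumerate(fa):
            if i not in used_a:
                x.append(f.intensity)
                y.append(0.0)
        for j, g in enumerate(fb):
            if j not in used_b:
                x.append(0.0)
                y.append(g.intensity)
    return np.array(x), np.array(y)


def spectral_pcc(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    """Pearson correlation of paired intensities; ``None`` when undefined
    (<3 pairs or zero variance on either side)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def compare_entries(
    a: LibraryEntry,
    b: LibraryEntry,
    tol_ppm: float = 15.0,
    by_annotation: bool = True,
    drop_unmatched: bool = False,
    min_matched: int = 3,
) -> SpectrumMatchResult:
    x, y = match_fragments(a, b, tol_ppm, by_annotation, drop_unmatched)
    n_shared = int(np.sum((x > 0) & (y > 0)))
    pcc = spectral_pcc(x, y)
    valid = pcc is not None and n_shared >= min_matched
    return SpectrumMatchResult(a.key, n_shared, float("nan") if pcc is None else pcc, valid)


def regress(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS y ~ x with R^2 and the two-tailed p-value for slope != 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError(f"regression requires n >= 3, got n={x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression input")
    if np.all(x == x[0]):
        raise ValueError("x is constant; regression undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        pvalue=float(fit.pvalue),
        n=int(x.size),
    )


def normalize_irt(
    run_rts: Sequence[tuple[str, float]],
    reference: Optional[Sequence[tuple[str, float]]] = None,
    gradient_min: float = 120.0,
    gradient_actual: Optional[float] = None,
) -> list[tuple[str, float]]:
    """Scale experimental RTs to an indexed (120-min-gradient) scale.

    Alignment mode (``reference`` given): a least-squares *linear* map
    rt -> irt is fitted on peptides shared with the reference and applied
    to every peptide (a lowess span of zero degenerates to linear).
    Scaling mode (no reference): irt = rt / gradient_actual * gradient_min.
    """
    if reference is None:
        if gradient_actual is None or gradient_actual <= 0:
            raise ValueError("scaling mode requires a positive gradient_actual")
        return [(p, rt / gradient_actual * gradient_min) for p, rt in run_rts]
    ref = dict(reference)
    shared = [(rt, ref[p]) for p, rt in run_rts if p in ref]
    if len(shared) < 2:
        raise ValueError(
            "alignment mode needs >= 2 peptides shared with the reference; "
            "use scaling mode (reference=None, gradient_actual=...)"
        )
    rts = np.array([s[0] for s in shared])
    irts = np.array([s[1] for s in shared])
    if np.all(rts == rts[0]):
        raise ValueError("shared anchor RTs are constant; cannot fit")
    slope, intercept = np.polyfit(rts, irts, 1)
    return [(p, slope * rt + intercept) for p, rt in run_rts]


def _pair_key(entry: LibraryEntry, proxy_pairing: bool) -> tuple:
    seq, mods, charge = entry.key
    if proxy_pairing:
        seq = seq.replace("U", "C")
        mods = ""  # modification strings differ only through the label mass
    return (seq, mods, charge)


def compare_libraries(
    pred: SpectralLibrary,
    exp: SpectralLibrary,
    tol_ppm: float = 15.0,
    by_annotation: bool = True,
    drop_unmatched: bool = False,
    min_matched: int = 3,
    proxy_pairing: bool = False,
) -> dict:
    """Per-precursor fragment PCC plus RT and ion-mobility regressions
    over the precursors shared between two libraries.

    ``proxy_pairing=True`` pairs a Cys entry with its Sec-substituted twin
    by mapping U -> C in the stripped sequence before matching keys.
    """
    pb = {_pair_key(e, proxy_pairing): e for e in exp}
    shared = [
        (e, pb[_pair_key(e, proxy_pairing)])
        for e in pred
        if _pair_key(e, proxy_pairing) in pb
    ]
    if not shared:
        raise ValueError("no precursors shared between the two libraries")
    results = [
        compare_entries(a, b, tol_ppm, by_annotation, drop_unmatched, min_matched)
        for a, b in shared
    ]
    valid = [r for r in results if r.valid]
    pccs = [r.pcc for r in valid]
    rt_pairs = [(a.irt, b.irt) for a, b in shared]
    im_pairs = [
        (a.ion_mobility, b.ion_mobility)
        for a, b in shared
        if a.ion_mobility is not None and b.ion_mobility is not None
    ]

    def _maybe_regress(pairs):
        if len(pairs) < 3:
            return None
        try:
            return regress([p[0] for p in pairs], [p[1] for p in pairs])
        except ValueError:
            return None

    return {
        "n": len(valid),
        "n_shared": len(shared),
        "median_pcc": float(np.median(pccs)) if pccs else float("nan"),
        "pcc": pccs,
        "rt_regression": _maybe_regress(rt_pairs),
        "im_regression": _maybe_regress(im_pairs),
        "results": results,
    }
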