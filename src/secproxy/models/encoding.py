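"""Peptide -> model-input encodings.

* Residue tokens: the 20 canonical amino acids plus ``U`` (Sec) as a
  distinct first-class token. Anything else is an error.
* PTMs: a signed elemental-composition count vector per residue position
  over the channels (C, H, N, O, S, Se, P, other); N-terminal mods ride on
  position 1. The IodoAPB-CAM adduct on a U is therefore visible to the
  model both through the U token and through its composition channel.
* Meta block: precursor-charge one-hot (1..4), NCE/100, instrument one-hot.
"""

from __future__ import annotations

import numpy as np

from ..entities import Peptide

__all__ = [
    "VOCAB",
    "ELEMENT_CHANNELS",
    "INSTRUMENTS",
    "META_DIM",
    "encode_tokens",
    "encode_ptm",
    "encode_meta",
    "token_index",
]

VOCAB = "ACDEFGHIKLMNPQRSTVWYU"
_TOKEN_INDEX = {aa: i for i, aa in enumerate(VOCAB)}
ELEMENT_CHANNELS = ("C", "H", "N", "O", "S", "Se", "P")
INSTRUMENTS = ("timsTOF", "QE", "generic")
MAX_CHARGE = 4
META_DIM = MAX_CHARGE + 1 + len(INSTRUMENTS)
PTM_DIM = len(ELEMENT_CHANNELS) + 1  # + "other"


def token_index(residue: str) -> int:
    try:
        return _TOKEN_INDEX[residue]
    except KeyError:
        raise ValueError(
            f"unknown residue token {residue!r}; allowed: {VOCAB}"
        ) from None


def encode_tokens(peptide: Peptide) -> np.ndarray:
    if len(peptide.sequence) < 2:
        raise ValueError("peptide must have length >= 2 for encoding")
    return np.array([token_index(aa) for aa in peptide.sequence], dtype=np.int64)


def encode_ptm(peptide: Peptide) -> np.ndarray:
    out = np.zeros((len(peptide.sequence), PTM_DIM), dtype=np.float32)
    for site, mod in peptide.modifications:
        row = max(site - 1, 0)
        for el, count in mod.composition:
            if el in ELEMENT_CHANNELS:
                out[row, ELEMENT_CHANNELS.index(el)] += count
            else:
                out[row, -1] += count
    return out


def encode_meta(
    charge: int, nce: float = 30.0, instrument: str = "timsTOF"
) -> np.ndarray:
    if instrument not in INSTRUMENTS:
        raise ValueError(f"unknown instrument {instrument!r}; allowed: {INSTRUMENTS}")
    out = np.zeros(META_DIM, dtype=np.float32)
    out[min(charge, MAX_CHARGE) - 1] = 1.0
    out[MAX_CHARGE] = nce / 100.0
    out[MAX_CHARGE + 1 + INSTRUMENTS.index(instrument)] = 1.0
    return out
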