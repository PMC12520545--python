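"""CCS <-> ion-mobility conversion via the Mason-Schamp proportionality.

1/K0 = CCS * sqrt(mu) / (k_const * z), with mu the reduced mass of the ion
and the buffer gas (default N2, 28.013 Da). ``k_const`` absorbs the
temperature/number-density prefactor; the default reproduces the scale
commonly used for timsTOF data (1/K0 ~ 0.6-1.6 Vs cm^-2 for tryptic
peptides at CCS 300-700 A^2).
"""

from __future__ import annotations

import numpy as np

__all__ = ["ccs_to_mobility", "mobility_to_ccs", "N2_MASS", "K0_CONST"]

N2_MASS = 28.013
K0_CONST = 1059.62245


def _reduced_mass(mz, charge, gas_mass):
    ion_mass = np.asarray(mz, dtype=float) * charge
    return ion_mass * gas_mass / (ion_mass + gas_mass)


def ccs_to_mobility(ccs, mz, charge, gas_mass: float = N2_MASS, k_const: float = K0_CONST):
    """Inverse reduced mobility 1/K0 (Vs cm^-2) from CCS (A^2)."""
    ccs = np.asarray(ccs, dtype=float)
    if np.any(ccs <= 0) or np.any(np.asarray(mz, float) <= 0) or charge < 1:
        raise ValueError("ccs, mz must be positive and charge >= 1")
    return ccs * np.sqrt(_reduced_mass(mz, charge, gas_mass)) / (k_const * charge)


def mobility_to_ccs(mobility, mz, charge, gas_mass: float = N2_MASS, k_const: float = K0_CONST):
    """CCS (A^2) from inverse reduced mobility 1/K0 (Vs cm^-2)."""
    mobility = np.asarray(mobility, dtype=float)
    if np.any(mobility <= 0) or np.any(np.asarray(mz, float) <= 0) or charge < 1:
        raise ValueError("mobility, mz must be positive and charge >= 1")
    return mobility * k_const * charge / np.sqrt(_reduced_mass(mz, charge, gas_mass))
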