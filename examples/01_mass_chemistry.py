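"""Selenopeptide mass chemistry: modification deltas and fragment ladders.

Builds a labeled selenopeptide and prints its precursor and b/y fragment
m/z values, showing how the Se-for-S substitution and the IodoAPB probe
adduct shift the masses.
"""

from secproxy import chem
from secproxy.entities import Peptide

print("Built-in modification deltas (recomputed from composition):")
for name, mod in chem.BUILTIN_MODIFICATIONS.items():
    print(f"  {name:12s} {mod.delta:+12.6f} Da  targets {sorted(mod.targets)}")

print(f"\nCys -> Sec mass shift (Se - S): {chem.sec_cys_delta():+.6f} Da")

iodo = chem.get_modification("IodoAPB-CAM")
cam = chem.get_modification("CAM")

cys_pep = Peptide("VLLIENVASLCGTTVR", ((11, iodo),))
sec_pep = Peptide("VLLIENVASLUGTTVR", ((11, iodo),))
del cam

for pep in (cys_pep, sec_pep):
    print(f"\n{pep.modified_string()}")
    print(f"  neutral mass {chem.peptide_neutral_mass(pep):.4f} Da, "
          f"[M+2H]2+ m/z {chem.precursor_mz(pep, 2):.4f}")
    for k in (3, 8, 13):
        b = chem.fragment_mz(pep, "b", k, 1)
        y = chem.fragment_mz(pep, "y", len(pep.sequence) - k, 1)
        print(f"  b{k}: {b:9.4f}   y{len(pep.sequence)-k}: {y:9.4f}")

shift = chem.peptide_neutral_mass(sec_pep) - chem.peptide_neutral_mass(cys_pep)
print(f"\nNeutral mass difference between the twins: {shift:+.6f} Da")
print("-> exactly the Se-S element difference: only fragments spanning the")
print("   substituted site move; everything else is identical.")
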