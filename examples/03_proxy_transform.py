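"""The Cys-S+Se proxy transform on a synthetic labeled-Cys library.

Generates a small labeled Cys library, rewrites it into a pseudo-Sec
training library, and shows that only the masses move while intensities,
RT and ion mobility are carried over unchanged.
"""

from secproxy import chem, proxy_transform, synth_gen

lib, _ = synth_gen.generate_cys_library(synth_gen.SynthConfig(n_peptides=5, seed=42))
pseudo = proxy_transform.transform_library(lib)
print(pseudo.provenance[-1])

before, after = lib.entries[0], pseudo.entries[0]
k = before.peptide.sequence.count("C")
print(f"\n{before.peptide.sequence}  ->  {after.peptide.sequence}  "
      f"({k} labeled Cys substituted, z={before.charge})")
print(f"precursor m/z: {before.precursor_mz:.4f} -> {after.precursor_mz:.4f} "
      f"(shift {after.precursor_mz - before.precursor_mz:+.4f} "
      f"= {k} x {chem.sec_cys_delta():.4f} / {before.charge})")
print(f"iRT unchanged: {before.irt == after.irt}; "
      f"1/K0 unchanged: {before.ion_mobility == after.ion_mobility}")

moved = sum(
    1 for fb, fa in zip(before.fragments, after.fragments) if fa.mz != fb.mz
)
print(f"fragments: {moved}/{len(before.fragments)} shifted "
      "(exactly those spanning a substituted site)")
for fb, fa in zip(before.fragments[:6], after.fragments[:6]):
    tag = "shifted " if fa.mz != fb.mz else "unchanged"
    print(f"  {fb.ion_type}{fb.series_number}^{fb.charge}+  "
          f"{fb.mz:9.4f} -> {fa.mz:9.4f}  {tag}  intensity {fb.intensity:.3f}")
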