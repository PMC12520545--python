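"""Proxy-train the three predictors and assemble a hybrid DIA library.

Small-scale version of the full pipeline (a few hundred peptides, short
pretraining) so it runs in about a minute: generate a Cys library,
transform to pseudo-Sec, pretrain + fine-tune MS2/RT/CCS, predict a
library for held-out Sec twins, and attach 2:1 Cys buffering peptides.
"""

import tempfile
from pathlib import Path

from secproxy import library_gen, proxy_transform, synth_gen
from secproxy.entities import PrecursorIon
from secproxy.models import api

cfg = synth_gen.SynthConfig(n_peptides=300, seed=1)
cys_lib, truth = synth_gen.generate_cys_library(cfg)
pseudo = proxy_transform.transform_library(cys_lib)
sec_lib, _ = synth_gen.generate_sec_holdout(cfg, cys_lib, truth)
print(f"training library: {len(pseudo)} pseudo-Sec entries")

bundles = api.train_all_models(
    cys_lib, pseudo, pretrain_epochs={"ms2": 20, "rt": 25, "ccs": 25}, seed=1
)
for task, b in bundles.items():
    print(f"  {task}: pretrain+finetune loss {b.loss_curve[0]:.4f} -> "
          f"{b.loss_curve[-1]:.4f} over {len(b.loss_curve)} epochs")

precursors = [
    PrecursorIon(e.peptide, e.charge, e.precursor_mz) for e in sec_lib.entries[:100]
]
predicted = library_gen.build_predicted_library(
    api.MS2Model(bundles["ms2"]), api.RTModel(bundles["rt"]),
    api.CCSModel(bundles["ccs"]), precursors,
)
print(predicted.provenance[-1])

hybrid = library_gen.add_buffering(predicted, cys_lib, ratio="2:1")
print(hybrid.provenance[-1])

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "hybrid_library.tsv"
    library_gen.write_library_tsv(hybrid, out)
    lines = out.read_text().splitlines()
    print(f"\nwrote {out.name}: {len(lines) - 1} fragment rows "
          f"({len(hybrid)} precursors); first data row:")
    print("  " + lines[1])
print("Columns follow the DIA-NN long format; origin flags separate "
      "predicted Sec targets from Cys buffering entries.")
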