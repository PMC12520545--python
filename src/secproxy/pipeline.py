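"""End-to-end workflows tying the modules together.

``run_recovery_experiment`` is the package's core validation: generate a
synthetic labeled-Cys library, transform it to pseudo-Sec, pretrain and
fine-tune the three predictors, and score predictions on Sec-substituted
held-out twins against the analytic noise ceilings of the generator.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import eval_metrics, proxy_transform, synth_gen
from .entities import PrecursorIon, SpectralLibrary
from .models import api

__all__ = ["run_recovery_experiment", "evaluate_on_holdout", "DEFAULT_PRETRAIN_EPOCHS"]

#: per-task pretraining epochs for desk-scale runs (the fine-tune recipe
#: itself is fixed by ModelConfig)
DEFAULT_PRETRAIN_EPOCHS = {"ms2": 50, "rt": 60, "ccs": 60}


def evaluate_on_holdout(
    bundles: dict[str, api.ModelBundle], holdout: SpectralLibrary
) -> dict:
    """Score the three predictors against an observed (noisy) library:
    per-spectrum fragment PCC over the union of annotation keys
    (zero-filled), and R^2 of predicted vs observed RT and CCS."""
    precursors = [PrecursorIon(e.peptide, e.charge, e.precursor_mz) for e in holdout]
    maps = api.MS2Model(bundles["ms2"]).predict(precursors)
    pccs = []
    for entry, predicted in zip(holdout, maps):
        observed = {f.key: f.intensity for f in entry.fragments}
        keys = sorted(set(observed) | set(predicted))
        pcc = eval_metrics.spectral_pcc(
            [predicted.get(k, 0.0) for k in keys],
            [observed.get(k, 0.0) for k in keys],
        )
        if pcc is not None:
            pccs.append(pcc)
    rt_pred = api.RTModel(bundles["rt"]).predict([e.peptide for e in holdout])
    ccs_pred = api.CCSModel(bundles["ccs"]).predict(precursors)
    rt_obs = np.array([e.irt for e in holdout])
    ccs_obs = np.array([e.ccs for e in holdout])
    return {
        "median_pcc": float(np.median(pccs)),
        "n_spectra": len(pccs),
        "rt_r2": eval_metrics.regress(rt_pred, rt_obs).r2,
        "ccs_r2": eval_metrics.regress(ccs_pred, ccs_obs).r2,
    }


def run_recovery_experiment(
    n_peptides: int = 2000,
    seed: int = 7,
    configs: Optional[dict[str, api.ModelConfig]] = None,
    pretrain_epochs: Optional[dict[str, int]] = None,
) -> dict:
    """Proxy-training parameter recovery on synthetic data.

    Returns the held-out metrics, the analytic noise ceilings they are
    judged against, and the trained bundles.
    """
    config = synth_gen.SynthConfig(n_peptides=n_peptides, seed=seed)
    cys_lib, truth = synth_gen.generate_cys_library(config)
    pseudo = proxy_transform.transform_library(cys_lib)
    sec_lib, sec_truth = synth_gen.generate_sec_holdout(config, cys_lib, truth)

    bundles = api.train_all_models(
        cys_lib,
        pseudo,
        configs=configs,
        pretrain_epochs=pretrain_epochs or DEFAULT_PRETRAIN_EPOCHS,
        seed=seed,
    )
    metrics = evaluate_on_holdout(bundles, sec_lib)
    ceilings = {
        "ms2": synth_gen.ms2_noise_ceiling(sec_truth.ms2, config.sigma_ms2),
        "rt": synth_gen.scalar_noise_ceiling(sec_truth.rt.values(), config.sigma_rt),
        "ccs": synth_gen.scalar_noise_ceiling(sec_truth.ccs.values(), config.sigma_ccs),
    }
    return {
        "config": config,
        "metrics": metrics,
        "ceilings": ceilings,
        "bundles": bundles,
        "n_train": len(pseudo),
        "n_holdout": len(sec_lib),
    }
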