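"""Model configuration, training (pretrain + fine-tune), prediction and
checkpointing for the three peptide-property predictors.

The reference architecture and fine-tuning recipe (transformer MS2 with
hidden dim 256 / 4 layers; CNN+LSTM RT/CCS with 128 channels / 2 LSTM
layers; L1 loss, 20 epochs with 5 warm-up epochs and a cosine schedule,
peak learning rate 1e-5, dropout 0.1, mini-batch 256) are the defaults of
:class:`ModelConfig`. Because no external pretrained weights are shipped,
the offline training path mirrors the pretrain-then-fine-tune procedure:
:func:`pretrain` fits the network on a (synthetic or experimental) Cys
library with its own schedule, and :func:`finetune` then applies the
reference recipe to the pseudo-Sec library. ``ModelConfig.desk_scale()``
gives reduced dimensions for CPU-scale runs; the training recipe fields
are unchanged by scaling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ..entities import Peptide, PrecursorIon, SpectralLibrary
from .autodiff import Adam, Tensor, l1_loss, warmup_cosine_lr
from .encoding import VOCAB, encode_meta, encode_ptm, encode_tokens, token_index
from .nets import CHANNELS, MODLOSS_SLICE, MS2Network, N_CHANNELS, ScalarNetwork

__all__ = [
    "ModelConfig",
    "ModelBundle",
    "pretrain",
    "finetune",
    "MS2Model",
    "RTModel",
    "CCSModel",
    "train_all_models",
]


@dataclass(frozen=True)
class ModelConfig:
    task: str  # ms2 | rt | ccs
    # MS2 transformer
    hidden_dim: int = 256
    n_layers: int = 4
    n_heads: int = 4
    ff_mult: int = 4
    fc_dim: int = 128
    # RT/CCS CNN + LSTM
    conv_channels: int = 128
    lstm_dim: int = 128
    lstm_layers: int = 2
    fc_scalar: int = 64
    # fine-tuning recipe
    epochs: int = 20
    warmup_epochs: int = 5
    learning_rate: float = 1e-5
    dropout: float = 0.1
    batch_size: int = 256
    # encoding
    max_len: int = 64
    default_nce: float = 30.0
    default_instrument: str = "timsTOF"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("ms2", "rt", "ccs"):
            raise ValueError(f"unknown task {self.task!r}")
        dims = (
            self.hidden_dim, self.n_layers, self.n_heads, self.fc_dim,
            self.conv_channels, self.lstm_dim, self.lstm_layers,
            self.fc_scalar, self.epochs, self.batch_size, self.max_len,
        )
        if any(d <= 0 for d in dims):
            raise ValueError("all dimensions/counts must be positive")
        if self.warmup_epochs > self.epochs:
            raise ValueError("warmup_epochs must be <= epochs")

    @classmethod
    def desk_scale(cls, task: str, **overrides) -> "ModelConfig":
        """Reduced dimensions for single-CPU runs; recipe unchanged."""
        small = dict(
            hidden_dim=64, n_layers=2, fc_dim=64,
            conv_channels=48, lstm_dim=48, fc_scalar=32,
        )
        small.update(overrides)
        return cls(task=task, **small)


class ModelBundle:
    """Config + network weights + training metadata for one task."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        if config.task == "ms2":
            self.network = MS2Network(config, rng)
        else:
            self.network = ScalarNetwork(config, rng, with_charge=config.task == "ccs")
        self.loss_curve: list[float] = []
        self.target_mean: float = 0.0
        self.target_std: float = 1.0
        self.fingerprint: str = ""

    # -- warm start --------------------------------------------------------

    def warm_start_sec_from_cys(self) -> None:
        """Initialize the U (Sec) input representation from the C (Cys)
        one — the proxy hypothesis expressed in weight space. Used when a
        network pretrained on Cys-only data is about to be fine-tuned on
        pseudo-Sec data."""
        u, c = token_index("U"), token_index("C")
        if self.config.task == "ms2":
            self.network.embed.table.data[u] = self.network.embed.table.data[c]
        else:
            self.network.conv.k.data[:, u, :] = self.network.conv.k.data[:, c, :]

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        params = {f"param::{k}": v.data for k, v in self.network.parameters().items()}
        np.savez(
            path,
            __config__=json.dumps(asdict(self.config)),
            __meta__=json.dumps(
                dict(
                    loss_curve=self.loss_curve,
                    target_mean=self.target_mean,
                    target_std=self.target_std,
                    fingerprint=self.fingerprint,
                )
            ),
            **params,
        )

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with np.load(path, allow_pickle=False) as data:
            config = ModelConfig(**json.loads(str(data["__config__"])))
            meta = json.loads(str(data["__meta__"]))
            bundle = cls(config)
            params = bundle.network.parameters()
            for key in data.files:
                if key.startswith("param::"):
                    params[key[len("param::"):]].data = data[key]
        bundle.loss_curve = list(meta["loss_curve"])
        bundle.target_mean = meta["target_mean"]
        bundle.target_std = meta["target_std"]
        bundle.fingerprint = meta["fingerprint"]
        return bundle


# ---------------------------------------------------------------------------
# dataset assembly


def _ms2_target(entry, length: int) -> np.ndarray:
    """(L-1, 8) intensity matrix; modloss channels stay zero."""
    out = np.zeros((length - 1, N_CHANNELS), dtype=np.float32)
    col = {(t, z): i for i, (t, z, kind) in enumerate(CHANNELS) if kind == "regular"}
    for f in entry.fragments:
        if (f.ion_type, f.charge) not in col:
            continue
        row = f.series_number - 1 if f.ion_type == "b" else length - f.series_number - 1
        out[row, col[(f.ion_type, f.charge)]] = f.intensity
    return out


def _ms2_items(library: SpectralLibrary, config: ModelConfig):
    items = []
    for e in library:
        tokens = encode_tokens(e.peptide)
        items.append(
            (
                tokens,
                encode_ptm(e.peptide),
                encode_meta(e.charge, config.default_nce, config.default_instrument),
                _ms2_target(e, len(tokens)),
            )
        )
    return items


def _scalar_items(library: SpectralLibrary, config: ModelConfig, task: str):
    from ..mobility import mobility_to_ccs

    items = []
    for e in library:
        target = e.irt if task == "rt" else e.ccs
        if task == "ccs" and target is None and e.ion_mobility is not None:
            target = float(mobility_to_ccs(e.ion_mobility, e.precursor_mz, e.charge))
        if target is None:
            raise ValueError(f"entry {e.key} lacks a {task} target")
        charge = np.zeros(4, dtype=np.float32)
        charge[min(e.charge, 4) - 1] = 1.0
        items.append((encode_tokens(e.peptide), encode_ptm(e.peptide), charge, float(target)))
    return items


def _length_batches(items, batch_size: int, rng: Optional[np.random.Generator]):
    """Batches of equal sequence length (no padding/masking needed)."""
    groups: dict[int, list[int]] = {}
    for i, item in enumerate(items):
        groups.setdefault(len(item[0]), []).append(i)
    batches = []
    for _, idxs in sorted(groups.items()):
        idxs = list(idxs)
        if rng is not None:
            rng.shuffle(idxs)
        for start in range(0, len(idxs), batch_size):
            batches.append(idxs[start : start + batch_size])
    if rng is not None:
        rng.shuffle(batches)
    return batches


def _fingerprint(library: SpectralLibrary) -> str:
    h = hashlib.sha1()
    for e in library:
        h.update(repr(e.key).encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# training


def _forward(bundle: ModelBundle, items, idxs, dropout, rng, training):
    task = bundle.config.task
    if task == "ms2":
        tokens = np.stack([items[i][0] for i in idxs])
        ptm = np.stack([items[i][1] for i in idxs])
        meta = np.stack([items[i][2] for i in idxs])
        target = np.stack([items[i][3] for i in idxs])
        out = bundle.network(tokens, ptm, meta, dropout, rng, training)
        return out, target
    tokens = np.stack([items[i][0] for i in idxs])
    ptm = np.stack([items[i][1] for i in idxs])
    charge = np.stack([items[i][2] for i in idxs])
    raw = np.array([items[i][3] for i in idxs], dtype=np.float32)
    target = (raw - bundle.target_mean) / bundle.target_std
    out = bundle.network(tokens, ptm, charge, dropout, rng, training)
    return out.reshape(-1), target


def _fit(
    bundle: ModelBundle,
    library: SpectralLibrary,
    epochs: int,
    warmup_epochs: int,
    peak_lr: float,
    batch_size: int,
    dropout: float,
    seed: int,
) -> list[float]:
    if len(library) == 0:
        raise ValueError("empty training set")
    config = bundle.config
    task = config.task
    if task == "ms2":
        items = _ms2_items(library, config)
    else:
        items = _scalar_items(library, config, task)
        if bundle.target_std == 1.0 and bundle.target_mean == 0.0:
            raw = np.array([it[3] for it in items])
            bundle.target_mean = float(raw.mean())
            bundle.target_std = float(raw.std() or 1.0)
    rng = np.random.default_rng(seed)
    params = bundle.network.parameters()
    opt = Adam(params)
    curve = []
    for epoch in range(epochs):
        lr = warmup_cosine_lr(epoch, epochs, warmup_epochs, peak_lr)
        total, count = 0.0, 0
        for idxs in _length_batches(items, batch_size, rng):
            out, target = _forward(bundle, items, idxs, dropout, rng, training=True)
            loss = l1_loss(out, target)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (task {task}); aborting"
                )
            opt.zero_grad()
            loss.backward()
            opt.step(lr)
            total += value * len(idxs)
            count += len(idxs)
        curve.append(total / count)
    bundle.loss_curve.extend(curve)
    bundle.fingerprint = _fingerprint(library)
    return curve


def pretrain(
    bundle: ModelBundle,
    library: SpectralLibrary,
    epochs: int = 150,
    warmup_epochs: int = 10,
    learning_rate: float = 2e-3,
    seed: Optional[int] = None,
) -> list[float]:
    """From-scratch training pass (the stand-in for loading pretrained
    generic weights); schedule is warm-up + cosine like the fine-tune."""
    return _fit(
        bundle, library, epochs, warmup_epochs, learning_rate,
        bundle.config.batch_size, bundle.config.dropout,
        bundle.config.seed if seed is None else seed,
    )


def finetune(
    bundle: ModelBundle,
    library: SpectralLibrary,
    seed: Optional[int] = None,
) -> list[float]:
    """Fine-tune with the reference recipe carried by the config (L1,
    epochs/warm-up/cosine/learning rate/dropout/batch size)."""
    c = bundle.config
    return _fit(
        bundle, library, c.epochs, c.warmup_epochs, c.learning_rate,
        c.batch_size, c.dropout, c.seed + 1 if seed is None else seed,
    )


# ---------------------------------------------------------------------------
# prediction


def _predict_batched(bundle: ModelBundle, items):
    """Run the network in eval mode over length-grouped batches,
    returning outputs in input order."""
    batches = _length_batches(items, bundle.config.batch_size, rng=None)
    out = [None] * len(items)
    for idxs in batches:
        pred, _ = _forward(bundle, items, idxs, 0.0, None, training=False)
        for j, i in enumerate(idxs):
            out[i] = pred.data[j]
    return out


class MS2Model:
    """Fragment-intensity predictor; returns per-precursor intensity maps
    keyed by (ion_type, series_number, fragment_charge). Modloss channels
    are forced to zero (no modloss-generating modifications registered)."""

    def __init__(self, bundle: ModelBundle):
        if bundle.config.task != "ms2":
            raise ValueError("bundle task is not ms2")
        self.bundle = bundle

    def predict_matrices(self, precursors: Sequence[PrecursorIon]) -> list[np.ndarray]:
        config = self.bundle.config
        items = []
        for p in precursors:
            if len(p.peptide.sequence) > config.max_len:
                raise ValueError(
                    f"peptide {p.peptide.sequence!r} exceeds model max length "
                    f"{config.max_len}"
                )
            items.append(
                (
                    encode_tokens(p.peptide),
                    encode_ptm(p.peptide),
                    encode_meta(p.charge, config.default_nce, config.default_instrument),
                    np.zeros((len(p.peptide.sequence) - 1, N_CHANNELS), dtype=np.float32),
                )
            )
        mats = _predict_batched(self.bundle, items)
        out = []
        for m in mats:
            m = np.array(m, dtype=np.float64)
            m[:, MODLOSS_SLICE] = 0.0
            peak = m.max()
            if peak > 0:
                m /= peak
            out.append(m)
        return out

    def predict(self, precursors: Sequence[PrecursorIon]) -> list[dict]:
        maps = []
        for p, m in zip(precursors, self.predict_matrices(precursors)):
            n = len(p.peptide.sequence)
            d = {}
            for row in range(n - 1):
                for i, (t, z, kind) in enumerate(CHANNELS):
                    if kind != "regular":
                        continue
                    series = row + 1 if t == "b" else n - row - 1
                    d[(t, series, z)] = float(m[row, i])
            maps.append(d)
        return maps


class RTModel:
    """Indexed-retention-time predictor (120-min-gradient scale)."""

    def __init__(self, bundle: ModelBundle):
        if bundle.config.task != "rt":
            raise ValueError("bundle task is not rt")
        self.bundle = bundle

    def predict(self, peptides: Sequence[Peptide]) -> np.ndarray:
        items = [
            (encode_tokens(p), encode_ptm(p), np.zeros(4, dtype=np.float32), 0.0)
            for p in peptides
        ]
        out = np.array(_predict_batched(self.bundle, items), dtype=np.float64)
        return out * self.bundle.target_std + self.bundle.target_mean


class CCSModel:
    """Collision-cross-section predictor (A^2, strictly positive)."""

    def __init__(self, bundle: ModelBundle):
        if bundle.config.task != "ccs":
            raise ValueError("bundle task is not ccs")
        self.bundle = bundle

    def predict(self, precursors: Sequence[PrecursorIon]) -> np.ndarray:
        items = []
        for p in precursors:
            charge = np.zeros(4, dtype=np.float32)
            charge[min(p.charge, 4) - 1] = 1.0
            items.append((encode_tokens(p.peptide), encode_ptm(p.peptide), charge, 0.0))
        out = np.array(_predict_batched(self.bundle, items), dtype=np.float64)
        out = out * self.bundle.target_std + self.bundle.target_mean
        return np.logaddexp(0.0, out)  # softplus: positive, identity at scale


def train_all_models(
    cys_library: SpectralLibrary,
    pseudo_sec_library: SpectralLibrary,
    configs: Optional[dict[str, ModelConfig]] = None,
    pretrain_epochs: dict[str, int] | int = 150,
    pretrain_lr: float = 2e-3,
    seed: int = 0,
) -> dict[str, ModelBundle]:
    """Pretrain on the Cys library, warm-start the Sec token, fine-tune on
    the pseudo-Sec library with the reference recipe; for all three tasks."""
    bundles = {}
    for task in ("ms2", "rt", "ccs"):
        config = (configs or {}).get(task) or ModelConfig.desk_scale(task, seed=seed)
        bundle = ModelBundle(config)
        n_epochs = (
            pretrain_epochs.get(task, 150)
            if isinstance(pretrain_epochs, dict)
            else pretrain_epochs
        )
        pretrain(bundle, cys_library, epochs=n_epochs, learning_rate=pretrain_lr,
                 seed=seed + 17)
        bundle.warm_start_sec_from_cys()
        finetune(bundle, pseudo_sec_library, seed=seed + 31)
        bundles[task] = bundle
    return bundles
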