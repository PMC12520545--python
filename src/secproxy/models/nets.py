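"""The two network architectures.

* MS2: residue embedding + PTM-composition projection + meta projection,
  sinusoidal positions, a stack of transformer encoder layers, then per
  cleavage site the concatenated flanking representations go through two
  FC layers to 8 output channels ({b,y} x {z1,z2} x {regular, modloss}),
  squashed to [0, 1] by a sigmoid.
* Scalar (RT/CCS): one-hot residues + PTM composition counts, one 1-D
  convolution, a stack of LSTM layers, mean pooling over positions
  (optionally concatenated with a charge one-hot for CCS), and two FC
  layers to a single value.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .encoding import META_DIM, PTM_DIM, VOCAB
from .layers import (
    Conv1d,
    Embedding,
    LayerNorm,
    Linear,
    LSTM,
    Module,
    TransformerLayer,
    sinusoidal_positions,
)

__all__ = ["MS2Network", "ScalarNetwork", "CHANNELS", "N_CHANNELS"]

#: output channel layout of the MS2 head, fixed across the package
CHANNELS: tuple[tuple[str, int, str], ...] = (
    ("b", 1, "regular"),
    ("b", 2, "regular"),
    ("y", 1, "regular"),
    ("y", 2, "regular"),
    ("b", 1, "modloss"),
    ("b", 2, "modloss"),
    ("y", 1, "modloss"),
    ("y", 2, "modloss"),
)
N_CHANNELS = len(CHANNELS)
MODLOSS_SLICE = slice(4, 8)


class MS2Network(Module):
    def __init__(self, config, rng: np.random.Generator):
        d = config.hidden_dim
        self.embed = Embedding(rng, len(VOCAB), d)
        self.ptm_proj = Linear(rng, PTM_DIM, d)
        self.meta_proj = Linear(rng, META_DIM, d)
        self.blocks = [
            TransformerLayer(rng, d, config.n_heads, config.ff_mult)
            for _ in range(config.n_layers)
        ]
        self.ln_out = LayerNorm(d)
        self.fc1 = Linear(rng, 2 * d, config.fc_dim)
        self.fc2 = Linear(rng, config.fc_dim, N_CHANNELS)
        self._posenc = sinusoidal_positions(config.max_len, d)

    def __call__(
        self,
        tokens: np.ndarray,   # (B, L) int
        ptm: np.ndarray,      # (B, L, PTM_DIM)
        meta: np.ndarray,     # (B, META_DIM)
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
        training: bool = False,
    ) -> Tensor:
        B, L = tokens.shape
        x = (
            self.embed(tokens)
            + self.ptm_proj(Tensor(ptm * 0.1))
            + self.meta_proj(Tensor(meta)).reshape(B, 1, -1)
            + Tensor(self._posenc[:L])
        )
        for block in self.blocks:
            x = block(x, dropout, rng, training)
        h = self.ln_out(x)
        pairs = Tensor.concat([h[:, : L - 1, :], h[:, 1:, :]], axis=-1)
        return self.fc2(self.fc1(pairs).relu()).sigmoid()  # (B, L-1, 8)


class ScalarNetwork(Module):
    def __init__(self, config, rng: np.random.Generator, with_charge: bool):
        c_in = len(VOCAB) + PTM_DIM
        self.conv = Conv1d(rng, c_in, config.conv_channels)
        dims = [config.conv_channels] + [config.lstm_dim] * config.lstm_layers
        self.lstms = [
            LSTM(rng, dims[i], dims[i + 1]) for i in range(config.lstm_layers)
        ]
        pooled = config.lstm_dim + (4 if with_charge else 0)
        self.fc1 = Linear(rng, pooled, config.fc_scalar)
        self.fc2 = Linear(rng, config.fc_scalar, 1)
        self.with_charge = with_charge

    def __call__(
        self,
        tokens: np.ndarray,       # (B, L) int
        ptm: np.ndarray,          # (B, L, PTM_DIM)
        charge_onehot: np.ndarray | None = None,  # (B, 4)
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
        training: bool = False,
    ) -> Tensor:
        onehot = np.eye(len(VOCAB), dtype=np.float32)[tokens]
        x = Tensor(np.concatenate([onehot, ptm * 0.1], axis=-1))
        h = self.conv(x).relu()
        for lstm in self.lstms:
            h = lstm(h)
            h = h.dropout(dropout, rng, training)
        pooled = h.mean(axis=1)
        if self.with_charge:
            pooled = Tensor.concat([pooled, Tensor(charge_onehot)], axis=-1)
        return self.fc2(self.fc1(pooled).relu())  # (B, 1)
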