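"""The protein-aware binding-site architecture.

Three stages:

1. **DNA encoder** — 1-D convolution (320 filters, width 26, valid, ReLU)
   over the one-hot window, non-overlapping max-pool (window 13), a 2-layer
   bidirectional LSTM (160 units per direction, so d1 = 320), and a 1-layer
   pre-norm transformer encoder (16 heads, FFN 1024). Output: per-position
   matrix H (L x d1) with L = floor((input_len - kernel + 1) / pool), and a
   pooled global vector x1 = position-mean of H. With the default 1000 bp
   input, L = 75.
2. **Protein projection** — a learnable affine map x2 = W_p e_p + b_p taking
   each TF's d2-dimensional protein-language-model embedding into the d1
   DNA feature space.
3. **Cross-attention fusion** — projected TF vectors act as queries over
   keys/values derived from H (softmax(q K^T / sqrt(d_head)) V per head,
   heads concatenated and output-projected); the attended rows are
   mean-pooled into a TF-aware summary z, and per-label affine heads score
   the concatenation [x1; z].

The multilabel model scores every experiment at once, each query using its
experiment's TF embedding. The pairwise variant runs the same stack with a
single query and one shared output head, so it can score an arbitrary
(TF embedding, DNA window) pair — including TFs whose labels were never in
training. Alternative fusion strategies (plain concatenation, bidirectional
cross-attention) and encoder ablations are configuration switches.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np

from .nn import (
    BiLSTM,
    Conv1d,
    Dense,
    Module,
    MultiheadAttention,
    Tensor,
    TransformerEncoderLayer,
    concat,
    dropout,
    max_pool1d,
    relu,
)

__all__ = [
    "ModelConfig",
    "DNARepresentation",
    "DNAEncoder",
    "TransBindModel",
    "PairwiseTransBind",
    "regularize_embedding",
    "save_checkpoint",
    "load_checkpoint",
]

FUSION_MODES = ("cross_attention", "bidirectional", "concat")
ENCODER_MODES = ("full", "lstm_only", "transformer_only", "sequence_only")


@dataclass
class ModelConfig:
    input_len: int = 1000
    conv_filters: int = 320
    conv_kernel: int = 26
    pool_window: int = 13
    lstm_hidden_per_dir: int = 160
    lstm_layers: int = 2
    transformer_heads: int = 16
    transformer_ffn: int = 1024
    d2: int = 1280
    cross_attn_heads: int = 16
    attn_dim: int | None = None  # defaults to d1
    dropout_p: float = 0.088
    n_labels: int = 690
    fusion_mode: str = "cross_attention"
    encoder_mode: str = "full"
    mask_prob: float = 0.05
    noise_sigma: float = 0.01
    seed: int = 0

    @property
    def d1(self) -> int:
        return 2 * self.lstm_hidden_per_dir

    @property
    def d(self) -> int:
        return self.attn_dim if self.attn_dim is not None else self.d1

    @property
    def effective_length(self) -> int:
        return (self.input_len - self.conv_kernel + 1) // self.pool_window

    def validate(self):
        if self.input_len < self.conv_kernel:
            raise ValueError("input_len shorter than convolution kernel")
        if self.effective_length < 1:
            raise ValueError("pooled sequence length would be < 1")
        if self.d % self.cross_attn_heads:
            raise ValueError("attention dim not divisible by cross_attn_heads")
        if self.d1 % self.transformer_heads:
            raise ValueError("d1 not divisible by transformer_heads")
        if self.fusion_mode not in FUSION_MODES:
            raise ValueError(f"fusion_mode must be one of {FUSION_MODES}")
        if self.encoder_mode not in ENCODER_MODES:
            raise ValueError(f"encoder_mode must be one of {ENCODER_MODES}")
        return self


@dataclass
class DNARepresentation:
    H: np.ndarray  # (B, L, d1)
    x1: np.ndarray  # (B, d1), the position-mean of H


class DNAEncoder(Module):
    """Convolution + pooling, then BiLSTM and/or transformer per config."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.conv = Conv1d(4, cfg.conv_filters, cfg.conv_kernel, rng)
        self.use_lstm = cfg.encoder_mode in ("full", "lstm_only")
        self.use_transformer = cfg.encoder_mode in ("full", "transformer_only")
        if self.use_lstm:
            self.lstm = BiLSTM(cfg.conv_filters, cfg.lstm_hidden_per_dir,
                               cfg.lstm_layers, rng)
        elif cfg.conv_filters != cfg.d1:
            # bring pooled conv features to the d1 channel width
            self.adapter = Dense(cfg.conv_filters, cfg.d1, rng)
        if self.use_transformer:
            self.transformer = TransformerEncoderLayer(
                cfg.d1, cfg.transformer_heads, cfg.transformer_ffn,
                cfg.dropout_p, rng,
            )

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None,
                 training: bool = False) -> tuple[Tensor, Tensor]:
        cfg = self.cfg
        if x.shape[1] < cfg.conv_kernel:
            raise ValueError("input shorter than convolution kernel")
        h = relu(self.conv(x))
        h = max_pool1d(h, cfg.pool_window)
        if training and rng is not None:
            h = dropout(h, cfg.dropout_p, rng, training)
        if self.use_lstm:
            h = self.lstm(h)
            if training and rng is not None:
                h = dropout(h, cfg.dropout_p, rng, training)
        elif hasattr(self, "adapter"):
            h = self.adapter(h)
        if self.use_transformer:
            h = self.transformer(h, rng or np.random.default_rng(0), training)
        x1 = h.mean(axis=1)
        return h, x1

    def encode(self, onehot: np.ndarray) -> DNARepresentation:
        """Eval-mode convenience on a raw (B, L, 4) array."""
        H, x1 = self(Tensor(np.asarray(onehot, dtype=float)))
        return DNARepresentation(H.data, x1.data)


class _FusionCore(Module):
    """Encoder + protein projection + fusion; shared by both model variants."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.encoder = DNAEncoder(cfg, rng)
        self.project = Dense(cfg.d2, cfg.d1, rng)  # x2 = W_p e_p + b_p
        if cfg.fusion_mode in ("cross_attention", "bidirectional"):
            self.cross = MultiheadAttention(cfg.d1, cfg.d1, cfg.d,
                                            cfg.cross_attn_heads, rng)
        if cfg.fusion_mode == "bidirectional":
            self.cross_rev = MultiheadAttention(cfg.d1, cfg.d1, cfg.d,
                                                cfg.cross_attn_heads, rng)

    def fuse(self, x: Tensor, queries: Tensor,
             rng: np.random.Generator | None, training: bool
             ) -> tuple[Tensor, Tensor]:
        """queries: (B, T, d1) projected TF vectors. Returns (x1, z-parts)."""
        H, x1 = self.encoder(x, rng, training)
        cfg = self.cfg
        if cfg.fusion_mode == "concat":
            z = queries.mean(axis=1)  # mean-projected TF features, no attention
        else:
            attended = self.cross(queries, H)  # (B, T, d)
            z = attended.mean(axis=1)
            if cfg.fusion_mode == "bidirectional":
                rev = self.cross_rev(H, queries)  # DNA queries attend the TF set
                z = concat([z, rev.mean(axis=1)], axis=-1)
        return x1, z


def _head_width(cfg: ModelConfig) -> int:
    base = cfg.d1 + (cfg.d1 if cfg.fusion_mode == "concat" else cfg.d)
    if cfg.fusion_mode == "bidirectional":
        base += cfg.d
    return base


class TransBindModel(Module):
    """Multilabel classifier: one logit per TF-cell-type experiment.

    `tf_embeddings` is the (E, d2) matrix of per-experiment protein
    embeddings (the same TF's vector duplicated across its cell types); all
    E queries are processed in one cross-attention pass.
    """

    def __init__(self, cfg: ModelConfig, tf_embeddings: np.ndarray):
        super().__init__()
        cfg.validate()
        tf_embeddings = np.asarray(tf_embeddings, dtype=float)
        if tf_embeddings.shape != (cfg.n_labels, cfg.d2):
            raise ValueError(
                f"tf_embeddings must be ({cfg.n_labels}, {cfg.d2}), "
                f"got {tf_embeddings.shape}"
            )
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.tf_embeddings = Tensor(tf_embeddings)  # fixed input, not trained
        self.core = _FusionCore(cfg, rng)
        self.head = Dense(_head_width(cfg), cfg.n_labels, rng)

    def __call__(self, x: Tensor | np.ndarray,
                 rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
        B = x.shape[0]
        x2 = self.core.project(self.tf_embeddings)  # (E, d1)
        E, d1 = x2.shape
        queries = x2.reshape(1, E, d1) + Tensor(np.zeros((B, 1, 1)))
        x1, z = self.core.fuse(x, queries, rng, training)
        return self.head(concat([x1, z], axis=-1))

    def predict(self, onehot: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Eval-mode binding probabilities, (N, E)."""
        outs = []
        for i in range(0, len(onehot), batch_size):
            logits = self(np.asarray(onehot[i : i + batch_size], dtype=float))
            outs.append(1.0 / (1.0 + np.exp(-logits.data)))
        return np.vstack(outs)


class PairwiseTransBind(Module):
    """Single-pair variant: (DNA window, one TF embedding) -> one logit.

    Identical stack with T = 1 and a shared affine head, so the model can
    score TFs absent from the training label set (label-zero-shot use).
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cfg = replace(cfg, fusion_mode="cross_attention")
        cfg.validate()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.core = _FusionCore(cfg, rng)
        self.head = Dense(_head_width(cfg), 1, rng)

    def __call__(self, x: Tensor | np.ndarray, e_p: Tensor | np.ndarray,
                 rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
        e_p = e_p if isinstance(e_p, Tensor) else Tensor(np.asarray(e_p, dtype=float))
        if e_p.ndim != 2 or e_p.shape[1] != self.cfg.d2:
            raise ValueError(f"embedding batch must be (B, {self.cfg.d2})")
        x2 = self.core.project(e_p)  # (B, d1)
        B, d1 = x2.shape
        queries = x2.reshape(B, 1, d1)
        x1, z = self.core.fuse(x, queries, rng, training)
        logits = self.head(concat([x1, z], axis=-1))
        return logits.reshape(B)

    def predict(self, onehot: np.ndarray, embeddings: np.ndarray,
                batch_size: int = 256) -> np.ndarray:
        outs = []
        for i in range(0, len(onehot), batch_size):
            logits = self(
                np.asarray(onehot[i : i + batch_size], dtype=float),
                np.asarray(embeddings[i : i + batch_size], dtype=float),
            )
            outs.append(1.0 / (1.0 + np.exp(-logits.data)))
        return np.concatenate(outs)


def regularize_embedding(x_batch: np.ndarray, mask_prob: float,
                         noise_sigma: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Training-time protein-embedding regularization.

    Each sample's whole embedding is zeroed with probability `mask_prob`;
    unmasked embeddings receive independent element-wise Gaussian noise of
    standard deviation `noise_sigma`. Discourages memorizing TF identity.
    """
    x_batch = np.asarray(x_batch, dtype=float)
    out = x_batch.copy()
    masked = rng.random(len(out)) < mask_prob
    if noise_sigma > 0:
        out[~masked] += rng.normal(scale=noise_sigma,
                                   size=out[~masked].shape)
    out[masked] = 0.0
    return out


def save_checkpoint(model: Module, path: str, extra: dict | None = None):
    """Model weights + config as a portable .npz (config JSON embedded)."""
    state = model.state_dict()
    meta = {"config": asdict(model.cfg), "class": type(model).__name__}
    if isinstance(model, TransBindModel):
        state["__tf_embeddings__"] = model.tf_embeddings.data
    if extra:
        meta["extra"] = extra
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path: str):
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        cfg = ModelConfig(**meta["config"])
        state = {k: npz[k] for k in npz.files if not k.startswith("__")}
        if meta["class"] == "TransBindModel":
            emb = npz["__tf_embeddings__"]
            model = TransBindModel(cfg, emb)
        else:
            model = PairwiseTransBind(cfg)
        model.load_state_dict(state)
    return model
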