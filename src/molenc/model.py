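"""Model architectures.

* :class:`TwoEncoderModel` — encoder 1 reads the unmasked canonical SMILES
  and yields a molecular embedding at the cls position; encoder 2 reads a
  heavily masked (usually differently spelled) sequence with that embedding
  injected at position 0 in place of the cls token, and predicts the
  original symbol at every masked slot.  The token-embedding table is
  shared between the two encoders; all other weights are independent.
* :class:`BertMlmModel` — a single encoder recovering masked symbols from
  context alone.
* :class:`PropertyPredictor` — the first encoder (or the MLM encoder) plus
  a two-layer fully connected head on the molecular embedding.

Loss and recovery accuracy are computed over masked positions only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import nn
from .pretrain_data import PairBatch
from .tokenizer import TokenSequence, Vocabulary

__all__ = [
    "EncoderConfig", "ModelBundle",
    "TwoEncoderModel", "BertMlmModel", "PropertyPredictor",
    "encode_first", "decode_second", "mlm_forward",
    "predict_property", "pooled_embedding",
    "save_bundle", "load_bundle",
]


@dataclass
class EncoderConfig:
    """Encoder hyperparameters.

    Full-scale settings are 8-10 layers, 8-16 heads and embedding
    dimension 128-256; tiny values are legitimate for desk-scale runs.
    ``max_positions`` defaults to 102: cls + 100 symbols, with one spare
    slot for the injected molecular embedding in the second encoder.
    """

    n_layers: int = 2
    n_heads: int = 4
    embed_dim: int = 64
    dropout: float = 0.1
    max_positions: int = 102
    vocab_size: int = 0
    ffn_mult: int = 4
    pre_norm: bool = True

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        for f in ("n_layers", "n_heads", "embed_dim", "max_positions"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


class TwoEncoderModel:
    """Dual-encoder pretraining architecture."""

    def __init__(self, cfg: EncoderConfig, rng_seed=0):
        if cfg.vocab_size <= 3:
            raise ValueError("vocab_size must include observed symbols")
        self.cfg = cfg
        rng = np.random.default_rng(rng_seed) if not isinstance(
            rng_seed, np.random.Generator) else rng_seed
        self.token_emb = nn.Embedding(cfg.vocab_size, cfg.embed_dim, rng, "tok")
        self.enc1 = nn.TransformerEncoder(
            self.token_emb, cfg.n_layers, cfg.embed_dim, cfg.n_heads,
            cfg.dropout, cfg.max_positions, rng, cfg.ffn_mult, "enc1",
            pre_norm=cfg.pre_norm)
        self.enc2 = nn.TransformerEncoder(
            self.token_emb, cfg.n_layers, cfg.embed_dim, cfg.n_heads,
            cfg.dropout, cfg.max_positions, rng, cfg.ffn_mult, "enc2",
            pre_norm=cfg.pre_norm)
        self.out_proj = nn.Dense(cfg.embed_dim, cfg.vocab_size, rng, "out")

    def params(self) -> List[nn.Parameter]:
        return (self.token_emb.params() + self.enc1.params(own_only=True)
                + self.enc2.params(own_only=True) + self.out_proj.params())

    def forward(self, batch: PairBatch, training: bool = False):
        h1 = self.enc1.forward(batch.enc1_ids, batch.enc1_lengths, training=training)
        mol = h1[:, 0, :]
        h2 = self.enc2.forward(batch.enc2_ids, batch.enc2_lengths,
                               inject=mol, training=training)
        return self.out_proj.forward(h2)

    def backward(self, d_logits: np.ndarray) -> None:
        d_h2 = self.out_proj.backward(d_logits)
        d_mol = self.enc2.backward(d_h2)
        d_h1 = np.zeros(
            (d_logits.shape[0], self._enc1_T, self.cfg.embed_dim),
            dtype=d_logits.dtype)
        d_h1[:, 0, :] = d_mol
        self.enc1.backward(d_h1)

    def loss_and_grads(self, batch: PairBatch, training: bool = True):
        self._enc1_T = batch.enc1_ids.shape[1]
        logits = self.forward(batch, training=training)
        loss, d_logits, n_correct, n_masked = nn.masked_cross_entropy(
            logits, batch.target_ids, batch.mask_flags)
        if training:
            self.backward(d_logits)
        return loss, n_correct, n_masked


class BertMlmModel:
    """Single-encoder masked-language-model baseline."""

    def __init__(self, cfg: EncoderConfig, rng_seed=0):
        if cfg.vocab_size <= 3:
            raise ValueError("vocab_size must include observed symbols")
        self.cfg = cfg
        rng = np.random.default_rng(rng_seed) if not isinstance(
            rng_seed, np.random.Generator) else rng_seed
        self.token_emb = nn.Embedding(cfg.vocab_size, cfg.embed_dim, rng, "tok")
        self.enc1 = nn.TransformerEncoder(
            self.token_emb, cfg.n_layers, cfg.embed_dim, cfg.n_heads,
            cfg.dropout, cfg.max_positions, rng, cfg.ffn_mult, "enc1",
            pre_norm=cfg.pre_norm)
        self.out_proj = nn.Dense(cfg.embed_dim, cfg.vocab_size, rng, "out")

    def params(self) -> List[nn.Parameter]:
        return (self.token_emb.params() + self.enc1.params(own_only=True)
                + self.out_proj.params())

    def forward(self, batch: PairBatch, training: bool = False):
        h = self.enc1.forward(batch.enc2_ids, batch.enc2_lengths, training=training)
        return self.out_proj.forward(h)

    def backward(self, d_logits: np.ndarray) -> None:
        d_h = self.out_proj.backward(d_logits)
        self.enc1.backward(d_h)

    def loss_and_grads(self, batch: PairBatch, training: bool = True):
        logits = self.forward(batch, training=training)
        loss, d_logits, n_correct, n_masked = nn.masked_cross_entropy(
            logits, batch.target_ids, batch.mask_flags)
        if training:
            self.backward(d_logits)
        return loss, n_correct, n_masked


class PredictionHead:
    """Two fully connected layers on the molecular embedding."""

    def __init__(self, embed_dim: int, n_out: int, rng: np.random.Generator):
        self.fc1 = nn.Dense(embed_dim, embed_dim, rng, "head.fc1")
        self.fc2 = nn.Dense(embed_dim, n_out, rng, "head.fc2")

    def params(self) -> List[nn.Parameter]:
        return self.fc1.params() + self.fc2.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pre = self.fc1.forward(x)
        return self.fc2.forward(nn.relu(self._pre))

    def backward(self, d: np.ndarray) -> np.ndarray:
        d_h = self.fc2.backward(d)
        return self.fc1.backward(d_h * nn._relu_grad(self._pre))


class PropertyPredictor:
    """Encoder + head for binary, regression or multi-label tasks."""

    HEADS = ("binary", "regression", "multilabel")

    def __init__(self, cfg: EncoderConfig, head: str, n_labels: int = 1, rng_seed=0):
        if head not in self.HEADS:
            raise ValueError(f"head must be one of {self.HEADS}")
        if head != "multilabel" and n_labels != 1:
            raise ValueError(f"{head} head expects a single output")
        if head == "multilabel" and n_labels < 2:
            raise ValueError("multilabel head needs n_labels >= 2")
        self.cfg = cfg
        self.head_kind = head
        self.n_labels = n_labels
        rng = np.random.default_rng(rng_seed) if not isinstance(
            rng_seed, np.random.Generator) else rng_seed
        self.token_emb = nn.Embedding(cfg.vocab_size, cfg.embed_dim, rng, "tok")
        self.enc1 = nn.TransformerEncoder(
            self.token_emb, cfg.n_layers, cfg.embed_dim, cfg.n_heads,
            cfg.dropout, cfg.max_positions, rng, cfg.ffn_mult, "enc1",
            pre_norm=cfg.pre_norm)
        self.head = PredictionHead(cfg.embed_dim, n_labels, rng)

    def params(self) -> List[nn.Parameter]:
        return (self.token_emb.params() + self.enc1.params(own_only=True)
                + self.head.params())

    def forward(self, ids: np.ndarray, lengths: np.ndarray,
                training: bool = False) -> np.ndarray:
        h = self.enc1.forward(ids, lengths, training=training)
        raw = self.head.forward(h[:, 0, :])
        if self.head_kind in ("binary", "multilabel"):
            return 1.0 / (1.0 + np.exp(-raw))
        return raw

    def loss_and_grads(self, ids: np.ndarray, lengths: np.ndarray,
                       y: np.ndarray, training: bool = True) -> Tuple[float, np.ndarray]:
        """BCE for classification heads, MSE for regression; returns
        (loss, predictions)."""
        preds = self.forward(ids, lengths, training=training)
        B = preds.shape[0]
        y = np.asarray(y, dtype=np.float64).reshape(preds.shape)
        if self.head_kind == "regression":
            loss = float(((preds - y) ** 2).mean())
            d_raw = 2.0 * (preds - y) / preds.size
        else:
            eps = 1e-12
            loss = float(-(y * np.log(preds + eps)
                           + (1 - y) * np.log(1 - preds + eps)).mean())
            # combined sigmoid+BCE gradient w.r.t. pre-sigmoid output
            d_raw = (preds - y) / preds.size
        if training:
            d_cls = self.head.backward(d_raw.astype(nn.DTYPE))
            d_h = np.zeros((B, ids.shape[1], self.cfg.embed_dim),
                           dtype=nn.DTYPE)
            d_h[:, 0, :] = d_cls
            self.enc1.backward(d_h)
        return loss, preds


@dataclass
class ModelBundle:
    """A model plus everything needed to reuse it safely.

    The vocabulary hash guards against fine-tuning a checkpoint with a
    different symbol inventory.
    """

    architecture: str  # two_encoder | bert_mlm | predictor
    config: EncoderConfig
    model: object
    vocab: Vocabulary

    def __post_init__(self):
        if self.architecture not in ("two_encoder", "bert_mlm", "predictor"):
            raise ValueError(f"unknown architecture {self.architecture!r}")

    @property
    def vocab_hash(self) -> str:
        return self.vocab.content_hash()


def encode_first(seq: TokenSequence, bundle: ModelBundle):
    """Molecular embedding (cls output) and per-position embeddings."""
    model = bundle.model
    ids = seq.ids[None, :]
    if ids.shape[1] > bundle.config.max_positions:
        raise ValueError("sequence longer than max positions")
    h = model.enc1.forward(ids, np.array([seq.length]), training=False)
    return h[0, 0, :].copy(), h[0, : seq.length, :].copy()


def decode_second(mol_embedding: np.ndarray, masked: TokenSequence,
                  bundle: ModelBundle) -> np.ndarray:
    """Per-position vocabulary logits from the second encoder."""
    if bundle.architecture != "two_encoder":
        raise ValueError("decode_second requires a two_encoder bundle")
    model = bundle.model
    if mol_embedding.shape[-1] != bundle.config.embed_dim:
        raise ValueError("molecular embedding dimension mismatch")
    if not np.any(masked.ids[: masked.length] == bundle.vocab.mask_id):
        raise ValueError("masked sequence contains no mask token")
    h = model.enc2.forward(masked.ids[None, :], np.array([masked.length]),
                           inject=mol_embedding[None, :], training=False)
    return model.out_proj.forward(h)[0]


def mlm_forward(masked: TokenSequence, bundle: ModelBundle) -> np.ndarray:
    if bundle.architecture != "bert_mlm":
        raise ValueError("mlm_forward requires a bert_mlm bundle")
    model = bundle.model
    h = model.enc1.forward(masked.ids[None, :], np.array([masked.length]),
                           training=False)
    return model.out_proj.forward(h)[0]


def predict_property(seq: TokenSequence, bundle: ModelBundle) -> np.ndarray:
    if bundle.architecture != "predictor":
        raise ValueError("predict_property requires a predictor bundle")
    out = bundle.model.forward(seq.ids[None, :], np.array([seq.length]))
    return out[0]


def pooled_embedding(seq: TokenSequence, bundle: ModelBundle) -> np.ndarray:
    """Mean of per-position outputs over non-pad, non-cls positions."""
    if seq.content_length < 1:
        raise ValueError("sequence has no content symbols")
    model = bundle.model
    h = model.enc1.forward(seq.ids[None, :], np.array([seq.length]), training=False)
    return h[0, 1 : seq.length, :].mean(axis=0)


def predictor_from_pretrained(bundle: ModelBundle, head: str,
                              n_labels: int = 1, rng_seed=0) -> ModelBundle:
    """Keep the first encoder of a pretrained bundle; add a fresh head.

    Encoder and token-embedding weights are copied bit-for-bit.
    """
    if bundle.architecture not in ("two_encoder", "bert_mlm"):
        raise ValueError("expected a pretrained two_encoder or bert_mlm bundle")
    pred = PropertyPredictor(bundle.config, head, n_labels, rng_seed)
    src = dict(zip(_param_names(bundle.model), bundle.model.params()))
    for name, p in zip(_param_names(pred), pred.params()):
        if name in src and not name.startswith("head."):
            p.data = src[name].data.copy()
    return ModelBundle("predictor", bundle.config, pred, bundle.vocab)


def _param_names(model) -> List[str]:
    return [p.name for p in model.params()]


_ARCH_CLASSES = {
    "two_encoder": TwoEncoderModel,
    "bert_mlm": BertMlmModel,
}


def save_bundle(bundle: ModelBundle, path) -> None:
    """Checkpoint: weights plus embedded config and vocabulary hash."""
    meta = {
        "architecture": bundle.architecture,
        "config": asdict(bundle.config),
        "vocab_hash": bundle.vocab_hash,
    }
    if bundle.architecture == "predictor":
        meta["head"] = bundle.model.head_kind
        meta["n_labels"] = bundle.model.n_labels
    arrays = {f"param_{i}": p.data for i, p in enumerate(bundle.model.params())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_bundle(path, vocab: Vocabulary) -> ModelBundle:
    """Load a checkpoint; refuses a vocabulary whose hash mismatches."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = {k: data[k] for k in data.files if k.startswith("param_")}
    if meta["vocab_hash"] != vocab.content_hash():
        raise ValueError(
            "vocabulary hash mismatch: checkpoint was trained with a "
            "different symbol inventory")
    cfg = EncoderConfig(**meta["config"])
    if meta["architecture"] == "predictor":
        m = PropertyPredictor(cfg, meta["head"], meta["n_labels"])
    else:
        m = _ARCH_CLASSES[meta["architecture"]](cfg)
    for i, p in enumerate(m.params()):
        p.data = arrays[f"param_{i}"].astype(np.float64)
    return ModelBundle(meta["architecture"], cfg, m, vocab)
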