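"""Training loops: pretraining, fine-tuning regimes, embedding export.

Pretraining resamples alternative spellings and mask sets every epoch and
logs masked-symbol recovery accuracy; the best-so-far weights are kept.
Fine-tuning supports the layer-freezing regimes (last two encoder layers +
head at lr 1e-3, last layer + head at 7e-4, head only at 1e-4) plus a
fully trained non-pretrained baseline, evaluated by k-fold cross-validation
with the fold mean reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import chem, metrics, nn
from .model import (EncoderConfig, ModelBundle, BertMlmModel, TwoEncoderModel,
                    PropertyPredictor, predictor_from_pretrained)
from .pretrain_data import (PairBatch, PretrainConfig, alternate_pool,
                            make_mlm_example, make_pair, pair_batches)
from .tokenizer import Vocabulary, build_vocab, encode, tokenize

__all__ = [
    "FinetuneConfig", "pretrain", "evaluate_recovery", "finetune",
    "extract_embeddings", "trainable_params",
]

#: Regime -> default learning rate.
REGIME_LR = {
    "last2_head": 1e-3,
    "last1_head": 7e-4,
    "head_only": 1e-4,
    "full": 1e-3,
}


@dataclass
class FinetuneConfig:
    regime: str = "last1_head"
    learning_rate: Optional[float] = None
    task: str = "binary"               # binary | regression | multilabel
    metric: str = "AUROC"
    epochs: int = 30
    folds: int = 5
    batch_size: int = 32
    max_len: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.regime not in REGIME_LR:
            raise ValueError(f"regime must be one of {sorted(REGIME_LR)}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.learning_rate is None:
            self.learning_rate = REGIME_LR[self.regime]


def _resolve_corpus(corpus) -> List[str]:
    if isinstance(corpus, (str, bytes)) or hasattr(corpus, "read"):
        return chem.read_corpus(corpus)
    return list(corpus)


def _alt_pools(corpus: List[str], cfg: PretrainConfig):
    if cfg.alternates_per_molecule is None:
        return None
    return {s: alternate_pool(s, cfg.alternates_per_molecule, cfg.pool_seed)
            for s in corpus}


def _make_examples(corpus: List[str], vocab: Vocabulary, arch: str,
                   cfg: PretrainConfig, rng: np.random.Generator,
                   source: str = "default", pools=None):
    """Build one epoch of examples.

    source='default': canonical for MLM, alt_prob-governed for the dual
    encoder (drawing from precomputed pools when configured).
    source='enumerated': force a fresh uniformly random alternative
    spelling (for held-out-spelling evaluation).  source='canonical': no
    alternates.
    """
    pairs = []
    for s in corpus:
        if arch == "two_encoder":
            if source == "default":
                alts = pools.get(s) if pools is not None else None
                pairs.append(make_pair(s, vocab, cfg, rng, alternates=alts))
            else:
                alt = 1.0 if source == "enumerated" else 0.0
                c = PretrainConfig(mask_rate=cfg.mask_rate, alt_prob=alt,
                                   max_len=cfg.max_len)
                pairs.append(make_pair(s, vocab, c, rng))
        else:
            src = s
            if source == "enumerated":
                for _ in range(20):
                    cand = chem.enumerate_smiles(s, rng)
                    if cand != s:
                        src = cand
                        break
            mcfg = PretrainConfig(mask_rate=cfg.mask_rate, alt_prob=0.0,
                                  max_len=cfg.max_len)
            pairs.append(make_mlm_example(src, vocab, mcfg, rng))
    return pairs


def _encoded_sources(smiles: List[str], vocab: Vocabulary, arch: str,
                     cfg: PretrainConfig, pools):
    """Pre-tokenized (enc1, [enc2 source variants]) per molecule.

    Only valid when the enc2 source set is fixed (MLM, or precomputed
    alternate pools); masks are the only per-epoch randomness left.
    """
    templates = {}
    for s in smiles:
        enc1 = encode(tokenize(s), vocab, max_len=cfg.max_len)
        if arch == "two_encoder" and pools is not None:
            variants = [encode(tokenize(a), vocab, max_len=cfg.max_len)
                        for a in pools[s]]
        else:
            variants = []
        templates[s] = (enc1, variants)
    return templates


def _fast_pairs(smiles: List[str], templates, arch: str,
                cfg: PretrainConfig, rng: np.random.Generator):
    from .pretrain_data import PretrainPair, sample_mask_positions
    from .tokenizer import TokenSequence

    pairs = []
    for s in smiles:
        enc1, variants = templates[s]
        src = enc1
        alt_used = False
        if arch == "two_encoder" and variants and rng.random() < cfg.alt_prob:
            src = variants[int(rng.integers(len(variants)))]
            alt_used = True
        positions = sample_mask_positions(src.content_length, cfg.mask_rate, rng)
        targets = src.ids[positions].copy()
        masked = TokenSequence(src.ids.copy(), src.length)
        masked.ids[positions] = 2  # mask id (reserved)
        pairs.append(PretrainPair(enc1, masked, targets, positions, alt_used))
    return pairs


def pretrain(corpus, arch: str, cfg: PretrainConfig, enc_cfg: EncoderConfig,
             log=None, eval_every: int = 10, patience: int = 8,
             ema_decay: Optional[float] = 0.999,
             cooldown_epochs: int = 200) -> Tuple[ModelBundle, List[Dict]]:
    """Pretrain either architecture on a one-SMILES-per-line corpus.

    Each epoch resamples alternates and mask sets, takes Adam steps at
    ``cfg.learning_rate`` and records the in-training recovery accuracy.
    An exponential moving average of the weights (decay ``ema_decay``;
    None disables) smooths late-training noise; every ``eval_every``
    epochs the averaged weights' masked-symbol recovery accuracy is
    measured in evaluation mode on a rotating mask realization and the
    best-scoring weights are checkpointed.  Once that accuracy has not
    improved for ``patience`` consecutive evaluations (or the epoch
    budget runs out), a cooldown phase of up to ``cooldown_epochs``
    linearly decays the learning rate to zero, which settles the weights
    into a sharper optimum.  Returns the bundle holding the best weights
    plus the full history (per-epoch loss/accuracy and periodic
    ``eval_accuracy``).
    """
    if arch not in ("two_encoder", "bert_mlm"):
        raise ValueError("arch must be 'two_encoder' or 'bert_mlm'")
    smiles = _resolve_corpus(corpus)
    if not smiles:
        raise ValueError("corpus is empty")
    vocab = build_vocab(smiles)
    enc_cfg = dc_replace(enc_cfg, vocab_size=len(vocab))
    rng = np.random.default_rng(cfg.rng_seed)
    eval_seed = int(rng.integers(2 ** 31))
    model_cls = TwoEncoderModel if arch == "two_encoder" else BertMlmModel
    model = model_cls(enc_cfg, rng_seed=rng)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    bundle = ModelBundle(arch, enc_cfg, model, vocab)

    history: List[Dict] = []
    best_acc, best_state = -1.0, None
    stale = 0
    pools = _alt_pools(smiles, cfg)
    # fixed source sets allow caching all tokenization up front
    fast = arch == "bert_mlm" or pools is not None
    templates = (_encoded_sources(smiles, vocab, arch, cfg, pools)
                 if fast else None)
    ema = ([p.data.copy() for p in model.params()]
           if ema_decay is not None else None)

    def swapped_in(weights):
        saved = [p.data for p in model.params()]
        for p, w in zip(model.params(), weights):
            p.data = w
        return saved

    order = np.arange(len(smiles))
    cooldown_left = -1  # -1: main phase; >=0: epochs of lr decay remaining
    epoch = 0
    while epoch < cfg.epochs + cooldown_epochs:
        if cooldown_left == 0:
            break
        if cooldown_left > 0:
            opt.lr = cfg.learning_rate * cooldown_left / max(cooldown_epochs, 1)
            cooldown_left -= 1
        rng.shuffle(order)
        shuffled = [smiles[i] for i in order]
        if fast:
            pairs = _fast_pairs(shuffled, templates, arch, cfg, rng)
        else:
            pairs = _make_examples(shuffled, vocab, arch, cfg, rng, pools=pools)
        # length-bucketed batches (less padding), visited in random order
        pairs.sort(key=lambda p: p.enc2_ids.length)
        batches = pair_batches(pairs, cfg.batch_size)
        rng.shuffle(batches)
        total_loss, n_correct, n_masked = 0.0, 0, 0
        for batch in batches:
            opt.zero_grad()
            loss, c, m = model.loss_and_grads(batch, training=True)
            opt.step()
            if ema is not None:
                for e, p in zip(ema, model.params()):
                    e *= ema_decay
                    e += (1.0 - ema_decay) * p.data
            total_loss += loss * m
            n_correct += c
            n_masked += m
        rec = {"epoch": epoch, "loss": total_loss / n_masked,
               "accuracy": n_correct / n_masked}
        last_of_phase = (cooldown_left == 1
                         or epoch == cfg.epochs + cooldown_epochs - 1)
        if (epoch + 1) % eval_every == 0 or last_of_phase:
            # rotate the eval mask realization so best-checkpoint selection
            # does not overfit one fixed mask set
            saved = swapped_in(ema) if ema is not None else None
            acc = evaluate_recovery(bundle, smiles, cfg,
                                    rng_seed=(eval_seed + epoch) % 2 ** 31)
            if saved is not None:
                weights = [p.data for p in model.params()]
                for p, w in zip(model.params(), saved):
                    p.data = w
            else:
                weights = [p.data.copy() for p in model.params()]
            rec["eval_accuracy"] = acc
            if acc > best_acc + 1e-4:
                best_acc = acc
                best_state = [w.copy() for w in weights]
                stale = 0
            else:
                stale += 1
        history.append(rec)
        if log is not None:
            log(rec)
        epoch += 1
        if cooldown_left < 0 and (stale >= patience or epoch >= cfg.epochs):
            cooldown_left = cooldown_epochs
            stale = -10 ** 9  # patience no longer ends training
    # final selection: the cooled (averaged) weights vs the best checkpoint,
    # judged on a more precise multi-realization evaluation
    final_weights = [w.copy() for w in (ema if ema is not None
                                        else [p.data for p in model.params()])]
    candidates = [final_weights]
    if best_state is not None:
        candidates.append(best_state)
    scored = []
    for weights in candidates:
        saved = swapped_in(weights)
        acc = evaluate_recovery(bundle, smiles, cfg,
                                rng_seed=(eval_seed + 7) % 2 ** 31, n_repeats=3)
        for p, w in zip(model.params(), saved):
            p.data = w
        scored.append(acc)
    chosen = candidates[int(np.argmax(scored))]
    for p, w in zip(model.params(), chosen):
        p.data = w
    return bundle, history


def evaluate_recovery(bundle: ModelBundle, corpus, cfg: PretrainConfig,
                      rng_seed=0, source: str = "default",
                      n_repeats: int = 1) -> float:
    """Masked-symbol recovery accuracy in evaluation mode.

    source='enumerated' evaluates on freshly enumerated spellings the
    model never saw verbatim; masks are drawn from ``rng_seed``.
    """
    smiles = _resolve_corpus(corpus)
    rng = np.random.default_rng(rng_seed)
    pools = _alt_pools(smiles, cfg) if source == "default" else None
    n_correct, n_masked = 0, 0
    for _ in range(n_repeats):
        pairs = _make_examples(smiles, bundle.vocab, bundle.architecture,
                               cfg, rng, source=source, pools=pools)
        pairs.sort(key=lambda p: p.enc2_ids.length)
        for batch in pair_batches(pairs, cfg.batch_size):
            _, c, m = bundle.model.loss_and_grads(batch, training=False)
            n_correct += c
            n_masked += m
    return n_correct / n_masked


def trainable_params(model: PropertyPredictor, regime: str) -> List[nn.Parameter]:
    """Parameter groups updated under each freezing regime."""
    if regime == "full":
        return model.params()
    head = model.head.params()
    if regime == "head_only":
        return head
    n = 1 if regime == "last1_head" else 2
    layer_params: List[nn.Parameter] = []
    for layer in model.enc1.layers[-n:]:
        layer_params += layer.params()
    return layer_params + head


def _encode_dataset(smiles: List[str], vocab: Vocabulary, max_len: int):
    seqs = [encode(tokenize(s), vocab, max_len=max_len) for s in smiles]
    T = max(sq.length for sq in seqs)
    ids = np.zeros((len(seqs), T), dtype=np.int64)
    lengths = np.zeros(len(seqs), dtype=np.int64)
    for i, sq in enumerate(seqs):
        ids[i, : sq.length] = sq.ids[: sq.length]
        lengths[i] = sq.length
    return ids, lengths


def _cv_splits(y: np.ndarray, task: str, folds: int, seed: int):
    from sklearn.model_selection import KFold, StratifiedKFold

    if task == "binary":
        kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        return list(kf.split(np.zeros(len(y)), y))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(kf.split(np.zeros(len(y))))


def finetune(pretrained: Optional[ModelBundle], data, cfg: FinetuneConfig,
             log=None) -> Tuple[ModelBundle, metrics.MetricReport]:
    """k-fold cross-validated fine-tuning.

    ``pretrained`` may be a two_encoder or bert_mlm bundle (its first
    encoder is kept); pass None with regime='full' for the non-pretrained
    baseline.  Returns the model trained on the final fold and the
    per-fold metric report.
    """
    if pretrained is None and cfg.regime != "full":
        raise ValueError("frozen regimes require a pretrained bundle")
    smiles, y = list(data.smiles), np.asarray(data.labels, dtype=np.float64)
    vocab = pretrained.vocab if pretrained is not None else data.vocab
    if pretrained is not None and hasattr(data, "vocab_hash") and data.vocab_hash:
        if data.vocab_hash != pretrained.vocab_hash:
            raise ValueError("vocabulary hash mismatch")
    ids, lengths = _encode_dataset(smiles, vocab, cfg.max_len)
    n_labels = y.shape[1] if (cfg.task == "multilabel" and y.ndim == 2) else 1
    head = {"binary": "binary", "regression": "regression",
            "multilabel": "multilabel"}[cfg.task]
    metric_fn = metrics.METRIC_FUNCS.get(cfg.metric)

    report = metrics.MetricReport(metric=cfg.metric)
    rng = np.random.default_rng(cfg.seed)
    bundle = None
    strat_y = y if cfg.task == "binary" else y[:, 0] if y.ndim == 2 else y
    for fold_idx, (train_idx, test_idx) in enumerate(
            _cv_splits(strat_y, cfg.task, cfg.folds, cfg.seed)):
        if pretrained is not None:
            bundle = predictor_from_pretrained(
                pretrained, head, n_labels, rng_seed=int(rng.integers(2 ** 31)))
        else:
            enc_cfg = dc_replace(data.encoder_config, vocab_size=len(vocab))
            model = PropertyPredictor(enc_cfg, head, n_labels,
                                      rng_seed=int(rng.integers(2 ** 31)))
            bundle = ModelBundle("predictor", enc_cfg, model, vocab)
        model = bundle.model
        opt = nn.Adam(trainable_params(model, cfg.regime), lr=cfg.learning_rate)
        tr = np.array(train_idx)
        for epoch in range(cfg.epochs):
            rng.shuffle(tr)
            for start in range(0, len(tr), cfg.batch_size):
                sel = tr[start : start + cfg.batch_size]
                opt.zero_grad()
                model.loss_and_grads(ids[sel], lengths[sel], y[sel], training=True)
                opt.step()
        preds = model.forward(ids[test_idx], lengths[test_idx], training=False)
        y_test = y[test_idx]
        if cfg.task == "multilabel":
            macro, micro = metrics.f1_scores(preds, y_test)
            report.fold_values.append(macro)
            report.notes.append(f"fold{fold_idx} micro_f1 {micro:.6f}")
        else:
            preds = preds.reshape(-1)
            try:
                value = metric_fn(preds, y_test.reshape(-1))
            except metrics.UndefinedMetricError as exc:
                report.notes.append(f"fold{fold_idx} skipped: {exc}")
                continue
            report.fold_values.append(float(value))
        if log is not None:
            log({"fold": fold_idx, "value": report.fold_values[-1]
                 if report.fold_values else None})
    if not report.fold_values:
        raise ValueError("every fold was skipped; metric undefined throughout")
    return bundle, report


def extract_embeddings(bundle: ModelBundle, smiles: Sequence[str]):
    """Embedding matrix (n x embed_dim) plus per-molecule metadata.

    cls embeddings for two_encoder-derived bundles and predictors; average
    pooling over symbol outputs for the MLM baseline.  Metadata columns:
    ring_count (cyclomatic), six_ring_count (benzene-ring proxy on the
    synthetic subset) and molecular weight.
    """
    import pandas as pd

    from .model import encode_first, pooled_embedding

    rows = []
    meta = []
    for s in smiles:
        seq = encode(tokenize(s), bundle.vocab, max_len=100)
        if bundle.architecture == "bert_mlm":
            vec = pooled_embedding(seq, bundle)
        else:
            vec, _ = encode_first(seq, bundle)
        rows.append(vec)
        try:
            g = chem.parse_smiles(s)
            meta.append({
                "smiles": s,
                "ring_count": chem.synthetic_labels(g, "ring_count"),
                "six_ring_count": chem.six_membered_ring_count(g),
                "mol_weight": g.molecular_weight(),
            })
        except chem.SmilesError:
            meta.append({"smiles": s, "ring_count": None,
                         "six_ring_count": None, "mol_weight": None})
    return np.vstack(rows), pd.DataFrame(meta)
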