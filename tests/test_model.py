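"""Architecture contracts: shapes, masking invariances, determinism."""

import numpy as np
import pytest

from molenc import nn
from molenc.model import (BertMlmModel, EncoderConfig, ModelBundle,
                          PropertyPredictor, TwoEncoderModel, decode_second,
                          encode_first, load_bundle, mlm_forward,
                          pooled_embedding, predict_property,
                          predictor_from_pretrained, save_bundle)
from molenc.pretrain_data import PretrainConfig, make_pair, pair_batches
from molenc.tokenizer import encode, tokenize


@pytest.fixture
def two_encoder_bundle(small_vocab):
    cfg = EncoderConfig(n_layers=2, n_heads=2, embed_dim=16, dropout=0.1,
                        vocab_size=len(small_vocab), ffn_mult=2)
    return ModelBundle("two_encoder", cfg, TwoEncoderModel(cfg, rng_seed=0),
                       small_vocab)


@pytest.fixture
def mlm_bundle(small_vocab):
    cfg = EncoderConfig(n_layers=2, n_heads=2, embed_dim=16, dropout=0.1,
                        vocab_size=len(small_vocab), ffn_mult=2)
    return ModelBundle("bert_mlm", cfg, BertMlmModel(cfg, rng_seed=0),
                       small_vocab)


def _seq(s, vocab, pad_to=None):
    return encode(tokenize(s), vocab, max_len=100, pad_to=pad_to)


class TestEncodeFirst:
    def test_embedding_shape(self, two_encoder_bundle, small_vocab):
        emb, per_pos = encode_first(_seq("CC(=O)CC", small_vocab),
                                    two_encoder_bundle)
        assert emb.shape == (16,)
        assert per_pos.shape == (9, 16)
        assert np.isfinite(emb).all()

    def test_padding_invariance(self, two_encoder_bundle, small_vocab):
        a, _ = encode_first(_seq("CC(=O)CC", small_vocab), two_encoder_bundle)
        b, _ = encode_first(_seq("CC(=O)CC", small_vocab, pad_to=40),
                            two_encoder_bundle)
        assert np.allclose(a, b, atol=1e-5)

    def test_batch_order_permutation(self, two_encoder_bundle, small_vocab, rng):
        model = two_encoder_bundle.model
        ids = np.stack([_seq(s, small_vocab, pad_to=12).ids
                        for s in ["CCO", "CC(=O)CC", "OCC"]])
        lengths = np.array([4, 9, 4])
        out = model.enc1.forward(ids, lengths, training=False)
        perm = np.array([2, 0, 1])
        out_p = model.enc1.forward(ids[perm], lengths[perm], training=False)
        assert np.allclose(out[perm], out_p, atol=1e-5)

    def test_eval_mode_determinism(self, two_encoder_bundle, small_vocab):
        a, _ = encode_first(_seq("CCO", small_vocab), two_encoder_bundle)
        b, _ = encode_first(_seq("CCO", small_vocab), two_encoder_bundle)
        assert (a == b).all()

    def test_too_long_sequence_rejected(self, two_encoder_bundle, small_vocab):
        from molenc.tokenizer import TokenSequence
        ids = np.ones(150, dtype=np.int64)
        ids[0] = small_vocab.cls_id
        with pytest.raises(ValueError, match="max positions|longer"):
            encode_first(TokenSequence(ids, 150), two_encoder_bundle)


class TestDecodeSecond:
    def test_logit_shape(self, two_encoder_bundle, small_vocab):
        seq = _seq("CC(=O)CC", small_vocab)
        masked = _seq("CC(=O)CC", small_vocab)
        masked.ids[2] = small_vocab.mask_id
        emb, _ = encode_first(seq, two_encoder_bundle)
        logits = decode_second(emb, masked, two_encoder_bundle)
        assert logits.shape == (len(masked.ids), len(small_vocab))

    def test_embedding_conditioning_is_live(self, two_encoder_bundle, small_vocab):
        seq = _seq("CC(=O)CC", small_vocab)
        masked = _seq("CC(=O)CC", small_vocab)
        masked.ids[2] = small_vocab.mask_id
        emb, _ = encode_first(seq, two_encoder_bundle)
        a = decode_second(emb, masked, two_encoder_bundle)
        b = decode_second(np.zeros_like(emb), masked, two_encoder_bundle)
        assert not np.allclose(a[2], b[2], atol=1e-6)

    def test_dimension_mismatch_error(self, two_encoder_bundle, small_vocab):
        masked = _seq("CCO", small_vocab)
        masked.ids[1] = small_vocab.mask_id
        with pytest.raises(ValueError, match="dimension"):
            decode_second(np.zeros(7), masked, two_encoder_bundle)

    def test_requires_mask_token(self, two_encoder_bundle, small_vocab):
        seq = _seq("CCO", small_vocab)
        emb, _ = encode_first(seq, two_encoder_bundle)
        with pytest.raises(ValueError, match="mask"):
            decode_second(emb, seq, two_encoder_bundle)


class TestMlmForward:
    def test_shape_and_determinism(self, mlm_bundle, small_vocab):
        masked = _seq("CC(=O)CC", small_vocab)
        masked.ids[3] = small_vocab.mask_id
        a = mlm_forward(masked, mlm_bundle)
        b = mlm_forward(masked, mlm_bundle)
        assert a.shape == (9, len(small_vocab))
        assert (a == b).all()


class TestPropertyPredictor:
    def test_binary_head_range(self, small_vocab):
        cfg = EncoderConfig(n_layers=1, n_heads=2, embed_dim=16,
                            vocab_size=len(small_vocab), ffn_mult=2)
        bundle = ModelBundle("predictor", cfg,
                             PropertyPredictor(cfg, "binary", rng_seed=0),
                             small_vocab)
        out = predict_property(_seq("CCO", small_vocab), bundle)
        assert out.shape == (1,) and 0.0 <= out[0] <= 1.0

    def test_multilabel_head_98_outputs(self, small_vocab):
        cfg = EncoderConfig(n_layers=1, n_heads=2, embed_dim=16,
                            vocab_size=len(small_vocab), ffn_mult=2)
        bundle = ModelBundle("predictor", cfg,
                             PropertyPredictor(cfg, "multilabel", 98, rng_seed=0),
                             small_vocab)
        out = predict_property(_seq("CCO", small_vocab), bundle)
        assert out.shape == (98,)
        assert ((out >= 0) & (out <= 1)).all()

    def test_zeroed_final_layer_gives_half(self, small_vocab):
        cfg = EncoderConfig(n_layers=1, n_heads=2, embed_dim=16,
                            vocab_size=len(small_vocab), ffn_mult=2)
        model = PropertyPredictor(cfg, "binary", rng_seed=0)
        model.head.fc2.W.data[...] = 0.0
        model.head.fc2.b.data[...] = 0.0
        bundle = ModelBundle("predictor", cfg, model, small_vocab)
        out = predict_property(_seq("CCO", small_vocab), bundle)
        assert out[0] == pytest.approx(0.5)

    def test_head_shape_validation(self, small_vocab):
        cfg = EncoderConfig(n_layers=1, n_heads=2, embed_dim=16,
                            vocab_size=len(small_vocab))
        with pytest.raises(ValueError):
            PropertyPredictor(cfg, "binary", n_labels=3)
        with pytest.raises(ValueError):
            PropertyPredictor(cfg, "spectral")


class TestPooledEmbedding:
    def test_single_token_equals_its_embedding(self, mlm_bundle, small_vocab):
        seq = _seq("C", small_vocab)
        pooled = pooled_embedding(seq, mlm_bundle)
        h = mlm_bundle.model.enc1.forward(seq.ids[None, :], np.array([2]),
                                          training=False)
        assert np.allclose(pooled, h[0, 1], atol=1e-6)

    def test_pad_length_invariance(self, mlm_bundle, small_vocab):
        a = pooled_embedding(_seq("CC(=O)CC", small_vocab), mlm_bundle)
        b = pooled_embedding(_seq("CC(=O)CC", small_vocab, pad_to=30), mlm_bundle)
        assert np.allclose(a, b, atol=1e-5)


class TestBundleLifecycle:
    def test_predictor_shares_first_encoder_weights(self, two_encoder_bundle):
        pred = predictor_from_pretrained(two_encoder_bundle, "binary")
        src = {p.name: p for p in two_encoder_bundle.model.params()}
        for p in pred.model.params():
            if p.name in src and not p.name.startswith("head."):
                assert (p.data == src[p.name].data).all()

    def test_checkpoint_round_trip(self, tmp_path, two_encoder_bundle,
                                   small_vocab):
        path = tmp_path / "ckpt.npz"
        save_bundle(two_encoder_bundle, path)
        loaded = load_bundle(path, small_vocab)
        for a, b in zip(loaded.model.params(),
                        two_encoder_bundle.model.params()):
            assert (a.data == b.data).all()

    def test_checkpoint_vocab_hash_guard(self, tmp_path, two_encoder_bundle):
        from molenc.tokenizer import build_vocab
        path = tmp_path / "ckpt.npz"
        save_bundle(two_encoder_bundle, path)
        other = build_vocab(["CCN"])
        with pytest.raises(ValueError, match="hash"):
            load_bundle(path, other)

    def test_loss_decreases_on_fixed_batch(self, small_vocab):
        cfg = EncoderConfig(n_layers=1, n_heads=2, embed_dim=16, dropout=0.0,
                            vocab_size=len(small_vocab), ffn_mult=2)
        model = TwoEncoderModel(cfg, rng_seed=0)
        pcfg = PretrainConfig(mask_rate=0.5, alt_prob=0.0)
        pairs = [make_pair(s, small_vocab, pcfg, rng_seed=i)
                 for i, s in enumerate(["CC(=O)CC", "OCC", "CCCC"])]
        (batch,) = pair_batches(pairs, 8)
        opt = nn.Adam(model.params(), lr=1e-3)
        first, _, _ = model.loss_and_grads(batch, training=True)
        opt.step()
        for _ in range(30):
            opt.zero_grad()
            last, _, _ = model.loss_and_grads(batch, training=True)
            opt.step()
        assert last < first
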