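"""Construction of masked pretraining examples.

Two regimes are supported:

* the dual-encoder pair — encoder 1 receives the unmasked canonical
  SMILES; encoder 2 receives a heavily masked sequence whose source is,
  with probability ``alt_prob`` (default 0.8), an alternative spelling of
  the same molecule rather than the canonical string;
* the plain masked-language-model example — a single masked canonical
  sequence, at a much lower default mask rate (0.1).

Masking always draws exactly ``max(1, round(rate * L))`` distinct content
positions (never cls, never padding) and replaces them with the mask ID;
original IDs are recorded as recovery targets before masking.  Alternates
and mask sets are meant to be resampled every epoch.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import chem
from .tokenizer import TokenSequence, Vocabulary, encode, tokenize

__all__ = [
    "PretrainConfig",
    "PretrainPair",
    "sample_mask_positions",
    "alternate_pool",
    "make_pair",
    "make_mlm_example",
    "pair_batches",
]

_MAX_ALT_DRAWS = 20


@dataclass
class PretrainConfig:
    """Pretraining hyperparameters.

    mask_rate: fraction of content symbols masked in the second-encoder
        input (0.5 for the dual-encoder objective, 0.1 for the MLM
        baseline).
    alt_prob: per-example probability that the masked sequence is an
        alternative spelling instead of the canonical one.
    """

    mask_rate: float = 0.5
    alt_prob: float = 0.8
    learning_rate: float = 3e-4
    dropout: float = 0.1
    max_len: int = 100
    epochs: int = 200
    batch_size: int = 16
    rng_seed: int = 0
    #: None -> a fresh uniform-random spelling every draw; an integer K ->
    #: each molecule gets a fixed pool of K precomputed alternates (the
    #: desk-scale setting; see docs/methods.md).
    alternates_per_molecule: Optional[int] = None
    #: seed for the precomputed alternate pools, independent of rng_seed so
    #: training and evaluation agree on the pools.
    pool_seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.mask_rate < 1.0):
            raise ValueError("mask_rate must be in (0, 1)")
        if not (0.0 <= self.alt_prob <= 1.0):
            raise ValueError("alt_prob must be in [0, 1]")
        if self.alternates_per_molecule is not None \
                and self.alternates_per_molecule < 1:
            raise ValueError("alternates_per_molecule must be >= 1 or None")


@dataclass
class PretrainPair:
    """One training example.

    enc1_ids: unmasked canonical sequence (unused by the MLM regime).
    enc2_ids: masked sequence; equals the unmasked alternate everywhere
        except at mask_positions, where the ID is the mask ID.
    targets: original IDs at mask_positions, aligned 1:1.
    """

    enc1_ids: TokenSequence
    enc2_ids: TokenSequence
    targets: np.ndarray
    mask_positions: np.ndarray
    alt_used: bool = False

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=np.int64)
        self.mask_positions = np.asarray(self.mask_positions, dtype=np.int64)
        if len(self.mask_positions) == 0:
            raise ValueError("mask_positions must be non-empty")
        if len(self.targets) != len(self.mask_positions):
            raise ValueError("targets must align with mask_positions")


def sample_mask_positions(length: int, rate: float, rng_seed=0) -> np.ndarray:
    """Exactly max(1, round(rate*length)) distinct positions in 1..length.

    ``length`` counts content symbols; returned indices index into the
    cls-prefixed sequence, so position 0 (cls) is never drawn.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 < rate < 1.0):
        raise ValueError("rate must be in (0, 1)")
    rng = chem._as_rng(rng_seed)
    k = max(1, int(round(rate * length)))
    positions = rng.choice(np.arange(1, length + 1), size=k, replace=False)
    return np.sort(positions)


def _mask_sequence(
    source: str,
    vocab: Vocabulary,
    cfg: PretrainConfig,
    rng: np.random.Generator,
    pad_to: int | None = None,
) -> tuple[TokenSequence, np.ndarray, np.ndarray]:
    seq = encode(tokenize(source), vocab, max_len=cfg.max_len, pad_to=pad_to)
    positions = sample_mask_positions(seq.content_length, cfg.mask_rate, rng)
    targets = seq.ids[positions].copy()
    masked = TokenSequence(seq.ids.copy(), seq.length)
    masked.ids[positions] = vocab.mask_id
    return masked, targets, positions


def alternate_pool(canonical: str, k: int, pool_seed: int = 0) -> List[str]:
    """Up to ``k`` distinct precomputed alternate spellings of a molecule.

    The pool is a deterministic function of (canonical string, pool_seed),
    so independently constructed pools agree across processes.  Molecules
    with fewer than ``k`` distinct alternative spellings yield a shorter
    (possibly empty) pool.
    """
    seed = (zlib.crc32(canonical.encode()) + pool_seed) % (2 ** 31)
    rng = np.random.default_rng(seed)
    alts: List[str] = []
    for _ in range(_MAX_ALT_DRAWS * k):
        cand = chem.enumerate_smiles(canonical, rng)
        if cand != canonical and cand not in alts:
            alts.append(cand)
        if len(alts) >= k:
            break
    return alts


def make_pair(
    canonical: str,
    vocab: Vocabulary,
    cfg: PretrainConfig,
    rng_seed=0,
    pad_to: int | None = None,
    alternates: Optional[Sequence[str]] = None,
) -> PretrainPair:
    """Dual-encoder example from one canonical SMILES.

    With probability ``cfg.alt_prob`` the masked sequence derives from an
    alternative spelling; the alternate is drawn from ``alternates`` when a
    precomputed pool is supplied, otherwise freshly enumerated (redrawn
    until it differs textually, when the molecule admits one).
    """
    rng = chem._as_rng(rng_seed)
    enc1 = encode(tokenize(canonical), vocab, max_len=cfg.max_len, pad_to=pad_to)
    source = canonical
    alt_used = False
    if rng.random() < cfg.alt_prob:
        if alternates is not None:
            if len(alternates):
                source = alternates[int(rng.integers(len(alternates)))]
                alt_used = source != canonical
        else:
            for _ in range(_MAX_ALT_DRAWS):
                candidate = chem.enumerate_smiles(canonical, rng)
                if candidate != canonical:
                    source = candidate
                    alt_used = True
                    break
    enc2, targets, positions = _mask_sequence(source, vocab, cfg, rng, pad_to=pad_to)
    return PretrainPair(enc1, enc2, targets, positions, alt_used=alt_used)


def make_mlm_example(
    canonical: str,
    vocab: Vocabulary,
    cfg: PretrainConfig | None = None,
    rng_seed=0,
    pad_to: int | None = None,
) -> PretrainPair:
    """Single-sequence masked-LM example (default mask rate 0.1).

    ``enc1_ids`` mirrors the masked sequence's unmasked form for interface
    uniformity but is unused by the MLM model.
    """
    if cfg is None:
        cfg = PretrainConfig(mask_rate=0.1, alt_prob=0.0)
    rng = chem._as_rng(rng_seed)
    enc1 = encode(tokenize(canonical), vocab, max_len=cfg.max_len, pad_to=pad_to)
    enc2, targets, positions = _mask_sequence(canonical, vocab, cfg, rng, pad_to=pad_to)
    return PretrainPair(enc1, enc2, targets, positions, alt_used=False)


@dataclass
class PairBatch:
    """Dense arrays for one minibatch of PretrainPairs."""

    enc1_ids: np.ndarray       # (B, T1)
    enc1_lengths: np.ndarray   # (B,)
    enc2_ids: np.ndarray       # (B, T2)
    enc2_lengths: np.ndarray   # (B,)
    target_ids: np.ndarray     # (B, T2) original IDs at masked slots, -1 elsewhere
    mask_flags: np.ndarray     # (B, T2) bool

    @property
    def n_masked(self) -> int:
        return int(self.mask_flags.sum())


def pair_batches(pairs: Sequence[PretrainPair], batch_size: int) -> List[PairBatch]:
    """Pack pairs into batches padded to each batch's longest sequence."""
    batches: List[PairBatch] = []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        t1 = max(p.enc1_ids.length for p in chunk)
        t2 = max(p.enc2_ids.length for p in chunk)
        B = len(chunk)
        enc1 = np.zeros((B, t1), dtype=np.int64)
        enc2 = np.zeros((B, t2), dtype=np.int64)
        len1 = np.zeros(B, dtype=np.int64)
        len2 = np.zeros(B, dtype=np.int64)
        tgt = np.full((B, t2), -1, dtype=np.int64)
        flags = np.zeros((B, t2), dtype=bool)
        for b, p in enumerate(chunk):
            enc1[b, : p.enc1_ids.length] = p.enc1_ids.ids[: p.enc1_ids.length]
            enc2[b, : p.enc2_ids.length] = p.enc2_ids.ids[: p.enc2_ids.length]
            len1[b] = p.enc1_ids.length
            len2[b] = p.enc2_ids.length
            tgt[b, p.mask_positions] = p.targets
            flags[b, p.mask_positions] = True
        batches.append(PairBatch(enc1, len1, enc2, len2, tgt, flags))
    return batches
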