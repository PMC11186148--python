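"""Symbol-level SMILES tokenization and vocabulary handling.

Tokens are the individual SMILES symbols: one- and two-character element
symbols, bracket atoms as whole units, ring-closure digits (including the
two-digit ``%NN`` form), bond and branch punctuation, and the stereo marks
``/ \\ @ @@``.  This granularity matches symbol-level masked-language-model
pipelines and is deliberately not a subword/BPE scheme.

Sequences fed to the encoders are truncated to the first ``max_len``
symbols, prefixed with a ``cls`` token (which does not count against the
budget), and padded to a fixed batch length.  Symbols absent from the
pretraining vocabulary are mapped to the mask ID rather than rejected.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "PAD", "CLS", "MASK",
    "TokenizationError",
    "tokenize",
    "Vocabulary",
    "build_vocab",
    "TokenSequence",
    "encode",
]

PAD, CLS, MASK = "<pad>", "<cls>", "<mask>"
_RESERVED = (PAD, CLS, MASK)

# Longest-match-first scan: bracket atoms whole, two-character elements,
# '@@', '%NN' ring closures, then any single character.
_TOKEN_RE = re.compile(r"(\[[^\[\]]*\]|Br|Cl|@@|%\d\d|.)")


class TokenizationError(ValueError):
    pass


def tokenize(s: str) -> List[str]:
    """Split a SMILES string into its symbols.

    The concatenation of the returned tokens reproduces ``s`` exactly.
    """
    if not s:
        raise TokenizationError("empty SMILES")
    tokens: List[str] = []
    pos = 0
    while pos < len(s):
        ch = s[pos]
        if ch == "[":
            end = s.find("]", pos)
            if end < 0:
                raise TokenizationError(f"unterminated '[' at position {pos}")
            tokens.append(s[pos : end + 1])
            pos = end + 1
            continue
        if ch == "]":
            raise TokenizationError(f"unmatched ']' at position {pos}")
        m = _TOKEN_RE.match(s, pos)
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


@dataclass(frozen=True)
class Vocabulary:
    """Dense symbol→ID map with reserved pad/cls/mask entries.

    Reserved IDs come first (pad=0, cls=1, mask=2); observed symbols follow
    in sorted order, so an identical corpus always yields identical IDs.
    """

    symbol_to_id: Dict[str, int]

    @property
    def pad_id(self) -> int:
        return self.symbol_to_id[PAD]

    @property
    def cls_id(self) -> int:
        return self.symbol_to_id[CLS]

    @property
    def mask_id(self) -> int:
        return self.symbol_to_id[MASK]

    def __len__(self) -> int:
        return len(self.symbol_to_id)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbol_to_id

    def id_of(self, symbol: str) -> int:
        """ID of a symbol; unseen symbols map to the mask ID."""
        return self.symbol_to_id.get(symbol, self.mask_id)

    def id_to_symbol(self) -> Dict[int, str]:
        return {i: s for s, i in self.symbol_to_id.items()}

    def content_hash(self) -> str:
        """Stable fingerprint used to guard checkpoint/vocabulary pairing."""
        payload = "\n".join(
            f"{s}\t{i}" for s, i in sorted(self.symbol_to_id.items(), key=lambda kv: kv[1])
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for sym, idx in sorted(self.symbol_to_id.items(), key=lambda kv: kv[1]):
                fh.write(f"{sym}\t{idx}\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        mapping: Dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                sym, idx = line.split("\t")
                mapping[sym] = int(idx)
        vocab = cls(mapping)
        vocab._check()
        return vocab

    def _check(self) -> None:
        ids = sorted(self.symbol_to_id.values())
        if ids != list(range(len(ids))):
            raise ValueError("vocabulary IDs must be dense 0..n-1")
        for r, want in zip(_RESERVED, range(3)):
            if self.symbol_to_id.get(r) != want:
                raise ValueError(f"reserved token {r} must have ID {want}")


def build_vocab(corpus: Iterable[str]) -> Vocabulary:
    """Vocabulary of every symbol observed in the corpus plus reserved IDs."""
    symbols = set()
    n = 0
    for s in corpus:
        n += 1
        symbols.update(tokenize(s))
    if n == 0:
        raise ValueError("corpus is empty")
    mapping = {r: i for i, r in enumerate(_RESERVED)}
    for k, sym in enumerate(sorted(symbols)):
        mapping[sym] = 3 + k
    return Vocabulary(mapping)


@dataclass
class TokenSequence:
    """cls-prefixed, truncated, optionally padded ID sequence.

    ``ids[0]`` is always cls; ``length`` counts the non-pad prefix
    (cls included); no pad precedes a non-pad ID.
    """

    ids: np.ndarray
    length: int

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.ids.ndim != 1:
            raise ValueError("ids must be 1-D")
        if not (1 <= self.length <= len(self.ids)):
            raise ValueError("length out of range")

    @property
    def content_length(self) -> int:
        """Number of real symbols (cls excluded)."""
        return self.length - 1

    def attention_mask(self) -> np.ndarray:
        m = np.zeros(len(self.ids), dtype=bool)
        m[: self.length] = True
        return m


def encode(
    tokens: Sequence[str],
    vocab: Vocabulary,
    max_len: int = 100,
    pad_to: int | None = None,
) -> TokenSequence:
    """Encode symbols to IDs: truncate to ``max_len``, map unseen symbols
    to the mask ID, prepend cls, pad with pad IDs up to ``pad_to`` total.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    kept = list(tokens)[:max_len]
    ids = [vocab.cls_id] + [vocab.id_of(t) for t in kept]
    length = len(ids)
    total = pad_to if pad_to is not None else length
    if total < length:
        raise ValueError("pad_to smaller than encoded length")
    ids = ids + [vocab.pad_id] * (total - length)
    return TokenSequence(np.array(ids, dtype=np.int64), length)
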