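"""Single-nucleotide tokenizer.

Byte-level BPE trained at a merge length of one nucleotide degenerates to a
fixed character vocabulary, so the tokenizer is its closed form: one token
per base plus the usual specials. The per-base resolution is what makes
base-level attribution possible downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

PAD, BOS, EOS, UNK, MASK = "<pad>", "<s>", "</s>", "<unk>", "<mask>"
MASK_CHAR = "?"  # decode() renders <mask> as this character

TOKENS: tuple[str, ...] = (PAD, BOS, EOS, UNK, MASK, "A", "C", "G", "T", "N")


@dataclass(frozen=True)
class Vocabulary:
    """Fixed token vocabulary with contiguous ids in listed order."""

    tokens: tuple[str, ...] = TOKENS

    @property
    def size(self) -> int:
        return len(self.tokens)

    def id(self, token: str) -> int:
        return self.tokens.index(token)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"tokens": list(self.tokens)}, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        with open(path) as fh:
            data = json.load(fh)
        return cls(tuple(data["tokens"]))


_DEFAULT = Vocabulary()
PAD_ID = _DEFAULT.id(PAD)
BOS_ID = _DEFAULT.id(BOS)
EOS_ID = _DEFAULT.id(EOS)
UNK_ID = _DEFAULT.id(UNK)
MASK_ID = _DEFAULT.id(MASK)
_BASE_IDS = {b: _DEFAULT.id(b) for b in "ACGTN"}


@dataclass
class TokenSequence:
    """Token ids with an attention mask (1 on non-PAD entries)."""

    ids: np.ndarray
    attention_mask: np.ndarray


def encode(sequence: str, max_len: int) -> TokenSequence:
    """BOS + one token per base + EOS, padded to ``max_len``.

    Characters outside the vocabulary map to UNK with a warning. A
    sequence longer than ``max_len - 2`` is a hard error — silent
    truncation would desynchronise positions from attribution output.
    """
    seq = sequence.upper()
    if len(seq) > max_len - 2:
        raise ValueError(
            f"sequence of length {len(seq)} does not fit max_len={max_len} "
            "(need room for BOS/EOS; no silent truncation)"
        )
    ids = np.full(max_len, PAD_ID, dtype=np.int64)
    ids[0] = BOS_ID
    n_unk = 0
    for i, ch in enumerate(seq):
        tid = _BASE_IDS.get(ch)
        if tid is None:
            tid = UNK_ID
            n_unk += 1
        ids[1 + i] = tid
    ids[1 + len(seq)] = EOS_ID
    if n_unk:
        log.warning("encode: %d characters outside {A,C,G,T,N} mapped to %s", n_unk, UNK)
    mask = (ids != PAD_ID).astype(np.int64)
    return TokenSequence(ids, mask)


def encode_batch(sequences: Sequence[str], max_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Stacked ids and attention masks for a batch of sequences."""
    encoded = [encode(s, max_len) for s in sequences]
    return (
        np.stack([e.ids for e in encoded]),
        np.stack([e.attention_mask for e in encoded]),
    )


def decode(ids: Iterable[int], vocab: Vocabulary = _DEFAULT) -> str:
    """Inverse of :func:`encode` on its image: specials stripped, MASK -> '?'."""
    out = []
    for i in ids:
        i = int(i)
        if i < 0 or i >= vocab.size:
            raise ValueError(f"unknown token id {i}")
        tok = vocab.tokens[i]
        if tok in (PAD, BOS, EOS):
            continue
        if tok == MASK:
            out.append(MASK_CHAR)
        elif tok == UNK:
            out.append("N")
        else:
            out.append(tok)
    return "".join(out)
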