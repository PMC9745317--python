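"""Base-level interpretability: attention export and mutagenesis importance.

Replaces interactive attention/attribution browsers with testable tabular
output: the full layers x heads x query x key attention tensor for one
input, and a deterministic in-silico mutagenesis importance track — for
each sequence position, the largest score drop over the three alternative
bases. Special tokens (BOS/EOS/PAD) are not mutable positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import PromoterTransformer
from .encoding import encode


@dataclass
class AttentionExport:
    """Attention weights (n_layers, n_heads, T, T) with token labels."""

    weights: np.ndarray
    tokens: list[str]

    def mean_over_heads(self) -> np.ndarray:
        """Per-layer mean attention received by each key token: (n_layers, T)."""
        return self.weights.mean(axis=1).mean(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        """Long-format TSV: layer, head, query, key, query_token, key_token, weight."""
        L, H, T, _ = self.weights.shape
        layer, head, q, k = np.meshgrid(
            np.arange(L), np.arange(H), np.arange(T), np.arange(T), indexing="ij"
        )
        df = pd.DataFrame(
            {
                "layer": layer.ravel(),
                "head": head.ravel(),
                "query": q.ravel(),
                "key": k.ravel(),
                "query_token": [self.tokens[i] for i in q.ravel()],
                "key_token": [self.tokens[i] for i in k.ravel()],
                "weight": self.weights.ravel(),
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class ImportanceTrack:
    """Per-position mutagenesis importance for one sequence."""

    importance: np.ndarray
    reference_score: float
    sequence: str
    method: str = "mutagenesis"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(len(self.sequence)),
                "base": list(self.sequence),
                "importance": self.importance,
            }
        )


def export_attention(model: PromoterTransformer, sequence: str) -> AttentionExport:
    """Full attention tensor of a fitted model for one input sequence."""
    ts = encode(sequence, model.max_len_)
    logits, attn = model.encoder_.forward(
        ts.ids[None, :], ts.attention_mask[None, :], train=False, return_attention=True
    )
    tokens = [model.vocab_.tokens[i] for i in ts.ids]
    return AttentionExport(weights=attn[:, 0], tokens=tokens)


def mutagenesis_importance(model: PromoterTransformer, sequence: str) -> ImportanceTrack:
    """Occlusion-style importance: max score drop over alternative bases.

    importance[j] = max over b != seq[j] of (reference_score - score with
    base j replaced by b). Positive where any substitution hurts the
    promoter score; near zero where the model is indifferent.
    """
    seq = sequence.upper()
    variants: list[str] = [seq]
    index: list[tuple[int, int]] = []
    for j, ch in enumerate(seq):
        for b in "ACGT":
            if b != ch:
                variants.append(seq[:j] + b + seq[j + 1:])
                index.append((j, len(variants) - 1))
    scores = model.predict_proba(variants)[:, 1]
    ref = float(scores[0])
    importance = np.full(len(seq), -np.inf)
    for j, vi in index:
        importance[j] = max(importance[j], ref - scores[vi])
    return ImportanceTrack(importance=importance, reference_score=ref, sequence=seq)
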