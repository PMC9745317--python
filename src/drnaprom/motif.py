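"""Monte Carlo discriminator-enrichment motif discovery.

Random fixed-length sequences are drawn and pushed through a trained
promoter classifier used as a discriminator; sequences scoring at or above
the cutoff are kept until a target count is reached. The accepted set is
summarized as a position frequency matrix (PFM), per-position information
content, and a consensus string — exposing the sequence features the
classifier rewards. ``reverse_enrich`` keeps the lowest-scoring sequences
instead; for a classifier driven by a localized motif this direction
yields no informative positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class MonteCarloConfig:
    """Generator and acceptance settings for discriminator enrichment.

    Defaults follow the reference procedure: 50-nt sequences accepted at a
    discriminator score >= 0.99 until 500 sequences pass. ``max_draws``
    bounds runtime when the discriminator accepts (almost) nothing, which
    is the expected outcome of reverse enrichment on a well-trained model.
    The generator draws i.i.d. bases; ``gc_content`` defaults to uniform.
    """

    seq_length: int = 50
    target_accepted: int = 500
    score_cutoff: float = 0.99
    max_draws: int = 10_000_000
    gc_content: float = 0.5
    seed: int = 0
    direction: str = "promoter_enrich"  # or "reverse_enrich"
    batch_size: int = 4096

    def __post_init__(self) -> None:
        if not 0.0 < self.score_cutoff < 1.0:
            raise ValueError("score_cutoff must be in (0, 1)")
        if self.target_accepted < 1:
            raise ValueError("target_accepted must be >= 1")
        if self.direction not in ("promoter_enrich", "reverse_enrich"):
            raise ValueError("direction must be 'promoter_enrich' or 'reverse_enrich'")


class PositionFrequencyMatrix:
    """Per-position base counts over an unaligned fixed-length sequence set."""

    def __init__(self, counts: np.ndarray, n_sequences: int):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix (rows A,C,G,T)")
        if np.any(counts.sum(axis=0) != n_sequences):
            raise ValueError("every column must sum to n_sequences")
        self.counts = counts
        self.n_sequences = int(n_sequences)

    @classmethod
    def from_sequences(cls, sequences: Sequence[str]) -> "PositionFrequencyMatrix":
        if not sequences:
            raise ValueError("need at least one sequence")
        L = len(sequences[0])
        counts = np.zeros((4, L), dtype=np.int64)
        for seq in sequences:
            if len(seq) != L:
                raise ValueError("all sequences must share one length")
            for j, ch in enumerate(seq):
                counts[_BASE_INDEX[ch], j] += 1
        return cls(counts, len(sequences))

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_sequences

    def information_content(self) -> np.ndarray:
        """Per-position IC in bits: 2 + sum_b f log2 f (0 log 0 := 0)."""
        f = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(f > 0, f * np.log2(f), 0.0)
        return 2.0 + term.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.counts, index=list("ACGT"),
                          columns=[str(i) for i in range(self.length)])
        df.to_csv(path, sep="\t", index_label="base")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PositionFrequencyMatrix":
        df = pd.read_csv(path, sep="\t", index_col="base")
        counts = df.loc[list("ACGT")].to_numpy(dtype=np.int64)
        return cls(counts, int(counts[:, 0].sum()))


@dataclass
class EnrichmentResult:
    accepted: list[str]
    n_drawn: int
    acceptance_rate: float
    pfm: PositionFrequencyMatrix | None
    reached_target: bool
    config: MonteCarloConfig = field(repr=False)


ScoreFn = Callable[[list[str]], np.ndarray]


def _as_score_fn(discriminator) -> ScoreFn:
    if callable(discriminator) and not hasattr(discriminator, "predict_proba"):
        return lambda seqs: np.asarray(discriminator(seqs), dtype=float)
    return lambda seqs: np.asarray(discriminator.predict_proba(seqs)[:, 1], dtype=float)


def enrich(discriminator, config: MonteCarloConfig | None = None) -> EnrichmentResult:
    """Rejection-sample sequences the discriminator scores past the cutoff.

    ``discriminator`` is either a fitted classifier exposing
    ``predict_proba`` or a callable mapping a list of sequences to scores.
    Acceptance: score >= cutoff (``promoter_enrich``) or
    score <= 1 - cutoff (``reverse_enrich``). The draw stream is a fixed
    function of the seed, so a higher cutoff accepts a subset of a lower
    cutoff's sequences over the same draws.
    """
    cfg = config or MonteCarloConfig()
    score = _as_score_fn(discriminator)
    rng = np.random.default_rng(cfg.seed)
    gc = cfg.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    accepted: list[str] = []
    n_drawn = 0
    while len(accepted) < cfg.target_accepted and n_drawn < cfg.max_draws:
        n_batch = min(cfg.batch_size, cfg.max_draws - n_drawn)
        chars = rng.choice(_BASES, size=(n_batch, cfg.seq_length), p=p)
        seqs = ["".join(row) for row in chars.tolist()]
        scores = score(seqs)
        if cfg.direction == "promoter_enrich":
            hits = np.flatnonzero(scores >= cfg.score_cutoff)
        else:
            hits = np.flatnonzero(scores <= 1.0 - cfg.score_cutoff)
        consumed = n_batch
        for i in hits:
            accepted.append(seqs[i])
            if len(accepted) == cfg.target_accepted:
                consumed = int(i) + 1  # draws past the last acceptance don't count
                break
        n_drawn += consumed

    reached = len(accepted) >= cfg.target_accepted
    if not reached:
        log.warning(
            "enrich: only %d/%d sequences accepted after %d draws "
            "(the discriminator rarely passes the %s cutoff)",
            len(accepted), cfg.target_accepted, n_drawn, cfg.direction,
        )
    pfm = PositionFrequencyMatrix.from_sequences(accepted) if accepted else None
    rate = len(accepted) / n_drawn if n_drawn else 0.0
    return EnrichmentResult(accepted, n_drawn, rate, pfm, reached, cfg)


def consensus(
    pfm: PositionFrequencyMatrix, wildcard_threshold: float = 0.4
) -> tuple[str, np.ndarray]:
    """Consensus string (modal base or N below threshold) and per-position IC."""
    f = pfm.frequencies
    modal = np.argmax(f, axis=0)
    letters = [
        "ACGT"[m] if f[m, j] >= wildcard_threshold else "N"
        for j, m in enumerate(modal)
    ]
    return "".join(letters), pfm.information_content()
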