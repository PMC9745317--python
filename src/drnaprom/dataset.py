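"""Promoter / non-promoter training-set construction.

Promoters are the L bases directly upstream of each called TSS (the TSS
base itself is excluded; window ends at position p-1). Non-promoters are
sampled from intervals between neighbouring same-strand TSSs whose gap
exceeds twice the sequence length, keeping clear of every promoter window;
a configurable fraction of i.i.d. random sequences is added as noise, and
the final dataset is balanced 1:1 and split into train/validation/test
with an exact-duplicate leakage guard.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import DATASET_COLUMNS, GenomeSequence, TSSRecord, reverse_complement

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class LabelledSequence:
    """Fixed-length nucleotide string with label and provenance.

    ``position`` is the 0-based genomic anchor (TSS for promoters, window
    start for sampled non-promoters) or -1 for random sequences.
    """

    sequence: str
    label: str  # "promoter" | "non_promoter"
    source: str  # "upstream_of_tss" | "downstream_interval" | "random"
    replicon: str = ""
    position: int = -1
    strand: str = "."


@dataclass
class DatasetConfig:
    promoter_length: int = 50
    random_fraction: float = 0.10
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    gc_content: float | None = None  # None: use the genome's GC content
    seed: int = 0

    def __post_init__(self) -> None:
        if self.promoter_length < 20:
            raise ValueError("promoter_length must be >= 20")
        if not 0.0 <= self.random_fraction < 1.0:
            raise ValueError("random_fraction must be in [0, 1)")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")


def promoter_window(tss: TSSRecord, L: int) -> tuple[int, int]:
    """Genomic half-open interval [start, end) of the promoter for one TSS."""
    if tss.strand == "+":
        return tss.position - L, tss.position
    return tss.position + 1, tss.position + 1 + L


def extract_promoters(
    tss: Sequence[TSSRecord], genome: GenomeSequence, L: int
) -> list[LabelledSequence]:
    """L bases directly upstream of each TSS, strand-aware.

    + strand TSS at p yields genome[p-L .. p-1]; - strand yields the
    reverse complement of genome[p+1 .. p+L]. TSSs closer than L to the
    relevant replicon end are skipped (count logged); duplicate sequences
    are retained once with their multiplicity logged.
    """
    out: list[LabelledSequence] = []
    seen: dict[str, int] = {}
    skipped = 0
    for r in tss:
        if r.replicon_id != genome.replicon_id:
            continue
        start, end = promoter_window(r, L)
        if start < 0 or end > genome.length:
            skipped += 1
            continue
        seq = genome.residues[start:end]
        if r.strand == "-":
            seq = reverse_complement(seq)
        if seq in seen:
            seen[seq] += 1
            continue
        seen[seq] = 1
        out.append(
            LabelledSequence(seq, "promoter", "upstream_of_tss",
                             r.replicon_id, r.position, r.strand)
        )
    if skipped:
        log.info("extract_promoters: skipped %d TSSs within %d bases of a replicon end",
                 skipped, L)
    n_dup = sum(v - 1 for v in seen.values())
    if n_dup:
        log.info("extract_promoters: %d duplicate promoter sequences collapsed", n_dup)
    return out


def _qualifying_intervals(
    positions: np.ndarray, strand: str, L: int
) -> list[tuple[int, int]]:
    """Half-open sampling intervals between neighbouring same-strand TSSs.

    For + strand neighbours t1 < t2 with gap > 2L the sampling interval is
    [t1 + L, t2 - 2L): it starts L bases downstream of the upstream TSS and
    ends L bases short of the downstream TSS's promoter window. The minus
    strand mirrors this (downstream = decreasing coordinates).
    """
    out = []
    for t1, t2 in zip(positions[:-1], positions[1:]):
        if t2 - t1 <= 2 * L:
            continue
        if strand == "+":
            a, b = t1 + L, t2 - 2 * L
        else:
            a, b = t1 + 2 * L + 1, t2 - L + 1
        if b - a >= L:
            out.append((int(a), int(b)))
    return out


def _sample_disjoint_windows(
    interval: tuple[int, int], L: int, rng: np.random.Generator,
    max_windows: int | None,
) -> list[int]:
    """Starts of non-overlapping length-L windows inside a half-open interval."""
    a, b = interval
    span = b - a
    k = span // L
    if max_windows is not None:
        k = min(k, max_windows)
    if k <= 0:
        return []
    extra = span - k * L
    gaps = rng.multinomial(extra, np.full(k + 1, 1.0 / (k + 1)))
    starts = a + np.cumsum(gaps[:-1]) + np.arange(k) * L
    return starts.tolist()


def extract_non_promoters(
    tss: Sequence[TSSRecord],
    genome: GenomeSequence,
    L: int,
    seed: int = 0,
    max_windows_per_interval: int | None = None,
) -> list[LabelledSequence]:
    """Sample non-promoter windows from wide inter-TSS intervals.

    For each strand, every pair of neighbouring TSSs whose gap exceeds 2L
    contributes non-overlapping length-L windows sampled uniformly without
    replacement from the region starting L bases downstream of the
    upstream TSS and ending L bases short of the downstream promoter
    window. Windows intersecting any promoter window (either strand) are
    discarded. Minus-strand windows are reverse complemented.
    """
    rng = np.random.default_rng(seed)
    promoter_ivs = [promoter_window(r, L) for r in tss if r.replicon_id == genome.replicon_id]
    p_starts = np.array([iv[0] for iv in promoter_ivs], dtype=np.int64)
    p_ends = np.array([iv[1] for iv in promoter_ivs], dtype=np.int64)

    out: list[LabelledSequence] = []
    for strand in ("+", "-"):
        positions = np.sort(
            np.array(
                [r.position for r in tss
                 if r.strand == strand and r.replicon_id == genome.replicon_id],
                dtype=np.int64,
            )
        )
        if positions.size < 2:
            continue
        for interval in _qualifying_intervals(positions, strand, L):
            for s in _sample_disjoint_windows(interval, L, rng, max_windows_per_interval):
                e = s + L
                if s < 0 or e > genome.length:
                    continue
                if p_starts.size and np.any((p_starts < e) & (p_ends > s)):
                    continue  # never intersect a promoter window
                seq = genome.residues[s:e]
                if strand == "-":
                    seq = reverse_complement(seq)
                out.append(
                    LabelledSequence(seq, "non_promoter", "downstream_interval",
                                     genome.replicon_id, int(s), strand)
                )
    if not out:
        log.warning("extract_non_promoters: no qualifying inter-TSS interval found")
    return out


def add_random_sequences(
    pool: list[LabelledSequence],
    fraction: float,
    L: int,
    gc_content: float = 0.5,
    seed: int = 0,
) -> list[LabelledSequence]:
    """Append ``ceil(fraction * genomic_count)`` i.i.d. random non-promoters.

    The count is based on the number of genome-derived non-promoters in the
    pool (source ``downstream_interval``), so re-application does not
    compound.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genomic = sum(1 for s in pool if s.source == "downstream_interval")
    n_random = math.ceil(fraction * genomic)
    p = np.array([(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2])
    out = list(pool)
    for _ in range(n_random):
        seq = "".join(rng.choice(_BASES, size=L, p=p).tolist())
        out.append(LabelledSequence(seq, "non_promoter", "random"))
    return out


def _to_frame(records: Sequence[LabelledSequence]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence": [r.sequence for r in records],
            "label": [r.label for r in records],
            "source": [r.source for r in records],
            "replicon": [r.replicon for r in records],
            "position": [r.position for r in records],
            "strand": [r.strand for r in records],
        },
        columns=DATASET_COLUMNS,
    )


def balance_and_split(
    promoters: Sequence[LabelledSequence],
    non_promoter_pool: Sequence[LabelledSequence],
    config: DatasetConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """1:1-balanced, stratified train/validation/test tables.

    The non-promoter pool is shuffled and truncated to the promoter count.
    Exact duplicate strings within a class are collapsed; strings appearing
    in both classes are dropped from both (leakage guard), so no sequence
    string occurs in more than one split.
    """
    cfg = config or DatasetConfig()
    rng = np.random.default_rng(cfg.seed)

    def dedupe(records):
        seen, out = set(), []
        for r in records:
            if r.sequence not in seen:
                seen.add(r.sequence)
                out.append(r)
        return out

    pos = dedupe(promoters)
    neg = dedupe(non_promoter_pool)
    cross = {r.sequence for r in pos} & {r.sequence for r in neg}
    if cross:
        log.warning("balance_and_split: %d sequences in both classes dropped", len(cross))
        pos = [r for r in pos if r.sequence not in cross]
        neg = [r for r in neg if r.sequence not in cross]

    if len(neg) < len(pos):
        raise ValueError(
            f"non-promoter pool ({len(neg)}) smaller than promoter count ({len(pos)}); "
            "simulate a larger genome or lower the TSS cutoffs"
        )
    order = rng.permutation(len(neg))
    neg = [neg[i] for i in order[: len(pos)]]

    f_train, f_val, _ = cfg.split_fractions
    splits: dict[str, list[LabelledSequence]] = {"train": [], "val": [], "test": []}
    for records in (pos, neg):
        idx = rng.permutation(len(records))
        n = len(records)
        n_train = round(f_train * n)
        n_val = round(f_val * n)
        for j, i in enumerate(idx):
            if j < n_train:
                splits["train"].append(records[i])
            elif j < n_train + n_val:
                splits["val"].append(records[i])
            else:
                splits["test"].append(records[i])

    out = {}
    for name, records in splits.items():
        order = rng.permutation(len(records))
        out[name] = _to_frame([records[i] for i in order]).reset_index(drop=True)
    return out


def genome_gc_content(genome: GenomeSequence) -> float:
    seq = genome.residues
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    return gc / acgt if acgt else 0.5


def build_dataset(
    tss: Sequence[TSSRecord],
    genome: GenomeSequence,
    config: DatasetConfig | None = None,
) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """End-to-end builder: extract, augment, balance, split.

    Returns the split tables and a count manifest.
    """
    cfg = config or DatasetConfig()
    L = cfg.promoter_length
    promoters = extract_promoters(tss, genome, L)
    pool = extract_non_promoters(tss, genome, L, seed=cfg.seed + 1)
    gc = cfg.gc_content if cfg.gc_content is not None else genome_gc_content(genome)
    pool = add_random_sequences(pool, cfg.random_fraction, L, gc_content=gc, seed=cfg.seed + 2)
    splits = balance_and_split(promoters, pool, cfg)
    manifest = {
        "n_promoters": len(promoters),
        "n_genomic_non_promoters": sum(1 for s in pool if s.source == "downstream_interval"),
        "n_random_non_promoters": sum(1 for s in pool if s.source == "random"),
        **{f"n_{k}": len(v) for k, v in splits.items()},
    }
    return splits, manifest
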