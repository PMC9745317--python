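"""Plain-text genomics I/O with explicit coordinate conventions.

All internal coordinates are 0-based. TSV reports of TSS positions are
1-based (the convention of most annotation tables); BED output is 0-based
half-open; bedGraph input/output is 0-based half-open.

Coverage values are accepted as reals, not only integers, so that
normalized tracks can be used interchangeably with raw depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an uppercase ACGTN string."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """One replicon: an uppercase nucleotide string over {A,C,G,T,N}."""

    replicon_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.replicon_id:
            raise ValueError("replicon_id must be nonempty")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class StrandCoverageTrack:
    """Per-base read depth for one strand of one replicon under one condition.

    ``depth[i]`` is the coverage at 0-based genomic position ``i``; positions
    absent from the source bedGraph are 0.
    """

    replicon_id: str
    strand: str  # "+" or "-"
    condition: str  # "TEX_plus" or "TEX_minus"
    depth: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if np.any(self.depth < 0):
            raise ValueError("coverage depth must be non-negative")

    @property
    def length(self) -> int:
        return int(self.depth.shape[0])


@dataclass
class TSSRecord:
    """A called transcription start site.

    ``position`` is the 0-based genomic index of the first transcribed base;
    ``change_factor`` is the calibrated coverage-change ratio at that base and
    ``enrichment_ratio`` the calibrated TEX(+)/TEX(-) depth ratio.
    """

    replicon_id: str
    position: int
    strand: str
    tex_plus_depth: float
    change_factor: float
    enrichment_ratio: float


def _clean_residues(raw: str, record_id: str) -> str:
    seq = raw.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        n_bad = sum(seq.count(ch) for ch in bad)
        log.warning(
            "record %s: %d non-ACGTN characters (%s) mapped to N",
            record_id, n_bad, ",".join(sorted(bad)),
        )
        seq = "".join(ch if ch in VALID_BASES else "N" for ch in seq)
    return seq


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a multi-record FASTA into :class:`GenomeSequence` objects.

    Residues are uppercased; characters outside {A,C,G,T,N} (e.g. IUPAC
    ambiguity codes) are mapped to N with a logged warning.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeSequence(rec.id, _clean_residues(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found (empty or malformed file)")
    return records


def write_fasta(genomes: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.replicon_id}\n")
            for i in range(0, g.length, width):
                fh.write(g.residues[i:i + width] + "\n")


def read_bedgraph(
    path: str | Path,
    replicon_lengths: Mapping[str, int],
    strand: str,
    condition: str,
) -> list[StrandCoverageTrack]:
    """Densify a 4-column bedGraph into per-base coverage tracks.

    Intervals are 0-based half-open ``[start, end)``. Overlapping intervals
    are summed; uncovered bases are 0. One track is returned per replicon in
    ``replicon_lengths`` (all-zero if the file never mentions it).
    """
    path = Path(path)
    dense = {rid: np.zeros(int(n), dtype=np.float64) for rid, n in replicon_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns, got {len(parts)}")
            rid, start_s, end_s, value_s = parts[:4]
            if rid not in dense:
                raise ValueError(f"{path}:{lineno}: unknown replicon {rid!r}")
            start, end, value = int(start_s), int(end_s), float(value_s)
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative coverage value {value}")
            if start < 0 or end > dense[rid].shape[0] or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: interval [{start},{end}) out of bounds for "
                    f"replicon {rid!r} of length {dense[rid].shape[0]}"
                )
            dense[rid][start:end] += value
    return [
        StrandCoverageTrack(rid, strand, condition, arr) for rid, arr in dense.items()
    ]


def write_bedgraph(track: StrandCoverageTrack, path: str | Path) -> None:
    """Write a dense track as run-length-compressed bedGraph (zero runs omitted)."""
    depth = track.depth
    # boundaries where the value changes
    change = np.flatnonzero(np.diff(depth)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [depth.shape[0]]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            v = depth[s]
            if v != 0:
                fh.write(f"{track.replicon_id}\t{s}\t{e}\t{v:g}\n")


_TSS_COLUMNS = ["replicon", "position_1based", "strand", "depth", "change_factor", "enrichment_ratio"]


def write_tss_table(
    records: Sequence[TSSRecord], path: str | Path, bed_path: str | Path | None = None
) -> None:
    """Write called TSSs as a 1-based TSV plus a companion BED6 file.

    The BED score is the change factor rounded and clamped to 1000 (the BED
    score ceiling); BED names are sequential TSS indices.
    """
    path = Path(path)
    if bed_path is None:
        bed_path = path.with_suffix(".bed")
    df = pd.DataFrame(
        {
            "replicon": [r.replicon_id for r in records],
            "position_1based": [r.position + 1 for r in records],
            "strand": [r.strand for r in records],
            "depth": [r.tex_plus_depth for r in records],
            "change_factor": [r.change_factor for r in records],
            "enrichment_ratio": [r.enrichment_ratio for r in records],
        },
        columns=_TSS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    with open(bed_path, "w") as fh:
        for i, r in enumerate(records):
            score = min(1000, round(r.change_factor))
            fh.write(
                f"{r.replicon_id}\t{r.position}\t{r.position + 1}\tTSS_{i}\t{score}\t{r.strand}\n"
            )


def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """Inverse of :func:`write_tss_table` (TSV side)."""
    df = pd.read_csv(path, sep="\t")
    return [
        TSSRecord(
            replicon_id=str(row.replicon),
            position=int(row.position_1based) - 1,
            strand=str(row.strand),
            tex_plus_depth=float(row.depth),
            change_factor=float(row.change_factor),
            enrichment_ratio=float(row.enrichment_ratio),
        )
        for row in df.itertuples(index=False)
    ]


DATASET_COLUMNS = ["sequence", "label", "source", "replicon", "position", "strand"]


def write_dataset_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=DATASET_COLUMNS)


def read_dataset_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, dtype={"sequence": str, "label": str})
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing dataset columns {sorted(missing)}")
    return df
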