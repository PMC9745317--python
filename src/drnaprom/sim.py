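"""Synthetic dRNA-seq data generator.

Emulates the post-alignment form of a differential RNA-seq experiment: a
genome carrying promoter motifs upstream of planted transcription start
sites, and four strand-specific coverage tracks (TEX+ / TEX- on + / -) in
which the TEX(+) library shows sharp coverage step-ups exactly at the true
TSS positions that the TEX(-) control lacks.

Coverage is produced by a read-stacking model rather than per-base
independent noise: background read 5' ends are drawn per base from a
gamma-Poisson (negative-binomial-like) law and extended by a fixed fragment
length, and each TSS emits a bundle of primary-transcript reads that start
exactly at the TSS base with geometrically distributed lengths of mean
``decay_length``. The resulting per-base expectations are::

    background:  background_depth_mean
    TEX+ at TSS: background_depth_mean * tss_step_multiplier
    TEX+ at TSS+j (transcript orientation): background + step * q**j,
                 q = 1 - 1/decay_length
    TEX-:        background + tex_minus_leakage * step

with a coverage-level variance of mean + dispersion * mean**2. Because
neighbouring bases share the reads that span them, upward coverage jumps
occur essentially only where reads start -- the statistical structure the
TSS caller relies on. On the minus strand "downstream" means decreasing
coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from .io_formats import (
    GenomeSequence,
    StrandCoverageTrack,
    reverse_complement,
    write_bedgraph,
    write_fasta,
)

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dRNA-seq experiment.

    Defaults describe a deeply sequenced bacterial dRNA-seq library: a
    100 kb replicon with 200 TSSs, ~20x background depth, a tenfold primary
    transcript pile-up at each TSS of which 10% leaks into the TEX(-)
    control, and a canonical -10 element (TATAAT) planted 10 bases upstream
    of each TSS with a 10% per-base mutation rate.
    """

    genome_length: int = 100_000
    n_tss: int = 200
    strand_fraction_plus: float = 0.5
    min_tss_spacing: int = 200
    background_depth_mean: float = 20.0
    tss_step_multiplier: float = 10.0
    tex_minus_leakage: float = 0.1
    decay_length: int = 100
    noise_dispersion: float = 0.05
    read_length: int = 60  # background fragment length of the read-stacking model
    motif_consensus: str = "TATAAT"
    motif_offset: int = 10  # bases from the TSS back to the motif START
    motif_mutation_rate: float = 0.1
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("strand_fraction_plus", "tex_minus_leakage", "gc_content",
                     "motif_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0,1], got {v}")
        if self.tss_step_multiplier <= 1:
            raise ValueError("tss_step_multiplier must exceed 1")
        if self.n_tss * self.min_tss_spacing >= self.genome_length:
            raise ValueError("n_tss * min_tss_spacing must be below genome_length")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth of a simulation: one motif per planted TSS."""

    tss_positions: list[tuple[str, int, str]] = field(default_factory=list)
    motif_positions: list[tuple[str, int, str]] = field(default_factory=list)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def mutate_motif(consensus: str, rate: float, rng: np.random.Generator) -> str:
    """Consensus with each non-N base substituted w.p. ``rate`` by another base."""
    out = []
    for ch in consensus:
        if ch != "N" and rng.random() < rate:
            out.append(rng.choice([b for b in "ACGT" if b != ch]))
        else:
            out.append(ch)
    return "".join(out)


# margin kept clear of the replicon ends so promoter windows up to 200 nt fit
_EDGE_MARGIN = 250


def simulate_genome(
    config: SimulationConfig, replicon_id: str = "sim_chr"
) -> tuple[GenomeSequence, PlantedTruth]:
    """Background genome at the configured GC content with planted motifs.

    TSS positions respect ``min_tss_spacing`` (in genome coordinates, across
    both strands) and keep an edge margin so promoter windows fit. On the +
    strand the (mutated) motif occupies ``[p - offset, p - offset + len)``;
    on the - strand the mirror interval holds its reverse complement.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    bases = _random_bases(rng, cfg.genome_length, cfg.gc_content)

    truth = PlantedTruth()
    if cfg.n_tss > 0:
        slack = cfg.genome_length - 2 * _EDGE_MARGIN - (cfg.n_tss - 1) * cfg.min_tss_spacing
        if slack <= 0:
            raise ValueError(
                f"cannot place {cfg.n_tss} TSSs with spacing {cfg.min_tss_spacing} "
                f"on a genome of length {cfg.genome_length}"
            )
        offsets = np.sort(rng.integers(0, slack, size=cfg.n_tss))
        positions = _EDGE_MARGIN + offsets + np.arange(cfg.n_tss) * cfg.min_tss_spacing
        strands = np.where(rng.random(cfg.n_tss) < cfg.strand_fraction_plus, "+", "-")
        mlen = len(cfg.motif_consensus)
        for p, s in zip(positions.tolist(), strands.tolist()):
            motif = mutate_motif(cfg.motif_consensus, cfg.motif_mutation_rate, rng)
            if s == "+":
                start = p - cfg.motif_offset
                placed = motif
            else:
                start = p + cfg.motif_offset - mlen + 1
                placed = reverse_complement(motif)
            for j, ch in enumerate(placed):
                if ch != "N":  # N in the consensus leaves background
                    bases[start + j] = ch
            truth.tss_positions.append((replicon_id, p, s))
            truth.motif_positions.append((replicon_id, start, s))

    genome = GenomeSequence(replicon_id, "".join(bases.tolist()))
    return genome, truth


def _start_counts(
    rng: np.random.Generator, n: int, mean_per_base: float, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson read-start counts per base (Poisson when dispersion == 0)."""
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = mean_per_base * rng.gamma(shape, 1.0 / shape, size=n)
    else:
        lam = np.full(n, mean_per_base)
    return rng.poisson(lam).astype(np.float64)


def _stack_reads(starts: np.ndarray, read_length: int, strand: str) -> np.ndarray:
    """Coverage from fixed-length reads whose 5' ends are ``starts``.

    Plus-strand reads extend toward increasing coordinates, minus-strand
    reads toward decreasing coordinates.
    """
    if strand == "-":
        return _stack_reads(starts[::-1], read_length, "+")[::-1]
    kernel = np.ones(read_length)
    return np.convolve(starts, kernel)[: starts.shape[0]]


def _signal_profile(
    rng: np.random.Generator,
    length: int,
    tss_positions: Iterable[int],
    mean_reads: float,
    decay_length: int,
    dispersion: float,
    strand: str,
) -> np.ndarray:
    """Coverage from primary-transcript read bundles starting at each TSS."""
    cov = np.zeros(length)
    for p in tss_positions:
        if dispersion > 0:
            shape = 1.0 / dispersion
            n_reads = rng.poisson(mean_reads * rng.gamma(shape, 1.0 / shape))
        else:
            n_reads = rng.poisson(mean_reads)
        if n_reads == 0:
            continue
        lens = rng.geometric(1.0 / decay_length, size=n_reads)
        # profile[j] = number of reads still covering offset j from the TSS,
        # i.e. reads with length > j
        counts = np.bincount(lens)
        profile = (n_reads - np.cumsum(counts)[:-1]).astype(np.float64)
        if strand == "+":
            span = min(profile.shape[0], length - p)
            cov[p : p + span] += profile[:span]
        else:
            span = min(profile.shape[0], p + 1)
            cov[p - span + 1 : p + 1] += profile[:span][::-1]
    return cov


def simulate_coverage(
    genome: GenomeSequence, truth: PlantedTruth, config: SimulationConfig
) -> dict[tuple[str, str], StrandCoverageTrack]:
    """Four coverage tracks keyed by ``(condition, strand)``.

    Conditions are ``"TEX_plus"`` and ``"TEX_minus"``; each track carries
    independent background noise, and the TSS signal (expected step height
    ``background_depth_mean * (tss_step_multiplier - 1)``) appears at full
    strength in TEX(+) and scaled by ``tex_minus_leakage`` in TEX(-).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)
    n = genome.length
    start_mean = cfg.background_depth_mean / cfg.read_length
    # per-start dispersion scaled so coverage-level variance is mean + d*mean^2
    start_disp = cfg.noise_dispersion * cfg.read_length
    step_reads = cfg.background_depth_mean * (cfg.tss_step_multiplier - 1.0)

    tss_by_strand: dict[str, list[int]] = {"+": [], "-": []}
    for rid, p, s in truth.tss_positions:
        if rid == genome.replicon_id:
            tss_by_strand[s].append(p)

    tracks: dict[tuple[str, str], StrandCoverageTrack] = {}
    for condition, signal_scale in (("TEX_plus", 1.0), ("TEX_minus", cfg.tex_minus_leakage)):
        for strand in ("+", "-"):
            starts = _start_counts(rng, n, start_mean, start_disp)
            cov = _stack_reads(starts, cfg.read_length, strand)
            if signal_scale > 0 and tss_by_strand[strand]:
                cov += _signal_profile(
                    rng, n, tss_by_strand[strand], signal_scale * step_reads,
                    cfg.decay_length, cfg.noise_dispersion, strand,
                )
            tracks[(condition, strand)] = StrandCoverageTrack(
                genome.replicon_id, strand, condition, cov
            )
    return tracks


def simulate_labelled_sequences(
    n_per_class: int, length: int, config: SimulationConfig
) -> "pd.DataFrame":
    """Balanced labelled sequences for desk-scale classifier experiments.

    Positives are background sequences with the (mutated) motif planted so
    that its start sits ``motif_offset`` bases from the 3' end -- the
    position it would occupy in a promoter window ending one base before
    the TSS. Negatives are pure background. Returns a dataset table with
    the standard columns (see :data:`drnaprom.io_formats.DATASET_COLUMNS`).
    """
    import pandas as pd  # local import keeps module load light

    cfg = config
    mlen = len(cfg.motif_consensus)
    if length <= cfg.motif_offset or cfg.motif_offset < mlen:
        raise ValueError(
            "sequence length must exceed motif_offset and motif_offset must "
            "be >= motif length so the planted motif fits"
        )
    rng = np.random.default_rng(cfg.seed + 2)
    rows = []
    for _ in range(n_per_class):
        seq = _random_bases(rng, length, cfg.gc_content)
        motif = mutate_motif(cfg.motif_consensus, cfg.motif_mutation_rate, rng)
        start = length - cfg.motif_offset
        for j, ch in enumerate(motif):
            if ch != "N":
                seq[start + j] = ch
        rows.append(("".join(seq.tolist()), "promoter", "upstream_of_tss"))
    for _ in range(n_per_class):
        seq = _random_bases(rng, length, cfg.gc_content)
        rows.append(("".join(seq.tolist()), "non_promoter", "random"))
    return pd.DataFrame(
        {
            "sequence": [r[0] for r in rows],
            "label": [r[1] for r in rows],
            "source": [r[2] for r in rows],
            "replicon": "synthetic",
            "position": -1,
            "strand": ".",
        }
    )


def planted_motif_start_in_window(length: int, config: SimulationConfig) -> int:
    """0-based index of the planted motif start within a labelled sequence."""
    return length - config.motif_offset


def write_simulation(
    outdir: str | Path,
    genome: GenomeSequence,
    truth: PlantedTruth,
    tracks: dict[tuple[str, str], StrandCoverageTrack],
    config: SimulationConfig,
) -> dict[str, Path]:
    """Write genome.fasta, four bedGraph tracks, truth.bed and config JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["fasta"] = outdir / "genome.fasta"
    write_fasta([genome], paths["fasta"])

    for (condition, strand), track in tracks.items():
        tag = f"{condition}_{'fwd' if strand == '+' else 'rev'}"
        paths[tag] = outdir / f"{tag}.bedgraph"
        write_bedgraph(track, paths[tag])

    paths["truth"] = outdir / "truth.bed"
    with open(paths["truth"], "w") as fh:
        for i, (rid, p, s) in enumerate(truth.tss_positions):
            fh.write(f"{rid}\t{p}\t{p + 1}\ttrue_TSS_{i}\t0\t{s}\n")

    paths["config"] = outdir / "simulation_config.json"
    with open(paths["config"], "w") as fh:
        json.dump(asdict(config), fh, indent=2)
    return paths
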