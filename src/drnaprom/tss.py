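"""Transcription start site calling from TEX(+)/TEX(-) coverage.

A TSS produces a sharp step-up in TEX(+) coverage at the first transcribed
base that the TEX(-) control lacks. Detection uses the calibrated
coverage-change factor

    delta_i = (x_{i+1} + c) / (x_i + c)

scanned in transcript orientation (toward decreasing coordinates on the
minus strand), with a small calibration constant ``c`` preventing division
by zero. A position is a candidate TSS when its change factor, TEX(+)
depth, and calibrated TEX(+)/TEX(-) enrichment ratio all clear their
cutoffs; runs of nearby candidates are collapsed to the strongest one.

The cutoffs are deliberately user-tunable: dRNA-seq library quality varies
widely and the appropriate stringency is dataset-dependent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GenomeSequence, StrandCoverageTrack, TSSRecord

log = logging.getLogger(__name__)


@dataclass
class TSSCallerConfig:
    """Cutoffs and calibration for TSS calling.

    ``calibration_c`` guards the coverage-change ratio against zero depth.
    ``replicate_mode`` controls how replicate tracks are combined: ``sum``
    pools coverage element-wise before calling (the default, appropriate
    for paired sequencing runs of one library), ``intersect`` calls each
    replicate separately and keeps only positions reproduced in all of
    them within ``cluster_window`` bases.
    """

    calibration_c: float = 0.01
    min_change_factor: float = 3.0
    min_tex_plus_depth: float = 10.0
    min_enrichment_ratio: float = 2.0
    cluster_window: int = 5
    replicate_mode: str = "sum"

    def __post_init__(self) -> None:
        if self.calibration_c <= 0:
            raise ValueError("calibration_c must be > 0")
        if min(self.min_change_factor, self.min_tex_plus_depth, self.min_enrichment_ratio) <= 0:
            raise ValueError("cutoffs must be > 0")
        if self.cluster_window < 0:
            raise ValueError("cluster_window must be >= 0")
        if self.replicate_mode not in ("sum", "intersect"):
            raise ValueError("replicate_mode must be 'sum' or 'intersect'")


def coverage_change(track: StrandCoverageTrack, c: float = 0.01) -> np.ndarray:
    """Per-position coverage-change factors in transcript orientation.

    Returns an array of length ``track.length - 1``. On the + strand entry
    ``i`` is ``(x[i+1]+c)/(x[i]+c)`` — the change onto candidate base
    ``i+1``. On the - strand the scan runs toward decreasing coordinates,
    so entry ``i`` is ``(x[i]+c)/(x[i+1]+c)`` — the change onto candidate
    base ``i``.
    """
    if c <= 0:
        raise ValueError("calibration constant c must be > 0")
    x = track.depth
    if x.shape[0] < 2:
        raise ValueError("track must have length >= 2")
    if track.strand == "+":
        return (x[1:] + c) / (x[:-1] + c)
    return (x[:-1] + c) / (x[1:] + c)


def call_candidates(
    tex_plus: StrandCoverageTrack,
    tex_minus: StrandCoverageTrack,
    config: TSSCallerConfig | None = None,
) -> list[TSSRecord]:
    """Positions passing the change, depth and TEX-enrichment filters.

    A candidate sits at the base *after* the jump in transcript orientation
    (the first transcribed base). Enrichment is the calibrated depth ratio
    ``(TEX+ + c) / (TEX- + c)`` at the candidate base.
    """
    cfg = config or TSSCallerConfig()
    if (
        tex_plus.replicon_id != tex_minus.replicon_id
        or tex_plus.strand != tex_minus.strand
        or tex_plus.length != tex_minus.length
    ):
        raise ValueError("TEX+ and TEX- tracks must share replicon, strand and length")

    c = cfg.calibration_c
    delta = coverage_change(tex_plus, c)
    if tex_plus.strand == "+":
        positions = np.arange(1, tex_plus.length)  # candidate for delta[i] is i+1
    else:
        positions = np.arange(0, tex_plus.length - 1)  # candidate for delta[i] is i

    depth = tex_plus.depth[positions]
    enrichment = (depth + c) / (tex_minus.depth[positions] + c)
    keep = (
        (delta >= cfg.min_change_factor)
        & (depth >= cfg.min_tex_plus_depth)
        & (enrichment >= cfg.min_enrichment_ratio)
    )
    idx = np.flatnonzero(keep)
    return [
        TSSRecord(
            replicon_id=tex_plus.replicon_id,
            position=int(positions[i]),
            strand=tex_plus.strand,
            tex_plus_depth=float(depth[i]),
            change_factor=float(delta[i]),
            enrichment_ratio=float(enrichment[i]),
        )
        for i in idx
    ]


def cluster_candidates(candidates: Sequence[TSSRecord], window: int) -> list[TSSRecord]:
    """Collapse runs of nearby candidates to the strongest position.

    Within any run of candidates (same replicon and strand) whose successive
    position gaps are <= ``window``, only the candidate with maximal change
    factor survives; ties break toward the 5'-most position in transcript
    orientation (smallest coordinate on +, largest on -).
    """
    out: list[TSSRecord] = []
    by_group: dict[tuple[str, str], list[TSSRecord]] = {}
    for r in candidates:
        by_group.setdefault((r.replicon_id, r.strand), []).append(r)

    for (rid, strand), group in by_group.items():
        group = sorted(group, key=lambda r: r.position)
        run: list[TSSRecord] = []
        for r in group:
            if run and r.position - run[-1].position > window:
                out.append(_best_of_run(run, strand))
                run = []
            run.append(r)
        if run:
            out.append(_best_of_run(run, strand))
    out.sort(key=lambda r: (r.replicon_id, r.position))
    return out


def _best_of_run(run: list[TSSRecord], strand: str) -> TSSRecord:
    best = run[0]
    for r in run[1:]:
        if r.change_factor > best.change_factor:
            best = r
        elif r.change_factor == best.change_factor and strand == "-":
            best = r  # later position is 5'-most on the minus strand
    return best


TrackSet = Mapping[tuple[str, str], "StrandCoverageTrack | Sequence[StrandCoverageTrack]"]


def _as_list(value) -> list[StrandCoverageTrack]:
    if isinstance(value, StrandCoverageTrack):
        return [value]
    return list(value)


def _sum_tracks(tracks: list[StrandCoverageTrack]) -> StrandCoverageTrack:
    first = tracks[0]
    depth = first.depth.copy()
    for t in tracks[1:]:
        if t.length != first.length or t.strand != first.strand:
            raise ValueError("replicate tracks must share strand and length")
        depth += t.depth
    return StrandCoverageTrack(first.replicon_id, first.strand, first.condition, depth)


def call_tss(
    genome: GenomeSequence,
    tracks: TrackSet,
    config: TSSCallerConfig | None = None,
) -> list[TSSRecord]:
    """Call, cluster and merge TSSs over both strands of one replicon.

    ``tracks`` maps ``(condition, strand)`` — condition in
    {"TEX_plus", "TEX_minus"}, strand in {"+", "-"} — to a track or a list
    of replicate tracks. Replicates are combined per
    ``config.replicate_mode``.
    """
    cfg = config or TSSCallerConfig()
    results: list[TSSRecord] = []
    for strand in ("+", "-"):
        try:
            plus_reps = _as_list(tracks[("TEX_plus", strand)])
            minus_reps = _as_list(tracks[("TEX_minus", strand)])
        except KeyError as err:
            raise ValueError(f"missing coverage track for {err.args[0]}") from None
        for t in plus_reps + minus_reps:
            if t.length != genome.length:
                raise ValueError("track length does not match genome length")

        if cfg.replicate_mode == "sum":
            cands = call_candidates(_sum_tracks(plus_reps), _sum_tracks(minus_reps), cfg)
            results.extend(cluster_candidates(cands, cfg.cluster_window))
        else:  # intersect
            n_rep = max(len(plus_reps), len(minus_reps))
            if len(plus_reps) != len(minus_reps):
                raise ValueError("intersect mode needs matched TEX+/TEX- replicate counts")
            per_rep = [
                cluster_candidates(
                    call_candidates(plus_reps[i], minus_reps[i], cfg), cfg.cluster_window
                )
                for i in range(n_rep)
            ]
            kept = []
            other_positions = [np.array([r.position for r in rep]) for rep in per_rep[1:]]
            for r in per_rep[0]:
                if all(
                    pos.size and np.min(np.abs(pos - r.position)) <= cfg.cluster_window
                    for pos in other_positions
                ):
                    kept.append(r)
            results.extend(kept)
    results.sort(key=lambda r: (r.replicon_id, r.position))
    return results


def match_to_truth(
    called: Sequence[TSSRecord],
    truth: Sequence[tuple[str, int, str]],
    tolerance: int = 1,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of calls to true TSSs within ``tolerance`` bp.

    Returns ``(n_matched, n_called, n_true)`` from which recall and
    precision follow directly.
    """
    remaining = {}
    for rid, p, s in truth:
        remaining.setdefault((rid, s), []).append(p)
    for key in remaining:
        remaining[key] = sorted(remaining[key])

    matched = 0
    for r in called:
        pool = remaining.get((r.replicon_id, r.strand), [])
        if not pool:
            continue
        arr = np.asarray(pool)
        i = int(np.argmin(np.abs(arr - r.position)))
        if abs(arr[i] - r.position) <= tolerance:
            matched += 1
            pool.pop(i)
    return matched, len(called), len(truth)
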