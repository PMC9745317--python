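"""TSS caller: change-factor formula, filters, clustering, strand symmetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drnaprom.io_formats import StrandCoverageTrack, GenomeSequence
from drnaprom.tss import (
    TSSCallerConfig,
    call_candidates,
    call_tss,
    cluster_candidates,
    coverage_change,
)
from drnaprom.io_formats import TSSRecord


def track(depth, strand="+", cond="TEX_plus"):
    return StrandCoverageTrack("chr", strand, cond, np.asarray(depth, dtype=float))


class TestCoverageChange:
    def test_zero_over_zero_is_one(self):
        delta = coverage_change(track([0.0, 0.0]), c=0.01)
        assert delta[0] == pytest.approx(1.0)

    def test_direct_evaluation(self):
        delta = coverage_change(track([2.0, 200.0]), c=0.01)
        assert delta[0] == pytest.approx(200.01 / 2.01)

    def test_downward_step_below_one(self):
        delta = coverage_change(track([100.0, 1.0]), c=0.01)
        assert delta[0] == pytest.approx(1.01 / 100.01)
        assert delta[0] < 1

    def test_minus_strand_scans_decreasing(self):
        # on the minus strand the "next" base is i-1; entry i is the change
        # onto candidate base i
        delta = coverage_change(track([200.0, 2.0], strand="-"), c=0.01)
        assert delta[0] == pytest.approx(200.01 / 2.01)

    def test_short_track_errors(self):
        with pytest.raises(ValueError):
            coverage_change(track([1.0]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_naive_loop(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 300, size=200).astype(float)
        c = 0.01
        delta = coverage_change(track(x), c=c)
        naive = [(x[i + 1] + c) / (x[i] + c) for i in range(len(x) - 1)]
        assert np.array_equal(delta, np.array(naive))
        assert np.all(np.isfinite(delta)) and np.all(delta > 0)


class TestCallCandidates:
    def test_flat_tracks_give_nothing(self):
        flat = np.full(100, 20.0)
        cands = call_candidates(track(flat), track(flat, cond="TEX_minus"))
        assert cands == []

    def test_step_with_quiet_control_is_called(self):
        xp = np.full(100, 2.0)
        xp[50:] = 200.0
        xm = np.full(100, 2.0)
        (cand,) = call_candidates(track(xp), track(xm, cond="TEX_minus"))
        assert cand.position == 50
        assert cand.change_factor == pytest.approx(200.01 / 2.01)
        assert cand.enrichment_ratio == pytest.approx(200.01 / 2.01)

    def test_step_in_both_conditions_rejected(self):
        xp = np.full(100, 2.0)
        xp[50:] = 200.0
        cands = call_candidates(track(xp), track(xp.copy(), cond="TEX_minus"))
        assert cands == []  # enrichment ~1 < 2

    def test_mismatched_tracks_error(self):
        with pytest.raises(ValueError):
            call_candidates(track([1, 2, 3]), track([1, 2], cond="TEX_minus"))

    def test_minus_strand_candidate_position(self):
        xp = np.full(100, 2.0)
        xp[:50] = 200.0  # jump when scanning right-to-left onto base 49
        xm = np.full(100, 2.0)
        (cand,) = call_candidates(
            track(xp, strand="-"), track(xm, strand="-", cond="TEX_minus")
        )
        assert cand.position == 49

    def test_monotone_in_cutoffs(self):
        rng = np.random.default_rng(42)
        xp = rng.poisson(30, size=2000).astype(float)
        xp[rng.integers(0, 2000, size=40)] += 300
        xm = rng.poisson(20, size=2000).astype(float)
        base = TSSCallerConfig()
        n0 = len(call_candidates(track(xp), track(xm, cond="TEX_minus"), base))
        for kw in ({"min_change_factor": 5.0}, {"min_tex_plus_depth": 50.0},
                   {"min_enrichment_ratio": 5.0}):
            n = len(call_candidates(track(xp), track(xm, cond="TEX_minus"),
                                    TSSCallerConfig(**kw)))
            assert n <= n0


def rec(pos, delta, strand="+"):
    return TSSRecord("chr", pos, strand, 100.0, delta, 5.0)


class TestCluster:
    def test_max_rule(self):
        kept = cluster_candidates([rec(100, 50.0), rec(102, 80.0)], window=5)
        assert [r.position for r in kept] == [102]

    def test_gap_beyond_window_keeps_both(self):
        kept = cluster_candidates([rec(100, 50.0), rec(200, 80.0)], window=5)
        assert [r.position for r in kept] == [100, 200]

    def test_tie_breaks_5prime_plus(self):
        kept = cluster_candidates([rec(100, 50.0), rec(101, 50.0)], window=5)
        assert [r.position for r in kept] == [100]

    def test_tie_breaks_5prime_minus(self):
        kept = cluster_candidates(
            [rec(100, 50.0, "-"), rec(101, 50.0, "-")], window=5)
        assert [r.position for r in kept] == [101]

    def test_chained_run_collapses_once(self):
        cands = [rec(10, 5.0), rec(13, 9.0), rec(16, 7.0)]
        kept = cluster_candidates(cands, window=5)
        assert [r.position for r in kept] == [13]


class TestCallTss:
    def _tracks(self, xp_fwd, xm_fwd, n):
        quiet = np.full(n, 2.0)
        return {
            ("TEX_plus", "+"): track(xp_fwd),
            ("TEX_minus", "+"): track(xm_fwd, cond="TEX_minus"),
            ("TEX_plus", "-"): track(quiet, strand="-"),
            ("TEX_minus", "-"): track(quiet.copy(), strand="-", cond="TEX_minus"),
        }

    def test_zero_replicate_is_additive_identity(self):
        n = 200
        xp = np.full(n, 2.0)
        xp[100:] = 200.0
        xm = np.full(n, 2.0)
        genome = GenomeSequence("chr", "A" * n)
        tracks = self._tracks(xp, xm, n)
        single = call_tss(genome, tracks, TSSCallerConfig())
        with_zero = dict(tracks)
        with_zero[("TEX_plus", "+")] = [track(xp), track(np.zeros(n))]
        with_zero[("TEX_minus", "+")] = [track(xm, cond="TEX_minus"),
                                         track(np.zeros(n), cond="TEX_minus")]
        combined = call_tss(genome, with_zero, TSSCallerConfig())
        assert [(r.position, r.strand) for r in combined] == \
            [(r.position, r.strand) for r in single]

    def test_missing_condition_errors(self):
        genome = GenomeSequence("chr", "A" * 10)
        with pytest.raises(ValueError, match="missing coverage track"):
            call_tss(genome, {}, TSSCallerConfig())

    def test_intersect_mode_requires_reproducibility(self):
        n = 200
        xp1 = np.full(n, 2.0); xp1[100:] = 200.0
        xp2 = np.full(n, 2.0); xp2[100:] = 200.0
        xp3 = np.full(n, 2.0)  # replicate without the step
        xm = np.full(n, 2.0)
        genome = GenomeSequence("chr", "A" * n)
        quiet = np.full(n, 2.0)
        base = {
            ("TEX_plus", "-"): track(quiet, strand="-"),
            ("TEX_minus", "-"): track(quiet.copy(), strand="-", cond="TEX_minus"),
        }
        cfg = TSSCallerConfig(replicate_mode="intersect")
        reproduced = dict(base)
        reproduced[("TEX_plus", "+")] = [track(xp1), track(xp2)]
        reproduced[("TEX_minus", "+")] = [track(xm, cond="TEX_minus")] * 2
        assert len(call_tss(genome, reproduced, cfg)) == 1
        unreproduced = dict(base)
        unreproduced[("TEX_plus", "+")] = [track(xp1), track(xp3)]
        unreproduced[("TEX_minus", "+")] = [track(xm, cond="TEX_minus")] * 2
        assert len(call_tss(genome, unreproduced, cfg)) == 0


def test_strand_symmetry_under_mirroring():
    """Reverse-complementing genome and mirroring tracks maps + calls to -."""
    rng = np.random.default_rng(11)
    n = 5000
    xp = rng.poisson(20, n).astype(float)
    for p in (500, 1500, 3000):
        xp[p:p + 60] += 250.0
    xm = rng.poisson(20, n).astype(float)
    genome = GenomeSequence("chr", "".join(rng.choice(list("ACGT"), n)))
    quiet = rng.poisson(20, n).astype(float)
    quiet_m = rng.poisson(20, n).astype(float)

    fwd_tracks = {
        ("TEX_plus", "+"): track(xp),
        ("TEX_minus", "+"): track(xm, cond="TEX_minus"),
        ("TEX_plus", "-"): track(quiet, strand="-"),
        ("TEX_minus", "-"): track(quiet_m, strand="-", cond="TEX_minus"),
    }
    from drnaprom.io_formats import reverse_complement
    mirrored = GenomeSequence("chr", reverse_complement(genome.residues))
    rev_tracks = {
        ("TEX_plus", "-"): track(xp[::-1].copy(), strand="-"),
        ("TEX_minus", "-"): track(xm[::-1].copy(), strand="-", cond="TEX_minus"),
        ("TEX_plus", "+"): track(quiet[::-1].copy()),
        ("TEX_minus", "+"): track(quiet_m[::-1].copy(), cond="TEX_minus"),
    }
    cfg = TSSCallerConfig()
    fwd_calls = [(r.position, r.strand) for r in call_tss(genome, fwd_tracks, cfg)]
    rev_calls = [(r.position, r.strand) for r in call_tss(mirrored, rev_tracks, cfg)]
    expected = sorted((n - 1 - p, "-" if s == "+" else "+") for p, s in fwd_calls)
    assert sorted(rev_calls) == expected
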