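"""K2P distances, sliding-window tracks, breakpoints, and partitions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import k2p_brute
from retrotrace.divergence import (
    OK,
    SATURATED,
    UNDEFINED,
    NoSignalError,
    SeqAlignment,
    detect_breakpoints,
    k2p_distance,
    partition_alignment,
    sliding_divergence,
)
from retrotrace.models import random_dna
from retrotrace.scenarios import simulate_recombinant

dna = st.text(alphabet="ACGT", min_size=12, max_size=200)


class TestK2P:
    def test_identical_sequences_have_zero_distance(self):
        assert k2p_distance("ACGT" * 20, "ACGT" * 20).d == 0.0

    def test_single_transition_in_ten_sites(self):
        # one A<->G change among 10 compared sites: P=0.1, Q=0
        res = k2p_distance("A" * 9 + "G", "A" * 10)
        assert res.status == OK and res.P == 0.1 and res.Q == 0.0
        assert res.d == pytest.approx(0.11157, abs=1e-5)

    def test_single_transversion_closed_form(self):
        # one A<->C change among 16 sites: P=0, Q=1/16
        res = k2p_distance("A" * 15 + "C", "A" * 16)
        Q = 1 / 16
        expected = -0.5 * math.log(1 - Q) - 0.25 * math.log(1 - 2 * Q)
        assert res.d == pytest.approx(expected, abs=1e-12)

    def test_too_few_comparable_sites_is_undefined(self):
        assert k2p_distance("ACGTACGT", "ACGTACGA").status == UNDEFINED
        # gaps/N reduce the comparable-site count
        res = k2p_distance("ACGT" + "-" * 12, "ACGT" + "A" * 12)
        assert res.status == UNDEFINED

    def test_saturation_marker_not_number(self):
        res = k2p_distance("A" * 40, "G" * 40)  # all transitions: 1-2P-Q < 0
        assert res.status == SATURATED and math.isnan(res.d)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            k2p_distance("ACGT", "ACG")

    def test_matches_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT-N"))
        for _ in range(300):
            n = int(rng.integers(12, 150))
            a = "".join(bases[rng.integers(0, 6, n)])
            b = "".join(bases[rng.integers(0, 6, n)])
            mine = k2p_distance(a, b)
            expected, status = k2p_brute(a, b)
            assert mine.status == status
            if status == "ok":
                assert mine.d == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(dna, dna)
    def test_symmetry(self, a, b):
        n = min(len(a), len(b))
        ra, rb = k2p_distance(a[:n], b[:n]), k2p_distance(b[:n], a[:n])
        assert ra.status == rb.status
        if ra.status == OK:
            assert ra.d == rb.d


class TestSlidingWindows:
    def test_window_count_formula(self):
        rng = np.random.default_rng(0)
        aln = SeqAlignment({"q": random_dna(1000, rng), "r": random_dna(1000, rng)})
        track = sliding_divergence(aln, "q", ["r"], window=50, step=10)
        assert track.n_windows == (1000 - 50) // 10 + 1 == 96
        assert np.all(np.diff(track.centers) == 10)

    def test_identical_query_gives_zero_track(self):
        rng = np.random.default_rng(1)
        s = random_dna(500, rng)
        aln = SeqAlignment({"q": s, "r": s, "other": random_dna(500, rng)})
        track = sliding_divergence(aln, "q", ["r"])
        assert np.allclose(track.d["r"], 0.0)

    def test_window_larger_than_alignment_rejected(self):
        aln = SeqAlignment({"a": "ACGTACGTACGT", "b": "ACGTACGTACGT"})
        with pytest.raises(ValueError):
            sliding_divergence(aln, "a", ["b"], window=50)

    def test_recombinant_track_crosses_at_breakpoint(self):
        pair = simulate_recombinant(length=3000, n_breakpoints=1, seed=5)
        bp = pair.breakpoints[0]
        track = sliding_divergence(pair.alignment, "recombinant", ["parentA", "parentB"])
        da, db = track.d["parentA"], track.d["parentB"]
        before = track.centers < bp - 50
        after = track.centers > bp + 50
        assert np.all(da[before] <= db[before])
        assert np.all(da[after] >= db[after])


class TestBreakpoints:
    def test_uniform_signal_yields_single_segment(self):
        rng = np.random.default_rng(2)
        anc = random_dna(2000, rng)
        from retrotrace.models import mutate_sequence

        aln = SeqAlignment(
            {"q": mutate_sequence(anc, 0.01, rng), "A": anc, "B": mutate_sequence(anc, 0.2, rng)}
        )
        track = sliding_divergence(aln, "q", ["A", "B"])
        bps = detect_breakpoints(track, "A", "B")
        assert bps.breakpoints == []
        assert len(bps.segments) == 1 and bps.segments[0].parent == "A"

    def test_planted_switch_located_within_one_window(self):
        pair = simulate_recombinant(length=3000, n_breakpoints=1, seed=7)
        track = sliding_divergence(pair.alignment, "recombinant", ["parentA", "parentB"])
        bps = detect_breakpoints(track, "parentA", "parentB")
        assert len(bps.breakpoints) == 1
        assert abs(bps.breakpoints[0] - pair.breakpoints[0]) <= 50
        assert [s.parent for s in bps.segments] == ["parentA", "parentB"]

    def test_mosaic_yields_two_breakpoints_middle_segment_assigned(self):
        pair = simulate_recombinant(length=5000, n_breakpoints=2, seed=9)
        track = sliding_divergence(pair.alignment, "recombinant", ["parentA", "parentB"])
        bps = detect_breakpoints(track, "parentA", "parentB")
        assert len(bps.breakpoints) == 2
        assert [s.parent for s in bps.segments] == ["parentA", "parentB", "parentA"]

    def test_all_undefined_track_raises(self):
        aln = SeqAlignment({"q": "N" * 200, "A": "A" * 200, "B": "C" * 200})
        track = sliding_divergence(aln, "q", ["A", "B"])
        with pytest.raises(NoSignalError):
            detect_breakpoints(track, "A", "B")


class TestPartition:
    def test_no_breakpoints_returns_input(self):
        aln = SeqAlignment({"a": "ACGTACGTAC", "b": "ACGTACGTAA"})
        parts = partition_alignment(aln, [])
        assert len(parts) == 1 and parts[0].records == aln.records

    def test_widths_tile_alignment(self):
        rng = np.random.default_rng(3)
        aln = SeqAlignment({"a": random_dna(1000, rng), "b": random_dna(1000, rng)})
        parts = partition_alignment(aln, [600])
        assert [p.length for p in parts] == [600, 400]
        parts3 = partition_alignment(aln, [300, 700])
        assert [p.length for p in parts3] == [300, 400, 300]

    def test_unsorted_breakpoints_rejected(self):
        aln = SeqAlignment({"a": "ACGT" * 100})
        with pytest.raises(ValueError):
            partition_alignment(aln, [300, 200])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(100, 400), st.lists(st.integers(1, 99), min_size=0, max_size=4, unique=True))
    def test_concatenation_roundtrip(self, length, cuts):
        rng = np.random.default_rng(length)
        aln = SeqAlignment({"x": random_dna(length, rng), "y": random_dna(length, rng)})
        bps = sorted(c * length // 100 for c in cuts)
        bps = [b for b in bps if 0 < b < length]
        bps = sorted(set(bps))
        parts = partition_alignment(aln, bps)
        for rid in aln.records:
            assert "".join(p.records[rid] for p in parts) == aln.records[rid]
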