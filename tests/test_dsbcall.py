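"""Hotspot grouping, sliding-window counting, peak detection and the
bidirectional-support rule, each checked against brute-force oracles."""

import numpy as np
import pytest

from breaktag.dsbcall import (
    CallParams,
    HotspotRegion,
    call_sites,
    detect_peaks,
    flag_dsb_sites,
    group_hotspots,
    window_counts,
)

P = CallParams()


def _positions(d):
    """position -> count on (+, fwd) unless a full class map is given."""
    return {
        pos: (v if isinstance(v, dict) else {("+", "fwd"): v}) for pos, v in d.items()
    }


# -- independent oracles -----------------------------------------------------

def windows_oracle(members, start, end, w):
    """Counts for every window by direct interval membership."""
    starts = list(range(start - (w - 1), end))
    return starts, [
        sum(
            sum(classes.values())
            for pos, classes in members.items()
            if s <= pos < s + w
        )
        for s in starts
    ]


def peaks_oracle(v, min_sep):
    """Strict local maxima via per-index neighbour comparison: an index is
    a candidate iff it is the left edge of its plateau and the nearest
    differing values on both sides (or the array edge) are lower."""
    n = len(v)
    candidates = []
    for i in range(n):
        if v[i] <= 0 or (i > 0 and v[i - 1] == v[i]):
            continue
        left_lower = i == 0 or v[i - 1] < v[i]
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        right_lower = j == n - 1 or v[j + 1] < v[i]
        if left_lower and right_lower:
            candidates.append(i)
    chosen = []
    for idx in sorted(candidates, key=lambda k: (-v[k], k)):
        if all(abs(idx - c) >= min_sep for c in chosen):
            chosen.append(idx)
    return sorted(chosen)


# -- hotspot grouping --------------------------------------------------------

class TestHotspots:
    def test_close_positions_share_one_region(self):
        regions = group_hotspots(_positions({100: 3, 105: 3, 109: 3}), "chr1", P)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (100, 110)

    def test_gap_equal_to_threshold_splits(self):
        regions = group_hotspots(_positions({100: 3, 110: 3}), "chr1", P)
        assert len(regions) == 2

    def test_empty_input(self):
        assert group_hotspots({}, "chr1", P) == []

    def test_every_position_in_exactly_one_region(self):
        rng = np.random.default_rng(3)
        positions = _positions({int(p): 1 for p in rng.integers(0, 500, 60)})
        regions = group_hotspots(positions, "chr1", P)
        covered = [p for r in regions for p in r.members]
        assert sorted(covered) == sorted(positions)
        for r in regions:
            ps = sorted(r.members)
            assert all(b - a < P.max_gap for a, b in zip(ps, ps[1:]))


# -- window counting ---------------------------------------------------------

class TestWindows:
    def test_single_position_counts_in_every_covering_window(self):
        region = HotspotRegion("chr1", 100, 101, _positions({100: 6}))
        starts, _cls, summed = window_counts(region, P)
        for s, c in zip(starts, summed):
            assert c == (6 if s <= 100 < s + P.window else 0)

    def test_two_positions_cocounted_only_when_cowindowed(self):
        region = HotspotRegion("chr1", 100, 105, _positions({100: 3, 104: 3}))
        starts, _cls, summed = window_counts(region, P)
        assert summed[starts.index(95)] == 6
        # no length-10 window covers both 100 and a position 10 away
        assert max(summed) == 6

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(trial)
        members = _positions(
            {int(p): int(rng.integers(1, 5)) for p in rng.integers(0, 30, 8)}
        )
        region = HotspotRegion("chr1", min(members), max(members) + 1, members)
        starts, _cls, summed = window_counts(region, P)
        o_starts, o_counts = windows_oracle(members, region.start, region.end, P.window)
        assert starts == o_starts and summed == o_counts


# -- peak detection ----------------------------------------------------------

class TestPeaks:
    def test_single_maximum(self):
        assert detect_peaks([0, 2, 6, 2, 0], P) == [2]

    def test_plateau_yields_leftmost(self):
        assert detect_peaks([0, 6, 6, 0], P) == [1]

    def test_all_zero_yields_nothing(self):
        assert detect_peaks([0, 0, 0], P) == []

    def test_close_peaks_keep_higher_then_leftmost(self):
        params = CallParams(min_peak_separation=5)
        v = [0, 5, 0, 0, 7, 0]
        assert detect_peaks(v, params) == [4]
        v = [0, 5, 0, 0, 5, 0]
        assert detect_peaks(v, params) == [1]

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        v = [int(x) for x in rng.integers(0, 6, 30)]
        assert detect_peaks(v, P) == peaks_oracle(v, P.min_peak_separation)


# -- support rule ------------------------------------------------------------

def _region_with_classes(class_counts, pos=100):
    return HotspotRegion("chr1", pos, pos + 1, {pos: dict(class_counts)})


def _flag(class_counts, rule="rgn", params=P):
    region = _region_with_classes(class_counts)
    starts, _cls, summed = window_counts(region, params)
    peaks = detect_peaks(summed, params)
    return flag_dsb_sites(region, starts, peaks, params, rule)


class TestSupportRule:
    def test_six_per_strand_flags_both_strands(self):
        sites = _flag({("+", "fwd"): 6, ("-", "fwd"): 6})
        assert len(sites) == 1 and sites[0].evidence_class == "both-strands"

    def test_six_five_fails_strand_branch_but_libraries_can_rescue(self):
        assert not _flag({("+", "fwd"): 6, ("-", "fwd"): 5})
        sites = _flag({("+", "fwd"): 6, ("+", "rev"): 6, ("-", "fwd"): 5})
        assert len(sites) == 1 and sites[0].evidence_class == "both-libraries"

    def test_single_library_single_strand_never_flags(self):
        assert not _flag({("+", "fwd"): 12})

    def test_transposon_rule_needs_total_five_and_both_strands(self):
        assert _flag({("+", "arm"): 3, ("-", "arm"): 2}, rule="transposon")
        assert not _flag({("+", "arm"): 4}, rule="transposon")
        assert not _flag({("+", "arm"): 2, ("-", "arm"): 2}, rule="transposon")

    def test_cut_position_is_modal_junction_leftmost_on_tie(self):
        region = HotspotRegion(
            "chr1", 100, 103,
            {
                100: {("+", "fwd"): 6},
                102: {("-", "fwd"): 6},
            },
        )
        starts, _cls, summed = window_counts(region, P)
        peaks = detect_peaks(summed, P)
        sites = flag_dsb_sites(region, starts, peaks, P)
        assert sites and sites[0].cut_position == 100  # tie 6/6 -> leftmost

    def test_min_support_monotonicity(self):
        rng = np.random.default_rng(7)
        tracks = {}
        for strand in "+-":
            for lib in ("fwd", "rev"):
                tracks[("chr1", strand, lib)] = {
                    int(p): int(rng.integers(1, 9))
                    for p in rng.integers(0, 2000, 40)
                }
        counts = [
            len(call_sites(tracks, CallParams(min_support=ms)))
            for ms in (1, 2, 4, 6, 9)
        ]
        assert counts == sorted(counts, reverse=True)


# -- recovery on simulated data ---------------------------------------------

class TestRecovery:
    def test_all_planted_sites_recovered_and_nothing_else(self, mismatch_ladder_run):
        config, _genome, truths, _truth, tracks = mismatch_ladder_run
        sites = call_sites(tracks, CallParams())
        planted = {t.cut_position for t in truths}
        assert len(sites) == len(planted)
        for s in sites:
            assert any(abs(s.cut_position - p) <= 1 for p in planted)
        for s in sites:
            assert min(abs(s.cut_position - p) for p in planted) <= 25
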