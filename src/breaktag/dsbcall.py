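"""Double-strand-break calling from junction tracks.

The caller follows a fixed-threshold, window-based recipe:

1. junction positions (pooled over strands and libraries) closer than
   ``max_gap`` (default 10 bp, strict) are grouped into hotspot regions;
2. 10-bp sliding windows (step 1) are laid over each region and the
   molecule count of every (strand x library) class is accumulated per
   window;
3. peaks are strict local maxima of the summed window counts (plateaus
   collapse to their leftmost window; peaks closer than
   ``min_peak_separation`` keep only the higher, leftmost on ties);
4. a peak becomes a DSB site when it has enough support on both strands,
   or on one strand from both tag-primer libraries (the break must be
   read out from both sides, or independently by both nested PCRs).

"More than five reads" is interpreted per evidence class: every class in
the satisfied branch needs ``min_support`` (default 6) molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alnstore import Track

ClassKey = tuple[str, str]  # (strand, library)


@dataclass
class CallParams:
    max_gap: int = 10  # strict: gaps < max_gap share a hotspot
    window: int = 10
    min_support: int = 6  # per class; "more than five reads"
    min_support_transposon: int = 5  # total; "at least five supporting reads"
    min_peak_separation: int = 10
    min_mapq: int = 20

    def __post_init__(self) -> None:
        if self.window < 1 or self.min_support < 1:
            raise ValueError("window and min_support must be >= 1")


@dataclass
class HotspotRegion:
    chrom: str
    start: int
    end: int  # half-open; end = max member position + 1
    members: dict[int, dict[ClassKey, int]] = field(default_factory=dict)

    def total(self) -> int:
        return sum(sum(d.values()) for d in self.members.values())


@dataclass
class DSBSite:
    chrom: str
    cut_position: int
    window_start: int
    window_end: int
    support_plus: int
    support_minus: int
    support_by_class: dict[ClassKey, int]
    total_support: int
    evidence_class: str  # "both-strands" or "both-libraries"


def merge_chrom_tracks(
    tracks: dict[tuple[str, str, str], Track],
) -> dict[str, dict[int, dict[ClassKey, int]]]:
    """Pool tracks per chromosome: position -> class -> count."""
    pooled: dict[str, dict[int, dict[ClassKey, int]]] = {}
    for (chrom, strand, library), track in tracks.items():
        chrom_map = pooled.setdefault(chrom, {})
        for pos, count in track.items():
            cls = chrom_map.setdefault(pos, {})
            cls[(strand, library)] = cls.get((strand, library), 0) + count
    return pooled


def group_hotspots(
    positions: dict[int, dict[ClassKey, int]], chrom: str, params: CallParams
) -> list[HotspotRegion]:
    """Maximal runs of positions with consecutive gaps < ``max_gap``."""
    regions: list[HotspotRegion] = []
    current: HotspotRegion | None = None
    for pos in sorted(positions):
        if current is not None and pos - max(current.members) < params.max_gap:
            current.members[pos] = dict(positions[pos])
            current.end = pos + 1
        else:
            current = HotspotRegion(chrom, pos, pos + 1, {pos: dict(positions[pos])})
            regions.append(current)
    return regions


def window_counts(
    region: HotspotRegion, params: CallParams
) -> tuple[list[int], dict[ClassKey, list[int]], list[int]]:
    """Sliding-window class counts over a region.

    Windows of length ``window`` advance by 1 bp and cover the region
    padded by ``window - 1`` on each side, so every window that touches a
    member position exists. Returns (window starts, per-class count
    vectors, summed count vector).
    """
    w = params.window
    starts = list(range(region.start - (w - 1), region.end))
    classes = sorted({cls for d in region.members.values() for cls in d})
    per_class: dict[ClassKey, list[int]] = {cls: [0] * len(starts) for cls in classes}
    summed = [0] * len(starts)
    for pos, class_counts in region.members.items():
        # position pos falls in windows with start in (pos - w, pos]
        lo = max(0, pos - w + 1 - starts[0])
        hi = min(len(starts), pos - starts[0] + 1)
        for i in range(lo, hi):
            for cls, count in class_counts.items():
                per_class[cls][i] += count
                summed[i] += count
    return starts, per_class, summed


def detect_peaks(summed: list[int], params: CallParams) -> list[int]:
    """Indices of strict local maxima of the summed window-count vector.

    A plateau (run of equal values above both neighbours, array edges
    counting as lower) yields a single peak at its leftmost window.
    Among peaks closer than ``min_peak_separation`` only the highest is
    kept, the leftmost winning ties.
    """
    n = len(summed)
    candidates: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and summed[j + 1] == summed[i]:
            j += 1
        left_ok = i == 0 or summed[i - 1] < summed[i]
        right_ok = j == n - 1 or summed[j + 1] < summed[i]
        if left_ok and right_ok and summed[i] > 0:
            candidates.append(i)
        i = j + 1
    kept: list[int] = []
    for idx in sorted(candidates, key=lambda k: (-summed[k], k)):
        if all(abs(idx - other) >= params.min_peak_separation for other in kept):
            kept.append(idx)
    return sorted(kept)


def _window_class_support(
    region: HotspotRegion, start: int, width: int
) -> dict[ClassKey, int]:
    support: dict[ClassKey, int] = {}
    for pos, class_counts in region.members.items():
        if start <= pos < start + width:
            for cls, count in class_counts.items():
                support[cls] = support.get(cls, 0) + count
    return support


def _passes_rule(
    support: dict[ClassKey, int], params: CallParams, rule: str
) -> str | None:
    plus = sum(c for (s, _), c in support.items() if s == "+")
    minus = sum(c for (s, _), c in support.items() if s == "-")
    if rule == "transposon":
        total = plus + minus
        if total >= params.min_support_transposon and plus >= 1 and minus >= 1:
            return "both-strands"
        return None
    ms = params.min_support
    if plus >= ms and minus >= ms:
        return "both-strands"
    libraries = sorted({lib for _, lib in support})
    if len(libraries) >= 2:
        for strand in "+-":
            per_lib = [support.get((strand, lib), 0) for lib in libraries]
            if sum(1 for c in per_lib if c >= ms) >= 2:
                return "both-libraries"
    return None


def flag_dsb_sites(
    region: HotspotRegion,
    starts: list[int],
    peak_indices: list[int],
    params: CallParams,
    rule: str = "rgn",
) -> list[DSBSite]:
    """Apply the bidirectional-support rule to each peak window.

    The consensus cut position is the modal junction position inside the
    peak window (pooled over classes), the leftmost winning ties.
    """
    sites: list[DSBSite] = []
    for idx in peak_indices:
        start = starts[idx]
        support = _window_class_support(region, start, params.window)
        evidence = _passes_rule(support, params, rule)
        if evidence is None:
            continue
        in_window = {
            pos: sum(d.values())
            for pos, d in region.members.items()
            if start <= pos < start + params.window
        }
        cut = min(in_window, key=lambda p: (-in_window[p], p))
        sites.append(
            DSBSite(
                chrom=region.chrom,
                cut_position=cut,
                window_start=start,
                window_end=start + params.window,
                support_plus=sum(c for (s, _), c in support.items() if s == "+"),
                support_minus=sum(c for (s, _), c in support.items() if s == "-"),
                support_by_class=support,
                total_support=sum(support.values()),
                evidence_class=evidence,
            )
        )
    return sites


def call_sites(
    tracks: dict[tuple[str, str, str], Track],
    params: CallParams | None = None,
    rule: str = "rgn",
) -> list[DSBSite]:
    """Full calling pass over junction tracks; sites sorted by support."""
    params = params or CallParams()
    sites: list[DSBSite] = []
    for chrom, positions in sorted(merge_chrom_tracks(tracks).items()):
        for region in group_hotspots(positions, chrom, params):
            starts, _per_class, summed = window_counts(region, params)
            peaks = detect_peaks(summed, params)
            sites.extend(flag_dsb_sites(region, starts, peaks, params, rule))
    sites.sort(key=lambda s: (-s.total_support, s.chrom, s.cut_position))
    return sites


def write_sites_tsv(sites: list[DSBSite], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tcut_position\twindow_start\twindow_end\tsupport_plus\t"
            "support_minus\ttotal_support\tevidence_class\n"
        )
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.cut_position}\t{s.window_start}\t{s.window_end}\t"
                f"{s.support_plus}\t{s.support_minus}\t{s.total_support}\t"
                f"{s.evidence_class}\n"
            )
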