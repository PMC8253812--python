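"""On-/off-target annotation of called break sites.

Each candidate site's +/-25 bp flank is searched for the best local,
ungapped placement of the guide spacer on either strand (a
Smith-Waterman alignment with gap penalties high enough that gaps never
pay: with unit match/mismatch scores the optimum is the placement
minimizing substitutions, with spacer bases hanging off the window
counted as mismatches). A site is on-target when the spacer matches
exactly, off-target with 1..max_mismatches substitutions, and unmatched
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dsbcall import DSBSite
from .seqs import revcomp


@dataclass
class MatchParams:
    flank: int = 25
    max_mismatches: int = 6
    require_pam: bool = False
    pam_pattern: str = "NGG"
    pam_side: str = "3prime"
    allow_gaps: bool = False  # gapped hits are reported but never off-target calls


@dataclass
class FlankWindow:
    chrom: str
    start: int
    end: int
    seq: str
    at_edge: bool = False


@dataclass
class SpacerMatch:
    strand: str
    offset: int  # placement of the spacer 5' end, window coordinates ("+" frame)
    mismatch_count: int
    mismatch_positions: tuple[int, ...]  # spacer coordinates, 5'->3'
    matched_seq: str  # genomic bases under the spacer, spacer orientation
    genome_start: int
    genome_end: int


@dataclass
class OffTargetHit:
    site: DSBSite
    classification: str  # on-target / off-target / unmatched / edge
    read_count: int
    match: SpacerMatch | None = None
    pam_observed: str = ""
    pam_ok: bool = False


def extract_flank(
    genome: dict[str, str], site: DSBSite, flank: int = 25
) -> FlankWindow:
    """The [cut - flank, cut + flank) reference window around a site."""
    chrom_seq = genome[site.chrom]
    start, end = site.cut_position - flank, site.cut_position + flank
    if start < 0 or end > len(chrom_seq):
        return FlankWindow(site.chrom, max(0, start), min(len(chrom_seq), end),
                           chrom_seq[max(0, start):end], at_edge=True)
    return FlankWindow(site.chrom, start, end, chrom_seq[start:end])


def _scan_strand(grna: str, window: str) -> tuple[int, int, tuple[int, ...]]:
    """Best ungapped placement of grna on the given window orientation:
    (mismatches, offset, mismatch positions). Spacer bases outside the
    window count as mismatches; ties break to the leftmost offset."""
    L, W = len(grna), len(window)
    best: tuple[int, int, tuple[int, ...]] | None = None
    for offset in range(-(L - 1), W):
        mismatches = []
        for i, base in enumerate(grna):
            j = offset + i
            if j < 0 or j >= W or window[j] != base or base == "N" or window[j] == "N":
                mismatches.append(i)
        cand = (len(mismatches), offset, tuple(mismatches))
        if best is None or cand[:2] < best[:2]:
            best = cand
    assert best is not None
    return best


def sw_match(grna: str, window: FlankWindow, params: MatchParams) -> SpacerMatch:
    """Best spacer placement over both strands of a flank window.

    Tie-break between equally good placements: leftmost genomic offset,
    then the + strand.
    """
    W = len(window.seq)
    L = len(grna)
    mm_p, off_p, pos_p = _scan_strand(grna, window.seq)
    mm_m, off_m_rc, pos_m = _scan_strand(grna, revcomp(window.seq))
    # map the minus-strand placement back to + frame window coordinates
    off_m = W - (off_m_rc + L)
    candidates = [
        (mm_p, off_p, 0, "+", pos_p),
        (mm_m, off_m, 1, "-", pos_m),
    ]
    mm, offset, _, strand, positions = min(candidates, key=lambda c: (c[0], c[1], c[2]))
    g_start = window.start + max(offset, 0)
    g_end = window.start + min(offset + L, W)
    if strand == "+":
        matched = window.seq[max(offset, 0): offset + L]
    else:
        matched = revcomp(window.seq[max(offset, 0): offset + L])
    return SpacerMatch(
        strand=strand,
        offset=offset,
        mismatch_count=mm,
        mismatch_positions=positions,
        matched_seq=matched,
        genome_start=g_start,
        genome_end=g_end,
    )


def observed_pam(
    genome: dict[str, str], chrom: str, match: SpacerMatch, params: MatchParams
) -> str:
    """Bases adjacent to the matched protospacer on the PAM side."""
    seq = genome[chrom]
    plen = len(params.pam_pattern)
    three_prime = params.pam_side == "3prime"
    if (match.strand == "+") == three_prime:
        lo, hi = match.genome_end, match.genome_end + plen
    else:
        lo, hi = match.genome_start - plen, match.genome_start
    if lo < 0 or hi > len(seq):
        return ""
    pam = seq[lo:hi]
    return pam if match.strand == "+" else revcomp(pam)


def annotate_sites(
    genome: dict[str, str],
    sites: list[DSBSite],
    grna: str,
    params: MatchParams | None = None,
) -> list[OffTargetHit]:
    """Match the guide against every site's flanks and classify."""
    from .seqs import matches_iupac

    params = params or MatchParams()
    if params.flank < len(grna):
        raise ValueError("flank must be at least the guide length")
    hits: list[OffTargetHit] = []
    for site in sites:
        window = extract_flank(genome, site, params.flank)
        if window.at_edge:
            hits.append(OffTargetHit(site, "edge", site.total_support))
            continue
        match = sw_match(grna, window, params)
        pam = observed_pam(genome, site.chrom, match, params)
        pam_ok = matches_iupac(pam, params.pam_pattern)
        if match.mismatch_count == 0:
            cls = "on-target"
        elif match.mismatch_count <= params.max_mismatches:
            cls = "off-target"
        else:
            cls = "unmatched"
        if params.require_pam and cls != "unmatched" and not pam_ok:
            cls = "unmatched"
        hits.append(OffTargetHit(site, cls, site.total_support, match, pam, pam_ok))
    return hits


def mismatch_string(grna: str, match: SpacerMatch) -> str:
    """Guide-length string: '.' where the genome matches the spacer, the
    genomic base where it does not (display convention of off-target
    tables; positions hanging off the window show '-')."""
    out = []
    mismatch_set = set(match.mismatch_positions)
    for i, base in enumerate(grna):
        if i not in mismatch_set:
            out.append(".")
        elif i < len(match.matched_seq):
            out.append(match.matched_seq[i] if match.offset + i >= 0 else "-")
        else:
            out.append("-")
    return "".join(out)


def classify_and_report(hits: list[OffTargetHit], grna: str) -> pd.DataFrame:
    """Annotated off-target table, sorted by read count (descending),
    ties by (chrom, cut position). Unmatched/edge sites sort after
    matched ones regardless of count."""
    rows = []
    for h in hits:
        m = h.match
        rows.append(
            {
                "chrom": h.site.chrom,
                "cut_position": h.site.cut_position,
                "classification": h.classification,
                "read_count": h.read_count,
                "mismatches": m.mismatch_count if m else None,
                "protospacer": m.matched_seq if m else "",
                "mismatch_pattern": mismatch_string(grna, m) if m else "",
                "strand": m.strand if m else "",
                "proto_start": m.genome_start if m else None,
                "proto_end": m.genome_end if m else None,
                "pam": h.pam_observed,
                "pam_ok": h.pam_ok,
                "support_plus": h.site.support_plus,
                "support_minus": h.site.support_minus,
                "evidence_class": h.site.evidence_class,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["_matched"] = ~df["classification"].isin(["on-target", "off-target"])
    df = df.sort_values(
        by=["_matched", "read_count", "chrom", "cut_position"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop(columns="_matched").reset_index(drop=True)
    return df
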