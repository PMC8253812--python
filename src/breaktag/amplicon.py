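"""Amplicon deep-seq validation: indel frequency, Tag-integration rate.

Reads are aligned to a short amplicon reference (infix alignment, both
orientations). Per-read indel and insertion boundaries are read off the
alignment path; inserted segments are then screened against the Tag with
a local alignment, and a Tag insertion is called when at least 16 bases
of the insertion match the Tag at >= 50% identity over the aligned
region (the printed decision rule; an aligner e-value is deliberately
not used).

indel_frequency = indel reads / total reads
integration_rate = donor (Tag-containing) reads / total reads
with exact rational arithmetic before any rounding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction

import edlib
from Bio import Align

from .seqs import revcomp

CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class TagDiscriminationParams:
    min_match_length: int = 16  # identical bases required
    min_identity: float = 0.5  # over the locally aligned region
    full_span_fraction: float = 0.9  # below this the manner is "partial"


@dataclass
class InsertionRecord:
    read_id: str
    classification: str  # wildtype / indel / donor / unaligned
    orientation: str = "+"
    boundaries: tuple[int, ...] = ()  # 0-based reference coords of I/D events
    inserted_segments: tuple[str, ...] = ()
    deletion_lengths: tuple[int, ...] = ()
    tag_matched: bool = False
    manner: str = ""  # forward / reverse / partial


@dataclass
class AmpliconResult:
    total_reads: int
    wildtype_reads: int
    indel_reads: int
    donor_reads: int
    unaligned_reads: int
    indel_frequency: float
    integration_rate: float


def _parse_path(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in CIGAR_RE.findall(cigar)]


def align_read(
    read: str, reference: str, max_divergence: float = 0.35
) -> tuple[str, str, list[tuple[int, str]]] | None:
    """Infix-align a read against the amplicon in both orientations.

    Returns (oriented read, orientation, alignment path) for the better
    orientation, or None when neither aligns within ``max_divergence``
    errors per read base.
    """
    best = None
    for orientation, seq in (("+", read), ("-", revcomp(read))):
        res = edlib.align(seq, reference, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        if best is None or res["editDistance"] < best[0]:
            start = res["locations"][0][0] if res["locations"] else 0
            best = (res["editDistance"], orientation, seq, res["cigar"], start)
    if best is None or best[0] > max_divergence * len(read):
        return None
    _dist, orientation, seq, cigar, start = best
    path = _parse_path(cigar)
    return seq, orientation, [(start, "start")] + path


def _variant_blocks(
    oriented: str,
    path: list[tuple[int, str]],
    min_indel_length: int,
    merge_distance: int = 10,
) -> tuple[list[int], list[str], list[int]]:
    """Collapse the alignment path into net indel events.

    Edit-distance paths are not unique and often fragment a long
    insertion into small I runs interleaved with coincidental matches,
    so variant ops (I/D/X) separated by match runs shorter than
    ``merge_distance`` are merged into one block first. A block with net
    query surplus is an insertion (its segment is the full query span of
    the block); net reference surplus is a deletion; a balanced block is
    a substitution run and not an indel. Returns (boundaries, inserted
    segments, deletion lengths), boundaries at block reference starts.
    """
    ref_pos = path[0][0]
    query_pos = 0
    # blocks of (ref_start, ref_end, query_start, query_end)
    blocks: list[list[int]] = []
    gap_since_block = None  # matched bases since the last block
    for length, op in path[1:]:
        is_match = op in ("=", "M")
        if is_match:
            if gap_since_block is not None:
                gap_since_block += length
            ref_pos += length
            query_pos += length
            continue
        q_len = length if op in ("I", "X") else 0
        r_len = length if op in ("D", "X") else 0
        if blocks and gap_since_block is not None and gap_since_block < merge_distance:
            blocks[-1][1] = ref_pos + r_len
            blocks[-1][3] = query_pos + q_len
        else:
            blocks.append([ref_pos, ref_pos + r_len, query_pos, query_pos + q_len])
        gap_since_block = 0
        ref_pos += r_len
        query_pos += q_len
    boundaries: list[int] = []
    inserted: list[str] = []
    deletions: list[int] = []
    for r_lo, r_hi, q_lo, q_hi in blocks:
        net = (q_hi - q_lo) - (r_hi - r_lo)
        if net >= min_indel_length:
            boundaries.append(r_lo)
            inserted.append(oriented[q_lo:q_hi])
        elif -net >= min_indel_length:
            boundaries.append(r_lo)
            deletions.append(-net)
    return boundaries, inserted, deletions


def find_insertion_boundaries(
    reads: list[tuple[str, str]],
    reference: str,
    tag: str,
    params: TagDiscriminationParams | None = None,
    min_indel_length: int = 1,
) -> list[InsertionRecord]:
    """Classify each (read_id, sequence) against the amplicon.

    wildtype: no indel in the alignment path (substitutions allowed);
    indel: insertions/deletions none of which match the Tag;
    donor: at least one inserted segment matches the Tag.
    """
    params = params or TagDiscriminationParams()
    records: list[InsertionRecord] = []
    for read_id, seq in reads:
        aligned = align_read(seq, reference)
        if aligned is None:
            records.append(InsertionRecord(read_id, "unaligned"))
            continue
        oriented, orientation, path = aligned
        boundaries_all, inserted, deletions = _variant_blocks(
            oriented, path, min_indel_length
        )
        boundaries = boundaries_all
        tag_matched, manner = False, ""
        for segment in inserted:
            matched, seg_manner = discriminate_tag(segment, tag, params)
            if matched:
                tag_matched, manner = True, seg_manner
                break
        if tag_matched:
            classification = "donor"
        elif boundaries:
            classification = "indel"
        else:
            classification = "wildtype"
        records.append(
            InsertionRecord(
                read_id=read_id,
                classification=classification,
                orientation=orientation,
                boundaries=tuple(boundaries),
                inserted_segments=tuple(inserted),
                deletion_lengths=tuple(deletions),
                tag_matched=tag_matched,
                manner=manner,
            )
        )
    return records


def _local_alignment_stats(segment: str, tag: str) -> tuple[int, int, int]:
    """(identical bases, aligned columns, aligned tag span) of the best
    local alignment of tag against segment."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    if not segment or not tag:
        return 0, 0, 0
    alignment = aligner.align(segment, tag)[0]
    identical = columns = 0
    tag_lo, tag_hi = None, 0
    for (s_lo, s_hi), (t_lo, t_hi) in zip(*alignment.aligned):
        columns += s_hi - s_lo
        if tag_lo is None:
            tag_lo = t_lo
        tag_hi = t_hi
        identical += sum(
            1 for a, b in zip(segment[s_lo:s_hi], tag[t_lo:t_hi]) if a == b
        )
    span = (tag_hi - tag_lo) if tag_lo is not None else 0
    return identical, columns, span


def discriminate_tag(
    segment: str, tag: str, params: TagDiscriminationParams | None = None
) -> tuple[bool, str]:
    """Is an inserted segment the Tag, and in which orientation?

    Matched iff the best local alignment (either strand) has at least
    ``min_match_length`` identical bases and identity >=
    ``min_identity``. The manner is forward/reverse by strand, or
    partial when only a sub-segment of the Tag matches.
    """
    params = params or TagDiscriminationParams()
    if not segment:
        raise ValueError("empty insertion segment")
    results = []
    for manner, query in (("forward", tag), ("reverse", revcomp(tag))):
        identical, columns, span = _local_alignment_stats(segment, query)
        results.append((identical, columns, span, manner))
    identical, columns, span, manner = max(results, key=lambda r: r[0])
    matched = bool(
        identical >= params.min_match_length
        and columns > 0
        and identical / columns >= params.min_identity
    )
    if matched and span < params.full_span_fraction * len(tag):
        manner = "partial"
    return matched, manner if matched else ""


def summarize_amplicon(
    records: list[InsertionRecord], include_unaligned: bool = False
) -> AmpliconResult:
    """Indel frequency and donor-integration rate over a read set.

    Unaligned reads are excluded from the denominator unless
    ``include_unaligned`` is set.
    """
    wildtype = sum(1 for r in records if r.classification == "wildtype")
    indel = sum(1 for r in records if r.classification == "indel")
    donor = sum(1 for r in records if r.classification == "donor")
    unaligned = sum(1 for r in records if r.classification == "unaligned")
    total = wildtype + indel + donor + (unaligned if include_unaligned else 0)
    if total == 0:
        raise ValueError("no reads in denominator")
    return AmpliconResult(
        total_reads=total,
        wildtype_reads=wildtype,
        indel_reads=indel,
        donor_reads=donor,
        unaligned_reads=unaligned,
        indel_frequency=float(Fraction(indel, total)),
        integration_rate=float(Fraction(donor, total)),
    )


def write_records_tsv(records: list[InsertionRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tclassification\tboundaries\ttag_matched\tmanner\n")
        for r in records:
            fh.write(
                f"{r.read_id}\t{r.classification}\t"
                f"{','.join(map(str, r.boundaries))}\t{int(r.tag_matched)}\t"
                f"{r.manner}\n"
            )
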