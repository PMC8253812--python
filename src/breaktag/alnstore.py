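"""Aligned-read ingestion, UMI consolidation and junction tracks.

Reads amplified with the tag-specific primer (read 2) start at the
tag-genome junction. For a plus-strand alignment the junction is the
leftmost aligned reference base; for a minus-strand alignment it is one
past the rightmost aligned base, so both strands report the same
molecular boundary. Soft clips (residual tag bases) are excluded from
the aligned span and therefore never shift the junction.

Reads sharing (chrom, position, strand, UMI, library) are PCR copies of
one pre-PCR molecule and are consolidated into a single observation;
every downstream read count is a count of consolidated molecules.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import pysam


@dataclass(frozen=True)
class AlignedPair:
    read_id: str
    chrom: str
    r2_start: int  # 0-based leftmost aligned base of read 2
    r2_end: int    # one past the rightmost aligned base
    strand: str
    mapq: int
    umi: str
    library: str

    @property
    def junction(self) -> int:
        return self.r2_start if self.strand == "+" else self.r2_end

    @property
    def key(self) -> tuple:
        """Consolidation key: same key means same pre-PCR molecule."""
        return (self.chrom, self.r2_start, self.strand, self.umi, self.library)


@dataclass(frozen=True)
class JunctionObservation:
    chrom: str
    junction: int
    strand: str
    library: str
    support: int = 1


@dataclass
class LoadReport:
    total: int = 0
    kept: int = 0
    unmapped: int = 0
    secondary: int = 0
    low_mapq: int = 0
    not_read2: int = 0


def _umi_from_name(name: str) -> str:
    """UMI is carried as the final underscore-delimited token of the name."""
    return name.rsplit("_", 1)[1] if "_" in name else ""


def load_alignments(
    path: str, min_mapq: int = 20, default_library: str = "fwd"
) -> tuple[list[AlignedPair], LoadReport]:
    """Load read-2 alignments from SAM/BAM, excluding secondary and
    supplementary records and anything below ``min_mapq``.

    The library is taken from the record's read group (RG tag) when
    present. Unmapped or mate-only records are counted and skipped.
    """
    report = LoadReport()
    pairs: list[AlignedPair] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            report.total += 1
            if rec.is_secondary or rec.is_supplementary:
                report.secondary += 1
                continue
            if rec.is_unmapped:
                report.unmapped += 1
                continue
            if rec.is_paired and not rec.is_read2:
                report.not_read2 += 1
                continue
            if rec.mapping_quality < min_mapq:
                report.low_mapq += 1
                continue
            try:
                library = rec.get_tag("RG")
            except KeyError:
                library = default_library
            pairs.append(
                AlignedPair(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    r2_start=rec.reference_start,
                    r2_end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mapq=rec.mapping_quality,
                    umi=_umi_from_name(rec.query_name),
                    library=str(library),
                )
            )
            report.kept += 1
    return pairs, report


def _umi_cluster_map(umis: list[str]) -> dict[str, str]:
    """Greedy 1-edit (substitution) clustering: each UMI maps to the most
    frequent UMI within Hamming distance 1, larger counts absorbing
    smaller (directional scheme)."""
    counts = Counter(umis)
    ordered = sorted(counts, key=lambda u: (-counts[u], u))
    mapping: dict[str, str] = {}
    for u in ordered:
        if u in mapping:
            continue
        mapping[u] = u
        for v in ordered:
            if v in mapping or len(v) != len(u):
                continue
            if sum(a != b for a, b in zip(u, v)) == 1 and counts[u] >= 2 * counts[v] - 1:
                mapping[v] = u
    return mapping


def consolidate_umi(
    pairs: list[AlignedPair], cluster_one_edit: bool = False
) -> list[JunctionObservation]:
    """Collapse PCR duplicates into one junction observation per molecule.

    With ``cluster_one_edit`` the UMIs at each (chrom, start, strand,
    library) are first clustered so a single sequencing error in the UMI
    does not split a molecule.
    """
    if cluster_one_edit:
        by_pos: dict[tuple, list[AlignedPair]] = defaultdict(list)
        for p in pairs:
            by_pos[(p.chrom, p.r2_start, p.strand, p.library)].append(p)
        keys = set()
        observations: Counter = Counter()
        for group in by_pos.values():
            mapping = _umi_cluster_map([p.umi for p in group])
            for p in group:
                keys.add((p.chrom, p.r2_start, p.strand, mapping[p.umi], p.library, p.junction))
        for chrom, _start, strand, _umi, library, junction in keys:
            observations[(chrom, junction, strand, library)] += 1
    else:
        seen: dict[tuple, int] = {}
        for p in pairs:
            seen.setdefault(p.key, p.junction)
        observations = Counter(
            (key[0], junction, key[2], key[4]) for key, junction in seen.items()
        )
    return [
        JunctionObservation(chrom=c, junction=j, strand=s, library=l, support=n)
        for (c, j, s, l), n in sorted(observations.items())
    ]


Track = dict[int, int]  # position -> consolidated molecule count


def junction_tracks(
    observations: list[JunctionObservation],
) -> dict[tuple[str, str, str], Track]:
    """Per (chrom, strand, library) sorted position->count tracks."""
    tracks: dict[tuple[str, str, str], Track] = defaultdict(dict)
    for obs in observations:
        track = tracks[(obs.chrom, obs.strand, obs.library)]
        track[obs.junction] = track.get(obs.junction, 0) + obs.support
    return {
        key: dict(sorted(track.items())) for key, track in sorted(tracks.items())
    }


def write_bed(tracks: dict[tuple[str, str, str], Track], path: str) -> None:
    """BED6: 0-based half-open single-base intervals, score = support,
    name = library."""
    rows = []
    for (chrom, strand, library), track in tracks.items():
        for pos, count in track.items():
            rows.append((chrom, pos, pos + 1, library, count, strand))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path: str) -> dict[tuple[str, str, str], Track]:
    observations = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, _end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            observations.append(
                JunctionObservation(chrom, int(start), strand, name, int(score))
            )
    return junction_tracks(observations)
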