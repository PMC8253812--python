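"""Demultiplexing, Tag filtering and read cleanup.

Raw read pairs carry a UMI and sample barcode at the start of read 1 and
a Tag-derived prefix at the start of read 2. Pairs are kept only when
read 2 begins with the expected Tag prefix (the hallmark of a read
amplified out of an integrated Tag); the prefix is stripped before
alignment. Adapter and quality trimming follow, and any pair left with a
mate shorter than 50 bp is discarded.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .seqs import phred_to_scores


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    umi: str = ""
    barcode: str = ""
    library: str = ""

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"sequence/quality length mismatch in {self.read_id}")


@dataclass
class FilterParams:
    tag_prefix: str = ""
    max_prefix_mismatches: int = 1
    min_length_after_trim: int = 50
    quality_threshold: int = 20
    adapter_sequences: tuple[str, ...] = ()
    umi_length: int = 8
    barcode_length: int = 8


@dataclass
class StageCounts:
    """Per-stage accounting; kept + dropped always equals the input."""

    stage: str
    kept: int = 0
    dropped: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.dropped


def _open_text(path: str) -> TextIO:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_pairs(r1_path: str, r2_path: str) -> Iterator[ReadPair]:
    """Stream paired FASTQ records; raises on malformed or desynced files."""
    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        it1, it2 = FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        for idx, (rec1, rec2) in enumerate(zip(it1, it2, strict=True)):
            (id1, seq1, qual1), (id2, seq2, qual2) = rec1, rec2
            core1, core2 = id1.split()[0], id2.split()[0]
            for suffix in ("/1", "/2"):
                core1 = core1.removesuffix(suffix)
                core2 = core2.removesuffix(suffix)
            if core1 != core2:
                raise ValueError(f"read id mismatch at record {idx}: {core1} vs {core2}")
            yield ReadPair(core1, seq1, qual1, seq2, qual2)


def write_pairs(pairs: Iterable[ReadPair], r1_path: str, r2_path: str) -> int:
    n = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")
            n += 1
    return n


def extract_umi_barcode(pair: ReadPair, params: FilterParams) -> ReadPair:
    """Move the UMI and sample barcode off the front of read 1."""
    k, b = params.umi_length, params.barcode_length
    pair.umi = pair.seq1[:k]
    pair.barcode = pair.seq1[k : k + b]
    pair.seq1 = pair.seq1[k + b :]
    pair.qual1 = pair.qual1[k + b :]
    return pair


def demultiplex(
    pairs: Iterable[ReadPair],
    barcode_table: dict[str, str],
    allow_one_mismatch: bool = False,
) -> tuple[dict[str, list[ReadPair]], StageCounts]:
    """Route pairs to samples by the barcode read off read 1.

    Returns per-sample lists plus an ``undetermined`` sink; counts are
    conserved. Barcodes must be unique and of equal length.
    """
    if len(set(barcode_table)) != len(barcode_table):
        raise ValueError("duplicate barcodes in table")
    lengths = {len(b) for b in barcode_table}
    if len(lengths) > 1:
        raise ValueError("barcodes must all have the same length")
    if len(set(barcode_table.values())) != len(barcode_table):
        raise ValueError("two barcodes map to the same sample name")
    out: dict[str, list[ReadPair]] = {s: [] for s in barcode_table.values()}
    out["undetermined"] = []
    counts = StageCounts("demultiplex")
    for pair in pairs:
        sample = barcode_table.get(pair.barcode)
        if sample is None and allow_one_mismatch:
            rescues = [
                s for b, s in barcode_table.items()
                if sum(x != y for x, y in zip(pair.barcode, b)) <= 1
                and len(pair.barcode) == len(b)
            ]
            if len(rescues) == 1:
                sample = rescues[0]
        if sample is None:
            out["undetermined"].append(pair)
            counts.dropped += 1
        else:
            out[sample].append(pair)
            counts.kept += 1
    return out, counts


def filter_tag_reads(
    pairs: Iterable[ReadPair], params: FilterParams
) -> tuple[list[ReadPair], StageCounts]:
    """Keep pairs whose read 2 starts with the Tag prefix; strip the prefix.

    A pair is retained iff the first ``len(tag_prefix)`` bases of read 2
    match the prefix with at most ``max_prefix_mismatches`` substitutions
    (no indels).
    """
    prefix = params.tag_prefix
    if not prefix:
        raise ValueError("tag_prefix must be non-empty")
    kept: list[ReadPair] = []
    counts = StageCounts("tag_filter")
    for pair in pairs:
        head = pair.seq2[: len(prefix)]
        if (
            len(head) == len(prefix)
            and sum(a != b for a, b in zip(head, prefix)) <= params.max_prefix_mismatches
        ):
            pair.seq2 = pair.seq2[len(prefix):]
            pair.qual2 = pair.qual2[len(prefix):]
            kept.append(pair)
            counts.kept += 1
        else:
            counts.dropped += 1
    return kept, counts


def _trim_adapter(seq: str, qual: str, adapters: tuple[str, ...]) -> tuple[str, str]:
    """Remove an adapter occurrence and everything 3' of it; also strip a
    partial adapter prefix overhanging the 3' read end (>= 5 bp)."""
    for adapter in adapters:
        idx = seq.find(adapter)
        if idx >= 0:
            return seq[:idx], qual[:idx]
        for k in range(len(adapter) - 1, 4, -1):
            if seq.endswith(adapter[:k]):
                return seq[:-k], qual[:-k]
    return seq, qual


def _trim_quality(seq: str, qual: str, threshold: int) -> tuple[str, str]:
    scores = phred_to_scores(qual)
    start, end = 0, len(seq)
    while start < end and scores[start] < threshold:
        start += 1
    while end > start and scores[end - 1] < threshold:
        end -= 1
    return seq[start:end], qual[start:end]


def trim_and_length_filter(
    pairs: Iterable[ReadPair], params: FilterParams
) -> tuple[list[ReadPair], StageCounts]:
    """Adapter- and quality-trim both mates; drop pairs with a short mate.

    Pairs in which either mate ends up shorter than
    ``min_length_after_trim`` (default 50 bp) are discarded.
    """
    kept: list[ReadPair] = []
    counts = StageCounts("trim_length_filter")
    for pair in pairs:
        s1, q1 = _trim_adapter(pair.seq1, pair.qual1, params.adapter_sequences)
        s2, q2 = _trim_adapter(pair.seq2, pair.qual2, params.adapter_sequences)
        s1, q1 = _trim_quality(s1, q1, params.quality_threshold)
        s2, q2 = _trim_quality(s2, q2, params.quality_threshold)
        if len(s1) < params.min_length_after_trim or len(s2) < params.min_length_after_trim:
            counts.dropped += 1
            continue
        pair.seq1, pair.qual1, pair.seq2, pair.qual2 = s1, q1, s2, q2
        kept.append(pair)
        counts.kept += 1
    return kept, counts
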