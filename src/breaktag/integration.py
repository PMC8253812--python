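"""Transposon integration-site mapping and TA-motif enrichment.

Sleeping Beauty-type transposases insert their cargo at TA dinucleotides.
Integration sites are called from a single arm-specific-primer library
with the same hotspot/window/peak machinery as nuclease breaks, but the
support rule is total molecules >= 5 with both strands represented.
Flanking sequence (+/-25 bp) is retrieved per site, and the dinucleotide
at the insertion step is tested for enrichment against a background
dinucleotide model with an exact binomial test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .alnstore import Track
from .dsbcall import CallParams, DSBSite, call_sites

DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]


@dataclass
class IntegrationSite:
    chrom: str
    position: int
    support_plus: int
    support_minus: int
    flank: str  # +/-25 bp around the insertion point
    annotation: str = ""

    @property
    def total_support(self) -> int:
        return self.support_plus + self.support_minus


@dataclass
class MotifResult:
    pfm: np.ndarray  # 4 x window, rows A/C/G/T, columns sum to 1
    window: int
    central_counts: dict[str, int]
    enrichment: "np.ndarray"  # unused placeholder kept simple; see table
    table: list[tuple[str, int, float, float]]  # (dinuc, count, fold, p), by p
    top_motif: str
    p_value: float


def call_integration_sites(
    tracks: dict[tuple[str, str, str], Track],
    genome: dict[str, str],
    params: CallParams | None = None,
    flank: int = 25,
) -> list[IntegrationSite]:
    """Peak calling in single-library mode with the transposon rule."""
    params = params or CallParams()
    sites: list[IntegrationSite] = []
    for s in call_sites(tracks, params, rule="transposon"):
        chrom_seq = genome[s.chrom]
        lo, hi = s.cut_position - flank, s.cut_position + flank
        sites.append(
            IntegrationSite(
                chrom=s.chrom,
                position=s.cut_position,
                support_plus=s.support_plus,
                support_minus=s.support_minus,
                flank=chrom_seq[max(0, lo):hi],
            )
        )
    return sites


def motif_windows(
    genome: dict[str, str], sites: list[IntegrationSite], halfwidth: int = 5
) -> list[str]:
    """Per-site windows of ``halfwidth`` bp either side of the central
    insertion dinucleotide (length 2*halfwidth + 2). Sites too close to a
    chromosome edge are skipped."""
    out = []
    for s in sites:
        seq = genome[s.chrom]
        lo, hi = s.position - halfwidth, s.position + halfwidth + 2
        if lo >= 0 and hi <= len(seq):
            out.append(seq[lo:hi])
    return out


def genome_dinucleotide_freqs(genome: dict[str, str]) -> dict[str, float]:
    counts = Counter()
    for seq in genome.values():
        for i in range(len(seq) - 1):
            d = seq[i : i + 2]
            if "N" not in d:
                counts[d] += 1
    total = sum(counts.values())
    return {d: counts.get(d, 0) / total for d in DINUCLEOTIDES}


def shuffled_background_freqs(
    windows: list[str], rng: np.random.Generator
) -> dict[str, float]:
    """Dinucleotide frequencies after per-window base shuffling: keeps
    composition, destroys positional structure."""
    counts = Counter()
    for w in windows:
        arr = np.array(list(w))
        rng.shuffle(arr)
        s = "".join(arr)
        for i in range(len(s) - 1):
            d = s[i : i + 2]
            if "N" not in d:
                counts[d] += 1
    total = sum(counts.values())
    return {d: counts.get(d, 0) / total for d in DINUCLEOTIDES}


def position_frequency_matrix(windows: list[str]) -> np.ndarray:
    """4 x L matrix (rows A, C, G, T); each column sums to 1."""
    L = len(windows[0])
    order = {b: i for i, b in enumerate("ACGT")}
    pfm = np.zeros((4, L))
    for w in windows:
        for j, base in enumerate(w):
            if base in order:
                pfm[order[base], j] += 1
    col_totals = pfm.sum(axis=0)
    col_totals[col_totals == 0] = 1
    return pfm / col_totals


def motif_enrichment(
    windows: list[str],
    background: dict[str, float],
    halfwidth: int = 5,
) -> MotifResult:
    """Exact binomial enrichment of each central-step dinucleotide.

    For each of the 16 dinucleotides the count of windows carrying it at
    the central insertion step is tested against the background frequency
    (one-sided, greater). Results are sorted by p-value ascending.
    """
    if len(windows) < 10:
        raise ValueError("need at least 10 flank windows for motif analysis")
    if len({len(w) for w in windows}) != 1:
        raise ValueError("flank windows must all have the same length")
    if len(windows[0]) != 2 * halfwidth + 2:
        raise ValueError("window length does not match halfwidth")

    pfm = position_frequency_matrix(windows)
    central = [w[halfwidth : halfwidth + 2] for w in windows]
    counts = Counter(c for c in central if "N" not in c)
    n = sum(counts.values())
    table = []
    for d in DINUCLEOTIDES:
        k = counts.get(d, 0)
        q = max(background.get(d, 0.0), 1e-12)
        p = binomtest(k, n, q, alternative="greater").pvalue
        fold = (k / n) / q if n else 0.0
        table.append((d, k, fold, p))
    table.sort(key=lambda row: (row[3], -row[1], row[0]))
    top = table[0]
    return MotifResult(
        pfm=pfm,
        window=len(windows[0]),
        central_counts=dict(counts),
        enrichment=np.array([row[2] for row in table]),
        table=table,
        top_motif=top[0],
        p_value=top[3],
    )


# ---------------------------------------------------------------------------
# genomic-region annotation

def load_region_intervals(path: str) -> list[tuple[str, int, int, str]]:
    """Read (chrom, start, end, class) intervals from a BED file whose
    name column is the region class (exon/intron/...)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            cls = fields[3] if len(fields) > 3 else "region"
            regions.append((chrom, start, end, cls.lower()))
    return regions


def annotate_regions(
    sites: list[IntegrationSite],
    intervals: list[tuple[str, int, int, str]],
) -> dict[str, int]:
    """Assign each site a region class by overlap; exon beats intron
    beats intergenic. Returns the class histogram (sites also get their
    ``annotation`` field set)."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, cls in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, cls)
    precedence = {"exon": 0, "exonic": 0, "intron": 1, "intronic": 1}
    histogram: Counter = Counter()
    for site in sites:
        hits = trees.get(site.chrom, IntervalTree())[site.position]
        classes = sorted(
            (h.data for h in hits), key=lambda c: precedence.get(c, 2)
        )
        label = {"exon": "exonic", "intron": "intronic"}.get(
            classes[0], classes[0]
        ) if classes else "intergenic"
        site.annotation = label
        histogram[label] += 1
    return dict(histogram)


def overlap_counts(
    runs: dict[str, list[IntegrationSite]], tolerance: int = 5
) -> dict[frozenset, int]:
    """Venn-style shared-site counts across runs: each site is labelled
    with the set of runs containing a site within ``tolerance`` bp on the
    same chromosome, and clusters are counted once."""
    points = []
    for run, sites in runs.items():
        for s in sites:
            points.append((s.chrom, s.position, run))
    points.sort()
    clusters: list[dict] = []
    for chrom, pos, run in points:
        if (
            clusters
            and clusters[-1]["chrom"] == chrom
            and pos - clusters[-1]["last"] <= tolerance
        ):
            clusters[-1]["runs"].add(run)
            clusters[-1]["last"] = pos
        else:
            clusters.append({"chrom": chrom, "last": pos, "runs": {run}})
    counts: Counter = Counter(frozenset(c["runs"]) for c in clusters)
    return dict(counts)


def ta_fraction(windows: list[str], halfwidth: int = 5) -> float:
    central = [w[halfwidth : halfwidth + 2] for w in windows]
    return sum(1 for c in central if c == "TA") / len(central)
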