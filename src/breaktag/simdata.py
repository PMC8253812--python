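"""Synthetic tag-integration sequencing data with full ground truth.

The simulator emulates the experiment end to end at desk scale: a random
genome, planted nuclease cleavage sites (with a protospacer carrying an
exact number of mismatches against the guide and a PAM next to it), a
double-stranded oligo Tag captured into each break, and paired-end reads
amplified with tag-specific primers. Every emitted read is recorded in a
truth table so each downstream stage can be scored against ground truth.

Geometry model
--------------
A break at top-strand nick ``c`` with signed overhang ``k`` (positive =
5' overhang) exposes two tag-genome junctions: the plus-library junction
at ``c`` and the minus-library junction at ``c + k``. Reads amplified
out of the Tag start at the junction and run into genomic sequence, so
the modal difference (minus junction - plus junction) recovers ``k``.

Coordinates are 0-based half-open throughout, including the truth table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .seqs import concrete_from_iupac, gc_content, matches_iupac, revcomp

# Synthetic stand-in for a GC-balanced double-stranded oligo Tag donor
# (35 nt, 45.7% GC). Not a vendor or published oligo sequence.
DEFAULT_TAG = "GTTGACATCGATGGTCAAGGTCTAACGATTACAGC"
assert round(100 * gc_content(DEFAULT_TAG), 1) == 45.7

DEFAULT_GRNA = "GATTACAGGCTCGAGCATCC"  # synthetic 20-nt spacer

BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class PlantedSite:
    """A nuclease target planted into the synthetic genome.

    ``cut_position`` is the 0-based top-strand nick. ``overhang`` may be a
    single signed offset (0 = blunt, +1 = 1-nt 5' overhang) or a tuple of
    offsets sampled uniformly per molecule (staggered cutters such as
    Cpf1 produce a mixture, e.g. ``(4, 5)``).
    """

    chrom: str
    cut_position: int
    strand: str = "+"
    mismatches_vs_grna: int = 0
    overhang: int | tuple[int, ...] = 0
    editing_efficiency: float = 1.0

    @property
    def overhangs(self) -> tuple[int, ...]:
        if isinstance(self.overhang, int):
            return (self.overhang,)
        return tuple(self.overhang)


@dataclass
class SimConfig:
    genome_length: int = 1_000_000
    n_chromosomes: int = 1
    gc_content: float = 0.41
    grna: str = DEFAULT_GRNA
    pam: str = "NGG"
    pam_side: str = "3prime"  # "3prime" (Cas9-like) or "5prime" (Cpf1-like)
    cut_offset_from_pam: int = 3
    planted_sites: list[PlantedSite] = field(default_factory=list)
    reads_per_site: int = 100
    background_integrations: int = 0
    pcr_duplicate_rate: float = 0.0
    error_rate: float = 0.0
    read_length: int = 100
    umi_length: int = 8
    barcode: str = "ACGTACGT"
    tag_sequence: str = DEFAULT_TAG
    seed: int = 0
    mode: str = "rgn"  # "rgn" (two tag-primer libraries) or "transposon" (one)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise SimulationError("gc_content must be in [0, 1]")
        for name in ("pcr_duplicate_rate", "error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1]")
        for name in ("genome_length", "n_chromosomes", "read_length", "umi_length"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.pam_side not in ("3prime", "5prime"):
            raise SimulationError("pam_side must be '3prime' or '5prime'")
        if self.mode not in ("rgn", "transposon"):
            raise SimulationError("mode must be 'rgn' or 'transposon'")
        min_r2 = len(self.tag_sequence) + 20
        min_r1 = self.umi_length + len(self.barcode) + 20
        if self.read_length < max(min_r1, min_r2):
            raise SimulationError(
                "read_length too short for UMI + barcode/tag + a genomic stub "
                f"(need >= {max(min_r1, min_r2)})"
            )

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_length(self) -> int:
        return self.genome_length // self.n_chromosomes


@dataclass
class SiteTruth:
    """Ground truth for one planted site."""

    site_id: str
    chrom: str
    cut_position: int
    strand: str
    mismatches: int
    overhangs: tuple[int, ...]
    protospacer: str  # as read on the protospacer strand
    proto_start: int  # + strand interval
    proto_end: int
    pam_observed: str
    editing_efficiency: float


@dataclass
class ReadTruth:
    read_id: str
    origin: str  # site_id or "background"
    chrom: str
    junction: int
    strand: str  # mapping strand of read 2
    library: str
    umi: str
    tag_orientation: str
    is_pcr_duplicate: bool


@dataclass
class SimReadPair:
    read_id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str
    library: str
    # alignment ground truth for read 2 (pre-aligned mode)
    chrom: str = ""
    pos: int = 0
    strand: str = "+"
    cigar: str = ""


@dataclass
class SimTruth:
    sites: list[SiteTruth]
    reads: list[ReadTruth]


def _protospacer_layout(
    config: SimConfig, site: PlantedSite
) -> tuple[int, int, bool]:
    """(+ strand start of the protospacer+PAM block, block length,
    pam_at_low_end) for a site's placement around its cut."""
    L = len(config.grna)
    plen = len(config.pam)
    off = config.cut_offset_from_pam
    c = site.cut_position
    if config.pam_side == "3prime":
        if site.strand == "+":
            return c - L + off, L + plen, False
        return c - off - plen, L + plen, True
    if site.strand == "+":
        return c - off - plen, L + plen, True
    return c + off - L, L + plen, False


def _mutate_spacer(grna: str, n_mismatches: int, rng: np.random.Generator) -> str:
    if n_mismatches > len(grna):
        raise SimulationError("more mismatches requested than guide length")
    spacer = list(grna)
    if n_mismatches:
        positions = rng.choice(len(grna), size=n_mismatches, replace=False)
        for p in positions:
            alternatives = [b for b in "ACGT" if b != spacer[p]]
            spacer[p] = alternatives[rng.integers(3)]
    return "".join(spacer)


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(BASES[rng.choice(4, size=length, p=probs)])


def _spurious_hits(
    window: str, win_start: int, grna: str, planted: list[tuple[int, str]]
) -> bool:
    """True if the window holds a <=6-mismatch guide occurrence that is
    not one of the planted (start, strand) placements."""
    L = len(grna)
    rc = revcomp(grna)
    for i in range(len(window) - L + 1):
        sub = window[i : i + L]
        for strand, query in (("+", grna), ("-", rc)):
            if (win_start + i, strand) in planted:
                continue
            if sum(a != b for a, b in zip(sub, query)) <= 6:
                return True
    return False


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], list[SiteTruth]]:
    """Build the reference and plant every configured site into it.

    Each planted site's flank carries a protospacer at exactly the
    requested Hamming distance from the guide, next to a concrete PAM
    drawn from the IUPAC pattern. Chromosomes are re-drawn (bounded
    retries) if the random background happens to contain another
    near-match of the guide within 100 bp of a planted site.
    """
    clen = config.chrom_length
    flank_clear = max(25, len(config.grna) + len(config.pam) + abs(config.cut_offset_from_pam))
    by_chrom: dict[str, list[PlantedSite]] = {c: [] for c in config.chrom_names}
    for site in config.planted_sites:
        if site.chrom not in by_chrom:
            raise SimulationError(f"site on unknown chromosome {site.chrom!r}")
        lo = site.cut_position - flank_clear - max(site.overhangs + (0,))
        hi = site.cut_position + flank_clear + max(site.overhangs + (0,))
        if lo < 0 or hi > clen:
            raise SimulationError(
                f"site at {site.chrom}:{site.cut_position} violates the "
                f"{flank_clear} bp flank clearance"
            )
        by_chrom[site.chrom].append(site)

    rng = np.random.default_rng(config.seed)
    genome: dict[str, str] = {}
    truths: list[SiteTruth] = []
    site_serial = 0
    for chrom in config.chrom_names:
        sites = by_chrom[chrom]
        for attempt in range(10):
            seq = list(_random_sequence(clen, config.gc_content, rng))
            chrom_truths = []
            planted_placements: list[tuple[int, str]] = []
            for site in sites:
                spacer = _mutate_spacer(config.grna, site.mismatches_vs_grna, rng)
                pam_seq = concrete_from_iupac(config.pam, rng)
                start, blen, pam_low = _protospacer_layout(config, site)
                if start < 0 or start + blen > clen:
                    raise SimulationError(
                        f"protospacer block out of bounds at {chrom}:{site.cut_position}"
                    )
                block = pam_seq + spacer if pam_low else spacer + pam_seq
                if site.strand == "-":
                    block = revcomp(spacer + pam_seq if pam_low else pam_seq + spacer)
                seq[start : start + blen] = block
                # the PAM occupies the low-coordinate end of the block iff
                # pam_low, on either strand
                proto_start = start + (len(config.pam) if pam_low else 0)
                chrom_truths.append(
                    SiteTruth(
                        site_id=f"site{site_serial + len(chrom_truths):03d}",
                        chrom=chrom,
                        cut_position=site.cut_position,
                        strand=site.strand,
                        mismatches=site.mismatches_vs_grna,
                        overhangs=site.overhangs,
                        protospacer=spacer,
                        proto_start=proto_start,
                        proto_end=proto_start + len(config.grna),
                        pam_observed=pam_seq,
                        editing_efficiency=site.editing_efficiency,
                    )
                )
                planted_placements.append(
                    (proto_start, site.strand)
                )
            text = "".join(seq)
            ok = True
            for site, truth in zip(sites, chrom_truths):
                w_lo = max(0, site.cut_position - 100 - len(config.grna))
                w_hi = min(clen, site.cut_position + 100 + len(config.grna))
                if _spurious_hits(text[w_lo:w_hi], w_lo, config.grna, planted_placements):
                    ok = False
                    break
            if ok:
                genome[chrom] = text
                truths.extend(chrom_truths)
                site_serial += len(chrom_truths)
                break
        else:
            raise SimulationError(
                f"could not place sites on {chrom} without a guide collision "
                f"(site near {sites[0].cut_position if sites else '?'}); "
                "planted sites may be too close together"
            )
    # planted protospacers must verify against the declared geometry
    for t in truths:
        window = genome[t.chrom][t.proto_start : t.proto_end]
        observed = window if t.strand == "+" else revcomp(window)
        if observed != t.protospacer:
            raise AssertionError("internal error: protospacer placement mismatch")
        if not matches_iupac(t.pam_observed, config.pam):
            raise AssertionError("internal error: PAM does not match its pattern")
    return genome, truths


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        current = arr[i].decode()
        alternatives = [b for b in "ACGT" if b != current]
        arr[i] = alternatives[rng.integers(3)].encode()
    return arr.tobytes().decode()


def simulate_reads(
    genome: dict[str, str], sites: list[SiteTruth], config: SimConfig
) -> tuple[list[SimReadPair], SimTruth]:
    """Emit tag-primer read pairs for every edited molecule.

    In ``rgn`` mode each edited molecule yields one read pair in the
    forward-primer library and one in the reverse-primer library (the two
    nested PCRs of a sample), covering the two sides of the break
    according to the random Tag orientation. In ``transposon`` mode a
    single arm-specific library is emitted and each molecule contributes
    one read pair on a random side.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1]).generate_state(1)[0]
    )
    tag = config.tag_sequence
    glen_r2 = config.read_length - len(tag)
    r1_genomic = config.read_length - config.umi_length - len(config.barcode)
    if glen_r2 < 20 or r1_genomic < 20:
        raise SimulationError("read_length leaves too short a genomic stub")

    reads: list[SimReadPair] = []
    truth_rows: list[ReadTruth] = []
    serial = 0

    def emit(origin: str, chrom: str, cut: int, overhang: int, orientation: str) -> None:
        nonlocal serial
        chrom_seq = genome[chrom]
        umi = "".join(BASES[rng.integers(0, 4, size=config.umi_length)])
        jp, jm = cut, cut + overhang
        if config.mode == "rgn":
            if orientation == "F":
                emissions = [("fwd", "+"), ("rev", "-")]
            else:
                emissions = [("fwd", "-"), ("rev", "+")]
        else:
            emissions = [("arm", "+" if rng.random() < 0.5 else "-")]
        for library, side in emissions:
            if side == "+":
                g = min(glen_r2, len(chrom_seq) - jp)
                genomic = chrom_seq[jp : jp + g]
                pos, cigar = jp, f"{len(tag)}S{g}M"
                r1_fill = revcomp(chrom_seq[jp : jp + r1_genomic])
                junction = jp
            else:
                g = min(glen_r2, jm)
                genomic = revcomp(chrom_seq[jm - g : jm])
                pos, cigar = jm - g, f"{g}M{len(tag)}S"
                r1_fill = chrom_seq[max(0, jm - r1_genomic) : jm]
                junction = jm
            r2 = tag + genomic
            r1 = umi + config.barcode + r1_fill
            n_copies = 1
            while rng.random() < config.pcr_duplicate_rate:
                n_copies += 1
            for copy in range(n_copies):
                read_id = f"sim{serial:07d}_{library}_{umi}"
                serial += 1
                reads.append(
                    SimReadPair(
                        read_id=read_id,
                        r1_seq=_apply_errors(r1, config.error_rate, rng),
                        r1_qual="I" * len(r1),
                        r2_seq=_apply_errors(r2, config.error_rate, rng),
                        r2_qual="I" * len(r2),
                        library=library,
                        chrom=chrom,
                        pos=pos,
                        strand=side,
                        cigar=cigar,
                    )
                )
                truth_rows.append(
                    ReadTruth(
                        read_id=read_id,
                        origin=origin,
                        chrom=chrom,
                        junction=junction,
                        strand=side,
                        library=library,
                        umi=umi,
                        tag_orientation=orientation,
                        is_pcr_duplicate=copy > 0,
                    )
                )

    for site in sites:
        for _ in range(config.reads_per_site):
            if rng.random() >= site.editing_efficiency:
                continue
            overhang = site.overhangs[rng.integers(len(site.overhangs))]
            orientation = "F" if rng.random() < 0.5 else "R"
            emit(site.site_id, site.chrom, site.cut_position, overhang, orientation)

    margin = config.read_length + 1
    for _ in range(config.background_integrations):
        chrom = config.chrom_names[rng.integers(config.n_chromosomes)]
        pos = int(rng.integers(margin, len(genome[chrom]) - margin))
        orientation = "F" if rng.random() < 0.5 else "R"
        emit("background", chrom, pos, 0, orientation)

    return reads, SimTruth(sites=list(sites), reads=truth_rows)


# ---------------------------------------------------------------------------
# writers (plain-text formats only)

def write_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: list[SimReadPair], r1_path: str, r2_path: str) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for r in reads:
            f1.write(f"@{r.read_id}/1\n{r.r1_seq}\n+\n{r.r1_qual}\n")
            f2.write(f"@{r.read_id}/2\n{r.r2_seq}\n+\n{r.r2_qual}\n")


def write_sam(reads: list[SimReadPair], genome: dict[str, str], path: str) -> None:
    """Pre-aligned mode: read-2 records with ground-truth POS/CIGAR.

    The tag prefix is represented as a soft clip so the aligned start is
    the tag-genome junction (plus strand) or the aligned end is (minus).
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in genome.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for lib in sorted({r.library for r in reads}):
            fh.write(f"@RG\tID:{lib}\tSM:sim\n")
        for r in reads:
            if r.strand == "+":
                flag = 0x1 | 0x8 | 0x80  # paired, mate unmapped, second of pair
                seq = r.r2_seq
            else:
                flag = 0x1 | 0x8 | 0x80 | 0x10
                seq = revcomp(r.r2_seq)
            fh.write(
                f"{r.read_id}\t{flag}\t{r.chrom}\t{r.pos + 1}\t60\t{r.cigar}"
                f"\t*\t0\t0\t{seq}\t{'I' * len(seq)}\tRG:Z:{r.library}\n"
            )


def write_truth(truth: SimTruth, sites_path: str, reads_path: str) -> None:
    with open(sites_path, "w") as fh:
        fh.write(
            "site_id\tchrom\tcut_position\tstrand\tmismatches\toverhangs\t"
            "protospacer\tproto_start\tproto_end\tpam\tediting_efficiency\n"
        )
        for s in truth.sites:
            fh.write(
                f"{s.site_id}\t{s.chrom}\t{s.cut_position}\t{s.strand}\t"
                f"{s.mismatches}\t{','.join(map(str, s.overhangs))}\t"
                f"{s.protospacer}\t{s.proto_start}\t{s.proto_end}\t"
                f"{s.pam_observed}\t{s.editing_efficiency}\n"
            )
    with open(reads_path, "w") as fh:
        fh.write(
            "read_id\torigin\tchrom\tjunction\tstrand\tlibrary\tumi\t"
            "tag_orientation\tis_pcr_duplicate\n"
        )
        for r in truth.reads:
            fh.write(
                f"{r.read_id}\t{r.origin}\t{r.chrom}\t{r.junction}\t{r.strand}\t"
                f"{r.library}\t{r.umi}\t{r.tag_orientation}\t"
                f"{int(r.is_pcr_duplicate)}\n"
            )


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["planted_sites"] = [dataclasses.asdict(s) for s in config.planted_sites]
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    sites = [
        PlantedSite(**{**s, "overhang": tuple(s["overhang"])
                       if isinstance(s.get("overhang"), list) else s.get("overhang", 0)})
        for s in d.pop("planted_sites", [])
    ]
    return SimConfig(planted_sites=sites, **d)
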