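"""Cleavage-geometry characterization at called break sites.

The two tag-specific libraries read the two sides of a break: plus-strand
junctions mark where the top strand was cut, minus-strand junctions where
the bottom strand was. The signed offset (minus-side junction minus the
modal plus-side junction) therefore recovers the overhang the nuclease
left: 0 for a blunt cutter, +1 for the 1-nt 5' overhang typical of Cas9,
+4/+5 mixtures for staggered cutters such as Cpf1. Positive offsets are
5' overhangs by convention.

The quantitative rule (modal offsets, 20% mass threshold for calling a
multi-overhang site) formalizes what is usually read off a junction
pileup by eye; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alnstore import Track
from .dsbcall import DSBSite
from .targetmatch import MatchParams, OffTargetHit

BLUNT = "blunt"
OVERHANG_5P = "1-nt 5' overhang"
OVERHANG_3P = "1-nt 3' overhang"
STAGGERED = "staggered-multi"
UNDETERMINED = "undetermined"


@dataclass
class CutProfile:
    site: DSBSite
    plus_hist: dict[int, int]
    minus_hist: dict[int, int]
    offsets: dict[int, float]  # signed offset -> fraction of minus-side mass
    modal_overhangs: list[tuple[int, float]]
    geometry_label: str

    @property
    def modal_offset(self) -> int | None:
        return self.modal_overhangs[0][0] if self.modal_overhangs else None


def _modal(hist: dict[int, int]) -> int:
    """Most supported position, leftmost on ties."""
    return min(hist, key=lambda p: (-hist[p], p))


def infer_cut_profile(
    site: DSBSite,
    tracks: dict[tuple[str, str, str], Track],
    margin: int = 15,
    multi_mass: float = 0.20,
) -> CutProfile:
    """Offset distribution and geometry label for one site.

    Junctions within ``margin`` bp of the consensus cut are pooled over
    libraries per strand. The offset distribution assigns each
    minus-side junction its offset from the modal plus-side junction,
    weighted by molecule support.
    """
    lo, hi = site.cut_position - margin, site.cut_position + margin + 1
    plus_hist: dict[int, int] = {}
    minus_hist: dict[int, int] = {}
    for (chrom, strand, _library), track in tracks.items():
        if chrom != site.chrom:
            continue
        hist = plus_hist if strand == "+" else minus_hist
        for pos, count in track.items():
            if lo <= pos < hi:
                hist[pos] = hist.get(pos, 0) + count
    if not plus_hist or not minus_hist:
        return CutProfile(site, plus_hist, minus_hist, {}, [], UNDETERMINED)

    anchor = _modal(plus_hist)
    total = sum(minus_hist.values())
    offsets = {
        pos - anchor: count / total for pos, count in sorted(minus_hist.items())
    }
    modal = sorted(offsets.items(), key=lambda kv: (-kv[1], kv[0]))
    top_offset = modal[0][0]
    heavy = [o for o, frac in offsets.items() if frac >= multi_mass]
    if len(heavy) >= 2 or abs(top_offset) >= 2:
        label = STAGGERED
    elif top_offset == 0:
        label = BLUNT
    elif top_offset == 1:
        label = OVERHANG_5P
    else:  # top_offset == -1
        label = OVERHANG_3P
    return CutProfile(site, plus_hist, minus_hist, offsets, modal, label)


def pam_offset(hit: OffTargetHit, params: MatchParams | None = None) -> int:
    """Signed distance from the consensus cut to the PAM-proximal
    protospacer boundary, normalized for protospacer orientation (so the
    Cas9 convention 'cut 3 bp upstream of the NGG PAM' reads 3 on either
    strand)."""
    params = params or MatchParams()
    if hit.match is None:
        raise ValueError("pam_offset requires a matched site")
    cut = hit.site.cut_position
    three_prime = params.pam_side == "3prime"
    if (hit.match.strand == "+") == three_prime:
        return hit.match.genome_end - cut
    return cut - hit.match.genome_start


def write_profiles_tsv(profiles: list[CutProfile], path: str) -> None:
    """Offset distributions, one row per site.

    Sign convention: positive offsets are 5' overhangs (the minus-side
    junction lies right of the plus-side junction).
    """
    with open(path, "w") as fh:
        fh.write("chrom\tcut_position\tgeometry\tmodal_offset\toffsets\n")
        for p in profiles:
            offs = ",".join(f"{o}:{frac:.3f}" for o, frac in sorted(p.offsets.items()))
            fh.write(
                f"{p.site.chrom}\t{p.site.cut_position}\t{p.geometry_label}\t"
                f"{p.modal_offset if p.modal_offset is not None else 'NA'}\t{offs}\n"
            )
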