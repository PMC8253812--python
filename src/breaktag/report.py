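"""Run reports and the three visualization modules: genome-wide site
distribution, per-site junction/editing view, and cross-experiment
comparison of a single break site.

All figures are written as SVG with a fixed hash salt and no embedded
date so that identical inputs give byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "breaktag"

import matplotlib.pyplot as plt
import pandas as pd

from .cutprofile import CutProfile
from .dsbcall import DSBSite

_SAVE_KW = {"format": "svg", "metadata": {"Date": None}}


@dataclass
class RunReport:
    """Per-stage accounting and the parameter record of one run."""

    stages: list[dict] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    site_count: int = 0
    outputs: dict = field(default_factory=dict)

    def add_stage(self, stage: str, kept: int, dropped: int) -> None:
        self.stages.append({"stage": stage, "kept": kept, "dropped": dropped,
                            "total": kept + dropped})

    def check_reconciled(self) -> bool:
        """Each stage's input must equal the previous stage's kept count."""
        for prev, cur in zip(self.stages, self.stages[1:]):
            if cur["total"] != prev["kept"]:
                return False
        return True

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def plot_genomewide(
    sites: list[DSBSite], chrom_lengths: dict[str, int], path: str
) -> None:
    """One panel per chromosome; each site a point at its coordinate with
    size proportional to molecule support."""
    chroms = sorted(chrom_lengths)
    n = max(1, len(chroms))
    fig, axes = plt.subplots(n, 1, figsize=(8, 1.2 * n + 1), squeeze=False)
    by_chrom: dict[str, list[DSBSite]] = {c: [] for c in chroms}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for ax, chrom in zip(axes[:, 0], chroms):
        ax.set_xlim(0, chrom_lengths[chrom])
        ax.set_ylim(-1, 1)
        ax.set_yticks([])
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center")
        here = by_chrom.get(chrom, [])
        if here:
            xs = [s.cut_position for s in here]
            sizes = [10 + 3 * s.total_support for s in here]
            ax.scatter(xs, [0] * len(xs), s=sizes, color="firebrick", alpha=0.7)
        ax.axhline(0, color="0.8", lw=0.8, zorder=0)
    axes[-1, 0].set_xlabel("position (bp)")
    fig.suptitle("Called DSB sites (point size ∝ molecule support)")
    fig.tight_layout()
    fig.savefig(path, **_SAVE_KW)
    plt.close(fig)


def plot_site_profile(profile: CutProfile, path: str) -> None:
    """Junction pileup around one site, plus/minus strands mirrored, with
    the consensus cut marked by a red dotted line."""
    fig, ax = plt.subplots(figsize=(7, 3))
    cut = profile.site.cut_position
    for hist, sign, color, label in (
        (profile.plus_hist, 1, "steelblue", "+ strand junctions"),
        (profile.minus_hist, -1, "darkorange", "- strand junctions"),
    ):
        if hist:
            xs = sorted(hist)
            ax.bar(
                [x - cut for x in xs],
                [sign * hist[x] for x in xs],
                width=0.8,
                color=color,
                label=label,
            )
    ax.axvline(0, color="red", linestyle=":", label="consensus cut")
    ax.axhline(0, color="0.3", lw=0.8)
    ax.set_xlabel(f"offset from cut ({profile.site.chrom}:{cut})")
    ax.set_ylabel("molecules")
    ax.set_title(f"geometry: {profile.geometry_label}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, **_SAVE_KW)
    plt.close(fig)


def plot_offtarget_table(df: pd.DataFrame, grna: str, path: str) -> None:
    """Guide-versus-sites alignment view: the guide on the first line,
    one line per site with mismatched bases highlighted and the read
    count at the right."""
    rows = df[df["classification"].isin(["on-target", "off-target"])]
    n = len(rows) + 1
    fig, ax = plt.subplots(figsize=(0.22 * len(grna) + 3, 0.3 * n + 1))
    ax.axis("off")
    mono = {"family": "monospace", "fontsize": 9}
    for j, base in enumerate(grna):
        ax.text(j, 0, base, ha="center", va="center", weight="bold", **mono)
    ax.text(len(grna) + 2, 0, "reads", va="center", **mono)
    for i, (_, row) in enumerate(rows.iterrows(), start=1):
        pattern = row["mismatch_pattern"]
        for j in range(len(grna)):
            ch = pattern[j] if j < len(pattern) else "."
            color = "0.6" if ch == "." else "crimson"
            shown = "." if ch == "." else ch
            ax.text(j, -i, shown, ha="center", va="center", color=color, **mono)
        ax.text(len(grna) + 2, -i, str(row["read_count"]), va="center", **mono)
    ax.set_xlim(-1, len(grna) + 6)
    ax.set_ylim(-n, 1)
    fig.tight_layout()
    fig.savefig(path, **_SAVE_KW)
    plt.close(fig)


def compare_experiments(
    site: tuple[str, int],
    run_tables: dict[str, pd.DataFrame],
    tolerance: int = 5,
) -> pd.DataFrame:
    """Read counts and mismatch annotation of one break site across runs.

    The site is keyed by (chrom, position); a run matches when it has a
    called site on that chromosome within ``tolerance`` bp. Runs without
    the site contribute a zero-count row.
    """
    if len(run_tables) < 2:
        raise ValueError("need at least two runs to compare")
    chrom, position = site
    rows = []
    for run, table in run_tables.items():
        found = pd.DataFrame()
        if not table.empty:
            found = table[
                (table["chrom"] == chrom)
                & ((table["cut_position"] - position).abs() <= tolerance)
            ]
        if found.empty:
            rows.append({"run": run, "present": False, "read_count": 0,
                         "mismatches": None, "cut_position": None})
        else:
            r = found.iloc[0]
            rows.append({
                "run": run,
                "present": True,
                "read_count": int(r["read_count"]),
                "mismatches": r["mismatches"],
                "cut_position": int(r["cut_position"]),
            })
    return pd.DataFrame(rows)
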