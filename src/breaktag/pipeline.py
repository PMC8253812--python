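"""End-to-end orchestration.

RGN mode: preprocess -> alignment ingest -> UMI consolidation -> DSB
calling -> guide matching -> cut-geometry profiles -> report.
Transposon mode: the same front end, then integration-site calling and
TA-motif enrichment.

Alignment to a genome-scale reference is an external interface: the
pipeline consumes a user-supplied SAM/BAM (for example the simulator's
pre-aligned output) or shells out to a configured aligner command. A
manifest ties every output to the input hashes and parameter record;
rerunning an identical configuration reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import shlex
import subprocess
from dataclasses import dataclass, field

from Bio import SeqIO

from . import alnstore, cutprofile, dsbcall, integration, preprocess, report, targetmatch

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    genome_fasta: str
    grna: str = ""
    outdir: str = "breaktag_out"
    r1_fastq: str | None = None
    r2_fastq: str | None = None
    alignments: str | None = None  # SAM/BAM of read 2, UMI in read name
    aligner_cmd: str | None = None  # e.g. "bwa mem {genome} {r1} {r2} -o {sam}"
    mode: str = "rgn"
    filter_params: preprocess.FilterParams = field(default_factory=preprocess.FilterParams)
    call_params: dsbcall.CallParams = field(default_factory=dsbcall.CallParams)
    match_params: targetmatch.MatchParams = field(default_factory=targetmatch.MatchParams)
    motif_background: str = "genome"  # or "shuffle"
    figures: bool = True


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: str | None, what: str) -> str:
    if path is None or not os.path.exists(path):
        raise FileNotFoundError(f"missing {what}: {path!r}")
    return path


def load_genome(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _preprocess_stage(config: PipelineConfig, run_report: report.RunReport) -> str | None:
    """Tag-filter and trim the FASTQ input, if given; returns the
    filtered R2 path (None when starting from alignments only)."""
    if config.r1_fastq is None:
        return None
    _require(config.r1_fastq, "R1 FASTQ")
    _require(config.r2_fastq, "R2 FASTQ")
    params = config.filter_params
    pairs = [
        preprocess.extract_umi_barcode(p, params)
        for p in preprocess.read_pairs(config.r1_fastq, config.r2_fastq)
    ]
    run_report.add_stage("input", len(pairs), 0)
    kept, counts = preprocess.filter_tag_reads(pairs, params)
    run_report.add_stage(counts.stage, counts.kept, counts.dropped)
    kept, counts = preprocess.trim_and_length_filter(kept, params)
    run_report.add_stage(counts.stage, counts.kept, counts.dropped)
    r1_out = os.path.join(config.outdir, "filtered_R1.fastq")
    r2_out = os.path.join(config.outdir, "filtered_R2.fastq")
    # re-attach the UMI to the read name so consolidation can use it
    for p in kept:
        if not p.read_id.endswith("_" + p.umi):
            p.read_id = f"{p.read_id}_{p.umi}"
    preprocess.write_pairs(kept, r1_out, r2_out)
    return r2_out


def _alignment_stage(config: PipelineConfig, run_report: report.RunReport) -> str:
    if config.alignments is not None:
        return _require(config.alignments, "alignment file")
    if config.aligner_cmd is None:
        raise ValueError("either alignments or aligner_cmd must be configured")
    sam_out = os.path.join(config.outdir, "aligned.sam")
    cmd = config.aligner_cmd.format(
        genome=config.genome_fasta,
        r1=os.path.join(config.outdir, "filtered_R1.fastq"),
        r2=os.path.join(config.outdir, "filtered_R2.fastq"),
        sam=sam_out,
    )
    subprocess.run(shlex.split(cmd), check=True)
    return sam_out


def _tracks_stage(config: PipelineConfig, sam_path: str, run_report: report.RunReport):
    pairs, load_rep = alnstore.load_alignments(sam_path, config.call_params.min_mapq)
    run_report.add_stage("load_alignments", load_rep.kept, load_rep.total - load_rep.kept)
    observations = alnstore.consolidate_umi(pairs)
    molecules = sum(o.support for o in observations)
    run_report.add_stage("umi_consolidation", molecules, len(pairs) - molecules)
    tracks = alnstore.junction_tracks(observations)
    alnstore.write_bed(tracks, os.path.join(config.outdir, "junctions.bed"))
    return tracks


def _write_manifest(config: PipelineConfig, outputs: list[str]) -> str:
    manifest = {
        "tool_version": __version__,
        "parameters": {
            "filter": dataclasses.asdict(config.filter_params),
            "call": dataclasses.asdict(config.call_params),
            "match": dataclasses.asdict(config.match_params),
            "mode": config.mode,
            "grna": config.grna,
        },
        "inputs": {
            name: _sha256(path)
            for name, path in (
                ("genome", config.genome_fasta),
                ("r1", config.r1_fastq),
                ("r2", config.r2_fastq),
                ("alignments", config.alignments),
            )
            if path is not None and os.path.exists(path)
        },
        "outputs": {
            os.path.basename(p): _sha256(p) for p in sorted(outputs) if os.path.exists(p)
        },
    }
    path = os.path.join(config.outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def run_rgn_mode(config: PipelineConfig):
    """Full nuclease-mode run; returns (off-target table, profiles, report)."""
    os.makedirs(config.outdir, exist_ok=True)
    _require(config.genome_fasta, "genome FASTA")
    if not config.grna:
        raise ValueError("rgn mode requires a guide spacer sequence")
    genome = load_genome(config.genome_fasta)
    run_report = report.RunReport(
        parameters={"mode": "rgn", "grna": config.grna}
    )
    _preprocess_stage(config, run_report)
    sam_path = _alignment_stage(config, run_report)
    tracks = _tracks_stage(config, sam_path, run_report)

    sites = dsbcall.call_sites(tracks, config.call_params)
    dsbcall.write_sites_tsv(sites, os.path.join(config.outdir, "sites.tsv"))
    hits = targetmatch.annotate_sites(genome, sites, config.grna, config.match_params)
    table = targetmatch.classify_and_report(hits, config.grna)
    table_path = os.path.join(config.outdir, "offtargets.tsv")
    table.to_csv(table_path, sep="\t", index=False)
    profiles = [cutprofile.infer_cut_profile(s, tracks) for s in sites]
    profiles_path = os.path.join(config.outdir, "cut_profiles.tsv")
    cutprofile.write_profiles_tsv(profiles, profiles_path)

    outputs = [
        os.path.join(config.outdir, "junctions.bed"),
        os.path.join(config.outdir, "sites.tsv"),
        table_path,
        profiles_path,
    ]
    if config.figures:
        chrom_lengths = {c: len(s) for c, s in genome.items()}
        fig1 = os.path.join(config.outdir, "genomewide.svg")
        report.plot_genomewide(sites, chrom_lengths, fig1)
        outputs.append(fig1)
        fig2 = os.path.join(config.outdir, "offtargets.svg")
        report.plot_offtarget_table(table, config.grna, fig2)
        outputs.append(fig2)
    run_report.site_count = len(sites)
    run_report.outputs = {os.path.basename(p): p for p in outputs}
    run_report.to_json(os.path.join(config.outdir, "run_report.json"))
    _write_manifest(config, outputs)
    return table, profiles, run_report


def run_transposon_mode(config: PipelineConfig):
    """Transposon-mode run; returns (integration sites, motif result, report)."""
    os.makedirs(config.outdir, exist_ok=True)
    _require(config.genome_fasta, "genome FASTA")
    genome = load_genome(config.genome_fasta)
    run_report = report.RunReport(parameters={"mode": "transposon"})
    _preprocess_stage(config, run_report)
    sam_path = _alignment_stage(config, run_report)
    tracks = _tracks_stage(config, sam_path, run_report)

    sites = integration.call_integration_sites(tracks, genome, config.call_params)
    sites_path = os.path.join(config.outdir, "integration_sites.tsv")
    with open(sites_path, "w") as fh:
        fh.write("chrom\tposition\tsupport_plus\tsupport_minus\tannotation\tflank\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.support_plus}\t{s.support_minus}\t"
                f"{s.annotation}\t{s.flank}\n"
            )
    motif = None
    windows = integration.motif_windows(genome, sites)
    if len(windows) >= 10:
        if config.motif_background == "shuffle":
            import numpy as np

            background = integration.shuffled_background_freqs(
                windows, np.random.default_rng(0)
            )
        else:
            background = integration.genome_dinucleotide_freqs(genome)
        motif = integration.motif_enrichment(windows, background)
        motif_path = os.path.join(config.outdir, "motif_report.txt")
        with open(motif_path, "w") as fh:
            fh.write(f"n_sites\t{len(windows)}\n")
            fh.write(f"top_motif\t{motif.top_motif}\tp={motif.p_value:.3e}\n")
            fh.write("dinucleotide\tcount\tfold\tp_value\n")
            for d, k, fold, p in motif.table:
                fh.write(f"{d}\t{k}\t{fold:.3f}\t{p:.3e}\n")
            fh.write("position_frequency_matrix (rows A,C,G,T)\n")
            for row in motif.pfm:
                fh.write("\t".join(f"{v:.3f}" for v in row) + "\n")
    run_report.site_count = len(sites)
    run_report.to_json(os.path.join(config.outdir, "run_report.json"))
    _write_manifest(config, [sites_path])
    return sites, motif, run_report
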