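"""Simulator: planted-site construction, read geometry, determinism."""

import collections

import pytest

from breaktag.seqs import gc_content, hamming, matches_iupac, revcomp
from breaktag.simdata import (
    DEFAULT_TAG,
    PlantedSite,
    SimConfig,
    SimulationError,
    simulate_genome,
    simulate_reads,
    write_fasta,
)


def _flank(genome, truth, pad=25):
    seq = genome[truth.chrom]
    return seq[truth.cut_position - pad - 20 : truth.cut_position + pad + 20]


class TestGenome:
    @pytest.mark.parametrize("n_mismatches", [0, 1, 3, 6])
    def test_planted_protospacer_has_exact_mismatch_count(self, n_mismatches):
        config = SimConfig(
            genome_length=10_000,
            planted_sites=[PlantedSite("chr1", 5_000, mismatches_vs_grna=n_mismatches)],
            seed=5,
        )
        genome, truths = simulate_genome(config)
        t = truths[0]
        window = genome[t.chrom][t.proto_start : t.proto_end]
        observed = window if t.strand == "+" else revcomp(window)
        assert hamming(observed, config.grna) == n_mismatches
        if n_mismatches == 0:
            assert config.grna in _flank(genome, t)

    def test_pam_matches_iupac_pattern_on_both_strands(self):
        for strand in "+-":
            config = SimConfig(
                genome_length=10_000,
                planted_sites=[PlantedSite("chr1", 5_000, strand=strand)],
                seed=6,
            )
            _genome, truths = simulate_genome(config)
            assert matches_iupac(truths[0].pam_observed, config.pam)

    def test_minus_strand_protospacer_recoverable_by_revcomp(self):
        config = SimConfig(
            genome_length=10_000,
            planted_sites=[PlantedSite("chr1", 5_000, strand="-")],
            seed=7,
        )
        genome, truths = simulate_genome(config)
        t = truths[0]
        assert revcomp(genome["chr1"][t.proto_start : t.proto_end]) == config.grna

    def test_same_seed_gives_byte_identical_fasta(self, tmp_path):
        config = SimConfig(
            genome_length=20_000,
            planted_sites=[PlantedSite("chr1", 5_000)],
            seed=42,
        )
        paths = []
        for i in range(2):
            genome, _ = simulate_genome(config)
            p = tmp_path / f"g{i}.fa"
            write_fasta(genome, str(p))
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_gc_content_is_respected(self):
        for gc in (0.3, 0.6):
            config = SimConfig(genome_length=200_000, gc_content=gc, seed=1)
            genome, _ = simulate_genome(config)
            assert abs(gc_content(genome["chr1"]) - gc) < 0.01

    def test_flank_clearance_violation_names_the_site(self):
        config = SimConfig(
            genome_length=10_000,
            planted_sites=[PlantedSite("chr1", 10)],
            seed=1,
        )
        with pytest.raises(SimulationError, match="chr1:10"):
            simulate_genome(config)

    def test_invalid_rates_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(gc_content=1.5)
        with pytest.raises(SimulationError):
            SimConfig(error_rate=-0.1)
        with pytest.raises(SimulationError, match="read_length"):
            SimConfig(read_length=30)


class TestReads:
    def _run(self, **kwargs):
        defaults = dict(
            genome_length=20_000,
            planted_sites=[PlantedSite("chr1", 10_000, **kwargs.pop("site", {}))],
            reads_per_site=50,
            seed=9,
        )
        defaults.update(kwargs)
        config = SimConfig(**defaults)
        genome, truths = simulate_genome(config)
        reads, truth = simulate_reads(genome, truths, config)
        return config, genome, reads, truth

    def test_read_count_equals_truth_rows_and_ids_unique(self):
        _, _, reads, truth = self._run(pcr_duplicate_rate=0.3)
        assert len(reads) == len(truth.reads)
        ids = [r.read_id for r in reads]
        assert len(set(ids)) == len(ids)

    def test_blunt_cut_junctions_coincide(self):
        _, _, _, truth = self._run(site={"overhang": 0})
        plus = {r.junction for r in truth.reads if r.strand == "+"}
        minus = {r.junction for r in truth.reads if r.strand == "-"}
        assert plus == minus == {10_000}

    def test_one_nt_overhang_shifts_minus_junction_by_one(self):
        # hand oracle on the duplex: a 5' overhang of k leaves the
        # bottom-strand nick k bases right of the top-strand nick, so the
        # minus-library junction reads k bases downstream
        _, _, _, truth = self._run(site={"overhang": 1})
        plus = {r.junction for r in truth.reads if r.strand == "+"}
        minus = {r.junction for r in truth.reads if r.strand == "-"}
        assert plus == {10_000} and minus == {10_001}

    @pytest.mark.parametrize("overhang", [-2, 0, 3])
    def test_junction_offset_equals_planted_overhang(self, overhang):
        _, _, _, truth = self._run(site={"overhang": overhang})
        modal = lambda xs: collections.Counter(xs).most_common(1)[0][0]
        plus = modal([r.junction for r in truth.reads if r.strand == "+"])
        minus = modal([r.junction for r in truth.reads if r.strand == "-"])
        assert minus - plus == overhang

    def test_read2_carries_tag_prefix_then_genomic(self):
        config, genome, reads, truth = self._run()
        by_id = {t.read_id: t for t in truth.reads}
        for r in reads[:10]:
            assert r.r2_seq.startswith(config.tag_sequence)
            genomic = r.r2_seq[len(config.tag_sequence):]
            t = by_id[r.read_id]
            if t.strand == "+":
                expected = genome["chr1"][t.junction : t.junction + len(genomic)]
            else:
                expected = revcomp(genome["chr1"][t.junction - len(genomic) : t.junction])
            assert genomic == expected

    def test_zero_duplicate_rate_gives_unique_umi_position_pairs(self):
        _, _, _, truth = self._run(pcr_duplicate_rate=0.0)
        keys = [(r.umi, r.junction, r.strand, r.library) for r in truth.reads]
        assert len(set(keys)) == len(keys)
        assert not any(r.is_pcr_duplicate for r in truth.reads)

    def test_duplicates_share_umi_and_coordinates(self):
        _, _, _, truth = self._run(pcr_duplicate_rate=0.5)
        dups = [r for r in truth.reads if r.is_pcr_duplicate]
        assert dups, "expected duplicates at rate 0.5"
        originals = {
            (r.umi, r.junction, r.strand, r.library)
            for r in truth.reads
            if not r.is_pcr_duplicate
        }
        for d in dups:
            assert (d.umi, d.junction, d.strand, d.library) in originals

    def test_editing_efficiency_thins_molecule_count(self):
        _, _, _, truth = self._run(site={"editing_efficiency": 0.2}, reads_per_site=200)
        molecules = len({r.umi for r in truth.reads})
        assert 15 <= molecules <= 70  # binomial(200, 0.2) well within 5 sigma


def test_default_tag_is_gc_balanced():
    """The synthetic default Tag donor is designed GC-balanced (45.7%)."""
    assert round(100 * gc_content(DEFAULT_TAG), 1) == 45.7
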