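import os

import pytest

from breaktag import alnstore
from breaktag.simdata import (
    PlantedSite,
    SimConfig,
    simulate_genome,
    simulate_reads,
    write_sam,
)


def sim_to_tracks(config, tmpdir):
    """Run the simulator and return (genome, truths, truth, tracks)."""
    genome, truths = simulate_genome(config)
    reads, truth = simulate_reads(genome, truths, config)
    sam = os.path.join(str(tmpdir), "sim.sam")
    write_sam(reads, genome, sam)
    pairs, _ = alnstore.load_alignments(sam)
    tracks = alnstore.junction_tracks(alnstore.consolidate_umi(pairs))
    return genome, truths, truth, tracks


@pytest.fixture(scope="session")
def mismatch_ladder_run(tmp_path_factory):
    """One on-target plus off-targets at 1..6 mismatches, clean reads."""
    sites = [
        PlantedSite("chr1", 5_000 + 4_000 * i, "+", mismatches_vs_grna=min(i, 6))
        for i in range(8)
    ]
    config = SimConfig(
        genome_length=60_000,
        planted_sites=sites,
        reads_per_site=30,
        seed=101,
    )
    tmpdir = tmp_path_factory.mktemp("ladder")
    return config, *sim_to_tracks(config, tmpdir)


@pytest.fixture(scope="session")
def geometry_run(tmp_path_factory):
    """Blunt, 1-nt overhang and staggered (4/5 nt) planted sites."""
    sites = [
        PlantedSite("chr1", 5_000, overhang=0),
        PlantedSite("chr1", 10_000, overhang=1),
        PlantedSite("chr1", 15_000, overhang=(4, 5)),
    ]
    config = SimConfig(
        genome_length=25_000, planted_sites=sites, reads_per_site=40, seed=202
    )
    tmpdir = tmp_path_factory.mktemp("geometry")
    return config, *sim_to_tracks(config, tmpdir)
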