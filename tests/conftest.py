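import pytest

from taxdecon.dbbuild import build_group_databases
from taxdecon.simulate import make_fixture_world, sample_reads, spike_contamination

WORLD_SEED = 11


@pytest.fixture(scope="session")
def world():
    """The synthetic study setting: taxonomy, genomes, target transcriptome."""
    return make_fixture_world(WORLD_SEED)


@pytest.fixture(scope="session")
def group_dbs(world, tmp_path_factory):
    """The 19 group databases built from the fixture assemblies."""
    out = tmp_path_factory.mktemp("group_dbs")
    databases = build_group_databases(world.assemblies, world.taxid_partition(), out)
    return {db.group: db for db in databases}


@pytest.fixture(scope="session")
def spiked_sample(world):
    """A 2,000-read sample: 1,600 clean target reads + 20% spiked contaminants."""
    clean = sample_reads(world.transcriptome, n_pairs=800, seed=WORLD_SEED + 1)
    return spike_contamination(clean, world.sources, seed=WORLD_SEED + 2)
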