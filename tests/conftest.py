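import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from syngc.formats_io import GeneModel, GeneSet
from syngc.simulate import SimConfig, packaged_fixture_config, generate_genome_pair


def make_geneset(tag: str, ordinals: dict[str, list[str]]) -> GeneSet:
    """GeneSet from {chrom: [gene ids in order]}; 1 kb per gene slot."""
    genes = {}
    for chrom, ids in ordinals.items():
        for i, gid in enumerate(ids):
            genes[gid] = GeneModel(
                gene_id=gid, chrom=chrom, strand="+",
                start=i * 1000, end=i * 1000 + 500, ordinal=i,
            )
    return GeneSet(species_tag=tag, genes=genes, chrom_order=sorted(ordinals))


@pytest.fixture(scope="session")
def small_pair():
    """The packaged small simulated genome pair (2 chromosomes x 60 genes)."""
    return generate_genome_pair(packaged_fixture_config())


@pytest.fixture(scope="session")
def default_pipeline_run(tmp_path_factory):
    """One full-scale pipeline run on generator defaults, shared by tests."""
    from syngc.pipeline import fixture_run_config, run_pipeline
    from syngc.simulate import write_fixture

    d = tmp_path_factory.mktemp("default_fixture")
    write_fixture(d, SimConfig())
    out = d / "out"
    result = run_pipeline(fixture_run_config(str(d), seed=0), str(out))
    return d, out, result


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
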