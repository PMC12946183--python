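import numpy as np
import pytest

from transductomics import (
    CommunitySpec,
    GenomeSpec,
    ProphageSpec,
    generate_community,
)


@pytest.fixture
def phage_community():
    """A single 102 kb circular phage genome (cos-type packaging unit)."""
    spec = CommunitySpec(
        genomes=[GenomeSpec("crassus", 102_000, domain="virus", is_viral=True,
                            taxon="Testvirus crassus")],
        seed=11,
    )
    return generate_community(spec)


@pytest.fixture
def lysogen_community():
    """A 600 kb chromosome carrying one 56.9 kb prophage with pac at its start."""
    spec = CommunitySpec(
        genomes=[
            GenomeSpec(
                "host", 600_000,
                taxon="d__Bacteria;p__Bacteroidota;g__Bacteroides;s__Bacteroides sp",
            )
        ],
        prophages=[ProphageSpec("host", 100_000, 156_900, "pp1", pac_offset=0)],
        seed=7,
    )
    return generate_community(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
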