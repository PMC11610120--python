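import numpy as np
import pytest

from hybridqtl.markers import ContigMap
from hybridqtl.synthcross import SimConfig, TraitModel, Qtl


@pytest.fixture
def small_config():
    """A 100 kb single-contig cross, small enough for fast unit tests."""
    return SimConfig(
        seed=7,
        n_progeny=60,
        contigs=[("chrA", 100_000, "Scer")],
        marker_spacing_bp=500,
        read_depth=60,
        pool_size=20,
    )


@pytest.fixture
def two_subgenome_config():
    return SimConfig(
        seed=11,
        n_progeny=60,
        contigs=[("Sc_1", 80_000, "Scer"), ("Sk_1", 80_000, "Skud")],
        read_depth=60,
    )


@pytest.fixture
def contig_map():
    return ContigMap.from_records(
        [("chrA", 100_000, "Scer", "OS104", "OS253")]
    )


@pytest.fixture
def single_qtl_trait():
    return TraitModel(
        condition="drug",
        qtls=[Qtl("chrA", 50_000, 30.0, "OS253")],
        baseline=100.0,
        noise_sd=3.0,
    )
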