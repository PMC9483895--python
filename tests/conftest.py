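import pytest

from ltrkit.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down simulation: ~600 loci, 800 genes, full species panel."""
    return SimulationConfig(
        seed=5,
        insertion_rate=15.0,
        universe_size=800,
        synaptic_count=40,
        fetal_gonad_count=10,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


#: Published per-subfamily locus totals of the human LTR7 catalog.
TABLE_SUBFAMILY_COUNTS = {
    "LTR7B": 547,
    "LTR7C": 412,
    "LTR7bc": 307,
    "LTR7o": 243,
    "LTR7d1": 215,
    "LTR7d2": 445,
    "LTR7u1": 143,
    "LTR7u2": 195,
    "LTR7up1": 378,
    "LTR7up2": 96,
    "LTR7Y": 373,
}


@pytest.fixture(scope="session")
def reference_catalog():
    """A 3354-locus LTR7 catalog with the published subfamily totals."""
    from ltrkit.types import LTRLocus

    loci = []
    pos = 1000
    for subfamily, count in TABLE_SUBFAMILY_COUNTS.items():
        for i in range(count):
            loci.append(
                LTRLocus(
                    locus_id=f"{subfamily}_{i}",
                    family="LTR7",
                    subfamily=subfamily,
                    chrom="chr1",
                    start=pos,
                    end=pos + 450,
                    strand="+",
                )
            )
            pos += 1000
    return loci
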