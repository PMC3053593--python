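import pytest

from utrsnp.core import FlicRecord, Interval
from utrsnp.simulate import SimConfig, simulate_targets


@pytest.fixture
def flic_600():
    """A 600-nt transcript: CDS (0, 390), 3'UTR (400, 600)."""
    cds = ("ATG" + "GCATCAGTCGTTACGGATTC" * 20)[:387] + "TAA"  # 390 nt, in frame
    linker = "CCCCAAAAGG"
    utr = "ACGTTGCAAC" * 20
    seq = cds + linker + utr
    return FlicRecord(
        accession="FLIC600",
        sequence=seq,
        cds=Interval(0, 390),
        utr3=Interval(400, 600),
        complete_cds_flag=True,
    ).validate()


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic simulated dataset shared across tests."""
    config = SimConfig(
        seed=11,
        n_genes=6,
        utr3_len_range=(250, 500),
        cds_len_range=(300, 900),
        paralog_fraction=0.5,
        est_per_gene=6,
        est_error_rate=0.01,
    )
    flics, paralogs, truth = simulate_targets(config)
    return config, flics, paralogs, truth
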