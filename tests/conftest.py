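import pytest

from batseq import (
    AmpliconPanel,
    AmpliconTarget,
    BarcodeSet,
    RunConfig,
)


@pytest.fixture
def cfg():
    return RunConfig()


@pytest.fixture
def m13(cfg):
    return cfg.m13_seq


@pytest.fixture
def tiny_bset():
    """Four barcodes, some only one base apart, with distinct 4-suffixes."""
    return BarcodeSet(
        barcodes=["AAGGTC", "CCAATG", "TTTTGG", "AAGGTA"],
        labels=["L1", "L2", "L3", "L4"],
        address_suffix_len=4,
    )


@pytest.fixture
def tiny_panel():
    return AmpliconPanel(
        [
            AmpliconTarget(
                name="T1",
                insert_seq="ACGTACGTACGTACGTACGTACGTACGTACGT",
                fwd_primer="GGATCC",
                rev_primer="GAATTC",
            ),
            AmpliconTarget(
                name="T2",
                insert_seq="TTGCAATTGCAATTGCAATTGCAATTGCAATT",
                fwd_primer="AAGCTT",
                rev_primer="CTGCAG",
            ),
        ]
    )
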