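import numpy as np
import pytest

import spliceclip as sc


@pytest.fixture(scope="session")
def demo():
    """Standard synthetic study conditions: custom index + background."""
    index, background = sc.demo_transcriptome(seed=7)
    return index, background


@pytest.fixture(scope="session")
def index(demo):
    return demo[0]


@pytest.fixture(scope="session")
def background(demo):
    return demo[1]


@pytest.fixture(scope="session")
def barcode_spec():
    return sc.default_barcode_spec()


@pytest.fixture(scope="session")
def substrate(index):
    return index.substrate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_substrate(seq_len=400, exon1=100, intron=200, bra_offset=20):
    """Small hand-buildable substrate: exon1=[0,100), intron=[100,300), exon2=[300,400)."""
    rng = np.random.default_rng(99)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=seq_len))
    bra = exon1 + intron - 1 - bra_offset
    seq = seq[:bra] + "A" + seq[bra + 1 :]
    return sc.Substrate(
        name="sub",
        sequence=seq,
        exon1=(0, exon1),
        intron=(exon1, exon1 + intron),
        exon2=(exon1 + intron, seq_len),
        brA=bra,
    )


@pytest.fixture(scope="session")
def small_substrate():
    return make_substrate()
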