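import numpy as np
import pytest

import somselect as ss


@pytest.fixture(scope="session")
def gene():
    """Synthetic 403-codon tumor-suppressor-like gene (1212-nt CDS)."""
    return ss.synthetic_gene()


@pytest.fixture(scope="session")
def mtl_spectrum():
    return ss.crc_like_spectrum("MT-L")


@pytest.fixture(scope="session")
def profile(gene, mtl_spectrum):
    return ss.site_mutability(gene, mtl_spectrum)


@pytest.fixture(scope="session")
def codon_table(profile, gene):
    return ss.codon_profile(profile, gene)


@pytest.fixture(scope="session")
def score_table(gene):
    return ss.synthetic_score_table(gene)


@pytest.fixture
def toy_gene():
    """12-nt toy CDS (4 codons, no stop) with explicit flanks."""
    return ss.build_gene_model("ATGAAACGCTGG", "TOY", flank5="C", flank3="A")


def make_sample(**kw):
    kw.setdefault("sample_id", "S1")
    return ss.SampleRecord(**kw)


@pytest.fixture
def sample_factory():
    return make_sample
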