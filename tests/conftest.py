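import numpy as np
import pytest

import splicearray as sa
from splicearray._seq import decode


@pytest.fixture
def rng():
    return np.random.default_rng(20120901)


@pytest.fixture
def geometry():
    return sa.paper_geometry()


@pytest.fixture
def tiny_genome():
    """One chromosome with two genes whose introns carry canonical motifs."""
    rng = np.random.default_rng(11)
    seq = list(decode(rng.integers(0, 4, 3000).astype(np.uint8)))

    def set_motifs(istart, iend, strand):
        if strand == "+":
            seq[istart : istart + 2] = "GT"
            seq[iend - 2 : iend] = "AG"
        else:
            seq[istart : istart + 2] = "CT"
            seq[iend - 2 : iend] = "AC"

    # gene A ('+'): exons (100,200),(400,500),(800,900)
    for istart, iend in [(200, 400), (500, 800)]:
        set_motifs(istart, iend, "+")
    # gene B ('-'): exons (1500,1600),(1900,2000)
    set_motifs(1600, 1900, "-")
    return {"chr1": "".join(seq)}


@pytest.fixture
def tiny_models():
    return [
        sa.GeneModel("A.T1", "GENEA", "chr1", "+",
                     [(100, 200), (400, 500), (800, 900)], "refseq"),
        sa.GeneModel("A.T2", "GENEA", "chr1", "+",
                     [(100, 200), (800, 900)], "mrna"),
        sa.GeneModel("B.T1", "GENEB", "chr1", "-",
                     [(1500, 1600), (1900, 2000)], "refseq"),
    ]


@pytest.fixture
def tiny_probeset(tiny_genome, tiny_models, geometry):
    events = sa.build_events(tiny_models, tiny_genome,
                             min_anchor=geometry.flank_length)
    probes = sa.build_probes(events, tiny_genome, geometry)
    probes, _ = sa.collapse_ambiguous_probes(probes)
    return sa.ProbeSet(probes, geometry)
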