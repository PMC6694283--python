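"""Shared fixtures: a synthetic readthrough locus and its simulated run."""

import pytest

import ribothrough as rt


@pytest.fixture(scope="session")
def locus():
    """Default synthetic locus: 99-nt ISR, cds:isr:utr3 densities 50:5:1."""
    spec = rt.SimSpec(seed=11)
    return spec, rt.make_transcript(spec)


@pytest.fixture(scope="session")
def simulated(locus):
    """Reads and truth table for the default locus (20,000 reads)."""
    spec, ann = locus
    reads, truth = rt.simulate_footprints(ann, spec)
    return spec, ann, reads, truth


@pytest.fixture(scope="session")
def mapped(simulated):
    """Footprints recovered by exact matching of the simulated reads."""
    spec, ann, reads, truth = simulated
    footprints, stats = rt.map_reads(reads, {ann.transcript_id: ann.sequence})
    return ann, footprints, stats, truth


@pytest.fixture()
def thousand_nt_annotation():
    """L=1000 transcript with cds=[100,400) and stop2=[499,502)."""
    spec = rt.SimSpec(utr5_len=100, cds_len=300, isr_len=99, utr3_rest_len=498, n_reads=0, seed=3)
    ann = rt.make_transcript(spec)
    assert ann.cds == (100, 400) and ann.stop2 == (499, 502) and ann.length == 1000
    return ann


def centered_footprint(p_site, transcript_id="sim_tx", length=29, read_id="r"):
    """A footprint of odd length whose central nucleotide is ``p_site``."""
    half = (length - 1) // 2
    return rt.Footprint(read_id, transcript_id, p_site - half, p_site - half + length, p_site)
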