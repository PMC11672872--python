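"""Shared fixtures: a small simulated experiment and hand-built toy models."""

import warnings

import pytest

from lengthome.synthetic_data import (
    SimulationConfig,
    simulate_deg_lists,
    simulate_genome_and_annotation,
)
from lengthome.transcript_models import GenomicInterval, TranscriptModel


@pytest.fixture(autouse=True)
def _quiet_codon_warning():
    # the packaged worked-example fixture contains one published CDS length
    # that is not a codon multiple; the model layer warns about it by design
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*not a multiple of 3")
        yield


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_genes=220,
        list_sizes={"C10": 60, "C24": 120, "T10": 40, "T24": 60},
        shared_genes={("C10", "C24"): 15, ("T10", "T24"): 8},
        planted_switches={("C10", "C24"): 3, ("T10", "T24"): 2},
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_genome_and_annotation(small_cfg)


@pytest.fixture(scope="session")
def small_lists(small_cfg, small_sim):
    lists, truth = simulate_deg_lists(small_cfg, small_sim)
    return lists, truth


def make_transcript(tid="tx1", gene="g1", chrom="c1", strand="+",
                    exons=((1, 100), (201, 300)), cds=(51, 150)):
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    if strand == "-":
        ivs = sorted(ivs, key=lambda e: e.start, reverse=True)
    cds_start, cds_end = cds if cds else (None, None)
    return TranscriptModel(tid, gene, ivs, cds_start, cds_end).validate()


@pytest.fixture
def toy_transcript():
    return make_transcript()
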