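"""Generator contracts: determinism, planted structure, sequence realism."""

import numpy as np
import pytest
from scipy import stats as sps

from lengthome.deg_io import volcano_filter
from lengthome.isoform_switching import detect_switches
from lengthome.synthetic_data import (
    ConfigError,
    SimulationConfig,
    draw_utr3_lengths,
    simulate_deg_lists,
    simulate_genome_and_annotation,
)
from lengthome.transcript_models import GenomeStore, reverse_complement, spliced_sequence


class TestConfig:
    def test_infeasible_overlap_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(
                list_sizes={"C10": 10, "C24": 10},
                shared_genes={("C10", "C24"): 20},
                planted_switches={},
            ).validate()

    def test_switches_bounded_by_shared(self):
        with pytest.raises(ConfigError):
            SimulationConfig(
                list_sizes={"C10": 50, "C24": 50},
                shared_genes={("C10", "C24"): 5},
                planted_switches={("C10", "C24"): 6},
            ).validate()


class TestAnnotation:
    def test_zero_genes_gives_empty_annotation(self):
        cfg = SimulationConfig(seed=0, n_genes=0, shared_genes={}, planted_switches={},
                               list_sizes={})
        sim = simulate_genome_and_annotation(cfg)
        assert sim.models == []
        assert sim.genome == {}

    def test_same_seed_reproduces_outputs_exactly(self, small_cfg, small_sim):
        again = simulate_genome_and_annotation(small_cfg)
        assert again.genome == small_sim.genome
        assert [
            (t.transcript_id, t.gene_symbol, t.cds_start, t.cds_end,
             [(e.start, e.end, e.strand) for e in t.exons])
            for t in again.models
        ] == [
            (t.transcript_id, t.gene_symbol, t.cds_start, t.cds_end,
             [(e.start, e.end, e.strand) for e in t.exons])
            for t in small_sim.models
        ]

    def test_every_transcript_passes_sequence_oracle(self, small_sim):
        """Planted codons and canonical GT/AG ends are physically present."""
        gs = GenomeStore(small_sim.genome)
        for t in small_sim.models:
            t.validate()
            seq = spliced_sequence(t, gs)
            if t.is_coding:
                assert seq[t.cds_start - 1 : t.cds_start + 2] == "ATG"
                assert seq[t.cds_end - 3 : t.cds_end] == "TAA"
            for up, down in zip(t.exons, t.exons[1:]):
                if t.strand == "+":
                    intron = gs.fetch(t.chrom, up.end + 1, down.start - 1)
                else:
                    intron = reverse_complement(
                        gs.fetch(t.chrom, down.end + 1, up.start - 1)
                    )
                assert intron[:2] == "GT" and intron[-2:] == "AG"

    def test_utr3_mixture_is_bimodal_at_published_modes(self):
        """KDE of generated 3'UTR lengths has local maxima near 100 and
        1000 bp, the two peaks of the reference distribution."""
        rng = np.random.default_rng(123)
        lengths, _ = draw_utr3_lengths(rng, 2000, SimulationConfig())
        kde = sps.gaussian_kde(np.log10(lengths), bw_method="silverman")
        grid = np.linspace(1.0, 4.0, 400)
        dens = kde(grid)
        peaks = [
            10 ** grid[i]
            for i in range(1, len(grid) - 1)
            if dens[i] > dens[i - 1] and dens[i] > dens[i + 1]
        ]
        assert any(50 <= p <= 200 for p in peaks)
        assert any(500 <= p <= 2000 for p in peaks)


class TestDegLists:
    def test_configured_sizes_overlaps_and_switches(self, small_cfg, small_sim, small_lists):
        lists, truth = small_lists
        for cond, n in small_cfg.list_sizes.items():
            assert lists[cond].size == n
        for pair, s in small_cfg.shared_genes.items():
            assert truth["pairs"][pair]["shared"] == s
            events = detect_switches(lists[pair[0]], lists[pair[1]])
            assert len(events) == s
            switching = [e for e in events if e.is_switch]
            assert len(switching) == small_cfg.planted_switches[pair]
            assert {e.gene_symbol for e in switching} == set(
                truth["pairs"][pair]["switch_genes"]
            )

    def test_volcano_filter_is_identity_on_generator_output(self, small_lists):
        lists, _ = small_lists
        for cond, cl in lists.items():
            kept = volcano_filter(cl.records, condition=cond)
            assert kept.size == cl.size

    def test_zero_planted_switches_yields_no_switch_only(self, small_cfg):
        cfg = SimulationConfig(
            seed=3, n_genes=small_cfg.n_genes,
            list_sizes=small_cfg.list_sizes,
            shared_genes=small_cfg.shared_genes,
            planted_switches={p: 0 for p in small_cfg.shared_genes},
        )
        sim = simulate_genome_and_annotation(cfg, with_sequence=False)
        lists, _ = simulate_deg_lists(cfg, sim)
        for pair in cfg.shared_genes:
            events = detect_switches(lists[pair[0]], lists[pair[1]])
            assert all(e.switch_class == "no_switch" for e in events)

    def test_different_seeds_vary_samples_but_keep_counts(self, small_cfg, small_lists):
        lists1, _ = small_lists
        cfg2 = SimulationConfig(
            seed=small_cfg.seed + 1, n_genes=small_cfg.n_genes,
            list_sizes=small_cfg.list_sizes, shared_genes=small_cfg.shared_genes,
            planted_switches=small_cfg.planted_switches,
        )
        sim2 = simulate_genome_and_annotation(cfg2, with_sequence=False)
        lists2, _ = simulate_deg_lists(cfg2, sim2)
        for cond in small_cfg.list_sizes:
            assert lists2[cond].size == lists1[cond].size
        assert lists2["C24"].seqnames() != lists1["C24"].seqnames()

    def test_pool_too_small_is_config_error(self):
        cfg = SimulationConfig(
            seed=0, n_genes=30,
            list_sizes={"C10": 40, "C24": 40},
            shared_genes={("C10", "C24"): 10},
            planted_switches={("C10", "C24"): 2},
        )
        sim = simulate_genome_and_annotation(cfg, with_sequence=False)
        with pytest.raises(ConfigError):
            simulate_deg_lists(cfg, sim)
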