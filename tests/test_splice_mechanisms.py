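"""Junction extraction, mechanism cascade and splice-signal scoring."""

import pytest

from lengthome.fixtures import CANONICAL_PAIRS, canonical_pair_models, fixture_models_by_id
from lengthome.splice_mechanisms import (
    ComparabilityError,
    classify_mechanism,
    consensus_score,
    count_apa_events,
    extract_splice_signal,
    junctions,
)
from lengthome.synthetic_data import simulate_mechanism_pairs
from lengthome.transcript_models import GenomicInterval, TranscriptModel

from conftest import make_transcript


class TestJunctions:
    def test_single_exon_has_none(self):
        t = make_transcript(exons=((1, 500),), cds=None)
        assert junctions(t).junctions == frozenset()

    def test_four_exons_have_three(self):
        t = make_transcript(
            exons=((1, 100), (201, 300), (401, 500), (601, 700)), cds=None
        )
        assert len(junctions(t).junctions) == 3

    def test_minus_strand_coordinates(self):
        """Donor is the transcription-order last base of the upstream exon,
        which on the minus strand is the exon's genomic start."""
        t = make_transcript(strand="-", exons=((201, 300), (1, 100)), cds=None)
        assert junctions(t).junctions == {(201, 100)}


class TestClassifyMechanism:
    def test_self_comparison_is_identical(self):
        for t in fixture_models_by_id().values():
            call = classify_mechanism(t, t)
            assert call.event_class == "identical"
            assert set(call.region_codes.values()) == {"="}

    @pytest.mark.parametrize("gene", [p[0] for p in CANONICAL_PAIRS])
    def test_fixture_pair_classes(self, gene):
        """Each worked-example pair reproduces its published mechanism."""
        row = {g: (o, n, c, ev, cr) for g, o, n, c, ev, cr in canonical_pair_models()}[gene]
        old, new, codes, event, cryptic = row
        call = classify_mechanism(old, new)
        assert call.event_class == event
        assert call.cryptic == cryptic
        got = "".join(call.region_codes[r] for r in ("full", "utr5", "cds", "utr3"))
        assert got == codes

    def test_antisymmetry_swaps_inclusion_and_codes(self):
        by_id = fixture_models_by_id()
        old, new = by_id["NM_177466"], by_id["NM_001003955"]
        fwd = classify_mechanism(old, new)
        rev = classify_mechanism(new, old)
        assert fwd.event_class == "cassette_exon_inclusion"
        assert rev.event_class == "cassette_exon_skipping"
        flip = {"S": "L", "L": "S", "=": "="}
        assert {k: flip[v] for k, v in fwd.region_codes.items()} == rev.region_codes

    def test_cryptic_evidence_is_interior_to_partner_exon(self):
        by_id = fixture_models_by_id()
        old, new = by_id["NM_001171053"], by_id["NM_001171052"]
        call = classify_mechanism(old, new)
        assert call.cryptic
        sites = [e for e in call.evidence if e["kind"] == "cryptic_site"]
        assert sites
        for site in sites:
            lo, hi = site["partner_exon"]
            assert lo < site["position"] < hi

    def test_different_genes_not_comparable(self):
        by_id = fixture_models_by_id()
        with pytest.raises(ComparabilityError):
            classify_mechanism(by_id["NM_001171053"], by_id["NM_134068"])

    def test_planted_classes_recovered(self):
        pairs = simulate_mechanism_pairs(60, seed=17)
        hits = sum(
            1 for cls, a, b in pairs if classify_mechanism(a, b).event_class == cls
        )
        assert hits >= 57  # >= 95 % exact recovery

    def test_unrelated_structure_change_is_complex(self):
        a = make_transcript(exons=((1, 300), (501, 800), (1001, 1300)), cds=(51, 750))
        b = TranscriptModel(
            "tx2", "g1",
            [GenomicInterval("c1", 1, 250, "+"), GenomicInterval("c1", 401, 700, "+"),
             GenomicInterval("c1", 2001, 2300, "+")],
            51, 750,
        ).validate()
        assert classify_mechanism(a, b).event_class == "complex"


class TestCountApa:
    def test_fixture_pairs_contain_no_apa(self):
        calls = [classify_mechanism(o, n) for _, o, n, _, _, _ in canonical_pair_models()]
        assert count_apa_events(calls) == 0

    def test_planted_apa_detected(self):
        (cls, a, b), = simulate_mechanism_pairs(
            1, seed=5, mix={"alternative_polyadenylation": 1.0}
        )
        assert cls == "alternative_polyadenylation"
        assert count_apa_events([classify_mechanism(a, b)]) == 1

    def test_empty_list_is_zero(self):
        assert count_apa_events([]) == 0


class TestSpliceSignals:
    def test_consensus_perfect_donor(self):
        #            exon | intron
        genome = {"c": "AACAGGTAAGTTTT"}
        sig = extract_splice_signal(genome, "c", 5, "donor", "+")
        assert sig.sequence == "CAGGTAAGT"
        assert sig.consensus_score == 1.0

    def test_consensus_perfect_acceptor(self):
        # 14 intronic (10 Y + N + YAG) then exonic G
        genome = {"c": "AA" + "TTTTTTTTTT" + "TCAG" + "G" + "AA"}
        sig = extract_splice_signal(genome, "c", 17, "acceptor", "+")
        assert sig.sequence.endswith("CAGG")
        assert sig.consensus_score == 1.0

    def test_all_c_donor_matches_hand_oracle(self):
        """Independent position-by-position IUPAC check on a degenerate window."""
        genome = {"c": "C" * 30}
        sig = extract_splice_signal(genome, "c", 10, "donor", "+")
        iupac = {"M": "AC", "A": "A", "G": "G", "U": "T", "R": "AG"}
        expected = sum(
            1 for base, code in zip("C" * 9, "MAGGURAGU") if base in iupac[code]
        ) / 9
        assert sig.consensus_score == pytest.approx(expected)
        assert expected == pytest.approx(1 / 9)

    def test_minus_strand_donor_reads_reverse_complement(self):
        # minus-strand exon ends (tx order) at genomic 10; the intron lies
        # genomically below it; both windows read as reverse complements
        seq = "AAA" + "ACTTAC" + "CTG" + "AA"  # rc(ACTTAC)=GTAAGT, rc(CTG)=CAG
        sig = extract_splice_signal({"c": seq}, "c", 10, "donor", "-")
        assert sig.sequence == "CAGGTAAGT"
        assert sig.consensus_score == 1.0

    def test_window_overrun_raises(self):
        with pytest.raises(IndexError):
            extract_splice_signal({"c": "ACGTACGT"}, "c", 7, "donor", "+")

    def test_consensus_score_bounds(self):
        assert consensus_score("ACGT", "NNNN") == 1.0
        assert 0.0 <= consensus_score("AAAA", "YYYY") <= 1.0
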