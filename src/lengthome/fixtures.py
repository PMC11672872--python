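"""Packaged worked-example fixture: the nine switching genes.

The shipped gene models are *synthetic*: exon coordinates are constructed, not
the real genomic ones, but every derived quantity the analysis consumes —
region lengths (e.g. Mta3 3'UTR 93 vs 820 nt, CDS 1542 vs 1757 nt), S/L/=
codes and mechanism classes — matches the published per-gene values exactly.

``fixture_condition_lists`` embeds the models in volcano-passing condition
lists: the progression pair (C10/C24) carries seven switching genes — six
gaining a de novo isoform plus Ly6e losing two of three — among 107
single-isoform distractor genes (114 shared genes total); the treatment pair
(T10/T24) carries three de novo switches among 150 distractors (153 shared).
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Tuple

from .deg_io import ConditionList, DEGRecord
from .transcript_models import RegionLengths, TranscriptModel, read_annotation, region_lengths

#: (gene, old seqname, new seqname, expected S/L/= codes FL/5'UTR/CDS/3'UTR,
#:  expected event class, expected cryptic tag), one row per published table
#: line; Ly6e is represented by one of its two equivalent (old, new) pairs.
CANONICAL_PAIRS: List[Tuple[str, str, str, str, str, bool]] = [
    ("Dusp22", "NM_001037955", "NM_134068", "S=SS", "alt_5prime_donor", True),
    ("Ly6e", "NM_001164038", "NM_001164037", "LL==", "alt_3prime_acceptor", False),
    ("Mta3", "NM_001171053", "NM_001171052", "L=LL", "alt_5prime_donor", True),
    ("Rab11fip5", "NM_177466", "NM_001003955", "L=L=", "cassette_exon_inclusion", False),
    ("Rbmx", "NM_001166623", "NM_011252", "SS==", "alt_3prime_acceptor", True),
    ("Skor", "NM_001163757", "NM_001163758", "SLS=", "alternative_start_codon", False),
    ("Srsf5", "NM_001079694", "NM_009159", "SS==", "alt_3prime_acceptor", True),
    ("Ilf3", "NM_001042708", "NM_001042707", "S=LS", "mutually_exclusive_terminal_exons", False),
    ("Pwwp2a", "NM_027557", "NM_001164231", "L=SL", "alt_5prime_donor", True),
]

#: seqnames per gene per condition of the two comparisons
C_PAIR_ISOFORMS = {
    "Dusp22": ({"NM_001037955"}, {"NM_001037955", "NM_134068"}),
    "Ly6e": ({"NM_001164037", "NM_001164038", "NM_001164040"}, {"NM_001164037"}),
    "Mta3": ({"NM_001171053"}, {"NM_001171053", "NM_001171052"}),
    "Rab11fip5": ({"NM_177466"}, {"NM_177466", "NM_001003955"}),
    "Rbmx": ({"NM_001166623"}, {"NM_001166623", "NM_011252"}),
    "Skor": ({"NM_001163757"}, {"NM_001163757", "NM_001163758"}),
    "Srsf5": ({"NM_001079694"}, {"NM_001079694", "NM_009159"}),
}

T_PAIR_ISOFORMS = {
    "Ilf3": ({"NM_001042708"}, {"NM_001042708", "NM_001042707"}),
    "Pwwp2a": ({"NM_027557"}, {"NM_027557", "NM_001164231"}),
    "Rbmx": ({"NM_001166623"}, {"NM_001166623", "NM_011252"}),
}

_N_DISTRACTORS = {"C": 107, "T": 150}
_CONDITIONS = {"C": ("C10", "C24"), "T": ("T10", "T24")}


def load_fixture_models() -> List[TranscriptModel]:
    """The 19 packaged transcript models across the nine switching genes."""
    ref = resources.files("lengthome.data") / "isoform_fixture_synthetic.tsv"
    with resources.as_file(ref) as path:
        return read_annotation(path, dialect="table")


def fixture_lengths() -> Dict[str, RegionLengths]:
    return {t.transcript_id: region_lengths(t) for t in load_fixture_models()}


def fixture_models_by_id() -> Dict[str, TranscriptModel]:
    return {t.transcript_id: t for t in load_fixture_models()}


def fixture_condition_lists(pair: str = "C") -> Tuple[ConditionList, ConditionList]:
    """Condition lists for one comparison pair ('C' or 'T'), with distractors.

    Distractor genes carry a single shared isoform in both conditions (they
    contribute to the shared-gene count but never switch).  FC/p values sit
    inside the volcano thresholds by construction.
    """
    if pair not in _CONDITIONS:
        raise ValueError(f"pair must be 'C' or 'T', got {pair!r}")
    cond_a, cond_b = _CONDITIONS[pair]
    isoforms = C_PAIR_ISOFORMS if pair == "C" else T_PAIR_ISOFORMS

    def rec(seqname: str, gene: str, condition: str) -> DEGRecord:
        return DEGRecord(seqname, gene, 2.5, 0.01, "down", condition)

    rec_a: List[DEGRecord] = []
    rec_b: List[DEGRecord] = []
    for gene, (set_a, set_b) in sorted(isoforms.items()):
        rec_a.extend(rec(sq, gene, cond_a) for sq in sorted(set_a))
        rec_b.extend(rec(sq, gene, cond_b) for sq in sorted(set_b))
    for i in range(1, _N_DISTRACTORS[pair] + 1):
        gene = f"{pair}dist{i:04d}"
        seqname = f"NM_9{ord(pair):02d}{i:04d}"
        rec_a.append(rec(seqname, gene, cond_a))
        rec_b.append(rec(seqname, gene, cond_b))
    return (
        ConditionList(cond_a, rec_a).validate(),
        ConditionList(cond_b, rec_b).validate(),
    )


def canonical_pair_models() -> List[Tuple[str, TranscriptModel, TranscriptModel, str, str, bool]]:
    """(gene, old model, new model, codes, event class, cryptic) per table row."""
    by_id = fixture_models_by_id()
    return [
        (gene, by_id[old], by_id[new], codes, event, cryptic)
        for gene, old, new, codes, event, cryptic in CANONICAL_PAIRS
    ]
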