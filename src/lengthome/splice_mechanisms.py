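"""Classify the structural mechanism behind a pair of isoforms of one gene.

Two transcript models of the same gene are compared through their splice
junctions (donor = last base of the upstream exon, acceptor = first base of
the downstream exon, genomic coordinates).  A decision cascade assigns one
event class per pair:

``identical``
    same exon chain and same CDS bounds.
``alternative_polyadenylation``
    same junctions, different 3'-terminal exon end, shared stop codon.
``alternative_start_codon``
    same junctions, different genomic start codon, shared stop codon.
``cassette_exon_inclusion`` / ``cassette_exon_skipping``
    exactly one internal exon of one isoform is absent from the other and
    removing it merges its flanking junctions into a junction of the partner.
``mutually_exclusive_terminal_exons``
    the two 3'-terminal exons are genomically disjoint from every exon of the
    partner isoform while the upstream exon chain is shared.
``alt_5prime_donor`` / ``alt_3prime_acceptor``
    a junction differs only at its donor (resp. acceptor) side, the affected
    partner exons overlapping genomically; a junction endpoint that falls
    strictly *inside* an exon of the partner isoform additionally carries the
    ``cryptic`` tag (a latent site activated within exonic sequence).
``complex``
    anything else — the honest fallback rather than a forced single label.

The cassette and terminal-exon checks run before the donor/acceptor-shift
analysis: a swapped terminal exon downstream of a shared exon necessarily
shares its donor, so a naive acceptor-shift rule would shadow the
mutually-exclusive-terminal-exon class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

from .isoform_switching import region_codes
from .transcript_models import (
    GenomeStore,
    GenomicInterval,
    TranscriptModel,
    region_lengths,
)

log = logging.getLogger(__name__)

EVENT_CLASSES = (
    "identical",
    "alternative_polyadenylation",
    "alternative_start_codon",
    "cassette_exon_inclusion",
    "cassette_exon_skipping",
    "mutually_exclusive_terminal_exons",
    "alt_5prime_donor",
    "alt_3prime_acceptor",
    "cryptic_site_activation",  # reported as a tag alongside a site-shift class
    "complex",
)

DONOR_CONSENSUS = "MAGGURAGU"  # 3 exonic | 6 intronic
ACCEPTOR_CONSENSUS = "YYYYYYYYYYNYAGG"  # 14 intronic | 1 exonic

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "M": "AC", "K": "GT", "S": "CG", "W": "AT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class ComparabilityError(ValueError):
    """The two isoforms are not comparable (different gene/contig/strand)."""


@dataclass(frozen=True)
class JunctionSet:
    """Splice junctions of one transcript, as genomic (donor, acceptor) pairs."""

    transcript_id: str
    junctions: frozenset


@dataclass
class SpliceSignal:
    side: str  # donor | acceptor
    sequence: str
    consensus: str
    consensus_score: float


@dataclass
class MechanismCall:
    gene_symbol: str
    old_id: str
    new_id: str
    region_codes: Dict[str, str]
    event_class: str
    cryptic: bool = False
    evidence: List[Dict[str, object]] = field(default_factory=list)


def junctions(t: TranscriptModel) -> JunctionSet:
    """Strand-aware genomic (donor, acceptor) pairs of adjacent exons."""
    pairs = []
    for up, down in zip(t.exons, t.exons[1:]):
        if t.strand == "+":
            pairs.append((up.end, down.start))
        else:
            pairs.append((up.start, down.end))
    return JunctionSet(transcript_id=t.transcript_id, junctions=frozenset(pairs))


def _exon_keys(t: TranscriptModel) -> List[Tuple[int, int]]:
    return [(e.start, e.end) for e in t.exons]


def _interior_exon(pos: int, t: TranscriptModel) -> Optional[GenomicInterval]:
    for e in t.exons:
        if e.strictly_contains(pos):
            return e
    return None


def _three_prime_end(t: TranscriptModel) -> int:
    """Genomic position of the transcript's last (3'-most in mRNA) base."""
    last = t.exons[-1]
    return last.end if t.strand == "+" else last.start


def _five_prime_end(t: TranscriptModel) -> int:
    first = t.exons[0]
    return first.start if t.strand == "+" else first.end


def classify_mechanism(old: TranscriptModel, new: TranscriptModel) -> MechanismCall:
    """Run the event-classification cascade on an (old, new) isoform pair."""
    if old.gene_symbol != new.gene_symbol:
        raise ComparabilityError(
            f"different genes: {old.gene_symbol} vs {new.gene_symbol}"
        )
    if old.chrom != new.chrom or old.strand != new.strand:
        raise ComparabilityError(
            f"{old.gene_symbol}: isoforms on different contigs or strands"
        )
    old.validate()
    new.validate()
    codes = region_codes(region_lengths(old), region_lengths(new))
    call = MechanismCall(
        gene_symbol=old.gene_symbol,
        old_id=old.transcript_id,
        new_id=new.transcript_id,
        region_codes=codes,
        event_class="complex",
    )

    if _exon_keys(old) == _exon_keys(new) and (old.cds_start, old.cds_end) == (
        new.cds_start,
        new.cds_end,
    ):
        call.event_class = "identical"
        return call

    j_old = junctions(old).junctions
    j_new = junctions(new).junctions

    if j_old == j_new:
        _classify_shared_junctions(old, new, call)
        return call

    cls = _cassette(old, new, j_old, j_new, call)
    if cls:
        call.event_class = cls
        return call
    if _mutually_exclusive_terminal(old, new, call):
        call.event_class = "mutually_exclusive_terminal_exons"
        return call
    _site_shift(old, new, j_old, j_new, call)
    return call


def _classify_shared_junctions(old: TranscriptModel, new: TranscriptModel,
                               call: MechanismCall) -> None:
    """Same junction chain: terminal-end or start-codon differences."""
    stop_old = old.tx_to_genomic(old.cds_end) if old.is_coding else None
    stop_new = new.tx_to_genomic(new.cds_end) if new.is_coding else None
    start_old = old.tx_to_genomic(old.cds_start) if old.is_coding else None
    start_new = new.tx_to_genomic(new.cds_start) if new.is_coding else None

    if _three_prime_end(old) != _three_prime_end(new) and stop_old == stop_new:
        call.event_class = "alternative_polyadenylation"
        call.evidence.append(
            {"kind": "terminal_end", "old": _three_prime_end(old), "new": _three_prime_end(new)}
        )
        return
    if start_old is not None and start_new is not None and start_old != start_new \
            and stop_old == stop_new:
        call.event_class = "alternative_start_codon"
        call.evidence.append(
            {"kind": "start_codon", "old": start_old, "new": start_new}
        )
        return
    call.event_class = "complex"


def _cassette(old: TranscriptModel, new: TranscriptModel,
              j_old: frozenset, j_new: frozenset, call: MechanismCall) -> Optional[str]:
    """Exactly one internal exon present in one isoform and absent in the other."""

    def check(host: TranscriptModel, partner_j: frozenset, partner_exons: set,
              label: str) -> Optional[str]:
        unique = [e for e in host.exons if (e.start, e.end) not in partner_exons]
        if len(unique) != 1:
            return None
        e = unique[0]
        idx = host.exons.index(e)
        if idx == 0 or idx == len(host.exons) - 1:
            return None  # terminal exons are not cassettes
        reduced = [x for x in host.exons if x is not e]
        t = TranscriptModel("_tmp", host.gene_symbol, reduced)
        if junctions(t).junctions == partner_j:
            call.evidence.append(
                {"kind": "cassette_exon", "exon": (e.start, e.end), "exon_index": idx,
                 "in": label}
            )
            return "cassette_exon_inclusion" if label == "new" else "cassette_exon_skipping"
        return None

    old_keys = set(_exon_keys(old))
    new_keys = set(_exon_keys(new))
    # only one side may carry a unique exon for a clean cassette
    if len(new_keys - old_keys) == 1 and not (old_keys - new_keys):
        return check(new, j_old, old_keys, "new")
    if len(old_keys - new_keys) == 1 and not (new_keys - old_keys):
        return check(old, j_new, new_keys, "old")
    return None


def _mutually_exclusive_terminal(old: TranscriptModel, new: TranscriptModel,
                                 call: MechanismCall) -> bool:
    term_old, term_new = old.exons[-1], new.exons[-1]
    if (term_old.start, term_old.end) == (term_new.start, term_new.end):
        return False
    if _exon_keys(old)[:-1] != _exon_keys(new)[:-1]:
        return False
    if any(term_old.overlaps(e) for e in new.exons):
        return False
    if any(term_new.overlaps(e) for e in old.exons):
        return False
    call.evidence.append(
        {
            "kind": "terminal_exons",
            "old": (term_old.start, term_old.end),
            "new": (term_new.start, term_new.end),
        }
    )
    return True


def _site_shift(old: TranscriptModel, new: TranscriptModel,
                j_old: frozenset, j_new: frozenset, call: MechanismCall) -> None:
    """Pair differing junctions by shared endpoint and call donor/acceptor shifts."""
    only_old = j_old - j_new
    only_new = j_new - j_old

    classes: Set[str] = set()
    cryptic = False

    def exon_at_acceptor(t: TranscriptModel, a: int) -> Optional[GenomicInterval]:
        for e in t.exons:
            tx_first = e.start if t.strand == "+" else e.end
            if tx_first == a:
                return e
        return None

    def exon_at_donor(t: TranscriptModel, d: int) -> Optional[GenomicInterval]:
        for e in t.exons:
            tx_last = e.end if t.strand == "+" else e.start
            if tx_last == d:
                return e
        return None

    def note_cryptic(pos: int, partner: TranscriptModel, side: str) -> bool:
        e = _interior_exon(pos, partner)
        if e is not None:
            call.evidence.append(
                {"kind": "cryptic_site", "side": side, "position": pos,
                 "partner_exon": (e.start, e.end), "partner": partner.transcript_id}
            )
            return True
        return False

    matched_old: Set[Tuple[int, int]] = set()
    for jn in sorted(only_new):
        d_new, a_new = jn
        partner_same_donor = [j for j in only_old if j[0] == d_new]
        partner_same_acceptor = [j for j in only_old if j[1] == a_new]
        if partner_same_donor:
            jo = partner_same_donor[0]
            matched_old.add(jo)
            e_old = exon_at_acceptor(old, jo[1])
            e_new = exon_at_acceptor(new, a_new)
            if e_old is not None and e_new is not None and e_old.overlaps(e_new):
                classes.add("alt_3prime_acceptor")
                call.evidence.append(
                    {"kind": "acceptor_shift", "donor": d_new,
                     "old_acceptor": jo[1], "new_acceptor": a_new}
                )
                cryptic |= note_cryptic(a_new, old, "acceptor")
            else:
                classes.add("complex")
        elif partner_same_acceptor:
            jo = partner_same_acceptor[0]
            matched_old.add(jo)
            e_old = exon_at_donor(old, jo[0])
            e_new = exon_at_donor(new, d_new)
            if e_old is not None and e_new is not None and e_old.overlaps(e_new):
                classes.add("alt_5prime_donor")
                call.evidence.append(
                    {"kind": "donor_shift", "acceptor": a_new,
                     "old_donor": jo[0], "new_donor": d_new}
                )
                cryptic |= note_cryptic(d_new, old, "donor")
            else:
                classes.add("complex")
        else:
            # junction unique to the new isoform with no endpoint-sharing partner
            if note_cryptic(d_new, old, "donor"):
                classes.add("alt_5prime_donor")
                cryptic = True
            elif note_cryptic(a_new, old, "acceptor"):
                classes.add("alt_3prime_acceptor")
                cryptic = True
            else:
                classes.add("complex")

    for jo in sorted(only_old - matched_old):
        d_old, a_old = jo
        # unmatched junction lost in the new isoform: cryptic relative to new?
        if note_cryptic(d_old, new, "donor"):
            classes.add("alt_5prime_donor")
            cryptic = True
        elif note_cryptic(a_old, new, "acceptor"):
            classes.add("alt_3prime_acceptor")
            cryptic = True
        else:
            classes.add("complex")

    if len(classes) == 1:
        call.event_class = classes.pop()
    else:
        call.event_class = "complex"
    call.cryptic = cryptic and call.event_class in ("alt_5prime_donor", "alt_3prime_acceptor")


def count_apa_events(calls: Sequence[MechanismCall]) -> int:
    """Number of calls classified as alternative polyadenylation."""
    return sum(1 for c in calls if c.event_class == "alternative_polyadenylation")


# ---------------------------------------------------------------------------
# Splice-signal extraction and consensus scoring


def iupac_match(base: str, code: str) -> bool:
    return base.upper() in _IUPAC.get(code.upper(), "")


def consensus_score(sequence: str, consensus: str) -> float:
    """Fraction of positions compatible with an IUPAC consensus (U == T)."""
    if len(sequence) != len(consensus):
        raise ValueError(
            f"sequence length {len(sequence)} != consensus length {len(consensus)}"
        )
    hits = sum(1 for b, c in zip(sequence, consensus) if iupac_match(b, c))
    return hits / len(consensus)


def extract_splice_signal(
    genome: Union[GenomeStore, Mapping[str, str]],
    chrom: str,
    position: int,
    side: str,
    strand: str,
    donor_exonic: int = 3,
    donor_intronic: int = 6,
    acceptor_intronic: int = 14,
    acceptor_exonic: int = 1,
) -> SpliceSignal:
    """Cut and score the splice-signal window at a junction endpoint.

    ``position`` is the genomic coordinate of the donor (last exonic base of
    the upstream exon) or acceptor (first exonic base of the downstream exon).
    Donor windows read (exonic..|intronic..) in transcription orientation;
    acceptor windows read (..intronic|exonic).  Windows that overrun the
    contig raise IndexError.
    """
    if not isinstance(genome, GenomeStore):
        genome = GenomeStore(genome)
    from .transcript_models import reverse_complement as rc

    if side == "donor":
        k, m = donor_exonic, donor_intronic
        if strand == "+":
            seq = genome.fetch(chrom, position - k + 1, position + m)
        else:
            seq = rc(genome.fetch(chrom, position - m, position + k - 1))
        consensus = ("MAG"[-k:] if k <= 3 else "N" * (k - 3) + "MAG") + \
            ("GURAGU"[:m] if m <= 6 else "GURAGU" + "N" * (m - 6))
    elif side == "acceptor":
        m, k = acceptor_intronic, acceptor_exonic
        if strand == "+":
            seq = genome.fetch(chrom, position - m, position + k - 1)
        else:
            seq = rc(genome.fetch(chrom, position - k + 1, position + m))
        if m >= 4:
            intron_cons = "Y" * (m - 4) + "NYAG"
        else:
            intron_cons = "NYAG"[-m:]
        consensus = intron_cons + ("G" + "N" * (k - 1) if k >= 1 else "")
    else:
        raise ValueError(f"side must be 'donor' or 'acceptor', got {side!r}")

    return SpliceSignal(
        side=side,
        sequence=seq.upper().replace("U", "T"),
        consensus=consensus,
        consensus_score=consensus_score(seq, consensus),
    )


def signals_for_transcript(
    t: TranscriptModel, genome: Union[GenomeStore, Mapping[str, str]], **window_kw
) -> List[Tuple[Tuple[int, int], SpliceSignal, SpliceSignal]]:
    """Donor and acceptor signals for every junction of a transcript."""
    out = []
    for d, a in sorted(junctions(t).junctions):
        donor = extract_splice_signal(genome, t.chrom, d, "donor", t.strand, **window_kw)
        acceptor = extract_splice_signal(genome, t.chrom, a, "acceptor", t.strand, **window_kw)
        out.append(((d, a), donor, acceptor))
    return out
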