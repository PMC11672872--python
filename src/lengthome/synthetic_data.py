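"""Synthetic genome, annotation and condition-list generator.

The generator emulates the statistical structure the analysis assumes from a
mouse microarray experiment of atherosclerosis progression (C10/C24) and
siRNA-treated regression (T10/T24):

* a reference exome whose 3'UTR lengths follow a bimodal log-normal mixture
  with modes near 100 bp and 1000 bp, 5'UTRs peaking at 100 bp, log-normal
  CDS lengths, and per-gene exon counts over 1..15;
* four downregulated-transcript condition lists of the published sizes
  (489 / 1285 / 300 / 690) with configured shared-gene overlaps (114, 153)
  and planted isoform-switch events (7, 3) whose structural mechanism is
  drawn from a configurable class mix;
* condition-specific 3'UTR dynamics realised by biasing each condition's
  sampling toward the long- or short-3'UTR mixture component (C10 short,
  C24 long), so the downstream distribution test recovers the planted
  direction of change;
* a toy genome in which every annotated feature is physically realised:
  ATG at each CDS start, a stop codon at each CDS end, and canonical GT/AG
  dinucleotides at every intron, including activated cryptic junctions.

Every random draw flows from one ``numpy`` Generator seeded by the config, so
a fixed seed reproduces byte-identical FASTA/annotation/TSV outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .deg_io import ConditionList, DEGRecord, write_deg_table
from .transcript_models import (
    GenomicInterval,
    TranscriptModel,
    region_lengths,
    write_table,
)

log = logging.getLogger(__name__)

MECHANISM_CLASSES = (
    "alt_5prime_donor",
    "alt_3prime_acceptor",
    "cassette_exon_inclusion",
    "cassette_exon_skipping",
    "alternative_start_codon",
    "mutually_exclusive_terminal_exons",
    "alternative_polyadenylation",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic experiment.

    ``length_shift`` multiplies the long-3'UTR component weight per condition
    (progression endpoint up-weighted, baseline down-weighted); the reference
    mixture weight itself stays at 0.5.  ``mechanism_mix`` assigns zero weight
    to alternative polyadenylation by default: the planted switch events are
    splicing-driven, and APA stays available as an explicit knob.
    """

    seed: int = 0
    n_genes: int = 3600
    list_sizes: Dict[str, int] = field(
        default_factory=lambda: {"C10": 489, "C24": 1285, "T10": 300, "T24": 690}
    )
    shared_genes: Dict[Tuple[str, str], int] = field(
        default_factory=lambda: {("C10", "C24"): 114, ("T10", "T24"): 153}
    )
    planted_switches: Dict[Tuple[str, str], int] = field(
        default_factory=lambda: {("C10", "C24"): 7, ("T10", "T24"): 3}
    )
    utr3_log10_means: Tuple[float, float] = (2.0, 3.0)  # short, long modes (100/1000 bp)
    utr3_log10_sds: Tuple[float, float] = (0.25, 0.30)
    utr3_weight_long: float = 0.5
    utr5_log10_mean: float = 2.0
    utr5_log10_sd: float = 0.25
    cds_log10_mean: float = 3.1
    cds_log10_sd: float = 0.25
    exon_count_probs: Tuple[float, ...] = (
        0.04, 0.07, 0.09, 0.11, 0.12, 0.11, 0.10, 0.09, 0.07, 0.06,
        0.04, 0.03, 0.03, 0.02, 0.02,
    )
    length_shift: Dict[str, float] = field(
        default_factory=lambda: {"C10": 0.6, "C24": 1.6, "T10": 1.0, "T24": 1.0}
    )
    mechanism_mix: Dict[str, float] = field(
        default_factory=lambda: {
            "alt_5prime_donor": 0.30,
            "alt_3prime_acceptor": 0.30,
            "cassette_exon_inclusion": 0.15,
            "cassette_exon_skipping": 0.05,
            "alternative_start_codon": 0.10,
            "mutually_exclusive_terminal_exons": 0.10,
            "alternative_polyadenylation": 0.0,
        }
    )
    intron_min: int = 60
    intron_max: int = 2000
    isoform_count_probs: Tuple[float, ...] = (0.6, 0.25, 0.15)
    frac_noncoding: float = 0.05

    def validate(self) -> "SimulationConfig":
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        if not 0 <= self.utr3_weight_long <= 1:
            raise ConfigError("utr3_weight_long must lie in [0,1]")
        for pair, s in self.shared_genes.items():
            a, b = pair
            if a not in self.list_sizes or b not in self.list_sizes:
                raise ConfigError(f"shared_genes pair {pair} not in list_sizes")
            if s > min(self.list_sizes[a], self.list_sizes[b]):
                raise ConfigError(f"shared genes for {pair} exceed the smaller list")
            if self.planted_switches.get(pair, 0) > s:
                raise ConfigError(f"planted switches for {pair} exceed shared genes")
        if abs(sum(self.mechanism_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("mechanism_mix must sum to 1")
        unknown = set(self.mechanism_mix) - set(MECHANISM_CLASSES)
        if unknown:
            raise ConfigError(f"unknown mechanism classes {sorted(unknown)}")
        return self


@dataclass
class PlantedPair:
    gene_symbol: str
    old_id: str
    new_id: str
    event_class: str
    pair: Optional[Tuple[str, str]] = None  # condition pair it is planted into


@dataclass
class SimulationResult:
    config: SimulationConfig
    models: List[TranscriptModel]
    genome: Dict[str, str]
    planted_pairs: List[PlantedPair]
    utr3_component: Dict[str, str]  # gene -> 'short' | 'long'
    cryptic_junctions: List[Tuple[str, str, int]] = field(default_factory=list)

    def by_gene(self) -> Dict[str, List[TranscriptModel]]:
        out: Dict[str, List[TranscriptModel]] = {}
        for t in self.models:
            out.setdefault(t.gene_symbol, []).append(t)
        return out


# ---------------------------------------------------------------------------
# length draws


def draw_utr3_lengths(rng: np.random.Generator, n: int, cfg: SimulationConfig,
                      weight_long: Optional[float] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Sample n 3'UTR lengths; returns (lengths, long-component flags)."""
    w = cfg.utr3_weight_long if weight_long is None else weight_long
    comp = rng.random(n) < w
    mu = np.where(comp, cfg.utr3_log10_means[1], cfg.utr3_log10_means[0])
    sd = np.where(comp, cfg.utr3_log10_sds[1], cfg.utr3_log10_sds[0])
    lengths = np.maximum(20, np.round(10 ** rng.normal(mu, sd))).astype(int)
    return lengths, comp


def _draw_utr5(rng, cfg) -> int:
    return int(max(10, round(10 ** rng.normal(cfg.utr5_log10_mean, cfg.utr5_log10_sd))))


def _draw_cds(rng, cfg) -> int:
    raw = int(max(150, round(10 ** rng.normal(cfg.cds_log10_mean, cfg.cds_log10_sd))))
    return raw - raw % 3


# ---------------------------------------------------------------------------
# structure builders (constructed on the plus strand, optionally mirrored)


def _partition(rng, total: int, parts: int, minimum: int = 30) -> List[int]:
    """Split `total` into `parts` chunks each >= minimum."""
    if parts * minimum > total:
        raise ConfigError(f"cannot split {total} nt into {parts} exons of >= {minimum}")
    extra = rng.multinomial(total - parts * minimum, rng.dirichlet(np.full(parts, 2.0)))
    return [minimum + int(x) for x in extra]


def _exons_from_lengths(chrom: str, lengths: Sequence[int], introns: Sequence[int],
                        offset: int = 50) -> List[GenomicInterval]:
    exons = []
    pos = offset + 1
    for i, ln in enumerate(lengths):
        exons.append(GenomicInterval(chrom, pos, pos + ln - 1, "+"))
        pos += ln + (introns[i] if i < len(introns) else 0)
    return exons


def _build_transcript(rng, cfg, chrom: str, tid: str, gene: str,
                      coding: bool = True,
                      utr5: Optional[int] = None, cds: Optional[int] = None,
                      utr3: Optional[int] = None,
                      n_exons: Optional[int] = None,
                      first_exon_len: Optional[int] = None,
                      last_exon_len: Optional[int] = None,
                      introns: Optional[List[int]] = None) -> TranscriptModel:
    """One plus-strand transcript with the requested region lengths."""
    if coding:
        utr5 = _draw_utr5(rng, cfg) if utr5 is None else utr5
        cds = _draw_cds(rng, cfg) if cds is None else cds
        if utr3 is None:
            utr3 = int(draw_utr3_lengths(rng, 1, cfg)[0][0])
        full = utr5 + cds + utr3
    else:
        full = int(max(200, round(10 ** rng.normal(3.0, 0.35))))
        utr5 = cds = utr3 = 0
    if n_exons is None:
        k = int(rng.choice(len(cfg.exon_count_probs), p=cfg.exon_count_probs)) + 1
        n_exons = max(1, min(k, full // 60))
    fixed_head = [first_exon_len] if first_exon_len else []
    fixed_tail = [last_exon_len] if last_exon_len else []
    middle = n_exons - len(fixed_head) - len(fixed_tail)
    remaining = full - sum(fixed_head) - sum(fixed_tail)
    lengths = fixed_head + (_partition(rng, remaining, middle) if middle else []) + fixed_tail
    if introns is None:
        introns = [int(x) for x in rng.integers(cfg.intron_min, cfg.intron_max + 1,
                                                max(0, n_exons - 1))]
    exons = _exons_from_lengths(chrom, lengths, introns)
    return TranscriptModel(
        transcript_id=tid, gene_symbol=gene, exons=exons,
        cds_start=utr5 + 1 if coding else None,
        cds_end=utr5 + cds if coding else None,
    ).validate()


def _mirror(models: List[TranscriptModel], contig_len: int) -> List[TranscriptModel]:
    """Flip a plus-strand gene to the minus strand of the same contig."""
    out = []
    for t in models:
        exons = [
            GenomicInterval(e.chrom, contig_len - e.end + 1, contig_len - e.start + 1, "-")
            for e in t.exons
        ]
        out.append(
            TranscriptModel(t.transcript_id, t.gene_symbol, exons, t.cds_start, t.cds_end).validate()
        )
    return out


# ---------------------------------------------------------------------------
# mechanism planting — derive isoform B from isoform A


def _edit_alt3_acceptor(rng, cfg, a: TranscriptModel, tid: str):
    """Shift the first junction's acceptor downstream within the 5'UTR."""
    utr5 = a.cds_start - 1
    first_len = len(a.exons[0])
    if a.n_exons < 2 or first_len >= utr5 - 15:
        return None, None
    delta = int(rng.integers(5, min(40, utr5 - first_len - 10)))
    e2 = a.exons[1]
    if len(e2) <= delta + 10:
        return None, None
    exons = [a.exons[0], GenomicInterval(e2.chrom, e2.start + delta, e2.end, "+")] + \
        list(a.exons[2:])
    b = TranscriptModel(tid, a.gene_symbol, exons, a.cds_start - delta, a.cds_end - delta)
    return b.validate(), None


def _edit_alt5_donor(rng, cfg, a: TranscriptModel, tid: str):
    """Activate a donor inside the last exon's CDS tail, splice to a new exon."""
    utr5 = a.cds_start - 1
    last = a.exons[-1]
    exonic_before = a.spliced_length - len(last)
    cds_in_last = a.cds_end - exonic_before  # CDS bases inside the last exon
    if cds_in_last < 60:
        return None, None
    # the cut must land strictly inside both the last exon and the CDS
    lo = max(30, a.cds_start - exonic_before + 3)
    hi = cds_in_last - 20
    if hi <= lo:
        return None, None
    j = int(rng.integers(lo, hi))
    cut_tx = exonic_before + j
    cut_g = a.tx_to_genomic(cut_tx)
    cds_before = cut_tx - utr5
    m = int(rng.integers(60, 151))
    m += (3 - (cds_before + m) % 3) % 3
    utr3_new = int(draw_utr3_lengths(rng, 1, cfg)[0][0])
    gap = int(rng.integers(200, 801))
    new_start = last.end + gap
    exons = list(a.exons[:-1]) + [
        GenomicInterval(last.chrom, last.start, cut_g, "+"),
        GenomicInterval(last.chrom, new_start, new_start + m + utr3_new - 1, "+"),
    ]
    b = TranscriptModel(tid, a.gene_symbol, exons, a.cds_start, cut_tx + m)
    return b.validate(), ("donor", cut_g)


def _edit_cassette(rng, cfg, a: TranscriptModel, tid: str):
    """Insert a frame-preserving exon into an intron that lies inside the CDS."""
    utr5, cds_end = a.cds_start - 1, a.cds_end
    cum = 0
    candidates = []
    for i, e in enumerate(a.exons[:-1]):
        cum += len(e)
        if utr5 < cum < cds_end - 3:  # junction i..i+1 falls inside the CDS
            gap = a.exons[i + 1].start - e.end - 1
            if gap >= 200:
                candidates.append((i, gap))
    if not candidates:
        return None, None
    i, gap = candidates[int(rng.integers(len(candidates)))]
    ln = 3 * int(rng.integers(10, min(51, (gap - 80) // 3)))
    left = a.exons[i]
    start = left.end + 40
    exons = list(a.exons[: i + 1]) + [
        GenomicInterval(left.chrom, start, start + ln - 1, "+")
    ] + list(a.exons[i + 1:])
    b = TranscriptModel(tid, a.gene_symbol, exons, a.cds_start, a.cds_end + ln)
    return b.validate(), None


def _edit_alt_start(rng, cfg, a: TranscriptModel, tid: str):
    cds = a.cds_end - a.cds_start + 1
    if cds < 200:
        return None, None
    d = 3 * int(rng.integers(10, min(41, (cds - 60) // 3)))
    b = TranscriptModel(tid, a.gene_symbol, list(a.exons), a.cds_start + d, a.cds_end)
    return b.validate(), None


def _edit_mete(rng, cfg, a: TranscriptModel, tid: str):
    """Swap the terminal exon for a disjoint downstream one."""
    if a.n_exons < 2:
        return None, None
    utr5 = a.cds_start - 1
    last = a.exons[-1]
    exonic_before = a.spliced_length - len(last)
    cds_before = exonic_before - utr5  # CDS bases upstream of the last junction
    if cds_before <= 3:
        return None, None
    m = int(rng.integers(90, 301))
    m += (3 - (cds_before + m) % 3) % 3
    utr3_new = int(draw_utr3_lengths(rng, 1, cfg)[0][0])
    gap = int(rng.integers(100, 501))
    start = last.end + gap
    exons = list(a.exons[:-1]) + [
        GenomicInterval(last.chrom, start, start + m + utr3_new - 1, "+")
    ]
    b = TranscriptModel(tid, a.gene_symbol, exons, a.cds_start, exonic_before + m)
    return b.validate(), None


def _edit_apa(rng, cfg, a: TranscriptModel, tid: str):
    delta = int(rng.integers(200, 801))
    last = a.exons[-1]
    exons = list(a.exons[:-1]) + [GenomicInterval(last.chrom, last.start, last.end + delta, "+")]
    b = TranscriptModel(tid, a.gene_symbol, exons, a.cds_start, a.cds_end)
    return b.validate(), None


_EDITORS = {
    "alt_3prime_acceptor": _edit_alt3_acceptor,
    "alt_5prime_donor": _edit_alt5_donor,
    "cassette_exon_inclusion": _edit_cassette,
    "cassette_exon_skipping": _edit_cassette,
    "alternative_start_codon": _edit_alt_start,
    "mutually_exclusive_terminal_exons": _edit_mete,
    "alternative_polyadenylation": _edit_apa,
}


def _build_mechanism_pair(rng, cfg, chrom: str, gene: str, tid_a: str, tid_b: str,
                          event_class: str, max_tries: int = 40):
    """Isoform pair (old, new) realising one planted event class."""
    for _ in range(max_tries):
        kwargs = {}
        if event_class == "alt_3prime_acceptor":
            utr5 = max(90, _draw_utr5(rng, cfg))
            kwargs = {"utr5": utr5, "first_exon_len": utr5 - 50,
                      "n_exons": int(rng.integers(2, 6))}
        elif event_class in ("alt_5prime_donor", "mutually_exclusive_terminal_exons"):
            utr3 = int(draw_utr3_lengths(rng, 1, cfg)[0][0])
            tail = int(rng.integers(120, 320))
            kwargs = {"utr3": utr3, "last_exon_len": utr3 + tail,
                      "n_exons": int(rng.integers(2, 6))}
        elif event_class in ("cassette_exon_inclusion", "cassette_exon_skipping"):
            kwargs = {"n_exons": int(rng.integers(3, 7)),
                      "introns": None}
        try:
            a = _build_transcript(rng, cfg, chrom, tid_a, gene, **kwargs)
        except ConfigError:
            continue
        if event_class in ("cassette_exon_inclusion", "cassette_exon_skipping"):
            # guarantee a roomy intron inside the CDS
            a = _widen_cds_intron(a)
        b, cryptic = _EDITORS[event_class](rng, cfg, a, tid_b)
        if b is None:
            continue
        if event_class == "cassette_exon_skipping":
            a, b = b, a
            a = TranscriptModel(tid_a, gene, a.exons, a.cds_start, a.cds_end).validate()
            b = TranscriptModel(tid_b, gene, b.exons, b.cds_start, b.cds_end).validate()
        return a, b, cryptic
    raise ConfigError(f"could not realise event class {event_class} for {gene}")


def _widen_cds_intron(a: TranscriptModel) -> TranscriptModel:
    """Stretch every intron to >= 400 nt so cassette insertion always fits."""
    shift = 0
    exons = []
    prev_end = None
    for e in a.exons:
        start = e.start + shift
        if prev_end is not None:
            gap = start - prev_end - 1
            if gap < 400:
                shift += 400 - gap
                start = prev_end + 401
        exons.append(GenomicInterval(e.chrom, start, start + len(e) - 1, "+"))
        prev_end = exons[-1].end
    return TranscriptModel(a.transcript_id, a.gene_symbol, exons, a.cds_start, a.cds_end).validate()


# ---------------------------------------------------------------------------
# gene-level assembly


def simulate_mechanism_pairs(
    n: int, cfg: Optional[SimulationConfig] = None, seed: int = 0,
    mix: Optional[Mapping[str, float]] = None,
) -> List[Tuple[str, TranscriptModel, TranscriptModel]]:
    """n standalone (class, old, new) pairs with planted ground truth."""
    cfg = (cfg or SimulationConfig()).validate()
    rng = np.random.default_rng(seed)
    mix = dict(mix or cfg.mechanism_mix)
    classes = [c for c in MECHANISM_CLASSES if mix.get(c, 0) > 0]
    probs = np.array([mix[c] for c in classes])
    probs = probs / probs.sum()
    out = []
    for i in range(n):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        gene = f"pairgene{i:05d}"
        a, b, _ = _build_mechanism_pair(
            rng, cfg, f"ctg_{gene}", gene, f"tx{2 * i:06d}", f"tx{2 * i + 1:06d}", cls
        )
        out.append((cls, a, b))
    return out


def _plant_transcript(t: TranscriptModel, cons: Dict[int, str]) -> None:
    """Record the base constraints one transcript imposes on its contig.

    Raises ConfigError when a position is already pinned to a different base
    (possible only between sibling isoforms of one gene).
    """

    def plant(pos: int, base: str) -> None:
        prev = cons.get(pos)
        if prev is not None and prev != base:
            raise ConfigError(
                f"{t.transcript_id}: conflicting base constraint at {t.chrom}:{pos}"
            )
        cons[pos] = base

    comp = t.strand == "-"
    if t.is_coding:
        for off, base in zip(range(3), "ATG"):
            plant(t.tx_to_genomic(t.cds_start + off), _COMP[base] if comp else base)
        for off, base in zip(range(3), "TAA"):
            plant(t.tx_to_genomic(t.cds_end - 2 + off), _COMP[base] if comp else base)
    for up, down in zip(t.exons, t.exons[1:]):
        if not comp:
            plant(up.end + 1, "G")
            plant(up.end + 2, "T")
            plant(down.start - 2, "A")
            plant(down.start - 1, "G")
        else:
            plant(up.start - 1, _COMP["G"])
            plant(up.start - 2, _COMP["T"])
            plant(down.end + 2, _COMP["A"])
            plant(down.end + 1, _COMP["G"])


def simulate_genome_and_annotation(
    cfg: SimulationConfig, with_sequence: bool = True
) -> SimulationResult:
    """Toy genome + annotation with planted ground truth.

    Every gene sits on its own contig; roughly half the genes are mirrored to
    the minus strand after construction (a pure coordinate flip, so every
    transcript-level quantity is preserved).  Sequence constraints (codons,
    splice dinucleotides) are accumulated per gene; an *extra* annotated
    isoform whose constraints clash with its siblings is discarded, while a
    planted switch pair is rebuilt until conflict-free.  ``with_sequence``
    controls only the synthesis of random contig sequences, not the models.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    models: List[TranscriptModel] = []
    planted: List[PlantedPair] = []
    utr3_component: Dict[str, str] = {}
    cryptic: List[Tuple[str, str, int]] = []
    constraints: Dict[str, Dict[int, str]] = {}
    contig_len: Dict[str, int] = {}

    mix_classes = [c for c in MECHANISM_CLASSES if cfg.mechanism_mix.get(c, 0) > 0]
    mix_probs = np.array([cfg.mechanism_mix[c] for c in mix_classes])
    if len(mix_probs):
        mix_probs = mix_probs / mix_probs.sum()

    tid_counter = 0

    def next_tid():
        nonlocal tid_counter
        tid_counter += 1
        return f"tx{tid_counter:06d}"

    def draw_class() -> str:
        if not mix_classes:
            return "alt_3prime_acceptor"
        return mix_classes[int(rng.choice(len(mix_classes), p=mix_probs))]

    def finalise_gene(chrom: str, group: List[TranscriptModel],
                      droppable: Sequence[bool]) -> List[TranscriptModel]:
        """Mirror to a random strand and plant constraints; drop clashing extras."""
        L = max(e.end for t in group for e in t.exons) + 50
        if rng.random() < 0.5:
            group = _mirror(group, L)
        cons: Dict[int, str] = {}
        kept: List[TranscriptModel] = []
        for t, drop_ok in zip(group, droppable):
            backup = dict(cons)
            try:
                _plant_transcript(t, cons)
                kept.append(t)
            except ConfigError:
                if not drop_ok:
                    raise
                cons = backup
        constraints[chrom] = cons
        contig_len[chrom] = L
        return kept

    gene_idx = 0
    for pair, k in sorted(cfg.planted_switches.items()):
        for _ in range(k):
            gene_idx += 1
            gene = f"gene{gene_idx:05d}"
            chrom = f"ctg{gene_idx:05d}"
            for _attempt in range(20):
                cls = draw_class()
                tid_a, tid_b = next_tid(), next_tid()
                a, b, cr = _build_mechanism_pair(rng, cfg, chrom, gene, tid_a, tid_b, cls)
                try:
                    kept = finalise_gene(chrom, [a, b], [False, False])
                    break
                except ConfigError:
                    continue
            else:
                raise ConfigError(f"{gene}: could not realise a conflict-free switch pair")
            models.extend(kept)
            planted.append(PlantedPair(gene, tid_a, tid_b, cls, pair))
            utr3_len = region_lengths(a).len_3utr
            utr3_component[gene] = (
                "long" if utr3_len >= 10 ** float(np.mean(cfg.utr3_log10_means)) else "short"
            )
            if cr:
                cryptic.append((chrom, cr[0], cr[1]))

    for _ in range(max(0, cfg.n_genes - gene_idx)):
        gene_idx += 1
        gene = f"gene{gene_idx:05d}"
        chrom = f"ctg{gene_idx:05d}"
        coding = rng.random() >= cfg.frac_noncoding
        if coding:
            utr3, comp = draw_utr3_lengths(rng, 1, cfg)
            t = _build_transcript(rng, cfg, chrom, next_tid(), gene, utr3=int(utr3[0]))
            utr3_component[gene] = "long" if comp[0] else "short"
        else:
            t = _build_transcript(rng, cfg, chrom, next_tid(), gene, coding=False)
            utr3_component[gene] = "short"
        gene_models = [t]
        n_iso = int(rng.choice(len(cfg.isoform_count_probs), p=cfg.isoform_count_probs)) + 1
        if coding and n_iso > 1 and mix_classes:
            # extra annotated isoforms realised as structural variants
            for _ in range(n_iso - 1):
                b, _ = _EDITORS[draw_class()](rng, cfg, t, next_tid())
                if b is not None:
                    gene_models.append(b)
        kept = finalise_gene(chrom, gene_models,
                             [False] + [True] * (len(gene_models) - 1))
        models.extend(kept)

    genome: Dict[str, str] = {}
    if with_sequence:
        rng_seq = np.random.default_rng(cfg.seed + 2)
        for chrom in sorted(contig_len):
            arr = _BASES[rng_seq.integers(0, 4, contig_len[chrom])].copy()
            for pos, base in constraints[chrom].items():
                arr[pos - 1] = ord(base)
            genome[chrom] = arr.tobytes().decode("ascii")

    return SimulationResult(
        config=cfg,
        models=models,
        genome=genome,
        planted_pairs=planted,
        utr3_component=utr3_component,
        cryptic_junctions=cryptic,
    )


# ---------------------------------------------------------------------------
# condition lists


def _weighted_sample(rng, genes: List[str], weights: np.ndarray, m: int) -> List[str]:
    """Weighted sampling of m genes without replacement (Gumbel top-k)."""
    if m > len(genes):
        raise ConfigError(f"cannot sample {m} genes from a pool of {len(genes)}")
    if m == 0:
        return []
    keys = np.log(weights + 1e-12) + rng.gumbel(size=len(genes))
    idx = np.argsort(keys)[::-1][:m]
    return [genes[i] for i in sorted(idx)]


def simulate_deg_lists(
    cfg: SimulationConfig, sim: SimulationResult
) -> Tuple[Dict[str, ConditionList], Dict[str, object]]:
    """Condition lists of the configured sizes over the simulated annotation.

    Returns (lists, truth) where truth records per-pair shared genes and the
    planted switch events.  FC and p values are drawn inside the volcano
    thresholds so that filtering is the identity on generator output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    by_gene = sim.by_gene()
    switch_genes = {p.gene_symbol for p in sim.planted_pairs}
    full_pool = sorted(
        g for g, ms in by_gene.items()
        if g not in switch_genes and ms[0].is_coding
    )
    # each condition pair samples the gene pool independently (cross-pair
    # overlap is unconstrained), so demand is per pair, not summed
    demand = max(
        (
            cfg.list_sizes[a] + cfg.list_sizes[b] - s
            - 2 * cfg.planted_switches.get((a, b), 0)
            for (a, b), s in cfg.shared_genes.items()
        ),
        default=0,
    )
    if demand > len(full_pool):
        raise ConfigError(
            f"annotation has {len(full_pool)} usable genes but a pair needs {demand}"
        )
    pool: List[str] = []

    def weight_for(w_long: float) -> np.ndarray:
        w_long = min(max(w_long, 0.05), 0.95)
        return np.array(
            [w_long if sim.utr3_component[g] == "long" else 1.0 - w_long for g in pool]
        )

    def take(genes: List[str]) -> None:
        s = set(genes)
        pool[:] = [g for g in pool if g not in s]

    records: Dict[str, List[DEGRecord]] = {c: [] for c in cfg.list_sizes}
    truth: Dict[str, object] = {"pairs": {}, "switches": []}

    def add(cond: str, gene: str, tid: str) -> None:
        fc = float(2.0 * np.exp(abs(rng.normal(0, 0.5))))
        p = float(rng.uniform(1e-6, 0.05))
        records[cond].append(DEGRecord(tid, gene, fc, p, "down", cond))

    planted_by_pair: Dict[Tuple[str, str], List[PlantedPair]] = {}
    for p in sim.planted_pairs:
        planted_by_pair.setdefault(p.pair, []).append(p)

    for pair, s_shared in sorted(cfg.shared_genes.items()):
        pool[:] = list(full_pool)
        cond_a, cond_b = pair
        k = cfg.planted_switches.get(pair, 0)
        pairs = planted_by_pair.get(pair, [])
        if len(pairs) < k:
            raise ConfigError(f"annotation lacks planted switch genes for {pair}")
        w_a = 0.5 * cfg.length_shift.get(cond_a, 1.0)
        w_b = 0.5 * cfg.length_shift.get(cond_b, 1.0)

        for p in pairs[:k]:
            add(cond_a, p.gene_symbol, p.old_id)
            add(cond_b, p.gene_symbol, p.old_id)
            add(cond_b, p.gene_symbol, p.new_id)
            truth["switches"].append(p)

        shared = _weighted_sample(rng, pool, weight_for((w_a + w_b) / 2), s_shared - k)
        take(shared)
        for g in shared:
            tid = by_gene[g][0].transcript_id
            add(cond_a, g, tid)
            add(cond_b, g, tid)

        n_a_only = cfg.list_sizes[cond_a] - s_shared
        n_b_only = cfg.list_sizes[cond_b] - s_shared - k
        a_only = _weighted_sample(rng, pool, weight_for(w_a), n_a_only)
        take(a_only)
        b_only = _weighted_sample(rng, pool, weight_for(w_b), n_b_only)
        take(b_only)
        for g in a_only:
            add(cond_a, g, by_gene[g][0].transcript_id)
        for g in b_only:
            add(cond_b, g, by_gene[g][0].transcript_id)
        truth["pairs"][pair] = {
            "shared": len(shared) + k,
            "switching": k,
            "switch_genes": [p.gene_symbol for p in pairs[:k]],
        }

    lists = {c: ConditionList(c, rs).validate() for c, rs in records.items()}
    for c, cl in lists.items():
        if cl.size != cfg.list_sizes[c]:
            raise ConfigError(f"{c}: built {cl.size} records, expected {cfg.list_sizes[c]}")
    return lists, truth


# ---------------------------------------------------------------------------
# file outputs


def write_gtf(models: Sequence[TranscriptModel], path: Union[str, Path]) -> None:
    """GTF with transcript/exon/CDS features (CDS includes the stop codon)."""
    with open(path, "w") as fh:
        for t in models:
            lo = min(e.start for e in t.exons)
            hi = max(e.end for e in t.exons)
            attrs = f'gene_id "{t.gene_symbol}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.chrom}\tlengthome\ttranscript\t{lo}\t{hi}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\tlengthome\texon\t{e.start}\t{e.end}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            if t.is_coding:
                for s, e in _cds_genomic_blocks(t):
                    fh.write(
                        f"{t.chrom}\tlengthome\tCDS\t{s}\t{e}\t.\t{t.strand}\t0\t{attrs}\n"
                    )


def _cds_genomic_blocks(t: TranscriptModel) -> List[Tuple[int, int]]:
    """Genomic (start, end) blocks covered by the CDS, ascending."""
    blocks = []
    cum = 0
    for e in t.exons:
        tx_lo, tx_hi = cum + 1, cum + len(e)
        lo = max(tx_lo, t.cds_start)
        hi = min(tx_hi, t.cds_end)
        if lo <= hi:
            if t.strand == "+":
                blocks.append((e.start + (lo - tx_lo), e.start + (hi - tx_lo)))
            else:
                blocks.append((e.end - (hi - tx_lo), e.end - (lo - tx_lo)))
        cum += len(e)
    return sorted(blocks)


def write_fasta(genome: Mapping[str, str], path: Union[str, Path], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_outputs(sim: SimulationResult, lists: Mapping[str, ConditionList],
                  truth: Mapping[str, object], outdir: Union[str, Path]) -> Dict[str, Path]:
    """Write genome.fa, models.gtf, models.tsv, per-condition TSVs and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    if sim.genome:
        write_fasta(sim.genome, outdir / "genome.fa")
        written["genome"] = outdir / "genome.fa"
    write_gtf(sim.models, outdir / "models.gtf")
    write_table(sim.models, outdir / "models.tsv")
    written["models_gtf"] = outdir / "models.gtf"
    written["models_table"] = outdir / "models.tsv"
    for cond, cl in sorted(lists.items()):
        p = outdir / f"{cond}.tsv"
        write_deg_table(cl.records, p)
        written[cond] = p
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("kind\tpair\tgene\told_id\tnew_id\tevent_class\n")
        for p in sim.planted_pairs:
            pair = "/".join(p.pair) if p.pair else ""
            fh.write(f"switch\t{pair}\t{p.gene_symbol}\t{p.old_id}\t{p.new_id}\t{p.event_class}\n")
    written["truth"] = outdir / "truth.tsv"
    return written
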