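"""End-to-end pipeline: filter -> lengths -> distribution stats -> exon
spectra -> switch detection -> mechanism classification -> report.

A single :class:`PipelineConfig` (YAML-loadable) drives the run; every output
TSV carries the config hash and seed as comment headers so that runs are
attributable and two runs with identical config and inputs produce identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import yaml

from . import deg_io, length_stats
from .deg_io import ConditionList
from .isoform_switching import SwitchEvent, detect_switches, switch_table, write_switch_table
from .length_stats import REGIONS, StatisticsError, compare_lengths, exon_count_spectrum, length_sample, lengthome_report
from .splice_mechanisms import MechanismCall, classify_mechanism, count_apa_events, extract_splice_signal
from .transcript_models import GenomeStore, TranscriptModel, read_annotation, region_lengths

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; partial outputs written so far are preserved."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    annotation: str
    deg_tables: Dict[str, str] = field(default_factory=dict)  # condition -> path
    out_dir: str = "lengthome_out"
    annotation_dialect: str = "table"
    genome: Optional[str] = None
    pairs: List[Tuple[str, str]] = field(
        default_factory=lambda: [("C10", "C24"), ("T10", "T24")]
    )
    fc_min: float = 2.0
    p_max: float = 0.05
    alpha: float = 0.05
    direction: str = "down"
    test: str = "welch"
    scale: str = "log10"
    donor_exonic: int = 3
    donor_intronic: int = 6
    acceptor_intronic: int = 14
    acceptor_exonic: int = 1
    seed: int = 0
    plots: bool = True
    columns: Optional[Dict[str, str]] = None

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "pairs" in data:
            data["pairs"] = [tuple(p) for p in data["pairs"]]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        # identifies the analysis parameters; the output location is not part
        # of the analysis identity
        data = dataclasses.asdict(self)
        data.pop("out_dir")
        blob = yaml.safe_dump(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def header_lines(self) -> List[str]:
        return [f"config_hash={self.config_hash()}", f"seed={self.seed}"]

    def validate(self) -> "PipelineConfig":
        if self.fc_min < 1 or not 0 < self.p_max <= 1 or not 0 < self.alpha < 1:
            raise ValueError("thresholds outside legal ranges")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        for pair in self.pairs:
            for cond in pair:
                if cond not in self.deg_tables:
                    raise ValueError(f"pair condition {cond} has no DEG table")
        return self


@dataclass
class PipelineResult:
    config: PipelineConfig
    condition_lists: Dict[str, ConditionList]
    comparisons: List[Tuple[str, object]]  # (condition, DistributionComparison)
    spectra: List[Tuple[str, object]]
    switch_events: Dict[Tuple[str, str], List[SwitchEvent]]
    mechanism_calls: Dict[Tuple[str, str], List[MechanismCall]]
    counts: Dict[str, int]
    written: Dict[str, Path]


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = cfg.header_lines()
    written: Dict[str, Path] = {}
    counts: Dict[str, int] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - stage attribution
                raise PipelineStageError(name, exc) from exc
        return deco

    @stage("annotation")
    def models() -> List[TranscriptModel]:
        ms = read_annotation(cfg.annotation, dialect=cfg.annotation_dialect)
        log.info("annotation: %d transcripts, %d genes", len(ms),
                 len({t.gene_symbol for t in ms}))
        return ms

    genome = GenomeStore(cfg.genome) if cfg.genome else None
    by_id = {t.transcript_id: t for t in models}
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for t in models:
        by_gene.setdefault(t.gene_symbol, []).append(t)
    lengths = {tid: region_lengths(t) for tid, t in by_id.items()}
    counts["annotation_transcripts"] = len(models)

    @stage("volcano_filter")
    def condition_lists() -> Dict[str, ConditionList]:
        lists = {}
        for cond, path in sorted(cfg.deg_tables.items()):
            records = deg_io.read_deg_table(path, cond, columns=cfg.columns)
            cl = deg_io.volcano_filter(
                records, fc_min=cfg.fc_min, p_max=cfg.p_max,
                direction=cfg.direction, condition=cond,
            )
            log.info("%s: %d records read, %d passed volcano filter",
                     cond, len(records), cl.size)
            counts[f"n_{cond}"] = cl.size
            lists[cond] = cl
        return lists

    @stage("length_statistics")
    def comparisons():
        ref_samples = {r: length_sample(models, r, "reference") for r in REGIONS}
        out_list = []
        for cond, cl in sorted(condition_lists.items()):
            matched = [by_id[r.seqname] for r in cl.records if r.seqname in by_id]
            n_missing = cl.size - len(matched)
            if n_missing:
                log.warning("%s: %d seqnames not in annotation", cond, n_missing)
            counts[f"matched_{cond}"] = len(matched)
            for region in REGIONS:
                try:
                    comp = compare_lengths(
                        length_sample(matched, region, cond),
                        ref_samples[region],
                        alpha=cfg.alpha, test=cfg.test, scale=cfg.scale,
                        compute_density=cfg.plots,
                    )
                except StatisticsError as exc:
                    log.warning("%s/%s: %s", cond, region, exc)
                    continue
                out_list.append((cond, comp))
        return out_list

    @stage("exon_spectra")
    def spectra():
        out_list = []
        ref_genes = {g: ms for g, ms in by_gene.items() if ms[0].is_coding}
        for cond, cl in sorted(condition_lists.items()):
            q_genes = {
                g: by_gene[g] for g in sorted(cl.gene_symbols())
                if g in by_gene and by_gene[g][0].is_coding
            }
            if not q_genes:
                log.info("%s: 0 genes for exon spectrum", cond)
                continue
            out_list.append((cond, exon_count_spectrum(q_genes, ref_genes)))
        return out_list

    @stage("report")
    def report_written():
        if not comparisons:
            log.info("no length comparisons computed; skipping report")
            return {}
        return lengthome_report(comparisons, spectra, out, header_lines=header,
                                plots=cfg.plots)

    written.update(report_written)

    @stage("switch_detection")
    def switch_events():
        events = {}
        for pair in cfg.pairs:
            a, b = condition_lists[pair[0]], condition_lists[pair[1]]
            evs = detect_switches(a, b)
            sw = [e for e in evs if e.is_switch]
            log.info("%s/%s: %d shared genes, %d switching",
                     pair[0], pair[1], len(evs), len(sw))
            counts[f"shared_{pair[0]}_{pair[1]}"] = len(evs)
            counts[f"switching_{pair[0]}_{pair[1]}"] = len(sw)
            events[pair] = evs
            rows = switch_table(sw, lengths)
            p = out / f"switch_{pair[0]}_{pair[1]}.tsv"
            write_switch_table(rows, p, header_lines=header)
            written[f"switch_{pair[0]}_{pair[1]}"] = p
        return events

    @stage("mechanisms")
    def mechanism_calls():
        calls: Dict[Tuple[str, str], List[MechanismCall]] = {}
        rows = []
        for pair, evs in switch_events.items():
            pair_calls = []
            for ev in evs:
                if not ev.is_switch:
                    continue
                for old in sorted(ev.isoforms_a):
                    for new in sorted(ev.isoforms_b):
                        if old == new or old not in by_id or new not in by_id:
                            continue
                        call = classify_mechanism(by_id[old], by_id[new])
                        pair_calls.append(call)
                        rows.append(_mechanism_row(call, pair, genome, by_id, cfg))
            calls[pair] = pair_calls
            counts[f"apa_{pair[0]}_{pair[1]}"] = count_apa_events(pair_calls)
        p = out / "mechanisms.tsv"
        _write_mechanisms(rows, p, header)
        written["mechanisms"] = p
        return calls

    @stage("summary")
    def _summary():
        p = out / "summary.tsv"
        with open(p, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            fh.write("quantity\tvalue\n")
            for k in sorted(counts):
                fh.write(f"{k}\t{counts[k]}\n")
        written["summary"] = p

    return PipelineResult(
        config=cfg,
        condition_lists=condition_lists,
        comparisons=comparisons,
        spectra=spectra,
        switch_events=switch_events,
        mechanism_calls=mechanism_calls,
        counts=counts,
        written=written,
    )


_MECH_COLS = [
    "gene_symbol", "pair", "old_seqname", "new_seqname",
    "code_full", "code_utr5", "code_cds", "code_utr3",
    "event_class", "cryptic", "evidence", "donor_score", "acceptor_score",
]


def _mechanism_row(call: MechanismCall, pair, genome, by_id, cfg) -> Dict[str, object]:
    donor_score = acceptor_score = ""
    if genome is not None:
        new = by_id[call.new_id]
        for item in call.evidence:
            pos = item.get("position") or item.get("new_donor") or item.get("new_acceptor")
            side = "donor" if ("donor" in item.get("kind", "") or item.get("side") == "donor") \
                else "acceptor"
            if pos is None:
                continue
            try:
                sig = extract_splice_signal(
                    genome, new.chrom, int(pos), side, new.strand,
                    donor_exonic=cfg.donor_exonic, donor_intronic=cfg.donor_intronic,
                    acceptor_intronic=cfg.acceptor_intronic,
                    acceptor_exonic=cfg.acceptor_exonic,
                )
            except (IndexError, KeyError):
                continue
            if side == "donor":
                donor_score = f"{sig.consensus_score:.3f}"
            else:
                acceptor_score = f"{sig.consensus_score:.3f}"
    evidence = ";".join(
        f"{d.get('kind')}:{d.get('position', d.get('new_donor', d.get('new_acceptor', '')))}"
        for d in call.evidence
    )
    return {
        "gene_symbol": call.gene_symbol,
        "pair": f"{pair[0]}/{pair[1]}",
        "old_seqname": call.old_id,
        "new_seqname": call.new_id,
        "code_full": call.region_codes["full"],
        "code_utr5": call.region_codes["utr5"],
        "code_cds": call.region_codes["cds"],
        "code_utr3": call.region_codes["utr3"],
        "event_class": call.event_class,
        "cryptic": str(call.cryptic).lower(),
        "evidence": evidence,
        "donor_score": donor_score,
        "acceptor_score": acceptor_score,
    }


def _write_mechanisms(rows, path, header_lines) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(_MECH_COLS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in _MECH_COLS) + "\n")
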