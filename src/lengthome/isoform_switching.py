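"""Isoform-switch detection from dual-identifier condition lists.

A gene "switches" between two conditions when the sets of isoform identifiers
(seqnames) observed under its gene symbol differ: isoforms present only in the
second condition are *de novo*, isoforms present only in the first are
*silenced*.  Region-level S/L/= codes compare each (old, new) isoform pair's
5'UTR/CDS/3'UTR/full lengths by exact nucleotide comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Set

from .deg_io import ConditionList
from .transcript_models import RegionLengths

log = logging.getLogger(__name__)

SWITCH_CLASSES = ("no_switch", "de_novo_isoform", "isoform_loss", "mixed")


class AnnotationGapError(KeyError):
    """A seqname in a switch table cannot be resolved to region lengths."""


@dataclass
class SwitchEvent:
    """Per-gene comparison of isoform sets between two conditions."""

    gene_symbol: str
    isoforms_a: Set[str]
    isoforms_b: Set[str]
    condition_a: str = ""
    condition_b: str = ""

    @property
    def de_novo(self) -> Set[str]:
        return self.isoforms_b - self.isoforms_a

    @property
    def silenced(self) -> Set[str]:
        return self.isoforms_a - self.isoforms_b

    @property
    def switch_class(self) -> str:
        if not self.de_novo and not self.silenced:
            return "no_switch"
        if self.de_novo and not self.silenced:
            return "de_novo_isoform"
        if self.silenced and not self.de_novo:
            return "isoform_loss"
        return "mixed"

    @property
    def is_switch(self) -> bool:
        return self.switch_class != "no_switch"


def shared_genes(a: ConditionList, b: ConditionList) -> Set[str]:
    """Gene symbols with at least one record in each condition list."""
    _check_directions(a, b)
    return a.gene_symbols() & b.gene_symbols()


def detect_switches(a: ConditionList, b: ConditionList) -> List[SwitchEvent]:
    """One SwitchEvent per shared gene, ordered by gene symbol.

    Events are emitted for non-switching genes too, so shared-gene counts stay
    recoverable from the one output (filter on ``is_switch``).
    """
    _check_directions(a, b)
    by_a = a.by_gene()
    by_b = b.by_gene()
    events = []
    for gene in sorted(shared_genes(a, b)):
        events.append(
            SwitchEvent(
                gene_symbol=gene,
                isoforms_a={r.seqname for r in by_a[gene]},
                isoforms_b={r.seqname for r in by_b[gene]},
                condition_a=a.condition,
                condition_b=b.condition,
            )
        )
    return events


def _check_directions(a: ConditionList, b: ConditionList) -> None:
    if a.records and b.records and a.direction != b.direction:
        raise ValueError(
            f"condition lists {a.condition}/{b.condition} have different regulation directions"
        )


# ---------------------------------------------------------------------------
# S/L/= region coding


def region_code(new: int, old: int) -> str:
    """L if the new isoform's region is longer, S if shorter, = if equal."""
    if new > old:
        return "L"
    if new < old:
        return "S"
    return "="


def region_codes(old: RegionLengths, new: RegionLengths) -> Dict[str, str]:
    """S/L/= per region for a (old, new) isoform pair, exact nt comparison."""
    return {
        "full": region_code(new.len_full, old.len_full),
        "utr5": region_code(new.len_5utr, old.len_5utr),
        "cds": region_code(new.len_cds, old.len_cds),
        "utr3": region_code(new.len_3utr, old.len_3utr),
    }


def switch_table(
    events: Sequence[SwitchEvent],
    lengths: Mapping[str, RegionLengths],
    include_no_switch: bool = False,
) -> List[Dict[str, object]]:
    """Tabulate per-pair S/L/= codes for switching genes.

    For each switching gene every (a, b) isoform pair with a != b is emitted
    (all old x new combinations: lossless when a gene has several isoforms on
    both sides).  Returns list-of-dict rows ready for TSV serialisation.
    """
    missing = set()
    for ev in events:
        if not ev.is_switch and not include_no_switch:
            continue
        for sq in ev.isoforms_a | ev.isoforms_b:
            if sq not in lengths:
                missing.add(sq)
    if missing:
        raise AnnotationGapError(
            f"seqnames without annotation/region lengths: {sorted(missing)}"
        )

    rows: List[Dict[str, object]] = []
    for ev in sorted(events, key=lambda e: e.gene_symbol):
        if not ev.is_switch and not include_no_switch:
            continue
        pairs = [
            (old, new)
            for old in sorted(ev.isoforms_a)
            for new in sorted(ev.isoforms_b)
            if old != new
        ]
        if not pairs and include_no_switch:
            pairs = [(sq, sq) for sq in sorted(ev.isoforms_a & ev.isoforms_b)][:1]
        for old, new in pairs:
            codes = region_codes(lengths[old], lengths[new])
            rows.append(
                {
                    "gene_symbol": ev.gene_symbol,
                    "condition_a": ev.condition_a,
                    "condition_b": ev.condition_b,
                    "old_seqname": old,
                    "new_seqname": new,
                    "switch_class": ev.switch_class,
                    "code_full": codes["full"],
                    "code_utr5": codes["utr5"],
                    "code_cds": codes["cds"],
                    "code_utr3": codes["utr3"],
                }
            )
    return rows


def write_switch_table(rows: Sequence[Mapping[str, object]], path,
                       header_lines: Sequence[str] = ()) -> None:
    cols = [
        "gene_symbol", "condition_a", "condition_b", "old_seqname", "new_seqname",
        "switch_class", "code_full", "code_utr5", "code_cds", "code_utr3",
    ]
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
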