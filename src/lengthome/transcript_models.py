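"""Gene models, annotation parsing and region-length arithmetic.

A transcript is represented as an ordered chain of genomic exon intervals
(transcription order, i.e. genomically descending on the minus strand) plus an
optional CDS span given in *transcript* coordinates (1-based positions on the
spliced mRNA).  By convention the CDS runs from the first base of the start
codon through the last base of the stop codon, so

    len_5utr = cds_start - 1
    len_cds  = cds_end - cds_start + 1
    len_3utr = spliced_length - cds_end

and the three regions tile the mRNA exactly.  Poly-A tails are never part of
the annotated transcript and therefore never counted in the 3'UTR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

TABLE_COLUMNS = [
    "transcript_id",
    "gene_symbol",
    "chrom",
    "strand",
    "exon_starts",
    "exon_ends",
    "cds_start_tx",
    "cds_end_tx",
]


class AnnotationError(ValueError):
    """Malformed annotation input (bad coordinates, unknown dialect...)."""


class ModelConsistencyError(AnnotationError):
    """A transcript violates its structural invariants."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, inclusive interval on a named contig."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ModelConsistencyError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ModelConsistencyError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def strictly_contains(self, pos: int) -> bool:
        return self.start < pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


@dataclass
class TranscriptModel:
    """One isoform: an exon chain plus an optional CDS span.

    ``transcript_id`` is the isoform-level identifier (RefSeq-style accession,
    the microarray "seqname"); ``gene_symbol`` is shared by every isoform of a
    gene.  ``cds_start``/``cds_end`` are transcript coordinates of the first
    base of the start codon and the last base of the stop codon; both are
    ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_symbol: str
    exons: List[GenomicInterval]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    def validate(self) -> "TranscriptModel":
        """Check structural invariants; raise ModelConsistencyError on violation.

        The codon-divisibility of the CDS is only warned about: annotated CDS
        lengths in the wild (and in published tables) are occasionally off by a
        base from a multiple of three.
        """
        if not self.exons:
            raise ModelConsistencyError(f"{self.transcript_id}: no exons")
        strands = {e.strand for e in self.exons}
        chroms = {e.chrom for e in self.exons}
        if len(strands) != 1 or len(chroms) != 1:
            raise ModelConsistencyError(
                f"{self.transcript_id}: exons span multiple strands/contigs"
            )
        ordered = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end >= b.start:
                raise ModelConsistencyError(f"{self.transcript_id}: overlapping exons")
        expect = ordered if self.strand == "+" else ordered[::-1]
        if list(self.exons) != expect:
            raise ModelConsistencyError(
                f"{self.transcript_id}: exons not in transcription order"
            )
        if self.is_coding:
            if not (1 <= self.cds_start < self.cds_end <= self.spliced_length):
                raise ModelConsistencyError(
                    f"{self.transcript_id}: CDS [{self.cds_start},{self.cds_end}] "
                    f"outside spliced length {self.spliced_length}"
                )
            if (self.cds_end - self.cds_start + 1) % 3 != 0:
                warnings.warn(
                    f"{self.transcript_id}: CDS length "
                    f"{self.cds_end - self.cds_start + 1} not a multiple of 3",
                    stacklevel=2,
                )
        elif (self.cds_start is None) != (self.cds_end is None):
            raise ModelConsistencyError(
                f"{self.transcript_id}: cds_start/cds_end must be both set or both absent"
            )
        return self

    # -- coordinate maps ---------------------------------------------------

    def tx_to_genomic(self, pos: int) -> int:
        """Map a 1-based transcript coordinate to its genomic position."""
        if not 1 <= pos <= self.spliced_length:
            raise ModelConsistencyError(
                f"{self.transcript_id}: transcript position {pos} out of range"
            )
        off = pos
        for e in self.exons:
            if off <= len(e):
                return e.start + off - 1 if self.strand == "+" else e.end - off + 1
            off -= len(e)
        raise AssertionError("unreachable")

    def genomic_to_tx(self, pos: int) -> int:
        """Map a genomic position inside an exon to transcript coordinates."""
        cum = 0
        for e in self.exons:
            if e.contains(pos):
                return cum + (pos - e.start + 1 if self.strand == "+" else e.end - pos + 1)
            cum += len(e)
        raise ModelConsistencyError(
            f"{self.transcript_id}: genomic position {pos} not exonic"
        )

    def cds_genomic_bounds(self) -> Optional[tuple]:
        """(genomic position of first start-codon base, last stop-codon base)."""
        if not self.is_coding:
            return None
        return self.tx_to_genomic(self.cds_start), self.tx_to_genomic(self.cds_end)


@dataclass(frozen=True)
class RegionLengths:
    """Per-transcript lengths of the functional regions, in nucleotides."""

    transcript_id: str
    len_full: int
    len_5utr: int
    len_cds: int
    len_3utr: int
    n_exons: int
    coding: bool = True


def region_lengths(t: TranscriptModel) -> RegionLengths:
    """Decompose a transcript into 5'UTR / CDS / 3'UTR lengths.

    Non-coding transcripts keep their full spliced length but carry zero for
    every coding-anchored region and are flagged ``coding=False``.
    """
    t.validate()
    full = t.spliced_length
    if not t.is_coding:
        return RegionLengths(t.transcript_id, full, 0, 0, 0, t.n_exons, coding=False)
    utr5 = t.cds_start - 1
    cds = t.cds_end - t.cds_start + 1
    utr3 = full - t.cds_end
    return RegionLengths(t.transcript_id, full, utr5, cds, utr3, t.n_exons)


# ---------------------------------------------------------------------------
# Genome sequence access


class GenomeStore:
    """Uppercase sequence access by contig name.

    Wraps either a plain ``{name: sequence}`` mapping or a FASTA file opened
    through :mod:`pyfaidx`.
    """

    def __init__(self, source: Union[str, Path, Mapping[str, str]]):
        if isinstance(source, (str, Path)):
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(source), as_raw=True, sequence_always_upper=True)
            self._dict = None
        else:
            self._fasta = None
            self._dict = {k: str(v).upper() for k, v in source.items()}

    def __contains__(self, name: str) -> bool:
        if self._dict is not None:
            return name in self._dict
        return name in self._fasta

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice of the plus strand."""
        if chrom not in self:
            raise KeyError(f"contig {chrom!r} not present in genome")
        if start < 1:
            raise IndexError(f"window start {start} < 1 on {chrom}")
        if self._dict is not None:
            seq = self._dict[chrom]
            if end > len(seq):
                raise IndexError(f"window end {end} beyond contig {chrom} ({len(seq)} nt)")
            return seq[start - 1 : end]
        seq = str(self._fasta[chrom][start - 1 : end]).upper()
        if len(seq) != end - start + 1:
            raise IndexError(f"window [{start},{end}] beyond contig {chrom}")
        return seq

    def length(self, chrom: str) -> int:
        if self._dict is not None:
            return len(self._dict[chrom])
        return len(self._fasta[chrom])


def spliced_sequence(t: TranscriptModel, genome: Union[GenomeStore, Mapping[str, str]]) -> str:
    """mRNA sequence of a transcript: exon slices joined in transcription
    order, reverse-complemented on the minus strand."""
    if not isinstance(genome, GenomeStore):
        genome = GenomeStore(genome)
    parts = []
    for e in t.exons:
        s = genome.fetch(e.chrom, e.start, e.end)
        parts.append(s if t.strand == "+" else reverse_complement(s))
    return "".join(parts)


# ---------------------------------------------------------------------------
# Annotation I/O


def read_annotation(path: Union[str, Path], dialect: str = "table") -> List[TranscriptModel]:
    """Read transcript models from ``gtf``, ``gff3`` or the tabular dialect.

    The tabular dialect is a TSV with columns ``transcript_id, gene_symbol,
    chrom, strand, exon_starts, exon_ends, cds_start_tx, cds_end_tx`` where the
    exon coordinate lists are comma-joined in transcription order and the CDS
    columns are empty for non-coding transcripts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "table":
        return _read_table(path)
    if dialect in ("gtf", "gff3"):
        return _read_gff(path, dialect)
    raise AnnotationError(f"unknown annotation dialect {dialect!r}")


def _read_table(path: Path) -> List[TranscriptModel]:
    models = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = set(TABLE_COLUMNS) - set(header)
                if missing:
                    raise AnnotationError(
                        f"{path}:{lineno}: missing columns {sorted(missing)}"
                    )
                idx = {c: header.index(c) for c in TABLE_COLUMNS}
                continue
            try:
                tid = fields[idx["transcript_id"]]
                gene = fields[idx["gene_symbol"]]
                chrom = fields[idx["chrom"]]
                strand = fields[idx["strand"]]
                starts = [int(x) for x in fields[idx["exon_starts"]].split(",")]
                ends = [int(x) for x in fields[idx["exon_ends"]].split(",")]
                cs = fields[idx["cds_start_tx"]].strip()
                ce = fields[idx["cds_end_tx"]].strip()
            except (ValueError, IndexError) as exc:
                raise AnnotationError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if len(starts) != len(ends):
                raise AnnotationError(
                    f"{path}:{lineno}: exon_starts/exon_ends length mismatch"
                )
            exons = [GenomicInterval(chrom, s, e, strand) for s, e in zip(starts, ends)]
            model = TranscriptModel(
                transcript_id=tid,
                gene_symbol=gene,
                exons=exons,
                cds_start=int(cs) if cs else None,
                cds_end=int(ce) if ce else None,
            )
            model.validate()
            models.append(model)
    return models


def write_table(models: Iterable[TranscriptModel], path: Union[str, Path],
                header_lines: Sequence[str] = ()) -> None:
    """Write models in the tabular dialect (round-trips with read_annotation)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for t in models:
            fh.write(
                "\t".join(
                    [
                        t.transcript_id,
                        t.gene_symbol,
                        t.chrom,
                        t.strand,
                        ",".join(str(e.start) for e in t.exons),
                        ",".join(str(e.end) for e in t.exons),
                        str(t.cds_start) if t.is_coding else "",
                        str(t.cds_end) if t.is_coding else "",
                    ]
                )
                + "\n"
            )


def _read_gff(path: Path, dialect: str) -> List[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    def attr(feat, *keys):
        for k in keys:
            if k in feat.attributes:
                return feat.attributes[k][0]
        return None

    exons: Dict[str, list] = {}
    cds: Dict[str, list] = {}
    stops: Dict[str, list] = {}
    genes: Dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        if dialect == "gtf":
            tid = attr(feat, "transcript_id")
            gene = attr(feat, "gene_name", "gene_id")
        else:
            tid = attr(feat, "Parent", "transcript_id")
            gene = attr(feat, "gene", "gene_id", "gene_name")
        if tid is None:
            raise AnnotationError(
                f"{path}: {feat.featuretype} feature without transcript attribute "
                f"at {feat.seqid}:{feat.start}"
            )
        if gene is not None:
            genes.setdefault(tid, gene)
        iv = GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
        {"exon": exons, "CDS": cds, "stop_codon": stops}[feat.featuretype].setdefault(
            tid, []
        ).append(iv)

    if dialect == "gff3":
        # fall back to the transcript feature's own gene linkage
        for feat in db.all_features():
            if feat.featuretype in ("mRNA", "transcript"):
                tid = attr(feat, "ID")
                gene = attr(feat, "gene", "Parent", "gene_id")
                if tid and gene and tid not in genes:
                    genes[tid] = gene

    models = []
    for tid, exon_list in exons.items():
        strand = exon_list[0].strand
        ordered = sorted(exon_list, key=lambda e: e.start, reverse=(strand == "-"))
        model = TranscriptModel(
            transcript_id=tid,
            gene_symbol=genes.get(tid, tid),
            exons=ordered,
        )
        spans = cds.get(tid, []) + stops.get(tid, [])
        if spans:
            gmin = min(iv.start for iv in spans)
            gmax = max(iv.end for iv in spans)
            first = gmin if strand == "+" else gmax  # 5'-most CDS base
            last = gmax if strand == "+" else gmin
            try:
                model.cds_start = model.genomic_to_tx(first)
                model.cds_end = model.genomic_to_tx(last)
            except ModelConsistencyError as exc:
                raise ModelConsistencyError(
                    f"{tid}: CDS not contained in exons"
                ) from exc
        model.validate()
        models.append(model)
    return models
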