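"""Transcript models and intron region classification from GTF annotation.

mRNAs are composed of a 5' untranslated region (UTR), a coding sequence
(CDS) terminated by a stop codon, and a 3' UTR.  A splice junction observed
in RNA-seq corresponds to an excised genomic intron; the analysis downstream
only keeps introns that lie entirely within an annotated 3' UTR and touch
neither a CDS nor a 5' UTR of any transcript.  This module parses a
GENCODE-style GTF into per-transcript interval models, derives UTRs when
they are not annotated explicitly, builds a genome-wide region index, and
classifies arbitrary introns against it.

All coordinates are handled internally as 0-based half-open intervals;
GTF (1-based, end-inclusive) is converted once at parse time.
"""

from __future__ import annotations

import enum
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

import gffutils
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GenomeAnnotation",
    "RegionClass",
    "RegionLabel",
    "GtfParseError",
    "parse_gtf",
    "classify_intron",
]


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be interpreted."""


class RegionLabel(str, enum.Enum):
    """Exonic region labels used in the genome-wide index."""

    FIVE_UTR = "FIVE_UTR"
    CDS = "CDS"
    THREE_UTR = "THREE_UTR"
    NONCODING_EXON = "NONCODING_EXON"


class RegionClass(str, enum.Enum):
    """Classification of an intron relative to the annotation."""

    THREE_UTR_EXCLUSIVE = "THREE_UTR_EXCLUSIVE"
    FIVE_UTR = "FIVE_UTR"
    CDS = "CDS"
    NONCODING = "NONCODING"
    MIXED = "MIXED"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """One transcript's exon/CDS/UTR structure.

    ``exons`` are sorted by genomic start and non-overlapping.  ``cds``
    includes the stop codon (appended at parse time), so for exclusion
    purposes the stop codon behaves as coding sequence.  ``utr3`` holds the
    exonic intervals 3' of the stop codon in transcript orientation; for a
    non-coding transcript it is empty.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    stop_codon: GenomicInterval | None = None
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def utr3_span(self) -> GenomicInterval | None:
        """Genomic span from the first to the last 3' UTR interval."""
        if not self.utr3:
            return None
        return GenomicInterval(
            self.chrom,
            min(iv.start for iv in self.utr3),
            max(iv.end for iv in self.utr3),
            self.strand,
        )

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


def _subtract(iv: GenomicInterval, cut: list[GenomicInterval]) -> list[GenomicInterval]:
    """Remove ``cut`` intervals from ``iv``, returning the remaining pieces."""
    pieces = [(iv.start, iv.end)]
    for c in sorted(cut, key=lambda x: x.start):
        nxt = []
        for s, e in pieces:
            if c.end <= s or c.start >= e:
                nxt.append((s, e))
                continue
            if s < c.start:
                nxt.append((s, c.start))
            if c.end < e:
                nxt.append((c.end, e))
        pieces = nxt
    return [GenomicInterval(iv.chrom, s, e, iv.strand) for s, e in pieces if e > s]


def _derive_utrs(tx: TranscriptModel) -> None:
    """Split non-CDS exonic sequence into 5' and 3' UTR by position
    relative to the CDS (stop codon counted as CDS)."""
    if not tx.cds:
        return
    coding = list(tx.cds)
    cds_start = min(iv.start for iv in coding)
    cds_end = max(iv.end for iv in coding)
    utr5, utr3 = [], []
    for exon in tx.exons:
        for piece in _subtract(exon, coding):
            if piece.end <= cds_start:
                side_5prime = tx.strand == "+"
            elif piece.start >= cds_end:
                side_5prime = tx.strand == "-"
            else:
                # Non-coding exonic piece inside the CDS genomic span
                # (e.g. an exon between coding exons with a retained UTR
                # piece) — not expected in well-formed models; skip.
                continue
            (utr5 if side_5prime else utr3).append(piece)
    tx.utr5 = sorted(utr5, key=lambda iv: iv.start)
    tx.utr3 = sorted(utr3, key=lambda iv: iv.start)


@dataclass
class GenomeAnnotation:
    """A collection of transcript models plus a queryable region index.

    The index maps genomic position to the set of exonic region labels at
    that position; it is exactly the union of every transcript's region
    intervals and supports strand-aware queries.
    """

    transcripts: dict[str, TranscriptModel]

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, RegionLabel], IntervalTree] = defaultdict(
            IntervalTree
        )
        self._utr3_spans: dict[str, list[TranscriptModel]] = defaultdict(list)
        for tx in self.transcripts.values():
            for label, ivs in self._region_intervals(tx):
                tree = self._index[(tx.chrom, label)]
                for iv in ivs:
                    tree.addi(iv.start, iv.end, iv.strand)
            if tx.utr3:
                self._utr3_spans[tx.chrom].append(tx)
        self._annotated_introns = {
            (iv.chrom, iv.start, iv.end)
            for tx in self.transcripts.values()
            for iv in tx.introns()
        }

    @staticmethod
    def _region_intervals(tx: TranscriptModel):
        if tx.is_coding:
            yield RegionLabel.CDS, tx.cds
            yield RegionLabel.FIVE_UTR, tx.utr5
            yield RegionLabel.THREE_UTR, tx.utr3
        else:
            yield RegionLabel.NONCODING_EXON, tx.exons

    @property
    def annotated_introns(self) -> set[tuple[str, int, int]]:
        """Exact (chrom, start, end) coordinates of every annotated intron."""
        return self._annotated_introns

    def labels_at(
        self, interval: GenomicInterval, same_strand_only: bool = False
    ) -> set[RegionLabel]:
        """Region labels whose intervals overlap ``interval``."""
        found = set()
        for label in RegionLabel:
            tree = self._index.get((interval.chrom, label))
            if tree is None:
                continue
            for hit in tree.overlap(interval.start, interval.end):
                if same_strand_only and hit.data != interval.strand:
                    continue
                found.add(label)
                break
        return found

    def overlap_bases(
        self, interval: GenomicInterval, label: RegionLabel,
        same_strand_only: bool = False,
    ) -> int:
        """Number of bases of ``interval`` covered by ``label`` intervals."""
        tree = self._index.get((interval.chrom, label))
        if tree is None:
            return 0
        covered: set[int] = set()
        for hit in tree.overlap(interval.start, interval.end):
            if same_strand_only and hit.data != interval.strand:
                continue
            covered.update(
                range(max(hit.begin, interval.start), min(hit.end, interval.end))
            )
        return len(covered)

    def utr3_containing_transcripts(
        self, interval: GenomicInterval
    ) -> list[TranscriptModel]:
        """Same-strand transcripts whose 3' UTR span fully contains ``interval``."""
        out = []
        for tx in self._utr3_spans.get(interval.chrom, ()):
            if tx.strand != interval.strand:
                continue
            span = tx.utr3_span
            if span is not None and span.contains(interval):
                out.append(tx)
        return out

    def region_to_bed(self, label: RegionLabel) -> list[str]:
        """Export one region label as 6-column BED lines."""
        lines = []
        for (chrom, lab), tree in sorted(self._index.items()):
            if lab is not label:
                continue
            for hit in sorted(tree):
                lines.append(
                    f"{chrom}\t{hit.begin}\t{hit.end}\t{label.value}\t0\t{hit.data}"
                )
        return lines

    def has_chrom(self, chrom: str) -> bool:
        return any(c == chrom for c, _ in self._index) or chrom in self._utr3_spans


def _validate_gtf_lines(path: str) -> None:
    feature_types = {"exon", "CDS", "stop_codon"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if fields[2] in feature_types and 'transcript_id "' not in fields[8]:
                raise GtfParseError(
                    f"{path}:{lineno}: {fields[2]} feature lacks a "
                    f'transcript_id "..." attribute'
                )


def parse_gtf(path: str) -> GenomeAnnotation:
    """Parse a GENCODE-dialect GTF into a :class:`GenomeAnnotation`.

    Exon, CDS and stop_codon features are grouped by ``transcript_id``.
    UTRs are derived as exon-minus-CDS split at the CDS boundaries, so
    explicit UTR features are not required.  A coding transcript without a
    stop_codon feature gets a 3-nt stop derived from the CDS 3' end (with a
    warning).  Coordinates are converted to 0-based half-open.
    """
    _validate_gtf_lines(path)
    db = gffutils.create_db(
        path,
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    exons: dict[str, list[GenomicInterval]] = defaultdict(list)
    cds: dict[str, list[GenomicInterval]] = defaultdict(list)
    stops: dict[str, GenomicInterval] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        gname = feat.attributes.get("gene_name", [gid])[0]
        meta.setdefault(tid, (gid, gname, feat.strand))
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if feat.featuretype == "exon":
            exons[tid].append(iv)
        elif feat.featuretype == "CDS":
            cds[tid].append(iv)
        else:
            stops[tid] = iv

    transcripts: dict[str, TranscriptModel] = {}
    for tid, (gid, gname, strand) in sorted(meta.items()):
        if tid not in exons:
            continue
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            gene_name=gname,
            strand=strand,
            exons=sorted(exons[tid], key=lambda iv: iv.start),
            cds=sorted(cds.get(tid, []), key=lambda iv: iv.start),
        )
        if tx.cds:
            stop = stops.get(tid)
            if stop is None:
                stop = _stop_from_cds(tx)
                logger.warning(
                    "transcript %s has CDS but no stop_codon; derived %s:%d-%d "
                    "from the CDS 3' end", tid, stop.chrom, stop.start, stop.end,
                )
            tx.stop_codon = stop
            # Stop codon counts as CDS for region labelling and exclusion.
            if not any(c.contains(stop) for c in tx.cds):
                tx.cds = sorted(tx.cds + [stop], key=lambda iv: iv.start)
            _derive_utrs(tx)
        transcripts[tid] = tx
    return GenomeAnnotation(transcripts=transcripts)


def _stop_from_cds(tx: TranscriptModel) -> GenomicInterval:
    """Place a 3-nt stop codon immediately 3' of the CDS end."""
    if tx.strand == "+":
        cds_end = max(iv.end for iv in tx.cds)
        return GenomicInterval(tx.chrom, cds_end, cds_end + 3, tx.strand)
    cds_start = min(iv.start for iv in tx.cds)
    return GenomicInterval(tx.chrom, max(0, cds_start - 3), cds_start, tx.strand)


def classify_intron(
    intron: GenomicInterval,
    ann: GenomeAnnotation,
    stranded_exclusion: bool = False,
    missing_chrom: str = "warn",
) -> RegionClass:
    """Classify an intron against the annotation.

    ``THREE_UTR_EXCLUSIVE`` requires full containment in at least one
    same-strand transcript's 3' UTR span and zero overlap with any CDS or
    5' UTR interval.  The CDS/5' UTR exclusion considers both strands by
    default (short-read junction evidence is often strand-ambiguous); pass
    ``stranded_exclusion=True`` to restrict it to same-strand features.

    Introns overlapping a single non-3'-UTR region class get that class;
    any mixture — including a 3' UTR overlap that fails the containment or
    exclusion rules — is ``MIXED``.  No overlap at all is ``NONCODING``.
    """
    if not ann.has_chrom(intron.chrom):
        if missing_chrom == "error":
            raise KeyError(f"chromosome {intron.chrom!r} absent from annotation")
        logger.warning("chromosome %s absent from annotation", intron.chrom)
        return RegionClass.NONCODING

    same = stranded_exclusion
    labels = ann.labels_at(intron, same_strand_only=False)
    excl_labels = (
        ann.labels_at(intron, same_strand_only=True) if same else labels
    )
    hits_cds = RegionLabel.CDS in excl_labels
    hits_utr5 = RegionLabel.FIVE_UTR in excl_labels
    contained = bool(ann.utr3_containing_transcripts(intron))

    if contained and not hits_cds and not hits_utr5:
        return RegionClass.THREE_UTR_EXCLUSIVE

    touches_utr3 = RegionLabel.THREE_UTR in labels or contained
    classes = set()
    if RegionLabel.CDS in labels:
        classes.add(RegionClass.CDS)
    if RegionLabel.FIVE_UTR in labels:
        classes.add(RegionClass.FIVE_UTR)
    if RegionLabel.NONCODING_EXON in labels:
        classes.add(RegionClass.NONCODING)
    if touches_utr3:
        return RegionClass.MIXED
    if len(classes) == 1:
        return classes.pop()
    if len(classes) > 1:
        return RegionClass.MIXED
    return RegionClass.NONCODING
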