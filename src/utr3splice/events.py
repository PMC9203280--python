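"""3' UTR splicing event (3USP) discovery and cohort-level calls.

A putative 3USP is a junction whose intron is exclusively located in a
3' UTR and that, in at least one sample, is supported by at least two
splicing-out reads while showing SPL > 10% (both conditions in the same
sample).  A common 3USP (c3USP) within a cohort is an event with SPL > 10%
in strictly more than half of the cohort's samples.  The per-sample 3USP
burden is the number of 3USPs divided by the number of all splicing events
in that sample, which removes the dependence on transcriptional activity
and sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd

from .annotation import (
    GenomeAnnotation,
    GenomicInterval,
    RegionClass,
    classify_intron,
)
from .junctions import Junction, SplMatrix

__all__ = [
    "SpliceEvent",
    "discover_3usps",
    "classify_matrix_events",
    "call_c3usp",
    "c3usp_flags",
    "normalize_burden",
    "sample_burden",
    "read_isoform_introns",
    "match_longread_support",
    "check_annotated",
]


@dataclass
class SpliceEvent:
    junction: Junction
    region: RegionClass
    gene_ids: frozenset[str]
    annotated: bool | None = None
    pacbio_supported: bool | None = None


def classify_matrix_events(
    matrix: SplMatrix, annotation: GenomeAnnotation, stranded_exclusion: bool = False
) -> pd.Series:
    """Region class of every junction in the matrix, keyed by event id."""
    out = {}
    for event_id in matrix.events:
        j = Junction.from_id(event_id)
        out[event_id] = classify_intron(
            j.interval, annotation, stranded_exclusion=stranded_exclusion
        ).value
    return pd.Series(out, name="region")


def support_filter(
    matrix: SplMatrix, min_reads: int = 2, min_spl: float = 0.10
) -> pd.Series:
    """Boolean per event: some sample has out_reads >= min_reads AND
    SPL > min_spl (strict), evaluated in the same sample."""
    spl = matrix.spl.to_numpy(dtype=float)
    out = matrix.out_reads.to_numpy()
    with np.errstate(invalid="ignore"):
        ok = (out >= min_reads) & (spl > min_spl)
    return pd.Series(ok.any(axis=1), index=matrix.events, name="supported")


def discover_3usps(
    matrix: SplMatrix,
    annotation: GenomeAnnotation,
    min_reads: int = 2,
    min_spl: float = 0.10,
    stranded_exclusion: bool = False,
) -> pd.DataFrame:
    """Discover putative 3USPs from the SPL matrix.

    Returns a frame indexed by event id with columns ``chrom, start, end,
    strand, region, gene_ids`` for events that are 3'-UTR-exclusive and
    pass the per-sample support filter.
    """
    regions = classify_matrix_events(matrix, annotation, stranded_exclusion)
    supported = support_filter(matrix, min_reads=min_reads, min_spl=min_spl)
    keep = (regions == RegionClass.THREE_UTR_EXCLUSIVE.value) & supported
    rows = []
    for event_id in matrix.events:
        if not keep.loc[event_id]:
            continue
        j = Junction.from_id(event_id)
        hosts = annotation.utr3_containing_transcripts(j.interval)
        rows.append(
            {
                "event_id": event_id,
                "chrom": j.interval.chrom,
                "start": j.interval.start,
                "end": j.interval.end,
                "strand": j.interval.strand,
                "region": RegionClass.THREE_UTR_EXCLUSIVE.value,
                "gene_ids": ",".join(sorted({t.gene_id for t in hosts})),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["event_id", "chrom", "start", "end", "strand", "region", "gene_ids"],
    ).set_index("event_id")


def call_c3usp(
    spl_values,
    min_spl: float = 0.10,
    prevalence_denominator: str = "all",
) -> bool:
    """Is this event common (SPL > min_spl in more than half the samples)?

    ``spl_values`` are one event's SPLs across one cohort, NaN = missing.
    With the default ``prevalence_denominator='all'`` missing samples stay
    in the denominator and count as not exceeding the threshold; with
    ``'observed'`` they are dropped from the denominator.
    """
    vals = np.asarray(spl_values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty cohort")
    n_above = int(np.nansum(vals > min_spl))
    if prevalence_denominator == "observed":
        n = int(np.sum(~np.isnan(vals)))
        if n == 0:
            return False
    elif prevalence_denominator == "all":
        n = vals.size
    else:
        raise ValueError(f"unknown prevalence_denominator {prevalence_denominator!r}")
    return n_above > n / 2


def c3usp_flags(
    matrix: SplMatrix,
    cohort: str,
    min_spl: float = 0.10,
    prevalence_denominator: str = "all",
) -> pd.Series:
    """Per-event c3USP flag within one cohort of the matrix."""
    samples = matrix.samples_in(cohort)
    if not samples:
        raise ValueError(f"no samples in cohort {cohort!r}")
    sub = matrix.spl[samples]
    return pd.Series(
        [
            call_c3usp(row, min_spl=min_spl,
                       prevalence_denominator=prevalence_denominator)
            for row in sub.to_numpy()
        ],
        index=matrix.events,
        name=f"c3usp_{cohort}",
    )


def normalize_burden(n_3usp: int, n_all_splicing: int) -> float:
    """3USP burden as a fraction of all splicing events in the sample."""
    if not 0 <= n_3usp <= n_all_splicing:
        raise ValueError("require 0 <= n_3usp <= n_all_splicing")
    if n_all_splicing == 0:
        raise ValueError("no splicing events; exclude the sample upstream")
    return n_3usp / n_all_splicing


def sample_burden(
    matrix: SplMatrix,
    regions: pd.Series,
    min_reads: int = 2,
    min_spl: float = 0.10,
    min_depth_junctions: int = 1000,
) -> pd.DataFrame:
    """Per-sample 3USP count, all-splicing count, normalized burden, and a
    low-depth flag.

    An event counts in a sample if it has >= min_reads splicing-out reads
    and SPL > min_spl there; the all-splicing denominator applies the same
    support rule to junctions of every region class.  Samples whose total
    junction count falls below ``min_depth_junctions`` are flagged for
    exclusion (too shallow to quantify burden).
    """
    spl = matrix.spl.to_numpy(dtype=float)
    out = matrix.out_reads.to_numpy()
    with np.errstate(invalid="ignore"):
        passing = (out >= min_reads) & (spl > min_spl)
    is_3utr = (
        regions.reindex(matrix.events) == RegionClass.THREE_UTR_EXCLUSIVE.value
    ).to_numpy()
    n_all = passing.sum(axis=0)
    n_3usp = passing[is_3utr].sum(axis=0)
    burden = np.divide(
        n_3usp, n_all, out=np.full(len(n_all), np.nan), where=n_all > 0
    )
    return pd.DataFrame(
        {
            "n_3usp": n_3usp.astype(int),
            "n_all_splicing": n_all.astype(int),
            "burden": burden,
            "low_depth": n_all < min_depth_junctions,
        },
        index=pd.Index(matrix.samples, name="sample_id"),
    )


def read_isoform_introns(path: str) -> set[tuple[str, int, int]]:
    """Exact intron coordinates (0-based half-open) of every isoform in a
    GTF/GFF of transcript models (e.g. long-read isoform assemblies)."""
    db = gffutils.create_db(
        path,
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    exons_by_tx: dict[str, list[tuple[str, int, int]]] = {}
    for feat in db.all_features():
        if feat.featuretype != "exon":
            continue
        tid = feat.attributes["transcript_id"][0]
        exons_by_tx.setdefault(tid, []).append((feat.seqid, feat.start - 1, feat.end))
    introns: set[tuple[str, int, int]] = set()
    for exons in exons_by_tx.values():
        exons.sort(key=lambda x: x[1])
        for (c1, _, e1), (c2, s2, _) in zip(exons, exons[1:]):
            if c1 == c2 and s2 > e1:
                introns.add((c1, e1, s2))
    return introns


def match_longread_support(
    event_ids, isoform_introns: set[tuple[str, int, int]]
) -> pd.Series:
    """Per event: does some long-read isoform contain an intron with
    identical donor and acceptor coordinates?  Strand is ignored — identity
    of both splice sites on the same chromosome is the criterion."""
    flags = {}
    for event_id in event_ids:
        j = Junction.from_id(event_id)
        key = (j.interval.chrom, j.interval.start, j.interval.end)
        flags[event_id] = key in isoform_introns
    return pd.Series(flags, name="pacbio_supported")


def check_annotated(event_ids, annotation: GenomeAnnotation) -> pd.Series:
    """Per event: do its boundaries equal an annotated transcript intron?"""
    flags = {}
    for event_id in event_ids:
        j = Junction.from_id(event_id)
        key = (j.interval.chrom, j.interval.start, j.interval.end)
        flags[event_id] = key in annotation.annotated_introns
    return pd.Series(flags, name="annotated")
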