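"""Junction evidence and the splicing level (SPL) statistic.

For each intron (splice junction) and each sample, two kinds of read
evidence exist:

* splicing-out reads — reads whose alignment is gapped exactly across the
  intron; they support excision and are reported per junction by aligners
  (STAR's ``SJ.out.tab``);
* splicing-in reads — reads covering a splice-site boundary contiguously
  with at least 6 aligned nt on each side; they support retention and are
  counted at the donor and the acceptor separately, then summed.

The splicing level is

    SPL = out / (out + in / 2)

where ``in`` sums the donor- and acceptor-spanning reads; dividing by two
averages the retention evidence over the two splice sites so that it is
commensurate with the single per-junction excision count.  When a sample
has no evidence at all for a junction (out = in = 0) the SPL is missing,
not zero: absence of coverage is not evidence of non-splicing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GenomicInterval

__all__ = [
    "Junction",
    "SplMatrix",
    "compute_spl",
    "compute_spl_array",
    "read_sj_table",
    "read_in_reads_table",
    "read_sample_sheet",
    "count_in_reads",
    "build_spl_matrix",
]

MISSING = float("nan")

_STRAND_CODE = {0: "+", 1: "+", 2: "-"}

COHORTS = ("TUMOUR", "NORMAL", "REFERENCE_NORMAL")


@dataclass(frozen=True)
class Junction:
    """An intron identified by exact genomic coordinates."""

    interval: GenomicInterval

    @property
    def id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}:{iv.strand}"

    @classmethod
    def from_id(cls, junction_id: str) -> "Junction":
        chrom, span, strand = junction_id.rsplit(":", 2)
        start, end = span.split("-")
        return cls(GenomicInterval(chrom, int(start), int(end), strand))


def compute_spl(out_reads: int, in_reads_total: int) -> float:
    """SPL = out / (out + in/2); NaN when there is no evidence at all."""
    if out_reads < 0 or in_reads_total < 0:
        raise ValueError("read counts must be non-negative")
    if out_reads == 0 and in_reads_total == 0:
        return MISSING
    return out_reads / (out_reads + in_reads_total / 2.0)


def compute_spl_array(out_reads, in_reads_total) -> np.ndarray:
    """Vectorised :func:`compute_spl`."""
    out = np.asarray(out_reads, dtype=float)
    inr = np.asarray(in_reads_total, dtype=float)
    if (out < 0).any() or (inr < 0).any():
        raise ValueError("read counts must be non-negative")
    denom = out + inr / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        spl = np.where(denom > 0, out / np.where(denom > 0, denom, 1.0), np.nan)
    return spl


def read_sj_table(
    path: str, sample_id: str, include_multimappers: bool = False
) -> pd.DataFrame:
    """Read one STAR ``SJ.out.tab``-dialect file.

    Columns: chrom, intron start (1-based), intron end (1-based inclusive),
    strand code {0: undefined, 1: +, 2: -}, intron motif, annotated flag,
    unique reads, multimapping reads, max overhang.  Coordinates are
    converted to 0-based half-open; junctions with undefined strand are
    kept on '+' and flagged.

    Returns a frame with columns ``junction_id, chrom, start, end, strand,
    strand_undefined, out_reads, sample_id``.
    """
    names = [
        "chrom", "start1", "end1", "strand_code", "motif",
        "annotated", "unique_reads", "multi_reads", "overhang",
    ]
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, names=names, comment="#",
            dtype={"chrom": str},
        )
    except Exception as exc:  # re-raise with file context
        raise ValueError(f"cannot parse SJ table {path}: {exc}") from exc
    if df.empty:
        return pd.DataFrame(
            columns=["junction_id", "chrom", "start", "end", "strand",
                     "strand_undefined", "out_reads", "sample_id"]
        )
    for col in ("start1", "end1", "strand_code", "unique_reads", "multi_reads"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            lineno = int(bad.idxmax()) + 1
            raise ValueError(
                f"{path}:{lineno}: non-integer value in column {col!r}"
            )
        df[col] = df[col].astype(int)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start1"] - 1,
            "end": df["end1"],
            "strand": df["strand_code"].map(_STRAND_CODE),
            "strand_undefined": df["strand_code"] == 0,
            "out_reads": df["unique_reads"]
            + (df["multi_reads"] if include_multimappers else 0),
        }
    )
    out["junction_id"] = (
        out["chrom"].astype(str)
        + ":" + out["start"].astype(str)
        + "-" + out["end"].astype(str)
        + ":" + out["strand"]
    )
    out["sample_id"] = sample_id
    return out[
        ["junction_id", "chrom", "start", "end", "strand",
         "strand_undefined", "out_reads", "sample_id"]
    ]


def read_in_reads_table(path: str) -> pd.DataFrame:
    """Read a TSV of per-junction splicing-in totals:
    ``junction_id, sample_id, in_reads_total``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"junction_id": str})
    required = {"junction_id", "sample_id", "in_reads_total"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    bad = pd.to_numeric(df["in_reads_total"], errors="coerce").isna()
    if bad.any():
        raise ValueError(f"{path}: non-integer in_reads_total at row {int(bad.idxmax())}")
    df["in_reads_total"] = df["in_reads_total"].astype(int)
    return df


def read_sample_sheet(path: str) -> pd.Series:
    """Read the sample sheet TSV (``sample_id, cohort``) into a Series
    mapping sample id to cohort label."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"sample_id", "cohort"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns sample_id, cohort")
    bad = set(df["cohort"]) - set(COHORTS)
    if bad:
        raise ValueError(f"{path}: unknown cohort labels {sorted(bad)}")
    return pd.Series(df["cohort"].values, index=df["sample_id"].values, name="cohort")


def _spans_boundary(
    blocks: Sequence[tuple[int, int]], boundary: int, min_overhang: int
) -> bool:
    """True if some ungapped block covers [boundary - k, boundary + k)."""
    return any(
        s <= boundary - min_overhang and e >= boundary + min_overhang
        for s, e in blocks
    )


def count_in_reads(
    reads: Iterable[Sequence[tuple[int, int]]],
    junction: Junction,
    min_overhang: int = 6,
    dedupe_spanning_reads: bool = False,
) -> int:
    """Count splicing-in (retention) reads for one junction.

    ``reads`` yields, per aligned read, its ungapped reference blocks as
    (start, end) pairs (e.g. ``pysam.AlignedSegment.get_blocks()``).  A read
    counts at the donor (acceptor) if one of its blocks covers that boundary
    with at least ``min_overhang`` aligned nt on each side — a read spliced
    across this junction has no such block, and a read spliced elsewhere
    counts only if its splice does not remove the boundary.  A single read
    spanning both boundaries contributes 2 by default (once per site);
    ``dedupe_spanning_reads=True`` counts it once.
    """
    donor = junction.interval.start
    acceptor = junction.interval.end
    total = 0
    for blocks in reads:
        at_donor = _spans_boundary(blocks, donor, min_overhang)
        at_acceptor = _spans_boundary(blocks, acceptor, min_overhang)
        if dedupe_spanning_reads:
            total += int(at_donor or at_acceptor)
        else:
            total += int(at_donor) + int(at_acceptor)
    return total


@dataclass
class SplMatrix:
    """Events-by-samples SPL values plus the raw counts behind them.

    ``spl``, ``out_reads`` and ``in_reads`` are aligned DataFrames indexed
    by junction id with one column per sample; missing SPLs are NaN.
    ``cohort`` maps each sample to TUMOUR / NORMAL / REFERENCE_NORMAL.
    """

    spl: pd.DataFrame
    out_reads: pd.DataFrame
    in_reads: pd.DataFrame
    cohort: pd.Series

    def __post_init__(self) -> None:
        vals = self.spl.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
        if not ok.all():
            raise ValueError("SPL values must lie in [0, 1] or be missing")
        missing = set(self.spl.columns) - set(self.cohort.index)
        if missing:
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")

    @property
    def events(self) -> list[str]:
        return list(self.spl.index)

    @property
    def samples(self) -> list[str]:
        return list(self.spl.columns)

    def samples_in(self, cohort: str) -> list[str]:
        return [s for s in self.samples if self.cohort.get(s) == cohort]

    def subset_events(self, event_ids: Sequence[str]) -> "SplMatrix":
        idx = [e for e in event_ids if e in self.spl.index]
        return SplMatrix(
            self.spl.loc[idx],
            self.out_reads.loc[idx],
            self.in_reads.loc[idx],
            self.cohort,
        )

    def to_tsv(self, path: str, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.spl.to_csv(fh, sep="\t", na_rep="NA", index_label="event_id")


def build_spl_matrix(
    sj_frames: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    in_reads: pd.DataFrame,
    sample_sheet: pd.Series,
) -> SplMatrix:
    """Assemble the SPL matrix from per-sample junction tables.

    The junction set is the outer union across samples; a junction absent
    from a sample gets out = in = 0 there (hence missing SPL unless the
    in-reads table says otherwise).  Every sample must appear in the sample
    sheet.
    """
    if isinstance(sj_frames, Mapping):
        frames = list(sj_frames.values())
    else:
        frames = list(sj_frames)
    sj = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["junction_id", "sample_id", "out_reads"])
    )
    samples = sorted(
        set(sj["sample_id"]).union(in_reads["sample_id"]) if len(sj) or len(in_reads)
        else set()
    )
    unknown = [s for s in samples if s not in sample_sheet.index]
    if unknown:
        raise ValueError(f"samples absent from sample sheet: {unknown}")
    events = sorted(set(sj["junction_id"]).union(in_reads["junction_id"]))

    out_m = (
        sj.pivot_table(
            index="junction_id", columns="sample_id", values="out_reads",
            aggfunc="sum", fill_value=0,
        )
        .reindex(index=events, columns=samples, fill_value=0)
        .astype(int)
    )
    in_m = (
        in_reads.pivot_table(
            index="junction_id", columns="sample_id", values="in_reads_total",
            aggfunc="sum", fill_value=0,
        )
        .reindex(index=events, columns=samples, fill_value=0)
        .astype(int)
    )
    spl = pd.DataFrame(
        compute_spl_array(out_m.to_numpy(), in_m.to_numpy()),
        index=events, columns=samples,
    )
    return SplMatrix(
        spl=spl, out_reads=out_m, in_reads=in_m,
        cohort=sample_sheet.loc[samples] if samples else sample_sheet.iloc[:0],
    )
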