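"""Sequence-context features of 3' UTR splicing events.

Three descriptive features inform the biological interpretation of an
event:

* the exonic (mRNA-coordinate) distance from the stop codon to the event's
  5' splice site — by the canonical 50-nt rule, an exon-exon junction more
  than 50 nt downstream of the stop codon predicts nonsense-mediated decay
  (NMD), so events splicing close to the stop escape it;
* the removed intron's length;
* the fraction of the intron covered by repeat elements and whether any
  of them is an Alu, which is relevant to Staufen-mediated decay.
"""

from __future__ import annotations

import pandas as pd

from .annotation import GenomeAnnotation, GenomicInterval, TranscriptModel
from .junctions import Junction

__all__ = [
    "stop_distance",
    "stop_distance_min",
    "predict_nmd",
    "read_repeats_bed",
    "repeat_overlap",
    "annotate_events",
]

NMD_THRESHOLD_NT = 50


def stop_distance(intron: GenomicInterval, tx: TranscriptModel) -> int:
    """Exonic nt from the first base after the stop codon to the intron's
    5' splice site, in transcript orientation.

    The intron must lie within this transcript's 3' UTR span.  On the plus
    strand the 5' splice site is the intron start and the distance counts
    3' UTR bases in [stop_end, intron_start); on the minus strand it is the
    mirror image.
    """
    span = tx.utr3_span
    if span is None or not span.contains(intron):
        raise ValueError(
            f"intron {intron.chrom}:{intron.start}-{intron.end} is not within "
            f"the 3' UTR of transcript {tx.transcript_id}"
        )
    if tx.stop_codon is None:
        raise ValueError(f"transcript {tx.transcript_id} has no stop codon")
    dist = 0
    if tx.strand == "+":
        lo, hi = tx.stop_codon.end, intron.start
    else:
        lo, hi = intron.end, tx.stop_codon.start
    for piece in tx.utr3:
        dist += max(0, min(piece.end, hi) - max(piece.start, lo))
    return dist


def stop_distance_min(intron: GenomicInterval, ann: GenomeAnnotation) -> int:
    """Minimum stop-codon distance over all transcripts whose 3' UTR
    contains the intron (conservative for NMD prediction)."""
    hosts = ann.utr3_containing_transcripts(intron)
    if not hosts:
        raise ValueError(
            f"no transcript 3' UTR contains {intron.chrom}:{intron.start}-{intron.end}"
        )
    return min(stop_distance(intron, tx) for tx in hosts)


def predict_nmd(stop_distance_nt: int, threshold: int = NMD_THRESHOLD_NT) -> bool:
    """NMD predicted iff the splice site lies strictly more than
    ``threshold`` exonic nt downstream of the stop codon."""
    if stop_distance_nt < 0:
        raise ValueError("distance must be non-negative")
    return stop_distance_nt > threshold


def read_repeats_bed(path: str) -> pd.DataFrame:
    """Read RepeatMasker-style BED (chrom, start, end, name[, score, strand])."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: BED line needs at least 4 columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from exc
            rows.append(
                {
                    "chrom": fields[0],
                    "start": start,
                    "end": end,
                    "name": fields[3],
                    "strand": fields[5] if len(fields) > 5 else ".",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])


def repeat_overlap(
    intron: GenomicInterval, repeats: pd.DataFrame
) -> tuple[float, bool]:
    """(fraction of intron bases under the union of repeat intervals,
    whether any overlapping repeat name starts with 'Alu')."""
    sub = repeats[
        (repeats["chrom"] == intron.chrom)
        & (repeats["start"] < intron.end)
        & (repeats["end"] > intron.start)
    ]
    if sub.empty:
        return 0.0, False
    clipped = sorted(
        (max(int(s), intron.start), min(int(e), intron.end))
        for s, e in zip(sub["start"], sub["end"])
    )
    covered = 0
    cur_s, cur_e = clipped[0]
    for s, e in clipped[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    has_alu = bool(sub["name"].astype(str).str.startswith("Alu").any())
    return covered / len(intron), has_alu


def annotate_events(
    event_ids,
    ann: GenomeAnnotation,
    repeats: pd.DataFrame | None = None,
    nmd_threshold: int = NMD_THRESHOLD_NT,
) -> pd.DataFrame:
    """Feature table for a set of 3' UTR events: stop distance, NMD
    prediction, intron length, repeat overlap fraction and Alu flag."""
    rows = []
    for event_id in event_ids:
        intron = Junction.from_id(event_id).interval
        dist = stop_distance_min(intron, ann)
        frac, alu = (
            repeat_overlap(intron, repeats) if repeats is not None else (0.0, False)
        )
        rows.append(
            {
                "event_id": event_id,
                "stop_distance_nt": dist,
                "nmd_predicted": predict_nmd(dist, threshold=nmd_threshold),
                "intron_length_nt": len(intron),
                "repeat_overlap_fraction": frac,
                "has_alu": alu,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["event_id", "stop_distance_nt", "nmd_predicted",
                 "intron_length_nt", "repeat_overlap_fraction", "has_alu"],
    ).set_index("event_id")
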