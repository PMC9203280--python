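"""Independent brute-force oracles used by the test suite.

Everything here re-derives expected results from first principles —
per-base set arithmetic, exhaustive enumeration, manual text parsing —
deliberately avoiding the package's interval indexes and vectorised paths.
"""

from __future__ import annotations

import math
import re
from itertools import combinations

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def parse_gtf_by_hand(gtf_text: str) -> dict:
    """Minimal line-by-line GTF parse into per-transcript feature lists
    (0-based half-open coordinates)."""
    txs: dict[str, dict] = {}
    for line in gtf_text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        feature, start, end, strand = f[2], int(f[3]) - 1, int(f[4]), f[6]
        if feature not in ("exon", "CDS", "stop_codon"):
            continue
        attrs = dict(_ATTR_RE.findall(f[8]))
        tid = attrs["transcript_id"]
        tx = txs.setdefault(
            tid,
            {"chrom": f[0], "strand": strand, "exon": [], "CDS": [],
             "stop_codon": []},
        )
        tx[feature].append((start, end))
    return txs


def per_base_regions(gtf_text: str) -> dict:
    """Per-transcript base sets for each region label, computed base by
    base.  The stop codon counts as CDS.  Returns
    {tid: {chrom, strand, cds, utr5, utr3, noncoding}} with coordinate
    sets, plus 3' UTR genomic spans."""
    txs = parse_gtf_by_hand(gtf_text)
    out = {}
    for tid, tx in txs.items():
        exon_bases = set()
        for s, e in tx["exon"]:
            exon_bases.update(range(s, e))
        cds_bases = set()
        for s, e in tx["CDS"] + tx["stop_codon"]:
            cds_bases.update(range(s, e))
        info = {"chrom": tx["chrom"], "strand": tx["strand"],
                "cds": cds_bases, "utr5": set(), "utr3": set(),
                "noncoding": set(), "utr3_span": None}
        if cds_bases:
            lo, hi = min(cds_bases), max(cds_bases)
            for b in exon_bases - cds_bases:
                if b < lo:
                    key = "utr5" if tx["strand"] == "+" else "utr3"
                elif b > hi:
                    key = "utr3" if tx["strand"] == "+" else "utr5"
                else:
                    continue
                info[key].add(b)
            if info["utr3"]:
                info["utr3_span"] = (min(info["utr3"]), max(info["utr3"]) + 1)
        else:
            info["noncoding"] = exon_bases
        out[tid] = info
    return out


def classify_by_hand(chrom, start, end, strand, regions, stranded=False) -> str:
    """Brute-force intron classification from the per-base region sets,
    applying the same decision rule as the package."""
    bases = set(range(start, end))

    def hit(key, strand_filter):
        return any(
            info["chrom"] == chrom
            and (not strand_filter or info["strand"] == strand)
            and bases & info[key]
            for info in regions.values()
        )

    contained = any(
        info["chrom"] == chrom
        and info["strand"] == strand
        and info["utr3_span"] is not None
        and info["utr3_span"][0] <= start
        and end <= info["utr3_span"][1]
        for info in regions.values()
    )
    cds_excl = hit("cds", stranded)
    utr5_excl = hit("utr5", stranded)
    if contained and not cds_excl and not utr5_excl:
        return "THREE_UTR_EXCLUSIVE"
    touches3 = hit("utr3", False) or contained
    classes = set()
    if hit("cds", False):
        classes.add("CDS")
    if hit("utr5", False):
        classes.add("FIVE_UTR")
    if hit("noncoding", False):
        classes.add("NONCODING")
    if touches3:
        return "MIXED"
    if len(classes) == 1:
        return classes.pop()
    if len(classes) > 1:
        return "MIXED"
    return "NONCODING"


def bh_by_hand(pvals):
    """Step-up Benjamini-Hochberg: q_(k) = min_{i >= k} p_(i) * m / i."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    best = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, pvals[i] * m / rank)
        q[i] = best
    return q


def mannwhitney_exact_by_hand(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating every assignment of
    the pooled ranks to group x (no ties allowed)."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires untied values"
    nx = len(x)
    obs_u = sum(1 for xi in x for yj in y if xi > yj)
    n = len(pooled)
    us = []
    for idx in combinations(range(n), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in idx]
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    mean_u = nx * (n - nx) / 2
    dev = abs(obs_u - mean_u)
    extreme = sum(1 for u in us if abs(u - mean_u) >= dev)
    return extreme / len(us)


def hypergeom_upper_tail_by_hand(k, K, n, N) -> float:
    """P(X >= k) by direct summation of hypergeometric point masses."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
        if n - j <= N - K
    ) / total


def union_overlap_by_hand(intron_start, intron_end, intervals) -> float:
    """Fraction of intron bases covered by the union of intervals."""
    covered = set()
    for s, e in intervals:
        covered.update(range(max(s, intron_start), min(e, intron_end)))
    return len(covered) / (intron_end - intron_start)


def count_in_reads_by_hand(reads, donor, acceptor, k=6, dedupe=False) -> int:
    """Per-read boundary coverage check via explicit base sets."""
    total = 0
    for blocks in reads:
        hits = []
        for boundary in (donor, acceptor):
            need = set(range(boundary - k, boundary + k))
            hits.append(
                any(need <= set(range(s, e)) for s, e in blocks)
            )
        total += int(any(hits)) if dedupe else sum(hits)
    return total
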