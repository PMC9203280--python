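"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emits a miniature genome annotation (one gene per splicing
event, mixed strands, with decoy introns in CDS, 5' UTR and non-coding
exons to exercise the region classifier), per-sample STAR-style junction
tables, a splicing-in read table, a sample sheet (tumour / adjacent normal
/ reference normal), clinical records, a repeat BED, and a ground-truth
record for recovery tests.

Generative model, per event e and sample s:

* a per-event baseline splicing level p_e ~ Beta(alpha, beta);
* a per-sample true level p_es ~ Beta(kappa*mu, kappa*(1-mu)) around the
  cohort target mu (mu = p_e in normals; mu = p_e + delta in tumours for
  dysregulated events, clipped into [0.01, 0.95]);
* an informative depth d_es ~ Poisson(depth_mean); splicing-out reads
  out ~ Binomial(d, p_es) and splicing-in total in = 2 * (d - out) — the
  factor two mirrors the two splice sites, so the plug-in SPL
  out / (out + in/2) = out / d is an unbiased estimate of p_es;
* survival (tumours only): exponential times with log-hazard
  surv_beta * x_s where x_s is the sample's mean true SPL across the
  designated prognostic events, censored uniformly.

All randomness flows through one seeded generator; outputs are
byte-stable for a fixed seed.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "SimTruth", "make_fixture_annotation", "simulate_cohort"]

_CHROMS = ("chr1", "chr2", "chr3", "chr4")
_GENE_SPACING = 10_000
_SPAN = 3_000  # gene footprint


@dataclass
class SimConfig:
    """Cohort-simulation parameters (defaults define the study conditions
    used throughout the test-suite recovery checks)."""

    n_events: int = 400
    frac_3utr: float = 0.70
    n_tumour: int = 40
    n_normal: int = 40
    n_reference: int = 40
    depth_mean: float = 100.0
    baseline_spl_alpha: float = 2.0
    baseline_spl_beta: float = 5.0
    frac_dysregulated: float = 0.05
    delta: float = 0.25
    surv_beta: float = math.log(4.0)
    frac_alu: float = 0.50
    seed: int = 0
    # within-cohort concentration of per-sample SPLs around the target
    sample_concentration: float = 50.0
    # fraction of 3' UTR events also present as an annotated spliced isoform
    frac_annotated: float = 0.30

    def __post_init__(self) -> None:
        for name in ("frac_3utr", "frac_dysregulated", "frac_alu", "frac_annotated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 < self.delta < 1.0:
            raise ValueError("delta must be in (-1, 1)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")


@dataclass
class SimTruth:
    """Ground truth for recovery assertions."""

    true_spl: pd.DataFrame  # events x samples, per-sample true p_es
    dysregulated_ids: list[str]
    prognostic_ids: list[str]
    designed_over_spliced: set[tuple[str, str]]
    placement: pd.Series  # event id -> designed region class
    baseline: pd.Series  # event id -> p_e

    def to_json_dict(self) -> dict:
        return {
            "dysregulated_ids": self.dysregulated_ids,
            "prognostic_ids": self.prognostic_ids,
            "designed_over_spliced": sorted(self.designed_over_spliced),
            "placement": self.placement.to_dict(),
            "baseline": {k: round(v, 6) for k, v in self.baseline.items()},
        }


@dataclass
class _Locus:
    gene_idx: int
    chrom: str
    offset: int
    strand: str
    placement: str  # THREE_UTR_EXCLUSIVE / CDS / FIVE_UTR / NONCODING
    stop_gap: int  # exonic nt between stop codon and the 5' splice site
    intron_len: int
    annotated_isoform: bool

    @property
    def gene_id(self) -> str:
        return f"SIMG{self.gene_idx:05d}"

    @property
    def gene_name(self) -> str:
        # locus 0 is always the designed near-stop (11-nt) event
        if self.gene_idx == 0 and self.placement == "THREE_UTR_EXCLUSIVE":
            return "CTNNB1_like"
        return f"GENE{self.gene_idx:05d}"

    def intron(self) -> tuple[str, int, int, str]:
        g = self.offset
        if self.placement == "THREE_UTR_EXCLUSIVE":
            if self.strand == "+":
                s = g + 1000 + self.stop_gap
                return self.chrom, s, s + self.intron_len, "+"
            e = g + _SPAN - 1000 - self.stop_gap
            return self.chrom, e - self.intron_len, e, "-"
        if self.placement == "CDS":
            if self.strand == "+":
                return self.chrom, g + 300, g + 600, "+"
            return self.chrom, g + 2400, g + 2700, "-"
        if self.placement == "FIVE_UTR":
            # 5' UTR decoy genes carry a 500-nt 5' UTR (plus strand only)
            return self.chrom, g + 100, g + 300, "+"
        return self.chrom, g + 500, g + 800, self.strand  # NONCODING

    def gtf_lines(self) -> list[str]:
        g, chrom, strand = self.offset, self.chrom, self.strand
        attrs = (
            f'gene_id "{self.gene_id}"; transcript_id "{self.gene_id}.T1"; '
            f'gene_name "{self.gene_name}";'
        )

        def row(feature: str, s0: int, e0: int, a: str = attrs) -> str:
            # convert 0-based half-open to GTF 1-based inclusive
            return f"{chrom}\tsim\t{feature}\t{s0 + 1}\t{e0}\t.\t{strand}\t.\t{a}"

        lines = []
        if self.placement == "NONCODING":
            lines.append(row("transcript", g, g + 2000))
            lines.append(row("exon", g, g + 2000))
            return lines
        if self.placement == "FIVE_UTR":
            lines.append(row("transcript", g, g + _SPAN))
            lines.append(row("exon", g, g + _SPAN))
            lines.append(row("CDS", g + 500, g + 1400))
            lines.append(row("stop_codon", g + 1400, g + 1403))
            return lines
        # coding gene with a 2,000-nt 3' UTR (hosts THREE_UTR and CDS introns)
        lines.append(row("transcript", g, g + _SPAN))
        lines.append(row("exon", g, g + _SPAN))
        if strand == "+":
            lines.append(row("CDS", g + 100, g + 997))
            lines.append(row("stop_codon", g + 997, g + 1000))
        else:
            lines.append(row("stop_codon", g + _SPAN - 1000, g + _SPAN - 997))
            lines.append(row("CDS", g + _SPAN - 997, g + _SPAN - 100))
        if self.placement == "THREE_UTR_EXCLUSIVE" and self.annotated_isoform:
            chrom_, s, e, _ = self.intron()
            attrs2 = attrs.replace(".T1", ".T2")
            lines.append(row("transcript", g, g + _SPAN, attrs2))
            lines.append(row("exon", g, s, attrs2))
            lines.append(row("exon", e, g + _SPAN, attrs2))
            if strand == "+":
                lines.append(row("CDS", g + 100, g + 997, attrs2))
                lines.append(row("stop_codon", g + 997, g + 1000, attrs2))
            else:
                lines.append(row("stop_codon", g + _SPAN - 1000, g + _SPAN - 997, attrs2))
                lines.append(row("CDS", g + _SPAN - 997, g + _SPAN - 100, attrs2))
        return lines


def _design_loci(config: SimConfig, rng: np.random.Generator) -> list[_Locus]:
    n3 = int(round(config.frac_3utr * config.n_events))
    placements = ["THREE_UTR_EXCLUSIVE"] * n3
    decoys = ("CDS", "FIVE_UTR", "NONCODING")
    for i in range(config.n_events - n3):
        placements.append(decoys[i % 3])
    cursors = {c: 0 for c in _CHROMS}
    loci = []
    for i, placement in enumerate(placements):
        chrom = _CHROMS[i % len(_CHROMS)]
        offset = cursors[chrom]
        cursors[chrom] += _GENE_SPACING
        strand = "+" if (placement == "FIVE_UTR" or i % 5 != 2) else "-"
        if placement == "THREE_UTR_EXCLUSIVE":
            # the first 3' UTR event reproduces the near-stop geometry
            stop_gap = 11 if i == 0 else int(rng.integers(5, 400))
            intron_len = int(rng.integers(150, 600))
            annotated = i == 0 or rng.random() < config.frac_annotated
        else:
            stop_gap, intron_len, annotated = 10_000, 300, False
        loci.append(
            _Locus(i, chrom, offset, strand, placement, stop_gap, intron_len,
                   annotated)
        )
    return loci


def make_fixture_annotation(config: SimConfig) -> tuple[str, pd.DataFrame]:
    """Build the fixture GTF text plus the event design table
    (event_id, placement, gene_id, stop_gap, intron_length)."""
    rng = np.random.default_rng(config.seed)
    loci = _design_loci(config, rng)
    lines, rows = [], []
    for locus in loci:
        lines.extend(locus.gtf_lines())
        chrom, s, e, strand = locus.intron()
        rows.append(
            {
                "event_id": f"{chrom}:{s}-{e}:{strand}",
                "placement": locus.placement,
                "gene_id": locus.gene_id,
                "gene_name": locus.gene_name,
                "stop_gap": locus.stop_gap if locus.placement
                == "THREE_UTR_EXCLUSIVE" else -1,
                "intron_length": locus.intron_len,
                "annotated_isoform": locus.annotated_isoform,
            }
        )
    design = pd.DataFrame(rows).set_index("event_id")
    return "\n".join(lines) + "\n", design


def _sample_ids(config: SimConfig) -> tuple[list[str], list[str], list[str]]:
    tum = [f"T{i:03d}" for i in range(1, config.n_tumour + 1)]
    nor = [f"N{i:03d}" for i in range(1, config.n_normal + 1)]
    ref = [f"R{i:03d}" for i in range(1, config.n_reference + 1)]
    return tum, nor, ref


def _draw_spl(
    rng: np.random.Generator, mu: np.ndarray, kappa: float
) -> np.ndarray:
    a = np.clip(mu, 1e-3, 1 - 1e-3) * kappa
    b = kappa - a
    return rng.beta(a, b)


def simulate_cohort(config: SimConfig, outdir: str | None = None):
    """Generate a full synthetic cohort.

    Returns ``(files, truth)`` where ``files`` maps logical names to paths
    (empty when ``outdir`` is None) and ``truth`` is a :class:`SimTruth`.
    When ``outdir`` is given, writes annotation.gtf, sj/<sample>.SJ.out.tab,
    in_reads.tsv, samples.tsv, clinical.tsv, repeats.bed, truth.json and
    truth_spl.tsv; additionally exposes in-memory frames on the returned
    truth-bundle via the ``tables`` attribute of the files dict.
    """
    rng = np.random.default_rng(config.seed)
    _design_loci(config, rng)  # advance the stream identically to the design
    gtf_text, design = make_fixture_annotation(config)
    event_ids = list(design.index)
    placement = design["placement"]

    tum, nor, ref = _sample_ids(config)
    samples = tum + nor + ref
    cohort = pd.Series(
        ["TUMOUR"] * len(tum) + ["NORMAL"] * len(nor)
        + ["REFERENCE_NORMAL"] * len(ref),
        index=samples, name="cohort",
    )

    n_events, n_samples = len(event_ids), len(samples)
    baseline = rng.beta(
        config.baseline_spl_alpha, config.baseline_spl_beta, size=n_events
    )

    utr3_ids = [e for e in event_ids if placement[e] == "THREE_UTR_EXCLUSIVE"]
    n_dys = int(round(config.frac_dysregulated * n_events))
    if n_dys > len(utr3_ids):
        warnings.warn("frac_dysregulated exceeds 3' UTR event count; capping")
        n_dys = len(utr3_ids)
    dys_ids = list(rng.choice(utr3_ids, size=n_dys, replace=False)) if n_dys else []
    dys_mask = np.array([e in set(dys_ids) for e in event_ids])

    target = np.tile(baseline[:, None], (1, n_samples))
    is_tumour = np.array([cohort[s] == "TUMOUR" for s in samples])
    shifted = np.outer(dys_mask, is_tumour)
    raw = target + np.where(shifted, config.delta, 0.0)
    clipped = np.clip(raw, 0.01, 0.95)
    if (clipped != raw).any():
        warnings.warn("some shifted SPL targets were clipped into [0.01, 0.95]")

    true_spl = _draw_spl(rng, clipped, config.sample_concentration)
    depth = rng.poisson(config.depth_mean, size=(n_events, n_samples))
    out_reads = rng.binomial(depth, true_spl)
    in_reads = 2 * (depth - out_reads)

    true_df = pd.DataFrame(true_spl, index=event_ids, columns=samples)
    truth = SimTruth(
        true_spl=true_df,
        dysregulated_ids=sorted(dys_ids),
        prognostic_ids=sorted(dys_ids),
        designed_over_spliced={
            (e, s) for e in dys_ids for s in tum
        },
        placement=placement.copy(),
        baseline=pd.Series(baseline, index=event_ids, name="baseline"),
    )

    # Survival for tumours: exponential, log-hazard surv_beta * mean true
    # SPL over prognostic events; uniform censoring.
    if dys_ids:
        x = true_df.loc[sorted(dys_ids), tum].mean(axis=0).to_numpy()
    else:
        x = true_df.loc[:, tum].mean(axis=0).to_numpy()
    lam = (1.0 / 1000.0) * np.exp(config.surv_beta * x)
    t_event = rng.exponential(1.0 / lam)
    t_censor = rng.uniform(200.0, 3000.0, size=len(tum))
    time_days = np.maximum(np.minimum(t_event, t_censor), 1.0)
    observed = (t_event <= t_censor).astype(int)
    clinical = pd.DataFrame(
        {"sample_id": tum, "time_days": np.round(time_days, 2), "event": observed}
    )

    # Repeat intervals over 3' UTR introns: Alu in the middle half for a
    # fraction of events, an L1 stub for a further fraction.
    rep_rows = []
    for k, e in enumerate(utr3_ids):
        chrom, span, strand = e.rsplit(":", 2)
        s, t = (int(v) for v in span.split("-"))
        u = rng.random()
        if u < config.frac_alu:
            q = (t - s) // 4
            rep_rows.append((chrom, s + q, t - q, f"AluY_{k}", 0, strand))
        elif u < config.frac_alu + 0.2:
            rep_rows.append((chrom, s, s + (t - s) // 3, f"L1MB_{k}", 0, strand))
    repeats = pd.DataFrame(
        rep_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )

    # Per-sample STAR-style junction rows (only observed junctions) and
    # the splicing-in table (entries with any informative depth).
    strand_code = {"+": 1, "-": 2}
    sj_frames: dict[str, pd.DataFrame] = {}
    in_rows = []
    coords = [e.rsplit(":", 2) for e in event_ids]
    spans = [tuple(int(v) for v in c[1].split("-")) for c in coords]
    for j, sample in enumerate(samples):
        rows = []
        for i, e in enumerate(event_ids):
            if depth[i, j] == 0:
                continue
            chrom, _, strand = coords[i]
            s, t = spans[i]
            if out_reads[i, j] > 0:
                rows.append(
                    (chrom, s + 1, t, strand_code[strand], 1,
                     int(design["annotated_isoform"].iloc[i]),
                     int(out_reads[i, j]), 0, 20)
                )
            in_rows.append((e, sample, int(in_reads[i, j])))
        sj_frames[sample] = pd.DataFrame(
            rows,
            columns=["chrom", "start1", "end1", "strand_code", "motif",
                     "annotated", "unique_reads", "multi_reads", "overhang"],
        )
    in_table = pd.DataFrame(
        in_rows, columns=["junction_id", "sample_id", "in_reads_total"]
    )

    tables = {
        "gtf_text": gtf_text,
        "design": design,
        "sj_frames": sj_frames,
        "in_reads": in_table,
        "cohort": cohort,
        "clinical": clinical,
        "repeats": repeats,
    }

    files: dict[str, str] = {"tables": tables}  # type: ignore[dict-item]
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        sj_dir = os.path.join(outdir, "sj")
        os.makedirs(sj_dir, exist_ok=True)
        files["annotation"] = os.path.join(outdir, "annotation.gtf")
        with open(files["annotation"], "w") as fh:
            fh.write(gtf_text)
        for sample, frame in sj_frames.items():
            path = os.path.join(sj_dir, f"{sample}.SJ.out.tab")
            frame.to_csv(path, sep="\t", header=False, index=False)
        files["sj_dir"] = sj_dir
        files["in_reads"] = os.path.join(outdir, "in_reads.tsv")
        in_table.to_csv(files["in_reads"], sep="\t", index=False)
        files["samples"] = os.path.join(outdir, "samples.tsv")
        cohort.rename_axis("sample_id").reset_index().to_csv(
            files["samples"], sep="\t", index=False
        )
        files["clinical"] = os.path.join(outdir, "clinical.tsv")
        clinical.to_csv(files["clinical"], sep="\t", index=False)
        files["repeats"] = os.path.join(outdir, "repeats.bed")
        repeats.to_csv(files["repeats"], sep="\t", header=False, index=False)
        files["truth"] = os.path.join(outdir, "truth.json")
        with open(files["truth"], "w") as fh:
            json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
        files["truth_spl"] = os.path.join(outdir, "truth_spl.tsv")
        true_df.round(6).to_csv(files["truth_spl"], sep="\t",
                                index_label="event_id")
    return files, truth


def cohort_matrix(tables: dict):
    """Build the :class:`~utr3splice.junctions.SplMatrix` straight from the
    in-memory simulation tables (no file round-trip)."""
    from .junctions import build_spl_matrix, read_sj_table
    import io

    frames = []
    for sample, frame in tables["sj_frames"].items():
        if frame.empty:
            continue
        buf = io.StringIO()
        frame.to_csv(buf, sep="\t", header=False, index=False)
        buf.seek(0)
        frames.append(read_sj_table(buf, sample))
    return build_spl_matrix(frames, tables["in_reads"], tables["cohort"])
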