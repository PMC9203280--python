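import warnings

import pytest

from utr3splice.annotation import parse_gtf
from utr3splice.simdata import SimConfig, cohort_matrix, simulate_cohort


def _gtf_row(chrom, feature, s0, e0, strand, tid, gid=None):
    gid = gid or tid.split(".")[0]
    attrs = f'gene_id "{gid}"; transcript_id "{tid}"; gene_name "{gid}";'
    return f"{chrom}\tfix\t{feature}\t{s0 + 1}\t{e0}\t.\t{strand}\t.\t{attrs}"


def build_toy_gtf() -> str:
    """Twenty transcripts on two chromosomes, mixed strands, coding and
    non-coding, single- and multi-exon, plus one overlapping antisense
    pair whose CDS sits inside another gene's 3' UTR."""
    lines = []
    for i in range(18):
        chrom = "c1" if i < 9 else "c2"
        b = (i % 9) * 20_000
        kind = i % 5
        if kind == 0:  # single-exon coding, plus strand
            lines += [
                _gtf_row(chrom, "exon", b, b + 3000, "+", f"T{i}.1"),
                _gtf_row(chrom, "CDS", b + 100, b + 997, "+", f"T{i}.1"),
                _gtf_row(chrom, "stop_codon", b + 997, b + 1000, "+", f"T{i}.1"),
            ]
        elif kind == 1:  # two exons, CDS ends mid exon 2, plus strand
            lines += [
                _gtf_row(chrom, "exon", b, b + 800, "+", f"T{i}.1"),
                _gtf_row(chrom, "exon", b + 1500, b + 4000, "+", f"T{i}.1"),
                _gtf_row(chrom, "CDS", b + 200, b + 800, "+", f"T{i}.1"),
                _gtf_row(chrom, "CDS", b + 1500, b + 2000, "+", f"T{i}.1"),
                _gtf_row(chrom, "stop_codon", b + 2000, b + 2003, "+", f"T{i}.1"),
            ]
        elif kind == 2:  # single-exon coding, minus strand
            lines += [
                _gtf_row(chrom, "exon", b, b + 3000, "-", f"T{i}.1"),
                _gtf_row(chrom, "stop_codon", b + 2000, b + 2003, "-", f"T{i}.1"),
                _gtf_row(chrom, "CDS", b + 2003, b + 2900, "-", f"T{i}.1"),
            ]
        elif kind == 3:  # non-coding, two exons
            lines += [
                _gtf_row(chrom, "exon", b, b + 1000, "+", f"T{i}.1"),
                _gtf_row(chrom, "exon", b + 1400, b + 2400, "+", f"T{i}.1"),
            ]
        else:  # three exons, 3' UTR spans the last two, plus strand
            lines += [
                _gtf_row(chrom, "exon", b, b + 500, "+", f"T{i}.1"),
                _gtf_row(chrom, "exon", b + 900, b + 1600, "+", f"T{i}.1"),
                _gtf_row(chrom, "exon", b + 2200, b + 3600, "+", f"T{i}.1"),
                _gtf_row(chrom, "CDS", b + 100, b + 500, "+", f"T{i}.1"),
                _gtf_row(chrom, "CDS", b + 900, b + 1197, "+", f"T{i}.1"),
                _gtf_row(chrom, "stop_codon", b + 1197, b + 1200, "+", f"T{i}.1"),
            ]
    # antisense pair at c1:200000 — B's CDS inside A's 3' UTR
    b = 200_000
    lines += [
        _gtf_row("c1", "exon", b, b + 3000, "+", "TA.1"),
        _gtf_row("c1", "CDS", b + 100, b + 997, "+", "TA.1"),
        _gtf_row("c1", "stop_codon", b + 997, b + 1000, "+", "TA.1"),
        _gtf_row("c1", "exon", b + 1500, b + 2500, "-", "TB.1"),
        _gtf_row("c1", "stop_codon", b + 1600, b + 1603, "-", "TB.1"),
        _gtf_row("c1", "CDS", b + 1603, b + 2400, "-", "TB.1"),
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def toy_gtf_text() -> str:
    return build_toy_gtf()


@pytest.fixture(scope="session")
def toy_gtf(tmp_path_factory, toy_gtf_text):
    path = tmp_path_factory.mktemp("ann") / "toy.gtf"
    path.write_text(toy_gtf_text)
    return str(path)


@pytest.fixture(scope="session")
def toy_annotation(toy_gtf):
    return parse_gtf(toy_gtf)


SMALL_SIM = dict(
    n_events=60, n_tumour=12, n_normal=12, n_reference=12,
    frac_dysregulated=0.10, seed=11,
)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small simulated cohort shared by cross-module tests."""
    outdir = tmp_path_factory.mktemp("sim")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        files, truth = simulate_cohort(SimConfig(**SMALL_SIM), outdir=str(outdir))
    matrix = cohort_matrix(files["tables"])
    annotation = parse_gtf(files["annotation"])
    return {"files": files, "truth": truth, "matrix": matrix,
            "annotation": annotation, "outdir": str(outdir)}
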