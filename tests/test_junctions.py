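"""SJ-table parsing, the SPL statistic, splicing-in counting, matrix build."""

import io
import math
import random

import numpy as np
import pandas as pd
import pytest

from utr3splice.junctions import (
    Junction,
    SplMatrix,
    build_spl_matrix,
    compute_spl,
    compute_spl_array,
    count_in_reads,
    read_sample_sheet,
    read_sj_table,
)
from utr3splice.annotation import GenomicInterval

from _oracles import count_in_reads_by_hand


def test_junction_id_roundtrip():
    j = Junction(GenomicInterval("chr1", 100, 200, "-"))
    assert j.id == "chr1:100-200:-"
    assert Junction.from_id(j.id) == j


class TestComputeSpl:
    def test_closed_form_on_grid(self):
        for out in range(0, 101):
            for inr in range(0, 101):
                got = compute_spl(out, inr)
                if out == 0 and inr == 0:
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(out / (out + inr / 2))

    @pytest.mark.parametrize(
        "out,inr,expected", [(10, 0, 1.0), (0, 8, 0.0), (5, 10, 0.5)]
    )
    def test_hand_examples(self, out, inr, expected):
        assert compute_spl(out, inr) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_spl(-1, 0)
        with pytest.raises(ValueError):
            compute_spl_array([1], [-2])

    def test_monotone_in_both_arguments(self):
        grid = np.arange(0, 101)
        spl = compute_spl_array(
            np.repeat(grid, 101), np.tile(grid, 101)
        ).reshape(101, 101)
        # increasing in out_reads (rows, skipping the missing corner)
        d_out = np.diff(spl[:, 1:], axis=0)
        assert np.all(d_out[~np.isnan(d_out)] >= 0)
        d_in = np.diff(spl[1:, :], axis=1)
        assert np.all(d_in[~np.isnan(d_in)] <= 0)

    def test_binomial_plugin_concentrates_on_p(self):
        """At depth 1,000 the mean plug-in SPL is within 0.02 of the true
        splicing probability (two-site in-read convention)."""
        rng = np.random.default_rng(5)
        for p in (0.1, 0.3, 0.7):
            out = rng.binomial(1000, p, size=500)
            spl = compute_spl_array(out, 2 * (1000 - out))
            assert abs(spl.mean() - p) < 0.02


class TestReadSjTable:
    def test_coordinate_conversion_and_strand(self):
        buf = io.StringIO("chr1\t101\t200\t1\t1\t0\t7\t3\t20\n")
        df = read_sj_table(buf, "s1")
        row = df.iloc[0]
        assert row["junction_id"] == "chr1:100-200:+"
        assert row["out_reads"] == 7 and not row["strand_undefined"]

    def test_multimappers_optional(self):
        line = "chr1\t101\t200\t2\t1\t0\t7\t3\t20\n"
        assert read_sj_table(io.StringIO(line), "s")["out_reads"].iloc[0] == 7
        assert (
            read_sj_table(io.StringIO(line), "s", include_multimappers=True)[
                "out_reads"
            ].iloc[0]
            == 10
        )

    def test_undefined_strand_flagged_plus(self):
        df = read_sj_table(io.StringIO("chr2\t11\t50\t0\t0\t0\t4\t0\t12\n"), "s")
        assert df.iloc[0]["strand"] == "+" and df.iloc[0]["strand_undefined"]

    def test_empty_file(self):
        assert read_sj_table(io.StringIO(""), "s").empty

    def test_non_integer_count_raises_with_line(self, tmp_path):
        p = tmp_path / "bad.tab"
        p.write_text(
            "chr1\t11\t50\t1\t0\t0\t4\t0\t12\n"
            "chr1\t61\t90\t1\t0\t0\tfour\t0\t12\n"
        )
        with pytest.raises(ValueError, match="unique_reads"):
            read_sj_table(str(p), "s")

    def test_fifty_line_fixture_matches_manual_parse(self, tmp_path):
        rng = random.Random(9)
        lines, expected = [], set()
        for i in range(50):
            chrom = f"chr{rng.randint(1, 3)}"
            s1 = rng.randint(1, 10_000)
            e1 = s1 + rng.randint(30, 500)
            code = rng.choice([0, 1, 2])
            u = rng.randint(0, 40)
            lines.append(f"{chrom}\t{s1}\t{e1}\t{code}\t1\t0\t{u}\t0\t15")
            strand = {0: "+", 1: "+", 2: "-"}[code]
            expected.add((f"{chrom}:{s1 - 1}-{e1}:{strand}", u))
        p = tmp_path / "f.tab"
        p.write_text("\n".join(lines) + "\n")
        df = read_sj_table(str(p), "s")
        assert set(zip(df["junction_id"], df["out_reads"])) == expected


class TestCountInReads:
    J = Junction(GenomicInterval("chr1", 1000, 1400, "+"))

    def test_exact_six_nt_flanks_count(self):
        reads = [[(994, 1006)]]  # exactly 6 nt each side of the donor
        assert count_in_reads(reads, self.J) == 1

    def test_five_nt_flank_fails(self):
        assert count_in_reads([[(995, 1006)]], self.J) == 0

    def test_read_spanning_both_boundaries_counts_twice(self):
        reads = [[(900, 1500)]]
        assert count_in_reads(reads, self.J) == 2
        assert count_in_reads(reads, self.J, dedupe_spanning_reads=True) == 1

    def test_read_spliced_at_this_junction_does_not_count(self):
        # gapped exactly across the intron: blocks end/start at boundaries
        assert count_in_reads([[(950, 1000), (1400, 1450)]], self.J) == 0

    def test_spliced_elsewhere_counts_only_if_boundary_intact(self):
        # splice inside the intron leaves the acceptor boundary covered
        reads = [[(1100, 1200), (1350, 1450)]]
        assert count_in_reads(reads, self.J) == 1

    def test_random_reads_match_per_read_oracle(self):
        rng = random.Random(13)
        reads = []
        for _ in range(300):
            s = rng.randint(800, 1500)
            if rng.random() < 0.3:
                gap = rng.randint(20, 200)
                reads.append([(s, s + 40), (s + 40 + gap, s + 80 + gap)])
            else:
                reads.append([(s, s + rng.randint(10, 120))])
        for dedupe in (False, True):
            assert count_in_reads(
                reads, self.J, dedupe_spanning_reads=dedupe
            ) == count_in_reads_by_hand(reads, 1000, 1400, dedupe=dedupe)


class TestBuildMatrix:
    sheet = pd.Series(
        {"a": "TUMOUR", "b": "NORMAL", "c": "REFERENCE_NORMAL"}, name="cohort"
    )

    @staticmethod
    def _sj(sample, rows):
        return pd.DataFrame(
            [
                {"junction_id": j, "chrom": "c", "start": 0, "end": 1,
                 "strand": "+", "strand_undefined": False, "out_reads": o,
                 "sample_id": sample}
                for j, o in rows
            ]
        )

    def test_hand_computed_spls(self):
        frames = [
            self._sj("a", [("e1", 5), ("e2", 10)]),
            self._sj("b", [("e1", 0)]),
            self._sj("c", [("e1", 3)]),
        ]
        inr = pd.DataFrame(
            {
                "junction_id": ["e1", "e1", "e1", "e2", "e2", "e2"],
                "sample_id": ["a", "b", "c", "a", "b", "c"],
                "in_reads_total": [10, 8, 0, 0, 0, 0],
            }
        )
        m = build_spl_matrix(frames, inr, self.sheet)
        assert m.spl.loc["e1", "a"] == pytest.approx(0.5)
        assert m.spl.loc["e1", "b"] == pytest.approx(0.0)
        assert m.spl.loc["e1", "c"] == pytest.approx(1.0)
        assert m.spl.loc["e2", "a"] == pytest.approx(1.0)
        # e2 absent in b and c with no in-reads: missing, not zero
        assert math.isnan(m.spl.loc["e2", "b"])
        assert math.isnan(m.spl.loc["e2", "c"])

    def test_sample_order_invariance(self):
        frames = [self._sj("a", [("e1", 5)]), self._sj("b", [("e1", 2)])]
        inr = pd.DataFrame(
            {"junction_id": ["e1", "e1"], "sample_id": ["a", "b"],
             "in_reads_total": [4, 4]}
        )
        m1 = build_spl_matrix(frames, inr, self.sheet)
        m2 = build_spl_matrix(frames[::-1], inr.iloc[::-1], self.sheet)
        pd.testing.assert_frame_equal(m1.spl, m2.spl)

    def test_unknown_sample_rejected(self):
        frames = [self._sj("zz", [("e1", 5)])]
        inr = pd.DataFrame(columns=["junction_id", "sample_id", "in_reads_total"])
        with pytest.raises(ValueError, match="zz"):
            build_spl_matrix(frames, inr, self.sheet)

    def test_spl_range_validated(self):
        bad = pd.DataFrame({"a": [1.5]}, index=["e"])
        ints = pd.DataFrame({"a": [1]}, index=["e"])
        with pytest.raises(ValueError):
            SplMatrix(bad, ints, ints, self.sheet)


def test_sample_sheet_rejects_unknown_cohort(tmp_path):
    p = tmp_path / "sheet.tsv"
    p.write_text("sample_id\tcohort\ns1\tWEIRD\n")
    with pytest.raises(ValueError, match="WEIRD"):
        read_sample_sheet(str(p))
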