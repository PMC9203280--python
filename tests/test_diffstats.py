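"""Rank tests, BH adjustment, permutation FDR, overlap tests, screens."""

import itertools

import numpy as np
import pandas as pd
import pytest

from utr3splice.diffstats import (
    bh_adjust,
    differential_cohort,
    hypergeom_overlap,
    mann_whitney_p,
    permutation_fdr_paired,
    rbp_screen,
)
from utr3splice.junctions import SplMatrix

from _oracles import (
    bh_by_hand,
    hypergeom_upper_tail_by_hand,
    mannwhitney_exact_by_hand,
)


class TestMannWhitney:
    def test_complete_separation_3v3_exact(self):
        """Fully separated groups of three: p = 2/20 = 0.1 exactly."""
        p = mann_whitney_p([0.4, 0.5, 0.6], [0.0, 0.1, 0.2])
        assert p == pytest.approx(0.1)

    def test_small_samples_match_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            nx, ny = rng.integers(2, 7, size=2)
            pool = rng.permutation(np.arange(nx + ny, dtype=float) / 10)
            x, y = pool[:nx], pool[nx:]
            assert mann_whitney_p(x, y) == pytest.approx(
                mannwhitney_exact_by_hand(list(x), list(y))
            )

    def test_identical_groups_near_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        assert mann_whitney_p(x, x) > 0.9


class TestBH:
    def test_hand_computed_examples(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_by_hand(list(p)))

    def test_monotone_after_sorting_by_p(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            p = rng.uniform(size=20)
            q = bh_adjust(p)
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()

    def test_empty_and_range_checks(self):
        assert bh_adjust([]).size == 0
        with pytest.raises(ValueError):
            bh_adjust([1.2])


def _cohort_matrix(tum, nor, ref, events=("e1",)):
    samples = (
        [f"t{i}" for i in range(len(tum[0]))]
        + [f"n{i}" for i in range(len(nor[0]))]
        + [f"r{i}" for i in range(len(ref[0]))]
    )
    cohort = pd.Series(
        ["TUMOUR"] * len(tum[0]) + ["NORMAL"] * len(nor[0])
        + ["REFERENCE_NORMAL"] * len(ref[0]),
        index=samples, name="cohort",
    )
    spl = pd.DataFrame(
        [list(t) + list(n) + list(r) for t, n, r in zip(tum, nor, ref)],
        index=list(events), columns=samples,
    )
    ones = (spl * 0 + 1).fillna(0).astype(int)
    return SplMatrix(spl, ones, ones, cohort)


class TestDifferentialCohort:
    def test_single_separated_event(self):
        m = _cohort_matrix([[0.4, 0.5, 0.6]], [[0.0, 0.1, 0.2]],
                           [[0.0, 0.1, 0.2]])
        res = differential_cohort(m)
        assert res.loc["e1", "p_value"] == pytest.approx(0.1)
        assert res.loc["e1", "fdr"] == pytest.approx(0.1)
        assert res.loc["e1", "delta_normal"] == pytest.approx(0.4)

    def test_identical_groups_not_significant(self):
        vals = [0.1, 0.2, 0.3, 0.4]
        m = _cohort_matrix([vals], [vals], [vals])
        res = differential_cohort(m)
        assert res.loc["e1", "direction"] == "NONE"
        assert not res.loc["e1", "significant"]

    def test_unidirectionality_required(self):
        # tumour above normal but below reference: signs disagree
        m = _cohort_matrix(
            [[0.30, 0.32, 0.34, 0.36] * 3],
            [[0.20, 0.21, 0.22, 0.23] * 3],
            [[0.40, 0.41, 0.42, 0.43] * 3],
        )
        res = differential_cohort(m)
        assert res.loc["e1", "delta_normal"] > 0.05
        assert res.loc["e1", "delta_reference"] < 0
        assert not res.loc["e1", "significant"]

    def test_min_delta_is_or_over_the_two_references(self):
        # delta vs normal tiny, vs reference large: OR satisfied
        m = _cohort_matrix(
            [[0.50, 0.52, 0.54, 0.56, 0.58, 0.60]],
            [[0.48, 0.49, 0.50, 0.51, 0.52, 0.53]],
            [[0.10, 0.11, 0.12, 0.13, 0.14, 0.15]],
        )
        res = differential_cohort(m)
        assert abs(res.loc["e1", "delta_normal"]) < 0.05
        assert res.loc["e1", "delta_reference"] > 0.05
        if res.loc["e1", "fdr"] < 0.1:
            assert res.loc["e1", "significant"]

    def test_untestable_events_excluded_from_bh(self):
        m = _cohort_matrix(
            [[0.4, 0.5, 0.6], [0.4, np.nan, np.nan]],
            [[0.0, 0.1, 0.2], [0.1, 0.1, np.nan]],
            [[0.0, 0.1, 0.2], [np.nan, np.nan, np.nan]],
            events=("ok", "sparse"),
        )
        res = differential_cohort(m)
        assert not res.loc["sparse", "tested"]
        assert np.isnan(res.loc["sparse", "p_value"])
        # BH family is the single tested event
        assert res.loc["ok", "fdr"] == pytest.approx(res.loc["ok", "p_value"])

    def test_requires_normals(self):
        samples = ["t0", "t1", "t2"]
        cohort = pd.Series(["TUMOUR"] * 3, index=samples, name="cohort")
        spl = pd.DataFrame([[0.1, 0.2, 0.3]], index=["e1"], columns=samples)
        ones = (spl * 0 + 1).astype(int)
        with pytest.raises(ValueError, match="NORMAL"):
            differential_cohort(SplMatrix(spl, ones, ones, cohort))


class TestPermutationFdr:
    def test_all_zero_differences(self):
        d = pd.DataFrame([[0.0, 0.0, 0.0, 0.0]], index=["e"])
        res = permutation_fdr_paired(d)
        assert res.loc["e", "statistic"] == 0.0
        assert res.loc["e", "fdr"] == 1.0

    def test_four_pairs_exhaustive_matches_enumeration(self):
        """16 sign-flips enumerated by hand: for constant differences 0.2
        the |null median| >= 0.2 in the 10 flips with #(minus) != 2."""
        d = pd.DataFrame([[0.2, 0.2, 0.2, 0.2]], index=["e"])
        res = permutation_fdr_paired(d, n_perm=16)
        # oracle: enumerate all flips
        tail = 0
        for signs in itertools.product((1, -1), repeat=4):
            null = np.median([0.2 * s for s in signs])
            tail += abs(null) >= 0.2
        assert res.loc["e", "fdr"] == pytest.approx(tail / 16 / 1)

    def test_sampled_matches_exhaustive_in_the_limit(self):
        rng = np.random.default_rng(3)
        d = pd.DataFrame(rng.normal(0.05, 0.1, size=(30, 4)))
        exact = permutation_fdr_paired(d, n_perm=16)        # exhaustive 2^4
        approx = permutation_fdr_paired(d, n_perm=10_000, seed=5)
        np.testing.assert_allclose(exact["fdr"], approx["fdr"], atol=0.05)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(4)
        d = pd.DataFrame(rng.normal(size=(10, 20)))
        a = permutation_fdr_paired(d, n_perm=500, seed=9)
        b = permutation_fdr_paired(d, n_perm=500, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            permutation_fdr_paired(pd.DataFrame([[0.1]]), n_perm=8)


class TestHypergeom:
    def test_full_overlap_closed_form(self):
        res = hypergeom_overlap(5, 5, 5, 10)
        assert res.p_value == pytest.approx(1 / 252)

    def test_zero_overlap_is_one(self):
        assert hypergeom_overlap(0, 5, 5, 10).p_value == pytest.approx(1.0)

    def test_random_instances_match_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            N = int(rng.integers(5, 15))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
            assert hypergeom_overlap(k, K, n, N).p_value == pytest.approx(
                hypergeom_upper_tail_by_hand(k, K, n, N)
            )

    def test_inconsistent_sizes(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(6, 5, 5, 10)


class TestRbpScreen:
    def _data(self):
        spl = pd.Series(
            {"c1": 0.30, "c2": 0.35, "c3": 0.32,
             "k1": 0.05, "k2": 0.06, "k3": 0.04,
             "m1": 0.31, "m2": 0.36, "m3": 0.29},
        )
        factor = pd.Series(
            {"c1": "CONTROL", "c2": "CONTROL", "c3": "CONTROL",
             "k1": "SF3B1", "k2": "SF3B1", "k3": "SF3B1",
             "m1": "NULLRBP", "m2": "NULLRBP", "m3": "NULLRBP"}
        )
        return spl, factor

    def test_separated_knockdown_exact_p(self):
        spl, factor = self._data()
        res = rbp_screen(spl, factor)
        assert res.loc["SF3B1", "p_value"] == pytest.approx(0.1)
        assert res.loc["SF3B1", "delta"] == pytest.approx(0.05 - 0.32)

    def test_null_factor_large_p_and_determinism(self):
        spl, factor = self._data()
        res1 = rbp_screen(spl, factor)
        res2 = rbp_screen(spl, factor)
        assert res1.loc["NULLRBP", "p_value"] > 0.5
        pd.testing.assert_frame_equal(res1, res2)

    def test_requires_controls(self):
        spl, factor = self._data()
        with pytest.raises(ValueError):
            rbp_screen(spl, factor.replace("CONTROL", "X"))
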