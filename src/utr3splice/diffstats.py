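"""Differential 3' UTR splicing between cohorts.

Per event, tumour and normal SPLs are compared with a two-sided
Mann-Whitney U test (exact enumeration for small groups, normal
approximation with tie correction otherwise), and p-values are adjusted
across events with Benjamini-Hochberg within the cohort.  An event is
called significantly dysregulated when

* FDR < 0.1,
* the tumour-vs-normal and tumour-vs-reference-normal median SPL
  differences agree in sign (unidirectionality), and
* at least one of the two median differences exceeds 5% in magnitude.

For very small matched cohorts (a few tumour/normal pairs) a sign-flip
permutation of paired SPL differences provides an empirical FDR instead.
A hypergeometric upper-tail test quantifies set overlaps (e.g. dysregulated
events versus oncogene-hosted events), and the same rank-test machinery
screens RNA-binding-protein knockdowns for effects on a single event's SPL.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .junctions import SplMatrix

__all__ = [
    "DifferentialResult",
    "OverlapTestResult",
    "mann_whitney_p",
    "bh_adjust",
    "differential_cohort",
    "permutation_fdr_paired",
    "hypergeom_overlap",
    "rbp_screen",
]

EXACT_MAX_N = 8


@dataclass
class DifferentialResult:
    event_id: str
    p_value: float
    fdr: float
    median_tumour: float
    median_normal: float
    median_reference: float
    delta_normal: float
    delta_reference: float
    direction: str  # UP / DOWN / NONE
    significant: bool
    tested: bool


@dataclass
class OverlapTestResult:
    k: int
    K: int
    n: int
    N: int
    p_value: float


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Uses exact enumeration when both groups have at most 8 observations
    and no cross-group ties, otherwise the normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(set(x) & set(y)) > 0 or len(set(np.concatenate([x, y]))) < x.size + y.size
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_cohort(
    matrix: SplMatrix,
    fdr_cut: float = 0.1,
    min_delta: float = 0.05,
    min_group_n: int = 3,
) -> pd.DataFrame:
    """Differential splicing for every event in the matrix.

    Tumour and normal SPLs (missing dropped) are rank-tested per event; BH
    runs across the tested events only.  Untestable events (fewer than
    ``min_group_n`` observations in tumour or normal) are reported with NA
    p and excluded from the BH family.  The reference-normal cohort enters
    only through its median (unidirectionality and delta criteria).
    """
    tum = matrix.samples_in("TUMOUR")
    nor = matrix.samples_in("NORMAL")
    ref = matrix.samples_in("REFERENCE_NORMAL")
    if not nor:
        raise ValueError("no NORMAL samples in matrix")

    rows = []
    for event_id in matrix.events:
        row = matrix.spl.loc[event_id]
        t = row[tum].dropna().to_numpy()
        n = row[nor].dropna().to_numpy()
        r = row[ref].dropna().to_numpy() if ref else np.array([])
        med_t = float(np.median(t)) if t.size else np.nan
        med_n = float(np.median(n)) if n.size else np.nan
        med_r = float(np.median(r)) if r.size else np.nan
        tested = t.size >= min_group_n and n.size >= min_group_n
        p = mann_whitney_p(t, n) if tested else np.nan
        rows.append(
            {
                "event_id": event_id,
                "p_value": p,
                "median_tumour": med_t,
                "median_normal": med_n,
                "median_reference": med_r,
                "delta_normal": med_t - med_n,
                "delta_reference": med_t - med_r if r.size else np.nan,
                "tested": tested,
            }
        )
    df = pd.DataFrame(rows).set_index("event_id")

    df["fdr"] = np.nan
    tested_mask = df["tested"].to_numpy()
    if tested_mask.any():
        df.loc[tested_mask, "fdr"] = bh_adjust(df.loc[tested_mask, "p_value"])

    dn = df["delta_normal"]
    dr = df["delta_reference"]
    # Without a reference cohort the unidirectionality criterion collapses
    # to the tumour-vs-normal direction alone.
    if ref:
        unidirectional = (np.sign(dn) == np.sign(dr)) & (np.sign(dn) != 0)
        big_enough = (dn.abs() > min_delta) | (dr.abs() > min_delta)
    else:
        unidirectional = np.sign(dn) != 0
        big_enough = dn.abs() > min_delta
    df["significant"] = (
        tested_mask & (df["fdr"] < fdr_cut) & unidirectional & big_enough
    ).fillna(False)
    df["direction"] = np.where(
        df["significant"], np.where(dn > 0, "UP", "DOWN"), "NONE"
    )
    return df[
        ["p_value", "fdr", "median_tumour", "median_normal", "median_reference",
         "delta_normal", "delta_reference", "direction", "significant", "tested"]
    ]


def permutation_fdr_paired(
    paired_diffs: pd.DataFrame, n_perm: int = 10000, seed: int = 0
) -> pd.DataFrame:
    """Sign-flip permutation FDR for matched tumour/normal pairs.

    ``paired_diffs`` is events x pairs of SPL differences (tumour minus
    normal).  The per-event statistic is the median paired difference; the
    null flips the sign of each pair (all 2^n flips when that is at most
    ``n_perm``, else ``n_perm`` sampled flips).  The per-event FDR is the
    mean null count of events with |statistic| at least as extreme, divided
    by the observed count, capped at 1.
    """
    diffs = paired_diffs.to_numpy(dtype=float)
    n_events, n_pairs = diffs.shape
    if n_pairs < 2:
        raise ValueError("need at least 2 matched pairs")
    observed = np.median(diffs, axis=1)

    if 2 ** n_pairs <= n_perm:
        signs = np.array(list(product((1.0, -1.0), repeat=n_pairs)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n_pairs))

    abs_obs = np.abs(observed)
    # null statistics: (n_flips, n_events)
    null_stats = np.abs(np.median(diffs[None, :, :] * signs[:, None, :], axis=2))
    order = np.sort(null_stats.reshape(-1))
    total_null = null_stats.size
    n_flips = signs.shape[0]

    fdrs = np.empty(n_events)
    obs_sorted = np.sort(abs_obs)
    for i, s in enumerate(abs_obs):
        null_count = total_null - np.searchsorted(order, s, side="left")
        mean_null = null_count / n_flips
        obs_count = n_events - np.searchsorted(obs_sorted, s, side="left")
        fdrs[i] = min(1.0, mean_null / max(obs_count, 1))
    return pd.DataFrame(
        {"statistic": observed, "fdr": fdrs}, index=paired_diffs.index
    )


def hypergeom_overlap(k: int, K: int, n: int, N: int) -> OverlapTestResult:
    """Upper-tail hypergeometric P(X >= k) for an overlap of size k between
    a set of size K and a set of size n drawn from a universe of size N."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent overlap sizes k={k}, K={K}, n={n}, N={N}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapTestResult(k=k, K=K, n=n, N=N, p_value=min(p, 1.0))


def rbp_screen(
    spl: pd.Series,
    factor_of: pd.Series,
    control_label: str = "CONTROL",
) -> pd.DataFrame:
    """Knockdown screen for one event's SPL.

    ``spl`` maps sample to SPL; ``factor_of`` maps sample to the knocked
    down factor name (or ``control_label``).  Each factor's knockdown
    samples are rank-tested against the pooled controls; the delta is the
    median SPL difference (knockdown minus control).  Output supports a
    volcano-style table.
    """
    controls = spl[factor_of[factor_of == control_label].index].dropna().to_numpy()
    if controls.size == 0:
        raise ValueError("no control samples")
    rows = []
    for factor in sorted(set(factor_of) - {control_label}):
        kd = spl[factor_of[factor_of == factor].index].dropna().to_numpy()
        if kd.size == 0:
            continue
        rows.append(
            {
                "factor": factor,
                "p_value": mann_whitney_p(kd, controls),
                "delta": float(np.median(kd) - np.median(controls)),
                "n_kd": int(kd.size),
                "n_control": int(controls.size),
            }
        )
    return pd.DataFrame(rows).set_index("factor")
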