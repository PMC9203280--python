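"""Per-sample over-/under-splicing calls for dysregulated events.

For a significantly dysregulated event, each tumour sample's SPL is
compared with the distribution of SPLs in normal samples.  The adjacent
normal and the reference normal cohorts are summarised separately; the
over-splicing cutoff is the larger of the two 90% quantiles (stringent)
and the under-splicing cutoff the smaller of the two 10% quantiles.  A
tumour strictly above the high cutoff is OVER, strictly below the low
cutoff is UNDER, otherwise NEITHER; a missing SPL yields MISSING.

Quantiles use the deterministic nearest-rank method: the ceil(p*n)-th
order statistic of the n non-missing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .junctions import SplMatrix

__all__ = [
    "SpliceStatusCall",
    "nearest_rank_quantile",
    "quantile_cutoffs",
    "call_status",
    "call_matrix",
    "tabulate_over_under",
]

MIN_NORMALS = 5


@dataclass(frozen=True)
class SpliceStatusCall:
    event_id: str
    sample_id: str
    status: str  # OVER / UNDER / NEITHER / MISSING
    cutoff_low: float
    cutoff_high: float


def nearest_rank_quantile(values, q: float) -> float:
    """The ceil(q*n)-th order statistic of the non-missing values."""
    vals = np.sort(np.asarray(values, dtype=float))
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no non-missing values")
    if not 0 < q <= 1:
        raise ValueError("quantile must be in (0, 1]")
    rank = max(1, math.ceil(q * vals.size))
    return float(vals[rank - 1])


def quantile_cutoffs(
    normal_spls,
    reference_spls,
    q_low: float = 0.10,
    q_high: float = 0.90,
    under_quantile_rule: str = "min",
) -> tuple[float, float]:
    """(cutoff_low, cutoff_high) from the two normal cohorts.

    cutoff_high = max of the two per-cohort 90% quantiles (stringent for
    over-splicing); cutoff_low defaults to the min of the two 10% quantiles
    (symmetric stringency for under-splicing; ``under_quantile_rule='max'``
    uses the larger one instead).  Each cohort needs at least 5 non-missing
    values.
    """
    groups = []
    for name, vals in (("normal", normal_spls), ("reference", reference_spls)):
        arr = np.asarray(vals, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < MIN_NORMALS:
            raise ValueError(
                f"{name} cohort has {arr.size} non-missing SPLs; "
                f"need at least {MIN_NORMALS}"
            )
        groups.append(arr)
    highs = [nearest_rank_quantile(g, q_high) for g in groups]
    lows = [nearest_rank_quantile(g, q_low) for g in groups]
    cutoff_high = max(highs)
    if under_quantile_rule == "min":
        cutoff_low = min(lows)
    elif under_quantile_rule == "max":
        cutoff_low = max(lows)
    else:
        raise ValueError(f"unknown under_quantile_rule {under_quantile_rule!r}")
    cutoff_low = min(cutoff_low, cutoff_high)
    return cutoff_low, cutoff_high


def call_status(spl: float, cutoffs: tuple[float, float]) -> str:
    """OVER / UNDER / NEITHER / MISSING for one tumour SPL (strict
    inequalities: a value equal to a cutoff is NEITHER)."""
    low, high = cutoffs
    if not low <= high:
        raise ValueError("cutoff_low must not exceed cutoff_high")
    if spl is None or (isinstance(spl, float) and math.isnan(spl)):
        return "MISSING"
    if spl > high:
        return "OVER"
    if spl < low:
        return "UNDER"
    return "NEITHER"


def call_matrix(
    matrix: SplMatrix,
    event_ids=None,
    q_low: float = 0.10,
    q_high: float = 0.90,
    under_quantile_rule: str = "min",
) -> pd.DataFrame:
    """Over-/under-splicing calls for every tumour sample of the selected
    events (by default all events in the matrix; callers normally pass the
    significantly dysregulated set).

    Returns a tidy frame: event_id, sample_id, spl, cutoff_low,
    cutoff_high, status.
    """
    if event_ids is None:
        event_ids = matrix.events
    tum = matrix.samples_in("TUMOUR")
    nor = matrix.samples_in("NORMAL")
    ref = matrix.samples_in("REFERENCE_NORMAL")
    rows = []
    for event_id in event_ids:
        spl_row = matrix.spl.loc[event_id]
        low, high = quantile_cutoffs(
            spl_row[nor], spl_row[ref] if ref else spl_row[nor],
            q_low=q_low, q_high=q_high, under_quantile_rule=under_quantile_rule,
        )
        for sample in tum:
            val = float(spl_row[sample])
            rows.append(
                {
                    "event_id": event_id,
                    "sample_id": sample,
                    "spl": val,
                    "cutoff_low": low,
                    "cutoff_high": high,
                    "status": call_status(val, (low, high)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["event_id", "sample_id", "spl", "cutoff_low", "cutoff_high",
                 "status"],
    )


def tabulate_over_under(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-event counts of over- and under-spliced tumour samples, sorted
    by the over-spliced count (descending)."""
    if calls.empty:
        return pd.DataFrame(columns=["n_over", "n_under", "n_tumour"]).rename_axis(
            "event_id"
        )
    counts = (
        calls.groupby("event_id")["status"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["OVER", "UNDER", "NEITHER", "MISSING"], fill_value=0)
    )
    out = pd.DataFrame(
        {
            "n_over": counts["OVER"],
            "n_under": counts["UNDER"],
            "n_tumour": counts.sum(axis=1),
        }
    ).rename_axis("event_id")
    return out.sort_values("n_over", ascending=False)
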