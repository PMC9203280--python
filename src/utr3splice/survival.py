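"""Survival association of 3' UTR splicing.

Each event's SPL (a value in [0, 1]) enters a univariate Cox proportional
hazards model of overall survival; the hazard ratio is therefore per full
0-to-1 change in SPL.  Events are labelled UNFAVOURABLE when HR > 1 with
Wald P < 0.05, FAVOURABLE when HR < 1 with P < 0.05, otherwise NS — no
multiplicity adjustment is applied to these labels (a BH column is emitted
for transparency alongside, when several events are tested together).

Kaplan-Meier curves compare the top and bottom halves of samples ranked by
SPL (ties and, for odd n, the middle sample go to the low group) with a
log-rank test.  The same machinery serves binary groupings (e.g. tumours
with versus without over-splicing of an event) and per-sample splicing
burden as the covariate.  Ties in the Cox partial likelihood use the Efron
approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

__all__ = [
    "PrognosisResult",
    "read_clinical",
    "cox_per_event",
    "km_half_split",
    "group_survival",
    "burden_survival",
    "prognosis_table",
]

MIN_SAMPLES = 20
MIN_EVENTS = 5


@dataclass
class PrognosisResult:
    event_id: str
    hazard_ratio: float
    p_value: float
    label: str  # FAVOURABLE / UNFAVOURABLE / NS
    km_p: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n: int = 0
    n_deaths: int = 0
    flag: str = ""


def read_clinical(path: str) -> pd.DataFrame:
    """Read the clinical TSV (sample_id, time_days, event)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    required = {"sample_id", "time_days", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if (df["time_days"] <= 0).any():
        raise ValueError(f"{path}: survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event indicator must be 0 or 1")
    return df.set_index("sample_id")


def _merged(covariate: pd.Series, clinical: pd.DataFrame) -> pd.DataFrame:
    df = clinical.join(covariate.rename("x"), how="inner").dropna()
    return df[["time_days", "event", "x"]]


def _label(hr: float, p: float) -> str:
    if p < 0.05 and hr > 1:
        return "UNFAVOURABLE"
    if p < 0.05 and hr < 1:
        return "FAVOURABLE"
    return "NS"


def cox_per_event(
    spl: pd.Series,
    clinical: pd.DataFrame,
    event_id: str = "",
    min_samples: int = MIN_SAMPLES,
    min_events: int = MIN_EVENTS,
    with_km: bool = False,
) -> PrognosisResult:
    """Univariate Cox PH with one event's SPL as the single covariate."""
    df = _merged(spl, clinical)
    n, deaths = len(df), int(df["event"].sum())
    if n < min_samples or deaths < min_events:
        return PrognosisResult(
            event_id, np.nan, np.nan, "NS", n=n, n_deaths=deaths,
            flag="insufficient_data",
        )
    if df["x"].nunique() <= 1:
        return PrognosisResult(
            event_id, np.nan, np.nan, "NS", n=n, n_deaths=deaths,
            flag="constant_covariate",
        )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time_days", event_col="event")
    except (ConvergenceError, ValueError):
        return PrognosisResult(
            event_id, np.nan, np.nan, "NS", n=n, n_deaths=deaths,
            flag="non_convergence",
        )
    hr = float(np.exp(cph.params_["x"]))
    p = float(cph.summary.loc["x", "p"])
    ci_low = float(np.exp(cph.confidence_intervals_.iloc[0, 0]))
    ci_high = float(np.exp(cph.confidence_intervals_.iloc[0, 1]))
    km_p = np.nan
    if with_km:
        km_p = km_half_split(spl, clinical).km_p
    return PrognosisResult(
        event_id, hr, p, _label(hr, p), km_p=km_p,
        ci_low=ci_low, ci_high=ci_high, n=n, n_deaths=deaths,
    )


@dataclass
class KmResult:
    km_p: float
    n_low: int
    n_high: int
    curves: dict = field(default_factory=dict)


def km_half_split(spl: pd.Series, clinical: pd.DataFrame) -> KmResult:
    """Log-rank test between the top and bottom halves ranked by SPL.

    Samples with SPL <= median go to the low group, so ties (and the middle
    sample at odd n) fall to the low side.
    """
    df = _merged(spl, clinical)
    if df.empty:
        raise ValueError("no overlapping samples with SPL and clinical data")
    med = df["x"].median()
    low = df[df["x"] <= med]
    high = df[df["x"] > med]
    if low.empty or high.empty:
        raise ValueError("degenerate half-split: one group is empty")
    res = logrank_test(
        low["time_days"], high["time_days"],
        event_observed_A=low["event"], event_observed_B=high["event"],
    )
    curves = {}
    for name, grp in (("low", low), ("high", high)):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time_days"], grp["event"], label=name)
        curves[name] = kmf.survival_function_
    return KmResult(
        km_p=float(res.p_value), n_low=len(low), n_high=len(high), curves=curves
    )


def group_survival(
    flagged: pd.Series, clinical: pd.DataFrame, event_id: str = ""
) -> PrognosisResult:
    """Binary-covariate Cox + log-rank: flagged versus unflagged samples
    (e.g. tumours with over-spliced 3' UTR versus the rest)."""
    cov = flagged.astype(float)
    if cov.nunique() <= 1:
        raise ValueError("grouping must contain both flagged and unflagged samples")
    df = _merged(cov, clinical)
    if df["x"].nunique() <= 1:
        raise ValueError("grouping degenerate after joining clinical data")
    res = cox_per_event(cov, clinical, event_id=event_id)
    a = df[df["x"] == 1]
    b = df[df["x"] == 0]
    lr = logrank_test(
        a["time_days"], b["time_days"],
        event_observed_A=a["event"], event_observed_B=b["event"],
    )
    res.km_p = float(lr.p_value)
    return res


def burden_survival(burden: pd.Series, clinical: pd.DataFrame) -> PrognosisResult:
    """Cox PH with the per-sample 3USP burden (count or normalized
    fraction) as the covariate."""
    return cox_per_event(burden, clinical, event_id="burden", with_km=True)


def prognosis_table(
    matrix_spl: pd.DataFrame, clinical: pd.DataFrame, event_ids=None
) -> pd.DataFrame:
    """Cox prognosis for each event across tumour samples, with a BH
    column over the tested events for transparency (labels use raw p)."""
    if event_ids is None:
        event_ids = list(matrix_spl.index)
    rows = []
    for event_id in event_ids:
        r = cox_per_event(matrix_spl.loc[event_id], clinical, event_id=event_id)
        rows.append(vars(r))
    df = pd.DataFrame(rows).set_index("event_id")
    tested = df["p_value"].notna()
    df["fdr"] = np.nan
    if tested.any():
        from .diffstats import bh_adjust

        df.loc[tested, "fdr"] = bh_adjust(df.loc[tested, "p_value"])
    return df
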