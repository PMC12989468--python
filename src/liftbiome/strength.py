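"""Strength and training metrics from session logs and fitness tests.

Three headline metrics summarize an individual's response to the program:

* maximum leg-press strength (kg) at each fitness test,
* average strength gain: the mean over machines of
  log2(S_followup / S_baseline), reported also as a percent via 2^x - 1,
* an age-equivalent of muscular fitness ("BioAge") from an exponential
  age-strength reference curve, floored at 21 years.

Compliance is the percent of targeted repetitions actually performed across
all logged sessions; training days counts distinct calendar dates with at
least one session.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import MACHINES, BioAgeParams, TIMEPOINTS


class MissingDataError(ValueError):
    """A required record (machine, timepoint) is absent."""


# ---------------------------------------------------------------------------
# core metric formulas


def average_strength_gain(
    baseline: Mapping[str, float], followup: Mapping[str, float]
) -> tuple[float, float]:
    """Average log2 fold change of maximum strength across machines.

    Returns ``(avg_log2fc, percent_gain)`` where the percent gain is derived
    from the mean log2 fold change as (2**avg_log2fc - 1) * 100 (not the
    mean of per-machine percent changes).
    """
    base_machines = set(baseline)
    follow_machines = set(followup)
    if base_machines != follow_machines:
        missing = base_machines.symmetric_difference(follow_machines)
        raise MissingDataError(
            f"machine sets differ between timepoints: {sorted(missing)}"
        )
    if not baseline:
        raise MissingDataError("empty machine set")
    ratios = []
    for machine in sorted(baseline):
        s0, s1 = baseline[machine], followup[machine]
        if s0 <= 0 or s1 <= 0:
            raise ValueError(f"nonpositive strength for machine {machine!r}")
        ratios.append(math.log2(s1 / s0))
    avg = float(np.mean(ratios))
    return avg, (2.0**avg - 1.0) * 100.0


def legpress_max(
    assessments: pd.DataFrame, timepoint: str, machine: str = "Leg press"
) -> float:
    """Maximum leg-press strength (kg) at one fitness-test timepoint."""
    rows = assessments[
        (assessments["machine"] == machine)
        & (assessments["timepoint"] == timepoint)
    ]
    if rows.empty:
        raise MissingDataError(f"no {machine!r} record at {timepoint}")
    return float(rows["max_strength"].max())


def bioage_strength(
    relative_strength: Mapping[str, float],
    age: float,
    sex: str,
    params: Optional[BioAgeParams] = None,
) -> float:
    """Age-equivalent of muscular fitness from relative strength per machine.

    For every machine the exponential reference curve is inverted
    analytically: the returned age is the age at which the sex- and
    machine-specific reference equals the observed strength/body-weight
    ratio.  Machine values are averaged first, then the result is clamped to
    ``params.floor`` (strength far above any reference value maps to the
    floor).  ``age`` is the chronological age, used only as documentation of
    the fixed point (observed strength on the curve at ``age`` returns
    ``age``).
    """
    params = params or BioAgeParams()
    params.validate()
    if not relative_strength:
        raise MissingDataError("empty machine set")
    ages = []
    for machine, strength in relative_strength.items():
        if strength <= 0:
            raise ValueError(f"nonpositive relative strength for {machine!r}")
        peak = (
            params.peak_relative_strength
            * params.sex_factor[sex]
            * params.machine_factor[machine]
        )
        ages.append(
            params.peak_age - math.log(strength / peak) / params.decline_rate
        )
    return max(float(np.mean(ages)), params.floor)


def compliance(sessions: pd.DataFrame) -> float:
    """Percent of targeted repetitions actually performed, over all sessions.

    Over-performance above 100% is reported as-is, not clamped.
    """
    if sessions.empty:
        raise ValueError("empty session log: compliance undefined")
    target = float(sessions["reps_target"].sum())
    if target <= 0:
        raise ValueError("zero targeted repetitions: compliance undefined")
    return 100.0 * float(sessions["reps_done"].sum()) / target


def training_days(sessions: pd.DataFrame) -> int:
    """Number of distinct calendar dates with at least one session."""
    if sessions.empty:
        return 0
    return int(sessions["date"].nunique())


# ---------------------------------------------------------------------------
# per-timepoint assessment strength


def assessment_strength(
    fitness: pd.DataFrame,
    sessions: pd.DataFrame,
    participant: str,
    timepoint: str,
    window_days: int = 3,
) -> dict[str, float]:
    """Per-machine maximum strength at a fitness-test timepoint.

    The fitness-test value is used when present; otherwise the maximum
    session ``max_strength`` within +/- ``window_days`` of the test date is
    substituted.
    """
    out: dict[str, float] = {}
    fit = fitness[
        (fitness["participant"] == participant)
        & (fitness["timepoint"] == timepoint)
    ]
    for _, row in fit.iterrows():
        out[row["machine"]] = float(row["max_strength"])
    missing = [m for m in MACHINES if m not in out]
    if missing and not fit.empty and "date" in fit.columns and not sessions.empty:
        test_date = pd.to_datetime(fit["date"].iloc[0])
        sess = sessions[sessions["participant"] == participant].copy()
        sess["date"] = pd.to_datetime(sess["date"])
        window = sess[(sess["date"] - test_date).abs().dt.days <= window_days]
        for machine in missing:
            rows = window[window["machine"] == machine]
            if not rows.empty:
                out[machine] = float(rows["max_strength"].max())
    return out


def strength_metrics_table(
    sessions: pd.DataFrame,
    fitness: pd.DataFrame,
    bioage_params: Optional[BioAgeParams] = None,
) -> pd.DataFrame:
    """Per-participant summary of all strength and training metrics.

    Only participants with complete W0 and W8 fitness tests (the analyzed
    cohort) receive gain metrics; rows are sorted by participant id.
    Expects ``fitness`` to carry ``body_weight``, ``age`` and ``sex``
    columns alongside the per-machine maxima.
    """
    bioage_params = bioage_params or BioAgeParams()
    records = []
    for participant, fit in fitness.groupby("participant"):
        sess = sessions[sessions["participant"] == participant]
        row: dict[str, object] = {"participant": participant}
        per_tp: dict[str, dict[str, float]] = {}
        for tp in TIMEPOINTS:
            strengths = assessment_strength(fitness, sessions, participant, tp)
            if strengths:
                per_tp[tp] = strengths
                try:
                    row[f"legpress_{tp}"] = legpress_max(
                        fit, tp
                    )
                except MissingDataError:
                    row[f"legpress_{tp}"] = np.nan
                info = fit[fit["timepoint"] == tp].iloc[0]
                rel = {
                    m: s / float(info["body_weight"])
                    for m, s in strengths.items()
                }
                row[f"bioage_{tp}"] = bioage_strength(
                    rel, float(info["age"]), str(info["sex"]), bioage_params
                )
            else:
                row[f"legpress_{tp}"] = np.nan
                row[f"bioage_{tp}"] = np.nan
        for follow in ("W4", "W8"):
            key = f"avg_log2fc_W0{follow}"
            if "W0" in per_tp and follow in per_tp:
                lfc, pct = average_strength_gain(per_tp["W0"], per_tp[follow])
                row[key] = lfc
                if follow == "W8":
                    row["percent_gain"] = pct
            else:
                row[key] = np.nan
        row.setdefault("percent_gain", np.nan)
        if not sess.empty and sess["reps_target"].sum() > 0:
            row["compliance"] = compliance(sess)
        else:
            row["compliance"] = np.nan
        row["training_days"] = training_days(sess)
        records.append(row)
    table = pd.DataFrame.from_records(records).sort_values("participant")
    return table.reset_index(drop=True)
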