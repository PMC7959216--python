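"""Exercise-capacity outcomes and the composite clinical endpoint.

Cardiopulmonary exercise testing (CPET) yields peak oxygen uptake (mean VO2
over the final 30 s of testing, reported only at maximal effort, defined as
a respiratory exchange ratio RER >= 1.05) and the ventilatory-efficiency
VE/VCO2 slope over the submaximal range.  Follow-up records are reduced to a
composite endpoint — death, listing for heart transplant, arrhythmia
requiring medication or intervention, and surgical or catheter
reintervention — with the study visit as day 0 and time-to-first-event or
censoring at last follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CpetResult",
    "CompositeOutcome",
    "QUALIFYING_CATEGORIES",
    "process_cpet",
    "build_composite",
]

RER_MAXIMAL_THRESHOLD = 1.05

QUALIFYING_CATEGORIES = frozenset(
    {
        "death",
        "transplant_listing",
        "arrhythmia",
        "reintervention_surgical",
        "reintervention_catheter",
    }
)


@dataclass(frozen=True)
class CpetResult:
    """Summary of one CPET: peak VO2 is withheld (NaN) below maximal effort."""

    peak_vo2: float
    rer_max: float
    maximal_effort: bool
    ve_vco2_slope: float
    pct_predicted: float = float("nan")
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CompositeOutcome:
    event: bool
    time_days: float
    first_category: str | None = None


def process_cpet(
    series: pd.DataFrame,
    predicted_peak_vo2: float | None = None,
    rer_threshold: float = RER_MAXIMAL_THRESHOLD,
    submax_rer: float = 1.0,
) -> CpetResult:
    """Reduce a breath series (time_s, vo2, vco2, ve) to a CPET result.

    peak VO2 = mean VO2 over the final 30 s; RER = VCO2/VO2 with the maximal
    effort gate at ``rer_threshold``; the VE/VCO2 slope is a least-squares
    fit restricted to samples before RER first exceeds ``submax_rer``.
    """
    t = series["time_s"].to_numpy(dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("series must have strictly increasing times")
    span = t[-1] - t[0]
    if span < 60.0:
        raise ValueError("series must span at least 60 s")
    vo2 = series["vo2"].to_numpy(dtype=float)
    vco2 = series["vco2"].to_numpy(dtype=float)
    ve = series["ve"].to_numpy(dtype=float)

    final = t >= t[-1] - 30.0
    if final.sum() < 2:
        raise ValueError("fewer than 30 s of samples at the end of testing")
    peak = float(vo2[final].mean())

    with np.errstate(divide="ignore", invalid="ignore"):
        rer = np.where(vo2 > 0, vco2 / vo2, np.nan)
    rer_max = float(np.nanmax(rer))
    maximal = rer_max >= rer_threshold

    flags: list[str] = []
    above = np.nonzero(rer > submax_rer)[0]
    submax = slice(0, above[0]) if above.size else slice(None)
    if t[submax].size >= 3:
        slope = float(np.polyfit(vco2[submax], ve[submax], 1)[0])
    else:
        slope = float("nan")
        flags.append("ve_slope_insufficient_submaximal_samples")

    if not maximal:
        flags.append("submaximal_effort_peak_vo2_withheld")
    pct = float("nan")
    if maximal and predicted_peak_vo2 is not None and predicted_peak_vo2 > 0:
        pct = 100.0 * peak / predicted_peak_vo2
    return CpetResult(
        peak_vo2=peak if maximal else float("nan"),
        rer_max=rer_max,
        maximal_effort=bool(maximal),
        ve_vco2_slope=slope,
        pct_predicted=pct,
        flags=tuple(flags),
    )


def build_composite(
    records: pd.DataFrame | None, follow_up_days: float
) -> CompositeOutcome:
    """Composite endpoint from follow-up records of one patient.

    ``records`` has columns offset_days, category, qualifying; day 0 is the
    study visit.  The event time is the first qualifying event's offset;
    arrhythmia episodes not requiring medication or intervention are excluded
    through the per-record qualifier flag.  Without a qualifying event the
    patient is censored at ``follow_up_days``.
    """
    if follow_up_days < 0:
        raise ValueError("follow-up time must be >= 0")
    if records is None or len(records) == 0:
        return CompositeOutcome(event=False, time_days=float(follow_up_days))
    offsets = records["offset_days"].to_numpy(dtype=float)
    if np.any(offsets < 0):
        raise ValueError("event offsets must be >= 0 (day 0 is the study visit)")
    qualifying = records["qualifying"].to_numpy(dtype=int).astype(bool)
    known = records["category"].isin(QUALIFYING_CATEGORIES).to_numpy()
    mask = qualifying & known
    if not mask.any():
        return CompositeOutcome(event=False, time_days=float(follow_up_days))
    idx = int(np.argmin(np.where(mask, offsets, np.inf)))
    return CompositeOutcome(
        event=True,
        time_days=float(offsets[idx]),
        first_category=str(records["category"].iloc[idx]),
    )
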