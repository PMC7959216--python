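"""Cohort-level report tables.

Reduces a cohort table (per-patient rest/stress/reserve features joined to
exercise outcomes and follow-up events) to three result tables:

* ``stress_response`` — median (IQR) at rest, under stress, and of the
  reserve per functional parameter, with a paired Wilcoxon p;
* ``exercise_correlations`` — Spearman rho of every reserve parameter
  against peak VO2 (maximal-effort subjects only) and against the VE/VCO2
  slope (all subjects);
* ``event_predictors`` — univariable Cox hazard ratio of the composite
  endpoint per reserve parameter.

All p-values are Benjamini-Hochberg adjusted; the family partition is
configurable (per table, per outcome within the correlation table, or with
the outcome-related tables pooled into one family).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import FEATURE_KEYS, feature_def
from .stats import bh_adjust, cox_ph, paired_wilcoxon, spearman

__all__ = ["summarize_cohort", "render_markdown"]


def _median_iqr(v: np.ndarray) -> str:
    v = v[np.isfinite(v)]
    if v.size == 0:
        return ""
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    return f"{q2:.1f} ({q1:.1f}-{q3:.1f})"


def _stress_response(cohort: pd.DataFrame, features) -> pd.DataFrame:
    rows = []
    for key in features:
        fd = feature_def(key)
        rest = cohort[f"{key}_rest"].to_numpy(dtype=float)
        stress = cohort[f"{key}_stress"].to_numpy(dtype=float)
        res = paired_wilcoxon(stress, rest, name=key)
        reserve = stress - rest
        rows.append(
            {
                "parameter": fd.label,
                "key": key,
                "unit": fd.unit,
                "rest": _median_iqr(rest),
                "stress": _median_iqr(stress),
                "reserve": _median_iqr(reserve[np.isfinite(reserve)]),
                "reserve_median": res.estimate,
                "n": res.n,
                "p_raw": res.p_raw,
                "flags": ";".join(res.flags),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def _exercise_correlations(cohort: pd.DataFrame, features) -> pd.DataFrame:
    maximal = cohort["maximal_effort"].astype(bool) if "maximal_effort" in cohort else None
    rows = []
    for key in features:
        fd = feature_def(key)
        reserve = cohort[f"{key}_reserve"]
        for outcome, restrict in (("peak_vo2", True), ("ve_vco2_slope", False)):
            if outcome not in cohort:
                continue
            sub = cohort
            if restrict and maximal is not None:
                sub = cohort[maximal]
            res = spearman(
                sub[f"{key}_reserve"], sub[outcome], name=f"{key}~{outcome}"
            )
            rows.append(
                {
                    "parameter": f"{fd.label} reserve",
                    "key": key,
                    "outcome": outcome,
                    "rho": res.estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n": res.n,
                    "p_raw": res.p_raw,
                    "flags": ";".join(res.flags),
                }
            )
    return pd.DataFrame(rows)


def _event_predictors(cohort: pd.DataFrame, features) -> pd.DataFrame:
    rows = []
    for key in features:
        fd = feature_def(key)
        try:
            res = cox_ph(
                cohort[f"{key}_reserve"],
                cohort["time_days"],
                cohort["event"],
                name=key,
            )
            rows.append(
                {
                    "parameter": f"{fd.label} reserve",
                    "key": key,
                    "hr": res.estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n": res.n,
                    "p_raw": res.p_raw,
                    "flags": ";".join(res.flags),
                }
            )
        except ValueError as err:
            rows.append(
                {
                    "parameter": f"{fd.label} reserve",
                    "key": key,
                    "hr": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "n": len(cohort),
                    "p_raw": np.nan,
                    "flags": f"error:{err}",
                }
            )
    return pd.DataFrame(rows)


def summarize_cohort(
    cohort: pd.DataFrame,
    features: tuple[str, ...] = FEATURE_KEYS,
    bh_scope: str = "per_outcome",
    by: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Compute the three report tables from a cohort table.

    ``bh_scope`` controls the multiple-testing families for the
    outcome-related tables: ``"per_outcome"`` adjusts the correlation table
    separately per outcome plus the Cox table as its own family;
    ``"per_table"`` adjusts each table as one family; ``"pooled"`` pools the
    correlation and Cox tables into a single family.  The stress-response
    table is always its own family.  ``by`` optionally stratifies every
    table by a covariate column (empty strata are omitted).
    """
    if by is not None:
        out: dict[str, pd.DataFrame] = {}
        for stratum, sub in cohort.groupby(by):
            if len(sub) < 5:
                continue
            tables = summarize_cohort(sub, features=features, bh_scope=bh_scope)
            for name, tbl in tables.items():
                tbl = tbl.copy()
                tbl.insert(0, by, stratum)
                out[name] = pd.concat([out.get(name), tbl], ignore_index=True)
        return out

    t3 = _stress_response(cohort, features)
    has_outcomes = "peak_vo2" in cohort or "ve_vco2_slope" in cohort
    has_events = "event" in cohort and "time_days" in cohort
    tables = {"stress_response": t3}
    t4 = _exercise_correlations(cohort, features) if has_outcomes else pd.DataFrame()
    t5 = _event_predictors(cohort, features) if has_events else pd.DataFrame()

    if bh_scope not in ("per_outcome", "per_table", "pooled"):
        raise ValueError("bh_scope must be per_outcome, per_table or pooled")
    if len(t4) or len(t5):
        if bh_scope == "pooled":
            fam4 = np.zeros(len(t4), dtype=int)
            fam5 = np.zeros(len(t5), dtype=int)
        elif bh_scope == "per_table":
            fam4 = np.zeros(len(t4), dtype=int)
            fam5 = np.ones(len(t5), dtype=int)
        else:
            fam4 = (
                pd.factorize(t4["outcome"])[0] if len(t4) else np.array([], dtype=int)
            )
            fam5 = np.full(len(t5), fam4.max() + 1 if len(t4) else 0, dtype=int)
        p_all = np.concatenate(
            [
                t4["p_raw"].to_numpy(dtype=float) if len(t4) else np.array([]),
                t5["p_raw"].to_numpy(dtype=float) if len(t5) else np.array([]),
            ]
        )
        fams = np.concatenate([fam4, fam5])
        adj = bh_adjust(p_all, fams)
        if len(t4):
            t4["p_adjusted"] = adj[: len(t4)]
            tables["exercise_correlations"] = t4
        if len(t5):
            t5["p_adjusted"] = adj[len(t4):]
            tables["event_predictors"] = t5
    return tables


def render_markdown(tables: dict[str, pd.DataFrame], digits: int = 3) -> str:
    """Plain-markdown rendering of the report tables."""
    parts = []
    titles = {
        "stress_response": "Functional parameters during rest and stress",
        "exercise_correlations": "Reserve parameters vs exercise capacity",
        "event_predictors": "Reserve parameters as predictors of events",
    }
    for name, tbl in tables.items():
        parts.append(f"## {titles.get(name, name)}\n")
        show = tbl.copy()
        for col in show.columns:
            if show[col].dtype.kind == "f":
                show[col] = show[col].round(digits)
        parts.append(show.to_markdown(index=False))
        parts.append("")
    return "\n".join(parts)
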