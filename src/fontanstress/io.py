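"""CSV plumbing for curves, features, patients and events.

Curves travel as one long CSV (patient_id, chamber, condition, time_ms,
volume_ml, heart_rate); features as a long CSV (patient_id, condition,
feature, value, units, flags) where condition includes the derived
``reserve`` rows.  Missing values are empty cells, never sentinel numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .curves import VolumeTimeCurve
from .schema import feature_def

__all__ = [
    "read_curves",
    "write_curves",
    "frame_to_curves",
    "read_features",
    "write_features",
    "features_to_wide",
]

CURVE_COLUMNS = ["patient_id", "chamber", "condition", "time_ms", "volume_ml", "heart_rate"]
FEATURE_COLUMNS = ["patient_id", "condition", "feature", "value", "units", "flags"]


def write_curves(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, columns=[c for c in CURVE_COLUMNS if c in frame])


def read_curves(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"patient_id", "chamber", "condition", "time_ms", "volume_ml"} - set(frame)
    if missing:
        raise ValueError(f"curve file lacks columns: {sorted(missing)}")
    return frame


def frame_to_curves(frame: pd.DataFrame) -> dict:
    """Group a long curve table into VolumeTimeCurve objects.

    Returns ``{patient_id: {(chamber, condition): VolumeTimeCurve}}``.  The
    heart rate column is used when present; otherwise it is inferred from
    the cycle duration.
    """
    out: dict[str, dict] = {}
    for (pid, chamber, condition), g in frame.groupby(
        ["patient_id", "chamber", "condition"], sort=True
    ):
        g = g.sort_values("time_ms")
        t = g["time_ms"].to_numpy(dtype=float)
        v = g["volume_ml"].to_numpy(dtype=float)
        cycle = float(t[-1] + np.median(np.diff(t)))
        if "heart_rate" in g:
            hr = float(g["heart_rate"].iloc[0])
        else:
            hr = 60000.0 / cycle
        out.setdefault(str(pid), {})[(chamber, condition)] = VolumeTimeCurve(
            times=t, volumes=v, chamber=chamber, condition=condition,
            heart_rate=hr, cycle_ms=cycle,
        )
    return out


def feature_rows(
    patient_id: str, condition: str, values: dict[str, float], flags: str = ""
) -> list[dict]:
    rows = []
    for key, val in values.items():
        unit = feature_def(key).unit
        rows.append(
            {
                "patient_id": patient_id,
                "condition": condition,
                "feature": key,
                "value": val if np.isfinite(val) else np.nan,
                "units": unit,
                "flags": flags,
            }
        )
    return rows


def write_features(rows: list[dict] | pd.DataFrame, path: str | Path) -> None:
    frame = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    frame.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS[:4]) - set(frame)
    if missing:
        raise ValueError(f"feature file lacks columns: {sorted(missing)}")
    return frame


def features_to_wide(features: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long feature table to one row per patient.

    Columns are ``{feature}_{condition}`` for rest/stress/reserve.
    """
    wide = features.pivot_table(
        index="patient_id", columns=["feature", "condition"], values="value",
        aggfunc="first",
    )
    wide.columns = [f"{feat}_{cond}" for feat, cond in wide.columns]
    return wide.reset_index()
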