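"""Canonical feature naming shared by the generator, extractor and reports.

Every functional parameter has a short key used for table columns and CSV
files, the attribute name it is read from on feature/ground-truth objects,
a human-readable label, a unit, and whether it is a volume (volumes are
indexed to body surface area, mL -> mL/m^2; rates, times and ratios are not).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable


@dataclass(frozen=True)
class FeatureDef:
    key: str
    attr: str
    label: str
    unit: str
    volume: bool


FEATURES: tuple[FeatureDef, ...] = (
    FeatureDef("hr", "heart_rate", "Heart rate", "/min", False),
    FeatureDef("edv", "edv", "End-diastolic volume", "mL/m2", True),
    FeatureDef("esv", "esv", "End-systolic volume", "mL/m2", True),
    FeatureDef("sv", "sv", "Stroke volume", "mL/m2", True),
    FeatureDef("ef", "ef", "Ejection fraction", "%", False),
    FeatureDef(
        "early_filling", "early_filling_volume", "Early filling volume", "mL/m2", True
    ),
    FeatureDef(
        "late_filling", "late_filling_volume", "Late (atrial) filling volume", "mL/m2", True
    ),
    FeatureDef(
        "early_pfr", "early_peak_filling_rate", "Early peak filling rate", "mL/s", False
    ),
    FeatureDef(
        "late_pfr", "late_peak_filling_rate", "Late peak filling rate", "mL/s", False
    ),
    FeatureDef("e_a_ratio", "e_a_ratio", "E/A ratio", "", False),
    FeatureDef("deceleration_time", "deceleration_time", "Deceleration time", "ms", False),
    FeatureDef("a_max", "v_max", "Atrial maximal volume", "mL/m2", True),
    FeatureDef("a_min", "v_min", "Atrial minimal volume", "mL/m2", True),
    FeatureDef("a_cyclic", "cyclic_volume_change", "Atrial cyclic volume change", "mL/m2", True),
    FeatureDef(
        "a_early_empty", "early_emptying_volume", "Atrial early emptying volume", "mL/m2", True
    ),
    FeatureDef(
        "a_late_empty", "late_emptying_volume", "Atrial late emptying volume", "mL/m2", True
    ),
    FeatureDef("a_conduit", "conduit_volume", "Atrial conduit volume", "mL/m2", True),
)

FEATURE_KEYS: tuple[str, ...] = tuple(f.key for f in FEATURES)
VOLUME_KEYS: frozenset[str] = frozenset(f.key for f in FEATURES if f.volume)
_BY_KEY = {f.key: f for f in FEATURES}


def feature_def(key: str) -> FeatureDef:
    return _BY_KEY[key]


def feature_row(
    sources: Iterable[object], bsa: float | None = None, heart_rate: float | None = None
) -> dict[str, float]:
    """Collect canonical feature values from one or more feature objects.

    ``sources`` are objects carrying the registry's attribute names (e.g. a
    VentricularFeatures and an AtrialFeatures, or a GroundTruth).  When
    ``bsa`` is given, volume features are indexed (divided by BSA).
    """
    row: dict[str, float] = {}
    for f in FEATURES:
        for src in sources:
            if hasattr(src, f.attr):
                val = float(getattr(src, f.attr))
                if f.volume and bsa is not None:
                    val = val / bsa
                row[f.key] = val
                break
    if heart_rate is not None:
        row["hr"] = float(heart_rate)
    return row
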