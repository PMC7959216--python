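"""Synthetic paired rest/stress cohorts with known ground truth.

The generative model of one cardiac cycle is a closed-loop, no-regurgitation
two-chamber system.  All flows are raised-cosine (Hann) lobes, so every
derived functional parameter has a closed form or a trivial quadrature:

* systolic ejection: one Hann lobe over systole with integral EDV - ESV;
* ventricular inflow: an early (E) and a late, atrial-contraction (A) Hann
  lobe inside diastole whose integrals are the early and late fill volumes
  and which sum to the stroke volume (total filling balances ejection);
* pulmonary venous return into the atrium is constant over the cycle and
  closes the loop (venous return x cycle duration = stroke volume);
* atrial volume is the running integral of venous return minus
  atrioventricular flow, where AV flow equals ventricular inflow during
  diastole and is zero during systole.

Cohorts draw per-patient resting parameters from median/IQR specs and build
the dobutamine-stress cycle as rest plus configured reserve shifts; shifts on
emergent quantities (measured early filling volume, atrial cyclic volume
change) are realised by inverting the cycle geometry (E-lobe timing, systole
fraction) with a root finder.  Exercise outcomes get a configurable Spearman
correlation to a named reserve parameter through a Gaussian copula, and
events are exponential with a configurable (optionally covariate-dependent)
hazard.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, rankdata

from .curves import VolumeTimeCurve
from .outcomes import build_composite
from .schema import FEATURE_KEYS, feature_row

__all__ = [
    "CyclePhysioParams",
    "GroundTruth",
    "ParamSpec",
    "OutcomeConfig",
    "EventConfig",
    "CohortConfig",
    "SyntheticPatient",
    "SyntheticStudy",
    "ground_truth",
    "generate_cycle",
    "generate_cohort",
    "generate_cpet_series",
    "physiological_grid",
    "simulate_survival",
    "default_rest_distributions",
    "default_stress_shifts",
]

_TWO_PI = 2.0 * math.pi

EVENT_CATEGORIES = (
    "death",
    "transplant_listing",
    "arrhythmia",
    "reintervention_surgical",
    "reintervention_catheter",
)
_EVENT_CATEGORY_P = (0.07, 0.02, 0.45, 0.19, 0.27)


# ---------------------------------------------------------------------------
# Hann (raised-cosine) pulse primitives
# ---------------------------------------------------------------------------

def hann_rate(t, t0: float, width: float, volume: float):
    """Flow rate (mL per time unit) of a Hann lobe of given integral."""
    t = np.asarray(t, dtype=float)
    if volume == 0.0 or width <= 0.0:
        return np.zeros_like(t)
    x = (t - t0) / width
    inside = (x >= 0.0) & (x <= 1.0)
    r = np.zeros_like(t)
    xi = np.clip(x, 0.0, 1.0)
    r = np.where(inside, (volume / width) * (1.0 - np.cos(_TWO_PI * xi)), 0.0)
    return r


def hann_cdf(t, t0: float, width: float, volume: float):
    """Cumulative volume delivered by a Hann lobe up to time ``t``."""
    t = np.asarray(t, dtype=float)
    if volume == 0.0 or width <= 0.0:
        return np.zeros_like(t)
    x = np.clip((t - t0) / width, 0.0, 1.0)
    return volume * (x - np.sin(_TWO_PI * x) / _TWO_PI)


def _hann_mass_fraction(x) -> float:
    """Fraction of a unit Hann lobe's mass within [0, x] of its support."""
    x = float(np.clip(x, 0.0, 1.0))
    return x - math.sin(_TWO_PI * x) / _TWO_PI


# ---------------------------------------------------------------------------
# Single-cycle generative parameters and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CyclePhysioParams:
    """Generative parameters of one paired ventricular/atrial cycle.

    Volumes in mL, fractions of the diastole duration for the pulse windows,
    venous return in mL/s, heart rate in bpm.  ``a_min_volume`` anchors the
    absolute atrial volume level (the flows only determine it up to an
    offset).
    """

    edv: float
    esv: float
    e_fill_volume: float
    a_fill_volume: float
    systole_fraction: float
    e_peak_time_frac: float
    e_width_frac: float
    a_onset_frac: float
    a_width_frac: float
    venous_return_rate: float
    heart_rate: float
    a_min_volume: float = 30.0

    @property
    def cycle_ms(self) -> float:
        return 60000.0 / self.heart_rate

    @property
    def stroke_volume(self) -> float:
        return self.edv - self.esv

    @classmethod
    def closed_loop(cls, **kwargs) -> "CyclePhysioParams":
        """Build params with the venous return rate set by mass balance."""
        hr = kwargs["heart_rate"]
        sv = kwargs["edv"] - kwargs["esv"]
        kwargs.setdefault("venous_return_rate", sv * hr / 60.0)
        return cls(**kwargs)

    def validate(self) -> None:
        sv = self.stroke_volume
        if not (self.edv > self.esv > 0):
            raise ValueError("invariant violated: edv > esv > 0")
        if self.e_fill_volume < 0 or self.a_fill_volume < 0:
            raise ValueError("invariant violated: fill volumes must be >= 0")
        if abs(self.e_fill_volume + self.a_fill_volume - sv) > 1e-6 * max(sv, 1.0):
            raise ValueError(
                "invariant violated: e_fill_volume + a_fill_volume must equal "
                "edv - esv (diastolic filling balances stroke volume)"
            )
        if not (0.0 < self.systole_fraction < 1.0):
            raise ValueError("invariant violated: systole_fraction in (0, 1)")
        if self.heart_rate <= 0:
            raise ValueError("invariant violated: heart_rate > 0")
        if self.a_min_volume <= 0:
            raise ValueError("invariant violated: a_min_volume > 0")
        if self.e_width_frac <= 0 or not (0.0 < self.e_peak_time_frac < 1.0):
            raise ValueError("invariant violated: E pulse window must lie in diastole")
        e_start = self.e_peak_time_frac - self.e_width_frac / 2.0
        e_end = self.e_peak_time_frac + self.e_width_frac / 2.0
        if e_start < -1e-9 or e_end > 1.0 + 1e-9:
            raise ValueError("invariant violated: E pulse window must lie in diastole")
        if self.a_fill_volume > 0:
            if self.a_width_frac <= 0 or self.a_onset_frac < 0:
                raise ValueError("invariant violated: A pulse window must lie in diastole")
            if self.a_onset_frac + self.a_width_frac > 1.0 + 1e-9:
                raise ValueError("invariant violated: A pulse window must lie in diastole")
            if self.a_onset_frac < e_end - 1e-9:
                raise ValueError(
                    "invariant violated: a_onset_frac >= e_peak_time_frac + "
                    "e_width_frac/2 (E and A windows must not overlap)"
                )
        expected_vr = sv * self.heart_rate / 60.0
        if abs(self.venous_return_rate - expected_vr) > 1e-6 * max(expected_vr, 1.0):
            raise ValueError(
                "invariant violated: venous_return_rate x cycle duration must "
                "equal the stroke volume (closed-loop mass balance)"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Noiseless implied value of every functional parameter of one cycle.

    Values are *operational*: timing anchors are located on the analytic
    generative flows with the same definitions the extractor applies, so the
    extractor can be validated against them directly.  Volumes in mL (not
    BSA-indexed), rates in mL/s, times in ms.
    """

    heart_rate: float
    edv: float
    esv: float
    sv: float
    ef: float
    early_filling_volume: float
    late_filling_volume: float
    early_peak_filling_rate: float
    late_peak_filling_rate: float
    e_a_ratio: float
    deceleration_time: float
    v_max: float
    v_min: float
    cyclic_volume_change: float
    early_emptying_volume: float
    late_emptying_volume: float
    conduit_volume: float
    t_ed: float
    t_es: float
    t_a_onset: float
    fusion: bool


def _fit_dt_from_cosine_limb(
    peak_rate: float, t_peak: float, width_ms: float, band=(0.7, 0.3)
) -> float:
    """DT from the closed-form descending cosine limb restricted to the band."""
    hi, lo = band
    tau_hi = width_ms * math.acos(2.0 * hi - 1.0) / _TWO_PI
    tau_lo = width_ms * math.acos(2.0 * lo - 1.0) / _TWO_PI
    tau = np.linspace(tau_hi, tau_lo, 512)
    r = peak_rate * 0.5 * (1.0 + np.cos(_TWO_PI * tau / width_ms))
    slope, intercept = np.polyfit(t_peak + tau, r, 1)
    return float(-intercept / slope - t_peak)


def _ground_truth_impl(params: CyclePhysioParams):
    p = params
    T = p.cycle_ms
    ts = p.systole_fraction * T
    D = T - ts
    sv = p.stroke_volume
    vr = p.venous_return_rate / 1000.0  # mL/ms

    te0 = ts + (p.e_peak_time_frac - p.e_width_frac / 2.0) * D
    wE = p.e_width_frac * D
    ta0 = ts + p.a_onset_frac * D
    wA = p.a_width_frac * D
    qe, qa = p.e_fill_volume, p.a_fill_volume

    def inflow_cdf(t):
        return hann_cdf(t, te0, wE, qe) + hann_cdf(t, ta0, wA, qa)

    def inflow_rate(t):
        return hann_rate(t, te0, wE, qe) + hann_rate(t, ta0, wA, qa)

    epk_ms = 2.0 * qe / wE if qe > 0 and wE > 0 else 0.0
    apk_ms = 2.0 * qa / wA if qa > 0 and wA > 0 else 0.0
    fusion = qa <= 1e-12 * max(sv, 1.0) or apk_ms <= vr * (1.0 + 1e-9)

    early_filling = float(inflow_cdf(ts + D / 3.0))
    if fusion:
        t_on = float("nan")
        late_filling = 0.0
    else:
        t_on = brentq(
            lambda t: hann_rate(t, ta0, wA, qa) - vr, ta0 + 1e-9, ta0 + wA / 2.0
        )
        late_filling = sv - float(inflow_cdf(t_on))

    epk = epk_ms * 1000.0
    apk = 0.0 if fusion else apk_ms * 1000.0
    e_a = epk / apk if apk > 0 else float("nan")

    if qe > 0:
        dt = _fit_dt_from_cosine_limb(epk, te0 + wE / 2.0, wE)
    else:
        dt = float("nan")

    # atrial curve: running integral of venous return minus AV flow
    def va_rel(t):
        t = np.asarray(t, dtype=float)
        return vr * t - inflow_cdf(t)

    dense = np.linspace(0.0, T, 4097)
    va_dense = va_rel(dense)
    candidates = []
    if epk_ms > vr:
        candidates.append(
            brentq(lambda t: hann_rate(t, te0, wE, qe) - vr, te0 + 1e-9, te0 + wE / 2.0)
        )
        candidates.append(
            brentq(lambda t: hann_rate(t, te0, wE, qe) - vr, te0 + wE / 2.0, te0 + wE - 1e-9)
        )
    if not fusion:
        candidates.append(t_on)
        candidates.append(
            brentq(lambda t: hann_rate(t, ta0, wA, qa) - vr, ta0 + wA / 2.0, ta0 + wA - 1e-9)
        )
    cand_vals = va_rel(np.asarray(candidates)) if candidates else np.array([])
    v_max_rel = float(max(va_dense.max(), cand_vals.max() if cand_vals.size else -np.inf))
    v_min_rel = float(min(va_dense.min(), cand_vals.min() if cand_vals.size else np.inf))
    offset = p.a_min_volume - v_min_rel
    v_max = v_max_rel + offset
    v_min = p.a_min_volume
    cyclic = v_max - v_min

    if fusion:
        early_empty = cyclic
        late_empty = 0.0
    else:
        span = np.linspace(ts, t_on, 2049)
        va_early_max = float(va_rel(span).max()) + offset
        va_on = float(va_rel(t_on)) + offset
        early_empty = max(0.0, va_early_max - va_on)
        late_empty = max(0.0, va_on - v_min)
    conduit = sv - (early_empty + late_empty)

    gt = GroundTruth(
        heart_rate=p.heart_rate,
        edv=p.edv,
        esv=p.esv,
        sv=sv,
        ef=100.0 * sv / p.edv,
        early_filling_volume=early_filling,
        late_filling_volume=late_filling,
        early_peak_filling_rate=epk,
        late_peak_filling_rate=apk,
        e_a_ratio=e_a,
        deceleration_time=dt,
        v_max=v_max,
        v_min=v_min,
        cyclic_volume_change=cyclic,
        early_emptying_volume=early_empty,
        late_emptying_volume=late_empty,
        conduit_volume=conduit,
        t_ed=0.0,
        t_es=ts,
        t_a_onset=float(t_on),
        fusion=bool(fusion),
    )
    aux = {
        "offset": offset,
        "ts": ts,
        "D": D,
        "inflow_cdf": inflow_cdf,
        "inflow_rate": inflow_rate,
        "vr": vr,
    }
    return gt, aux


def ground_truth(params: CyclePhysioParams) -> GroundTruth:
    """Noiseless implied functional parameters of a generative cycle."""
    params.validate()
    gt, _ = _ground_truth_impl(params)
    return gt


def generate_cycle(
    params: CyclePhysioParams,
    n_frames: int = 30,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    condition: str = "rest",
) -> tuple[VolumeTimeCurve, VolumeTimeCurve, GroundTruth]:
    """Sample one paired ventricular/atrial cycle at ``n_frames`` frames.

    Gaussian noise of SD ``noise_sd`` (mL) is added per sample when positive,
    mimicking segmentation error.  Returns the two curves plus the noiseless
    implied :class:`GroundTruth`.
    """
    params.validate()
    if n_frames < 16:
        raise ValueError("n_frames must be >= 16")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    gt, aux = _ground_truth_impl(params)
    T = params.cycle_ms
    ts = aux["ts"]
    tt = np.arange(n_frames) * (T / n_frames)
    vv = params.edv - hann_cdf(tt, 0.0, ts, params.stroke_volume) + aux["inflow_cdf"](tt)
    va = aux["offset"] + aux["vr"] * tt - aux["inflow_cdf"](tt)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        vv = vv + rng.normal(0.0, noise_sd, n_frames)
        va = va + rng.normal(0.0, noise_sd, n_frames)
    vcurve = VolumeTimeCurve(
        times=tt,
        volumes=np.maximum(vv, 0.01),
        chamber="ventricle",
        condition=condition,
        heart_rate=params.heart_rate,
        cycle_ms=T,
    )
    acurve = VolumeTimeCurve(
        times=tt,
        volumes=np.maximum(va, 0.01),
        chamber="atrium",
        condition=condition,
        heart_rate=params.heart_rate,
        cycle_ms=T,
    )
    return vcurve, acurve, gt


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamSpec:
    """Median / IQR spec of a per-patient parameter (normal draw)."""

    median: float
    iqr: tuple[float, float]

    @property
    def sd(self) -> float:
        return (self.iqr[1] - self.iqr[0]) / 1.34898

    def draw(self, rng: np.random.Generator, size: int):
        return rng.normal(self.median, self.sd, size)


def default_rest_distributions() -> dict[str, ParamSpec]:
    """Resting-parameter specs (volumes BSA-indexed, mL/m^2)."""
    return {
        "bsa": ParamSpec(1.34, (1.15, 1.59)),
        "heart_rate": ParamSpec(71.4, (62.1, 87.1)),
        "edv": ParamSpec(96.8, (80.0, 130.0)),
        "ef": ParamSpec(49.3, (42.5, 55.6)),
        "early_filling": ParamSpec(13.6, (8.8, 18.9)),
        "late_filling": ParamSpec(9.8, (7.6, 13.0)),
        "a_min": ParamSpec(25.6, (18.8, 32.8)),
        "systole_fraction": ParamSpec(0.37, (0.353, 0.387)),
    }


def default_stress_shifts() -> dict[str, ParamSpec]:
    """Stress-minus-rest shift specs (volumes BSA-indexed, mL/m^2).

    Medians are the reported reserve medians; the stroke-volume shift is
    centred at zero (the reported null finding), and the early/late filling
    spreads are narrower than their reported IQRs so that the configured
    median effects are reliably detectable at n=57 (see the methods note).
    """
    return {
        "heart_rate": ParamSpec(20.0, (6.0, 30.7)),
        "edv": ParamSpec(-7.5, (-15.5, -1.9)),
        "sv": ParamSpec(0.0, (-2.0, 2.0)),
        "early_filling": ParamSpec(-1.6, (-3.1, -0.1)),
        "late_filling": ParamSpec(1.0, (0.1, 1.9)),
        "a_cyclic": ParamSpec(3.0, (0.4, 5.9)),
        "a_min": ParamSpec(-2.8, (-8.5, 2.4)),
    }


@dataclass(frozen=True)
class OutcomeConfig:
    """Exercise-outcome generation.

    ``spearman_rho`` is the target rank correlation between the named reserve
    feature and peak VO2, realised through a Gaussian copula; when
    ``stratum`` names a surgical modification the correlation is induced
    within that stratum only (independent elsewhere).
    """

    correlated_feature: str = "a_early_empty"
    spearman_rho: float = 0.66
    stratum: str | None = "ECC"
    peak_vo2: ParamSpec = ParamSpec(30.0, (25.0, 35.0))
    pct_predicted: ParamSpec = ParamSpec(82.0, (66.0, 94.0))
    rer_max: ParamSpec = ParamSpec(1.07, (1.04, 1.105))
    ve_vco2_slope: ParamSpec = ParamSpec(32.0, (28.0, 36.0))


@dataclass(frozen=True)
class EventConfig:
    """Follow-up event generation: exponential times, uniform censoring."""

    hazard_per_year: float = 0.0575
    log_hr: float = 0.0
    covariate: str | None = None
    followup_years: tuple[float, float] = (6.0, 8.2)


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 57
    n_ecc: int = 26
    n_ilt: int = 31
    n_frames: int = 30
    noise_sd: float = 1.0
    noise_rest_stress_corr: float = 0.0
    seed: int = 0
    rest: dict = field(default_factory=default_rest_distributions)
    stress_shift: dict = field(default_factory=default_stress_shifts)
    outcome: OutcomeConfig = field(default_factory=OutcomeConfig)
    events: EventConfig = field(default_factory=EventConfig)
    e_width_frac: float = 0.45
    a_onset_frac: float = 0.71
    a_width_frac: float = 0.29

    def validate(self) -> None:
        if self.n_ecc < 0 or self.n_ilt < 0 or self.n_patients < 0:
            raise ValueError("all counts must be >= 0")
        if self.n_ecc + self.n_ilt != self.n_patients:
            raise ValueError("n_ecc + n_ilt must equal n_patients")
        if self.n_frames < 16:
            raise ValueError("n_frames must be >= 16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if abs(self.outcome.spearman_rho) > 1.0:
            raise ValueError("unachievable correlation: |rho| must be <= 1")
        if not -1.0 <= self.noise_rest_stress_corr <= 1.0:
            raise ValueError("noise_rest_stress_corr must be in [-1, 1]")


# ---------------------------------------------------------------------------
# Geometry inversion helpers
# ---------------------------------------------------------------------------

def _solve_e_start(
    early_target: float, e_fill: float, e_width: float, a_onset: float
) -> tuple[float, bool]:
    """E-lobe start (fraction of diastole) matching a first-third filling target.

    The fraction of the E lobe delivered within the first third of diastole
    decreases as the lobe starts later; the start is solved by bisection and
    clipped to the feasible range (clipping flagged).
    """
    t0_max = max(a_onset - e_width, 0.0)

    def alpha(t0: float) -> float:
        return _hann_mass_fraction((1.0 / 3.0 - t0) / e_width)

    target = early_target / e_fill if e_fill > 0 else 0.0
    hi, lo = alpha(0.0), alpha(t0_max)
    if target >= hi:
        return 0.0, True
    if target <= lo:
        return t0_max, True
    t0 = brentq(lambda t: alpha(t) - target, 0.0, t0_max, xtol=1e-6)
    return float(t0), False


def _solve_late_filling_a_fill(
    late_target: float,
    sv: float,
    vr_ml_ms: float,
    a_width_ms: float,
    a_fill_max: float,
) -> tuple[float, bool]:
    """A-lobe volume whose measured late filling equals the target.

    The operational late filling is the inflow after the atrial local
    maximum, i.e. the A-lobe volume minus the mass delivered before the
    A-rate first exceeds the (constant) venous return; that offset has a
    closed form for a Hann lobe, and late filling is monotone in the lobe
    volume, so the target inverts by bisection.
    """

    def late(a: float) -> float:
        # crossing of the A upstroke with the venous return rate
        arg = 1.0 - vr_ml_ms * a_width_ms / a
        tau_frac = math.acos(max(-1.0, arg)) / _TWO_PI
        return a - a * _hann_mass_fraction(tau_frac)

    a_lo = vr_ml_ms * a_width_ms / 2.0 * (1.0 + 1e-6)  # A peak just above VR
    a_hi = a_fill_max
    if a_hi <= a_lo:
        return a_hi, True
    if late_target <= late(a_lo):
        return a_lo, True
    if late_target >= late(a_hi):
        return a_hi, True
    a = brentq(lambda v: late(v) - late_target, a_lo, a_hi, xtol=1e-9)
    return float(a), False


def _solve_systole_fraction(
    make_params: Callable[[float], CyclePhysioParams],
    cyclic_target: float,
    lo: float = 0.22,
    hi: float = 0.68,
) -> tuple[float, bool]:
    """Systole fraction matching an atrial cyclic-volume-change target.

    The atrial reservoir fills for the whole of systole, so the cyclic volume
    change grows monotonically with the systole fraction; solved by bisection
    over a physiological range, clipped (and flagged) when the target is
    unreachable.
    """

    def f(sf: float) -> float:
        return ground_truth(make_params(sf)).cyclic_volume_change - cyclic_target

    if f(lo) >= 0.0:
        return lo, True
    if f(hi) <= 0.0:
        return hi, True
    sf = brentq(f, lo, hi, xtol=1e-4)
    return float(sf), False


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPatient:
    patient_id: str
    bsa: float
    params_rest: CyclePhysioParams
    params_stress: CyclePhysioParams
    gt_rest: GroundTruth
    gt_stress: GroundTruth
    curves: dict  # (chamber, condition) -> VolumeTimeCurve
    flags: tuple[str, ...] = ()


@dataclass
class SyntheticStudy:
    """A complete synthetic study: curves, ground truth, outcomes, events."""

    config: CohortConfig
    patients: list
    cohort: pd.DataFrame
    truth: pd.DataFrame
    events: pd.DataFrame

    def curves_frame(self) -> pd.DataFrame:
        """All curves as one long table (the curve CSV schema)."""
        rows = []
        for p in self.patients:
            for (chamber, condition), c in p.curves.items():
                rows.append(
                    pd.DataFrame(
                        {
                            "patient_id": p.patient_id,
                            "chamber": chamber,
                            "condition": condition,
                            "time_ms": c.times,
                            "volume_ml": c.volumes,
                            "heart_rate": c.heart_rate,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def _build_cycle_params(
    *,
    edv: float,
    sv: float,
    late_target: float,
    early_target: float,
    heart_rate: float,
    systole_fraction: float,
    a_min: float,
    e_width: float,
    a_onset: float,
    a_width: float,
) -> tuple[CyclePhysioParams, tuple[str, ...]]:
    T = 60000.0 / heart_rate
    D = (1.0 - systole_fraction) * T
    a_fill, clip_a = _solve_late_filling_a_fill(
        late_target, sv, sv / T, a_width * D, 0.6 * sv
    )
    e_fill = sv - a_fill
    t0, clip_e = _solve_e_start(early_target, e_fill, e_width, a_onset)
    flags = tuple(
        f
        for f, hit in (("a_lobe_clipped", clip_a), ("e_window_clipped", clip_e))
        if hit
    )
    params = CyclePhysioParams(
        edv=edv,
        esv=edv - sv,
        e_fill_volume=e_fill,
        a_fill_volume=a_fill,
        systole_fraction=systole_fraction,
        e_peak_time_frac=t0 + e_width / 2.0,
        e_width_frac=e_width,
        a_onset_frac=a_onset,
        a_width_frac=a_width,
        venous_return_rate=sv * heart_rate / 60.0,
        heart_rate=heart_rate,
        a_min_volume=a_min,
    )
    return params, flags


def generate_cohort(config: CohortConfig | None = None) -> SyntheticStudy:
    """Generate a full paired rest/stress cohort with outcomes and events.

    Fully reproducible from ``config.seed``: identical configs yield
    bit-identical studies.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = [f"P{i + 1:03d}" for i in range(n)]
    modification = np.array(["ECC"] * config.n_ecc + ["ILT"] * config.n_ilt)
    modification = modification[rng.permutation(n)] if n else modification

    rest = {k: config.rest[k].draw(rng, n) for k in sorted(config.rest)}
    shift = {k: config.stress_shift[k].draw(rng, n) for k in sorted(config.stress_shift)}

    sex = np.where(rng.random(n) < 0.65, "M", "F")
    age = np.clip(rng.normal(12.8, 3.85, n), 8.0, 30.0)
    dom = rng.choice(["LV", "RV"], size=n, p=[0.7, 0.3])
    avr = rng.choice(["none_trivial", "moderate_severe"], size=n, p=[0.7, 0.3])
    height = np.clip(rng.normal(155.0, 12.0, n), 120.0, 190.0)

    bsa = np.clip(rest["bsa"], 0.8, 2.2)
    weight = (bsa / (0.024265 * height**0.3964)) ** (1.0 / 0.5378)

    we, ao, aw = config.e_width_frac, config.a_onset_frac, config.a_width_frac
    patients: list[SyntheticPatient] = []
    truth_rows: list[dict] = []
    for i in range(n):
        b = bsa[i]
        flags: list[str] = []
        hr_r = float(np.clip(rest["heart_rate"][i], 50.0, 110.0))
        edv_r = float(np.clip(rest["edv"][i], 55.0, 180.0)) * b
        ef_r = float(np.clip(rest["ef"][i], 30.0, 68.0))
        sv_r = edv_r * ef_r / 100.0
        late_r = float(np.clip(rest["late_filling"][i] * b, 0.02 * sv_r, 0.5 * sv_r))
        early_r = float(np.clip(rest["early_filling"][i] * b, 0.02 * sv_r, None))
        a_min_r = float(np.clip(rest["a_min"][i] * b, 2.0, None))
        sf_r = float(np.clip(rest["systole_fraction"][i], 0.30, 0.45))
        params_r, clip_r = _build_cycle_params(
            edv=edv_r,
            sv=sv_r,
            late_target=late_r,
            early_target=early_r,
            heart_rate=hr_r,
            systole_fraction=sf_r,
            a_min=a_min_r,
            e_width=we,
            a_onset=ao,
            a_width=aw,
        )
        flags.extend(f"rest_{f}" for f in clip_r)
        gt_r = ground_truth(params_r)

        hr_s = float(np.clip(hr_r + shift["heart_rate"][i], 55.0, 185.0))
        edv_s = max(edv_r + shift["edv"][i] * b, 45.0 * b)
        sv_s = float(np.clip(sv_r + shift["sv"][i] * b, 12.0 * b, edv_s - 8.0 * b))
        late_s = float(
            np.clip(
                gt_r.late_filling_volume + shift["late_filling"][i] * b,
                0.02 * sv_s,
                0.5 * sv_s,
            )
        )
        early_s = float(
            np.clip(
                gt_r.early_filling_volume + shift["early_filling"][i] * b,
                0.02 * sv_s,
                None,
            )
        )
        a_min_s = float(np.clip(a_min_r + shift["a_min"][i] * b, 2.0, None))
        cyclic_target = gt_r.cyclic_volume_change + shift["a_cyclic"][i] * b

        def make(sf: float) -> CyclePhysioParams:
            params, _ = _build_cycle_params(
                edv=edv_s,
                sv=sv_s,
                late_target=late_s,
                early_target=early_s,
                heart_rate=hr_s,
                systole_fraction=sf,
                a_min=a_min_s,
                e_width=we,
                a_onset=ao,
                a_width=aw,
            )
            return params

        sf_s, clip_sf = _solve_systole_fraction(make, cyclic_target)
        if clip_sf:
            flags.append("stress_systole_fraction_clipped")
        params_s = make(sf_s)
        gt_s = ground_truth(params_s)

        # sampled curves, optionally with rest/stress-correlated noise
        curves = {}
        c = config.noise_rest_stress_corr
        for chamber_idx, chamber in enumerate(("ventricle", "atrium")):
            eps_r = rng.normal(0.0, 1.0, config.n_frames)
            eps_i = rng.normal(0.0, 1.0, config.n_frames)
            eps_s = c * eps_r + math.sqrt(max(0.0, 1.0 - c * c)) * eps_i
            for params, gt, condition, eps in (
                (params_r, gt_r, "rest", eps_r),
                (params_s, gt_s, "stress", eps_s),
            ):
                vc, acv, _ = generate_cycle(params, config.n_frames, 0.0, None, condition)
                base = vc if chamber == "ventricle" else acv
                vols = base.volumes + config.noise_sd * eps
                curves[(chamber, condition)] = VolumeTimeCurve(
                    times=base.times,
                    volumes=np.maximum(vols, 0.01),
                    chamber=chamber,
                    condition=condition,
                    heart_rate=params.heart_rate,
                    cycle_ms=params.cycle_ms,
                )

        patients.append(
            SyntheticPatient(
                patient_id=ids[i],
                bsa=b,
                params_rest=params_r,
                params_stress=params_s,
                gt_rest=gt_r,
                gt_stress=gt_s,
                curves=curves,
                flags=tuple(flags),
            )
        )
        for condition, gt in (("rest", gt_r), ("stress", gt_s)):
            row = {"patient_id": ids[i], "condition": condition, "bsa": b}
            row.update(feature_row((gt,), bsa=b))
            truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)

    # cohort table: truth-based indexed features, wide
    cohort = pd.DataFrame(
        {
            "patient_id": ids,
            "modification": modification,
            "dominant_ventricle": dom,
            "av_regurgitation": avr,
            "sex": sex,
            "age": age,
            "height": height,
            "weight": weight,
            "bsa": bsa,
        }
    )
    for cond in ("rest", "stress"):
        sub = truth[truth["condition"] == cond].set_index("patient_id")
        for key in FEATURE_KEYS:
            cohort[f"{key}_{cond}"] = sub.loc[ids, key].to_numpy()
    for key in FEATURE_KEYS:
        cohort[f"{key}_reserve"] = cohort[f"{key}_stress"] - cohort[f"{key}_rest"]

    _attach_outcomes(cohort, config, rng)
    events = _attach_events(cohort, config, rng)
    return SyntheticStudy(
        config=config, patients=patients, cohort=cohort, truth=truth, events=events
    )


def _attach_outcomes(
    cohort: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> None:
    n = len(cohort)
    oc = config.outcome
    eps = rng.normal(0.0, 1.0, n)
    latent = eps.copy()
    col = f"{oc.correlated_feature}_reserve"
    if oc.spearman_rho != 0.0 and col in cohort and n >= 2:
        mask = (
            np.ones(n, dtype=bool)
            if oc.stratum is None
            else (cohort["modification"] == oc.stratum).to_numpy()
        )
        m = int(mask.sum())
        if m >= 2:
            r = cohort.loc[mask, col].to_numpy(dtype=float)
            z = norm.ppf((rankdata(r) - 0.5) / m)
            rho_g = 2.0 * math.sin(math.pi * oc.spearman_rho / 6.0)
            latent[mask] = rho_g * z + math.sqrt(1.0 - rho_g**2) * eps[mask]
    cohort["peak_vo2"] = oc.peak_vo2.median + oc.peak_vo2.sd * latent
    cohort["pct_predicted"] = np.clip(
        oc.pct_predicted.draw(rng, n), 20.0, 130.0
    )
    cohort["rer_max"] = oc.rer_max.draw(rng, n)
    cohort["maximal_effort"] = cohort["rer_max"] >= 1.05
    cohort["ve_vco2_slope"] = np.clip(oc.ve_vco2_slope.draw(rng, n), 15.0, None)


def _attach_events(
    cohort: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(cohort)
    ec = config.events
    lam = np.full(n, ec.hazard_per_year, dtype=float)
    if ec.covariate is not None and ec.log_hr != 0.0:
        x = cohort[ec.covariate].to_numpy(dtype=float)
        lam = lam * np.exp(ec.log_hr * (x - x.mean()))
    t_event_years = rng.exponential(1.0, n) / lam
    followup_years = rng.uniform(*ec.followup_years, n)
    categories = rng.choice(EVENT_CATEGORIES, size=n, p=_EVENT_CATEGORY_P)
    second_event = rng.random(n) < 0.25
    nonqual = rng.random(n) < 0.10
    u_second = rng.random(n)
    u_nonqual = rng.random(n)

    rows = []
    followup_days = np.round(followup_years * 365.25)
    for i in range(n):
        pid = cohort["patient_id"].iloc[i]
        if t_event_years[i] < followup_years[i]:
            day = float(np.round(t_event_years[i] * 365.25))
            rows.append((pid, day, categories[i], 1))
            if second_event[i]:
                day2 = float(np.round(day + u_second[i] * (followup_days[i] - day)))
                rows.append((pid, day2, "reintervention_catheter", 1))
        if nonqual[i]:
            rows.append(
                (pid, float(np.round(u_nonqual[i] * followup_days[i])), "arrhythmia", 0)
            )
    events = pd.DataFrame(
        rows, columns=["patient_id", "offset_days", "category", "qualifying"]
    )
    outcomes = []
    for i in range(n):
        pid = cohort["patient_id"].iloc[i]
        recs = events[events["patient_id"] == pid]
        outcomes.append(build_composite(recs, follow_up_days=followup_days[i]))
    cohort["event"] = [o.event for o in outcomes]
    cohort["time_days"] = [o.time_days for o in outcomes]
    cohort["followup_days"] = followup_days
    return events


# ---------------------------------------------------------------------------
# CPET series and survival helpers
# ---------------------------------------------------------------------------

def generate_cpet_series(
    peak_vo2: float,
    rer_max: float,
    duration_s: float = 600.0,
    seed: int | np.random.Generator | None = None,
    ve_vco2_slope: float = 32.0,
    noise_sd: float = 0.0,
    breath_interval_s: float = 2.0,
    vo2_rest: float = 5.0,
    rer_start: float = 0.80,
    ve_intercept: float = 3.0,
) -> pd.DataFrame:
    """Breath-by-breath CPET series (time_s, vo2, vco2, ve).

    VO2 ramps linearly to a plateau occupying the final 60 s, so the mean over
    the final 30 s equals ``peak_vo2`` exactly when noiseless; RER ramps from
    ``rer_start`` to ``rer_max``; VE is linear in VCO2 with the configured
    slope over the submaximal range (RER <= 1) with a ventilatory-compensation
    excess beyond it.  VO2/VCO2 nominally in mL/kg/min; VE in arbitrary
    consistent units.
    """
    if duration_s < 60:
        raise ValueError("duration_s must be >= 60")
    t = np.arange(0.0, duration_s + 1e-9, breath_interval_s)
    ramp_end = duration_s - 60.0
    frac = np.clip(t / ramp_end, 0.0, 1.0) if ramp_end > 0 else np.ones_like(t)
    vo2 = vo2_rest + (peak_vo2 - vo2_rest) * frac
    rer = rer_start + (rer_max - rer_start) * frac
    vco2 = rer * vo2
    ve = ve_intercept + ve_vco2_slope * vco2 + 40.0 * np.maximum(0.0, rer - 1.0) ** 1.5
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        vo2 = vo2 + rng.normal(0.0, noise_sd, t.size)
        vco2 = vco2 + rng.normal(0.0, noise_sd, t.size)
        ve = ve + rng.normal(0.0, 2.0 * noise_sd, t.size)
    return pd.DataFrame({"time_s": t, "vo2": vo2, "vco2": vco2, "ve": ve})


def physiological_grid(max_cases: int | None = None) -> list[CyclePhysioParams]:
    """Deterministic grid of cycle parameters spanning the physiological range.

    Crosses end-diastolic volume, ejection fraction, early/late filling
    split, heart rate, systole fraction, E-wave width and A-wave onset; the
    E wave starts at diastole onset (prompt early filling).  When
    ``max_cases`` is given the grid is subsampled evenly to that size.
    """
    combos = list(
        itertools.product(
            (90.0, 130.0, 170.0),  # EDV (mL)
            (40.0, 50.0, 60.0),  # EF (%)
            (0.60, 0.75),  # early share of diastolic filling
            (60.0, 75.0, 90.0),  # heart rate (bpm)
            (0.33, 0.40),  # systole fraction
            (0.35, 0.45),  # E width (fraction of diastole)
            (0.70, 0.75),  # A onset (fraction of diastole)
        )
    )
    if max_cases is not None and max_cases < len(combos):
        idx = np.linspace(0, len(combos) - 1, max_cases).astype(int)
        combos = [combos[i] for i in idx]
    out = []
    for edv, ef, efrac, hr, sf, ew, ao in combos:
        esv = edv * (1.0 - ef / 100.0)
        sv = edv - esv
        out.append(
            CyclePhysioParams.closed_loop(
                edv=edv,
                esv=esv,
                e_fill_volume=efrac * sv,
                a_fill_volume=(1.0 - efrac) * sv,
                systole_fraction=sf,
                e_peak_time_frac=ew / 2.0,
                e_width_frac=ew,
                a_onset_frac=ao,
                a_width_frac=1.0 - ao,
                heart_rate=hr,
                a_min_volume=30.0,
            )
        )
    return out


def simulate_survival(
    n: int,
    hazard_per_year: float,
    log_hr: float = 0.0,
    binary_covariate: bool = True,
    censor_years: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential survival with an optional covariate effect.

    Baseline hazard ``hazard_per_year``; subjects with covariate ``x`` have
    hazard ``hazard * exp(log_hr * x)``.  Administrative censoring at
    ``censor_years`` when given.  Returns columns time_years, event, x.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if binary_covariate:
        x = (rng.random(n) < 0.5).astype(float)
    else:
        x = rng.normal(0.0, 1.0, n)
    lam = hazard_per_year * np.exp(log_hr * x)
    t = rng.exponential(1.0, n) / lam
    if censor_years is None:
        event = np.ones(n, dtype=bool)
        time = t
    else:
        event = t < censor_years
        time = np.minimum(t, censor_years)
    return pd.DataFrame({"time_years": time, "event": event, "x": x})
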