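"""Functional-parameter extraction from chamber volume-time curves.

One cardiac cycle of a chamber (functional single ventricle or functional
mono-atrium) is represented as a :class:`VolumeTimeCurve`.  Extraction fits a
periodic smoothing spline, locates the cycle landmarks (end-diastole,
end-systole, atrial-contraction onset), and derives the standard diastolic
and atrial function parameters: filling volumes, peak filling rates, E/A
ratio, deceleration time, atrial reservoir / booster-pump emptying volumes
and conduit volume.  Volumes can be indexed to body surface area (Haycock)
and paired rest/stress extractions reduced to stress reserves
(stress value minus resting value).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import splev, splrep
from scipy.signal import find_peaks

__all__ = [
    "VolumeTimeCurve",
    "CycleLandmarks",
    "VentricularFeatures",
    "AtrialFeatures",
    "ExtractionSettings",
    "resample_periodic",
    "detect_landmarks",
    "extract_ventricular",
    "deceleration_time",
    "extract_atrial",
    "extract_features",
    "haycock_bsa",
    "index_features",
    "compute_reserve",
]

CHAMBERS = ("ventricle", "atrium")
CONDITIONS = ("rest", "stress")

_MIN_SAMPLES = 16


@dataclass(frozen=True)
class VolumeTimeCurve:
    """One cardiac cycle of chamber volume samples.

    ``times`` are in ms with ``times[0] == 0`` spanning a single cycle;
    ``volumes`` in mL.  ``cycle_ms`` is the full period; when omitted it is
    inferred as ``times[-1] + median frame spacing`` (equispaced sampling
    does not include the wrap point).
    """

    times: np.ndarray
    volumes: np.ndarray
    chamber: str
    condition: str
    heart_rate: float
    cycle_ms: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "volumes", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and volumes must be 1-d arrays of equal length")
        if t.size < _MIN_SAMPLES:
            raise ValueError(f"curve must have >= {_MIN_SAMPLES} samples, got {t.size}")
        if t[0] != 0.0:
            raise ValueError("times must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("all volumes must be > 0")
        if self.chamber not in CHAMBERS:
            raise ValueError(f"chamber must be one of {CHAMBERS}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.cycle_ms is None:
            object.__setattr__(
                self, "cycle_ms", float(t[-1] + np.median(np.diff(t)))
            )
        nominal = 60000.0 / self.heart_rate
        if abs(self.cycle_ms - nominal) > 0.05 * nominal:
            raise ValueError(
                "cycle duration inconsistent with heart rate "
                f"(cycle {self.cycle_ms:.1f} ms vs 60000/HR {nominal:.1f} ms)"
            )

    @property
    def n_samples(self) -> int:
        return int(self.times.size)


def _periodic_penalized_smooth(values: np.ndarray, noise_sd: float) -> np.ndarray:
    """Periodic discrete smoothing: second-difference penalty, DFT solve.

    Minimises ``||y - f||^2 + lam * ||D2_circ f||^2`` where D2 is the
    circulant second difference; the penalty diagonalises under the DFT, and
    ``lam`` is chosen by the discrepancy principle so the residual sum of
    squares matches ``n * noise_sd**2`` (the classic smoothing-spline
    smoothness/fidelity target, here on equispaced periodic samples).
    """
    n = values.size
    target = n * noise_sd**2
    yhat = np.fft.rfft(values)
    mu2 = (2.0 * np.cos(2.0 * np.pi * np.arange(yhat.size) / n) - 2.0) ** 2
    # weight of each Fourier mode in the residual, doubled for the modes that
    # appear twice in the full spectrum
    w = np.full(yhat.size, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0

    def rss(lam: float) -> float:
        shrink = lam * mu2 / (1.0 + lam * mu2)
        return float(np.sum(w * np.abs(yhat * shrink) ** 2) / n)

    if target <= 0 or rss(1e12) <= target:
        lam = 1e12 if target > 0 else 0.0
    else:
        lo, hi = 1e-9, 1e12
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if rss(mid) < target:
                lo = mid
            else:
                hi = mid
        lam = math.sqrt(lo * hi)
    fhat = yhat / (1.0 + lam * mu2)
    return np.fft.irfft(fhat, n)


class PeriodicSpline:
    """Periodic smoothing spline through one cycle of samples.

    ``smoothing_sd`` is the expected per-sample noise SD in mL: samples are
    first smoothed by a periodic penalised-least-squares fit whose residual
    matches that noise level, then represented as an interpolating periodic
    spline (FITPACK) so values and derivatives are continuous across the
    cycle boundary.  With ``smoothing_sd == 0`` the original samples are
    interpolated exactly.
    """

    def __init__(
        self,
        times: np.ndarray,
        values: np.ndarray,
        period: float,
        degree: int = 3,
        smoothing_sd: float = 0.0,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if smoothing_sd > 0:
            values = _periodic_penalized_smooth(values, smoothing_sd)
        x = np.concatenate([times, [times[0] + period]])
        y = np.concatenate([values, [values[0]]])
        self._tck = splrep(x, y, k=degree, s=0, per=1)
        self.period = float(period)
        self._t0 = float(times[0])

    def __call__(self, t, der: int = 0):
        tt = self._t0 + np.mod(np.asarray(t, dtype=float) - self._t0, self.period)
        return splev(tt, self._tck, der=der)


@dataclass(frozen=True)
class ExtractionSettings:
    """Tunable knobs of the extraction pipeline.

    resolution
        Number of equispaced evaluation points per cycle for the dense
        spline evaluation used by landmark detection and extraction.
    spline_degree, smoothing_sd
        Periodic spline order and expected per-sample noise SD (mL).
    dt_band
        Fraction-of-peak band defining the "linear segment" of the early
        filling deceleration limb (echocardiographic 70-30% convention).
    a_onset_search_frac
        The atrial-contraction onset is sought among local maxima of the
        atrial curve in the last ``1 - frac`` of diastole; earlier atrial
        maxima belong to the reservoir/conduit phase.
    fusion_fallback_frac
        When no late-diastolic atrial maximum is resolvable (E-A fusion,
        e.g. under dobutamine tachycardia), the onset falls back to this
        fraction of diastole and the result carries a ``fusion`` flag.
    peak_prominence_frac
        Minimum prominence of an atrial local maximum, as a fraction of the
        atrial volume range (rejects noise wiggles).
    floor_emptying
        Floor negative atrial emptying volumes at 0 (with a flag).  The
        conduit volume is never floored: its sign is diagnostic.
    """

    resolution: int = 1024
    spline_degree: int = 3
    smoothing_sd: float = 0.0
    dt_band: tuple[float, float] = (0.7, 0.3)
    dt_min_samples: int = 3
    a_onset_search_frac: float = 0.5
    fusion_fallback_frac: float = 2.0 / 3.0
    peak_prominence_frac: float = 0.005
    floor_emptying: bool = True

    def fit(self, curve: VolumeTimeCurve) -> PeriodicSpline:
        return PeriodicSpline(
            curve.times,
            curve.volumes,
            curve.cycle_ms,
            degree=self.spline_degree,
            smoothing_sd=self.smoothing_sd,
        )


DEFAULT_SETTINGS = ExtractionSettings()


@dataclass(frozen=True)
class CycleLandmarks:
    """Timing anchors of one cycle (ms from cycle start).

    Diastole is the ventricular-curve interval from minimal volume (t_es) to
    the next maximal volume (wrapping across the cycle end if needed); the
    atrial-contraction onset ``t_a_onset`` is the last local maximum of the
    atrial volume curve within late diastole.
    """

    t_ed: float
    t_es: float
    diastole_start: float
    diastole_duration: float
    t_a_onset: float
    fusion: bool = False
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class VentricularFeatures:
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
    flags: tuple[str, ...] = ()

    _volume_fields = (
        "edv",
        "esv",
        "sv",
        "early_filling_volume",
        "late_filling_volume",
    )


@dataclass(frozen=True)
class AtrialFeatures:
    v_max: float
    v_min: float
    cyclic_volume_change: float
    early_emptying_volume: float
    late_emptying_volume: float
    conduit_volume: float
    flags: tuple[str, ...] = ()

    _volume_fields = (
        "v_max",
        "v_min",
        "cyclic_volume_change",
        "early_emptying_volume",
        "late_emptying_volume",
        "conduit_volume",
    )


def resample_periodic(
    curve: VolumeTimeCurve,
    resolution: int,
    smoothing_sd: float = 0.0,
    spline_degree: int = 3,
) -> VolumeTimeCurve:
    """Resample one cycle onto ``resolution`` equispaced times.

    Uses a periodic smoothing spline, so value and first derivative are
    continuous across the cycle wrap; with ``smoothing_sd == 0`` the original
    samples are reproduced exactly.
    """
    if resolution < _MIN_SAMPLES:
        raise ValueError(f"resolution must be >= {_MIN_SAMPLES}")
    spl = PeriodicSpline(
        curve.times, curve.volumes, curve.cycle_ms, spline_degree, smoothing_sd
    )
    tt = np.arange(resolution) * (curve.cycle_ms / resolution)
    vv = np.asarray(spl(tt), dtype=float)
    return VolumeTimeCurve(
        times=tt,
        volumes=np.maximum(vv, 1e-9),
        chamber=curve.chamber,
        condition=curve.condition,
        heart_rate=curve.heart_rate,
        cycle_ms=curve.cycle_ms,
    )


def detect_landmarks(
    vcurve: VolumeTimeCurve,
    acurve: VolumeTimeCurve,
    settings: ExtractionSettings = DEFAULT_SETTINGS,
) -> CycleLandmarks:
    """Locate end-diastole, end-systole and the atrial-contraction onset.

    t_ed / t_es are the times of ventricular maximal / minimal volume on the
    dense periodic-spline evaluation (earliest time wins on ties).  The
    atrial-contraction onset is the last local maximum of the atrial curve in
    late diastole (the atrium refills during the conduit phase and empties at
    contraction); if none is resolvable the 2/3-diastole fallback is used and
    the ``fusion`` flag set.
    """
    T = vcurve.cycle_ms
    if abs(acurve.cycle_ms - T) > 0.01 * T:
        raise ValueError(
            "ventricular and atrial cycle durations do not overlap "
            f"({T:.1f} vs {acurve.cycle_ms:.1f} ms)"
        )
    vspl = settings.fit(vcurve)
    aspl = settings.fit(acurve)
    tt = np.arange(settings.resolution) * (T / settings.resolution)
    vv = np.asarray(vspl(tt), dtype=float)

    flags: list[str] = []
    vrange = float(vv.max() - vv.min())
    if vrange < 1e-9:
        # Degenerate flat ventricular curve: treat the whole cycle as
        # diastole so downstream differences evaluate to zero.
        flags.append("flat_ventricular_curve")
        t_ed, t_es = 0.0, 0.0
        diastole_start, diastole_duration = 0.0, T
    else:
        # Earliest time wins on ties; with smoothing, "tie" means within a
        # noise-scaled tolerance, so an isovolumic plateau is anchored at its
        # start rather than wherever residual noise puts the literal argmin.
        tol = 0.5 * settings.smoothing_sd
        vmax, vmin = float(vv.max()), float(vv.min())
        t_ed = float(tt[int(np.argmax(vv >= vmax - tol))])
        t_es = float(tt[int(np.argmax(vv <= vmin + tol))])
        diastole_start = t_es
        diastole_duration = float((t_ed - t_es) % T)
        if diastole_duration == 0.0:
            diastole_duration = T

    ds, D = diastole_start, diastole_duration
    lo = ds + settings.a_onset_search_frac * D
    ta = np.linspace(lo, ds + D, settings.resolution // 2, endpoint=False)
    av = np.asarray(aspl(ta), dtype=float)
    arange_ = float(
        np.ptp(np.asarray(aspl(np.arange(settings.resolution) * T / settings.resolution)))
    )
    fusion = True
    t_a_onset = ds + settings.fusion_fallback_frac * D
    if arange_ > 1e-9:
        # two-stage prominence: prefer a clear peak, fall back to a faint one
        # before declaring E-A fusion
        prom = settings.peak_prominence_frac * arange_
        for p in (prom, prom / 5.0):
            peaks, _ = find_peaks(av, prominence=p)
            if peaks.size:
                fusion = False
                t_a_onset = float(ta[int(peaks[-1])])
                break
    if fusion:
        flags.append("ea_fusion_fallback_onset")
    return CycleLandmarks(
        t_ed=t_ed,
        t_es=t_es,
        diastole_start=ds,
        diastole_duration=D,
        t_a_onset=t_a_onset,
        fusion=fusion,
        flags=tuple(flags),
    )


def deceleration_time(
    times: np.ndarray,
    rates: np.ndarray,
    t_e_peak: float,
    band: tuple[float, float] = (0.7, 0.3),
    min_samples: int = 3,
) -> tuple[float, tuple[str, ...]]:
    """Deceleration time from a sampled filling-rate curve (ms, mL/s).

    A least-squares line is fitted to the descending-limb samples whose rate
    lies between ``band[0]`` and ``band[1]`` of the peak rate and extrapolated
    to the zero-velocity baseline; DT is the zero-crossing time minus the
    peak time.  Returns ``(nan, flags)`` when fewer than ``min_samples`` fall
    in the band or the fitted slope is not negative.
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(rates, dtype=float)
    hi, lo = band
    after = t > t_e_peak
    if not np.any(after):
        return float("nan"), ("dt_no_descending_limb",)
    t_after, r_after = t[after], r[after]
    # truncate at the first non-positive rate: beyond lies the baseline
    nonpos = np.nonzero(r_after <= 0)[0]
    if nonpos.size:
        t_after = t_after[: nonpos[0]]
        r_after = r_after[: nonpos[0]]
    peak = float(np.interp(t_e_peak, t, r))
    if peak <= 0:
        return float("nan"), ("dt_no_descending_limb",)
    in_band = (r_after <= hi * peak) & (r_after >= lo * peak)
    if int(in_band.sum()) < min_samples:
        return float("nan"), ("dt_insufficient_support",)
    slope, intercept = np.polyfit(t_after[in_band], r_after[in_band], 1)
    if slope >= -1e-9:
        return float("nan"), ("dt_nonnegative_slope",)
    t_zero = -intercept / slope
    return float(t_zero - t_e_peak), ()


def extract_ventricular(
    vcurve: VolumeTimeCurve,
    landmarks: CycleLandmarks,
    settings: ExtractionSettings = DEFAULT_SETTINGS,
) -> VentricularFeatures:
    """Ventricular volumes, filling volumes, peak filling rates, E/A, DT.

    Early filling volume is the volume gained over the first third of
    diastole (a temporal partition); late filling is the gain from the
    atrial-contraction onset to end-diastole.  Rates come from the periodic
    spline derivative (mL/s).
    """
    spl = settings.fit(vcurve)
    T = vcurve.cycle_ms
    tt = np.arange(settings.resolution) * (T / settings.resolution)
    vv = np.asarray(spl(tt), dtype=float)
    flags: list[str] = list(landmarks.flags)

    edv = float(vv.max())
    esv = float(vv.min())
    sv = edv - esv
    ef = 100.0 * sv / edv if edv > 0 else float("nan")

    ds, D = landmarks.diastole_start, landmarks.diastole_duration
    t_on = landmarks.t_a_onset
    early_filling = float(spl(ds + D / 3.0) - spl(ds))
    late_filling = float(spl(ds + D) - spl(t_on))

    td = np.linspace(ds, ds + D, settings.resolution, endpoint=True)
    rate = np.asarray(spl(td, der=1), dtype=float) * 1000.0  # mL/ms -> mL/s
    early_mask = td <= t_on
    late_mask = td > t_on
    epk = float(rate[early_mask].max()) if early_mask.any() else 0.0
    apk = float(rate[late_mask].max()) if late_mask.any() else 0.0
    epk = max(epk, 0.0)
    apk = max(apk, 0.0)
    if sv < 1e-9:  # flat curve: numeric residue is not a filling wave
        epk = apk = 0.0
    if apk > 0:
        e_a = epk / apk
    else:
        e_a = float("nan")
        flags.append("ea_ratio_undefined")

    if epk > 0:
        i_pk = int(np.argmax(np.where(early_mask, rate, -np.inf)))
        t_e_peak = float(td[i_pk])
        dt, dt_flags = deceleration_time(
            td[early_mask],
            rate[early_mask],
            t_e_peak,
            band=settings.dt_band,
            min_samples=settings.dt_min_samples,
        )
        flags.extend(dt_flags)
    else:
        dt = float("nan")
        flags.append("dt_no_descending_limb")

    return VentricularFeatures(
        edv=edv,
        esv=esv,
        sv=sv,
        ef=ef,
        early_filling_volume=early_filling,
        late_filling_volume=late_filling,
        early_peak_filling_rate=epk,
        late_peak_filling_rate=apk,
        e_a_ratio=e_a,
        deceleration_time=dt,
        flags=tuple(flags),
    )


def extract_atrial(
    acurve: VolumeTimeCurve,
    landmarks: CycleLandmarks,
    sv: float,
    settings: ExtractionSettings = DEFAULT_SETTINGS,
) -> AtrialFeatures:
    """Atrial reservoir / booster-pump volumes and conduit volume.

    Early emptying is the drop from the early-diastolic atrial maximum to the
    volume at atrial-contraction onset (reservoir function); late emptying is
    the drop from onset to minimal volume (booster pump); conduit volume is
    ``sv - (early + late emptying)`` and is never floored.
    """
    if sv is None or not np.isfinite(sv):
        raise ValueError("paired ventricular stroke volume is required")
    spl = settings.fit(acurve)
    T = acurve.cycle_ms
    tt = np.arange(settings.resolution) * (T / settings.resolution)
    vv = np.asarray(spl(tt), dtype=float)
    flags: list[str] = []

    v_max = float(vv.max())
    v_min = float(vv.min())
    cyclic = v_max - v_min

    ds = landmarks.diastole_start
    t_on = landmarks.t_a_onset
    span = (t_on - ds) % T or T
    te = np.linspace(ds, ds + span, max(settings.resolution // 2, 64))
    va_early_max = float(np.asarray(spl(te), dtype=float).max())
    va_on = float(spl(t_on))

    early = va_early_max - va_on
    late = va_on - v_min
    if settings.floor_emptying:
        if early < 0:
            flags.append("early_emptying_floored")
            early = 0.0
        if late < 0:
            flags.append("late_emptying_floored")
            late = 0.0
    conduit = sv - (early + late)
    if conduit < -1e-9:
        flags.append("negative_conduit_volume")
    return AtrialFeatures(
        v_max=v_max,
        v_min=v_min,
        cyclic_volume_change=cyclic,
        early_emptying_volume=early,
        late_emptying_volume=late,
        conduit_volume=conduit,
        flags=tuple(flags),
    )


def extract_features(
    vcurve: VolumeTimeCurve,
    acurve: VolumeTimeCurve,
    settings: ExtractionSettings = DEFAULT_SETTINGS,
) -> tuple[VentricularFeatures, AtrialFeatures, CycleLandmarks]:
    """Landmarks + ventricular + atrial extraction for one paired cycle."""
    lm = detect_landmarks(vcurve, acurve, settings)
    vf = extract_ventricular(vcurve, lm, settings)
    af = extract_atrial(acurve, lm, vf.sv, settings)
    return vf, af, lm


def haycock_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2) by the Haycock formula.

    BSA = 0.024265 * weight^0.5378 * height^0.3964 (weight kg, height cm).
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be > 0")
    return 0.024265 * weight_kg**0.5378 * height_cm**0.3964


def index_features(features, bsa: float):
    """Divide every volume field by BSA (mL -> mL/m^2).

    Rates, times, ratios and ejection fraction are unchanged.  Works for
    :class:`VentricularFeatures` and :class:`AtrialFeatures`.
    """
    if not np.isfinite(bsa) or bsa <= 0:
        raise ValueError("bsa must be a positive finite number")
    volume_fields = getattr(type(features), "_volume_fields", None)
    if volume_fields is None:
        raise TypeError(f"cannot index features of type {type(features).__name__}")
    updates = {name: getattr(features, name) / bsa for name in volume_fields}
    return replace(features, **updates)


def compute_reserve(rest, stress):
    """Stress reserve: elementwise ``stress - rest`` over a feature set.

    Both sides must be the same feature type (and indexed identically);
    a missing (NaN) value on either side yields a missing reserve.
    """
    if type(rest) is not type(stress):
        raise TypeError(
            f"feature schema mismatch: {type(rest).__name__} vs {type(stress).__name__}"
        )
    updates = {}
    missing = []
    for f in dataclasses.fields(rest):
        if f.name == "flags":
            continue
        r, s = getattr(rest, f.name), getattr(stress, f.name)
        updates[f.name] = s - r
        if not (np.isfinite(r) and np.isfinite(s)):
            missing.append(f.name)
    flags = tuple(f"reserve_missing:{name}" for name in missing)
    return replace(rest, **updates, flags=flags)
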