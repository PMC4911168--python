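"""Elastic indices of the aortic wall from an area-time curve and cuff pressures.

Given the lumen cross-sectional area over one cardiac cycle and the brachial
systolic/diastolic pressures bracketing the acquisition, this module computes:

* ``delta_s`` — systolic-diastolic area excursion, Amax - Amin (mm2)
* ``ac``  — compliance, delta_s / pulse pressure (mm2/mmHg)
* ``ad``  — distensibility, ac / Amin (1/mmHg)
* ``strain`` — relative area excursion, delta_s / Amin (dimensionless)
* ``mrsd`` / ``mrdr`` — extrema of dA/dt: maximum rate of systolic
  distension (>= 0) and of diastolic recoil (<= 0, stored signed), mm2/ms.

The algebraic identities ``ad * pp == strain`` and ``ac == ad * a_min`` hold
exactly by construction and are asserted throughout the test-suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline


@dataclass
class AreaCurve:
    """Calibrated area-vs-time waveform for one plane and condition."""

    times: np.ndarray  # ms, strictly increasing, within one cycle
    areas: np.ndarray  # mm2, positive
    site: str = "AA"
    condition: str = "rest"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.areas.shape:
            raise ValueError("times and areas must be 1-D and equally long")
        if self.times.size < 8:
            raise ValueError("an AreaCurve needs at least 8 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.areas <= 0):
            raise ValueError("areas must be positive")

    @property
    def a_min(self) -> float:
        return float(self.areas.min())

    @property
    def a_max(self) -> float:
        return float(self.areas.max())

    @property
    def delta_s(self) -> float:
        return self.a_max - self.a_min


@dataclass
class PressurePair:
    """Brachial pressures measured before and after one acquisition.

    The after-measurement may be missing (NaN); the available reading is then
    used alone and the fallback is flagged on the instance.
    """

    sbp_before: float
    dbp_before: float
    sbp_after: float = float("nan")
    dbp_after: float = float("nan")
    incomplete: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if not self.sbp_before > self.dbp_before > 0:
            raise ValueError("need SBP > DBP > 0 for the before measurement")
        if np.isnan(self.sbp_after) or np.isnan(self.dbp_after):
            self.incomplete = True
        elif not self.sbp_after > self.dbp_after > 0:
            raise ValueError("need SBP > DBP > 0 for the after measurement")

    @property
    def sbp(self) -> float:
        if self.incomplete:
            return self.sbp_before
        return 0.5 * (self.sbp_before + self.sbp_after)

    @property
    def dbp(self) -> float:
        if self.incomplete:
            return self.dbp_before
        return 0.5 * (self.dbp_before + self.dbp_after)

    @property
    def map(self) -> float:
        """Mean arterial pressure, DBP + PP/3 (reporting only)."""
        return self.dbp + (self.sbp - self.dbp) / 3.0


@dataclass
class ElasticIndices:
    delta_s: float  # mm2
    ac: float  # mm2/mmHg
    ad: float  # 1/mmHg
    strain: float  # dimensionless
    mrsd: float  # mm2/ms, >= 0
    mrdr: float  # mm2/ms, <= 0 (signed; report |mrdr| downstream)
    pp: float  # mmHg
    a_min: float  # mm2
    a_max: float  # mm2
    site: str = ""
    condition: str = ""


def pulse_pressure(p: PressurePair) -> float:
    """Brachial pulse pressure: mean SBP minus mean DBP over before/after."""
    if p.incomplete:
        warnings.warn("pressure pair incomplete; using the before measurement only", stacklevel=2)
    return p.sbp - p.dbp


def compliance(curve: AreaCurve, pp: float) -> float:
    """Area compliance (Amax - Amin) / PP in mm2/mmHg."""
    if pp <= 0:
        raise ValueError("pulse pressure must be positive")
    return curve.delta_s / pp


def distensibility(ac: float, a_min: float) -> float:
    """Distensibility: compliance normalised by the minimum area, 1/mmHg."""
    if a_min <= 0:
        raise ValueError("a_min must be positive")
    return ac / a_min


def strain(curve: AreaCurve) -> float:
    """Relative area excursion (Amax - Amin) / Amin."""
    return curve.delta_s / curve.a_min


def max_rates(
    curve: AreaCurve,
    smoothing_window: int = 1,
    interp_ms: float | None = None,
    smoothing_poly: int | None = None,
) -> tuple[float, float]:
    """Extrema of dA/dt by central finite differences.

    An optional smoothing of ``smoothing_window`` samples is applied first
    (1 = off): a moving average by default, or a Savitzky-Golay fit of order
    ``smoothing_poly`` when that is given (slope-preserving, preferred on
    segmented curves).  With ``interp_ms`` set, the smoothed curve is
    resampled by a cubic spline on that step before differencing; this
    removes most of the sin(x)/x attenuation of the peak slope at 30-40
    frames per cycle and is what the pipeline uses.
    """
    if smoothing_window >= curve.times.size:
        raise ValueError("smoothing window must be shorter than the curve")
    t = curve.times
    a = curve.areas.copy()
    if smoothing_window > 1:
        if smoothing_poly is not None:
            from scipy.signal import savgol_filter

            a = savgol_filter(a, smoothing_window, smoothing_poly)
        else:
            kernel = np.ones(smoothing_window) / smoothing_window
            pad = smoothing_window // 2
            padded = np.pad(a, pad, mode="edge")
            a = np.convolve(padded, kernel, mode="valid")[: t.size]
    if interp_ms is not None:
        if interp_ms <= 0:
            raise ValueError("interp_ms must be positive")
        spline = CubicSpline(t, a)
        t = np.arange(t[0], t[-1] + 0.5 * interp_ms, interp_ms)
        a = spline(t)
    slopes = np.gradient(a, t)
    return float(slopes.max()), float(slopes.min())


def rate_pressure_product(hr: float, sbp: float) -> float:
    """Heart rate x systolic pressure, bpm*mmHg — a cardiac-work surrogate."""
    if hr <= 0 or sbp <= 0:
        raise ValueError("heart rate and systolic pressure must be positive")
    return hr * sbp


def elastic_indices(
    curve: AreaCurve,
    pressures: PressurePair | float,
    smoothing_window: int = 1,
    interp_ms: float | None = None,
    smoothing_poly: int | None = None,
) -> ElasticIndices:
    """Compute the full index set for one area curve.

    ``pressures`` is either a :class:`PressurePair` or a pulse pressure in
    mmHg directly.
    """
    pp = pressures if isinstance(pressures, (int, float)) else pulse_pressure(pressures)
    ac = compliance(curve, pp)
    ad = distensibility(ac, curve.a_min)
    mrsd, mrdr = max_rates(curve, smoothing_window=smoothing_window,
                           interp_ms=interp_ms, smoothing_poly=smoothing_poly)
    return ElasticIndices(
        delta_s=curve.delta_s,
        ac=ac,
        ad=ad,
        strain=strain(curve),
        mrsd=mrsd,
        mrdr=mrdr,
        pp=float(pp),
        a_min=curve.a_min,
        a_max=curve.a_max,
        site=curve.site,
        condition=curve.condition,
    )
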