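"""Segmental aortic pulse wave velocity from paired flow waveforms.

A flow pulse arrives at a distal plane later than at a proximal one; the
transit time divided into the centerline distance between the planes gives
the wave speed.  Two transit-time estimators are provided:

* ``foot`` — locate the foot of each wave (intersection of a regression line
  through the systolic upslope with the diastolic baseline) and subtract;
* ``lsq``  — after peak normalisation, find the shift that minimises the
  summed squared difference between the two systolic upslopes.

Both operate on cubic-spline-interpolated curves (default 1 ms step) because
the native temporal resolution of velocity-encoded acquisitions (~28 ms) can
alone contribute tens of ms of transit-time error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from skimage.draw import polygon as draw_polygon

from .biomech import AreaCurve  # noqa: F401  (re-exported convenience)
from .io import VelocitySeries


@dataclass
class FlowCurve:
    """Flow (mm3/ms) or mean-velocity waveform at one plane."""

    times: np.ndarray  # ms, strictly increasing
    values: np.ndarray
    plane: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equally long")
        if self.times.size < 16:
            raise ValueError("a FlowCurve needs at least 16 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def shifted(self, offset_ms: float) -> "FlowCurve":
        return FlowCurve(self.times + offset_ms, self.values.copy(), self.plane)


@dataclass
class SegmentGeometry:
    """Ordered centerline points (mm) between two measurement planes."""

    points: np.ndarray  # (n, 3)
    label: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2 or self.points.shape[1] != 3:
            raise ValueError("need at least two 3-D points")

    @property
    def length(self) -> float:
        return centerline_length(self.points)


@dataclass
class TransitResult:
    delta_t: float  # ms
    method: str  # "foot" | "lsq"
    interp_ms: float
    detail: dict = field(default_factory=dict)


@dataclass
class PWVResult:
    pwv: float  # m/s
    delta_t: float  # ms
    length: float  # mm
    segment: str = ""
    condition: str = ""
    method: str = ""


def extract_flow_curve(vel: VelocitySeries, contours) -> FlowCurve:
    """Integrate through-plane velocity over the lumen mask of each frame.

    ``contours`` is a :class:`aortaflex.segmentation.ContourSet` aligned with
    the velocity frames; flow per frame is sum(velocity * pixel area), mm3/ms.
    """
    if len(contours.contours) != vel.n_frames:
        raise ValueError("contour count must match velocity frame count")
    px_area = vel.pixel_mm**2
    shape = vel.frames.shape[1:]
    flows = np.empty(vel.n_frames)
    clipped = 0
    for i, contour in enumerate(contours.contours):
        x_px, y_px = contour.vertices_px()
        rr, cc = draw_polygon(y_px, x_px, shape=shape)
        frame = vel.frames[i]
        clipped += int(np.sum(np.abs(frame[rr, cc]) >= 0.999 * vel.venc))
        flows[i] = frame[rr, cc].sum() * px_area
    if clipped:
        warnings.warn(f"{clipped} lumen pixels at the velocity-encoding limit (venc)", stacklevel=2)
    return FlowCurve(vel.frame_times.copy(), flows, plane=vel.plane)


def _interpolated(
    curve: FlowCurve, interp_ms: float, presmooth: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline resampling, after an optional short moving average.

    The moving average (default 3 samples, 1 = off) tames spline ringing on
    noisy coarse acquisitions; it shifts both curves of a pair identically,
    so transit times are unaffected by its (small) shape bias.
    """
    if interp_ms <= 0:
        raise ValueError("interp_ms must be positive")
    y = curve.values
    if presmooth > 1:
        kernel = np.ones(presmooth) / presmooth
        pad = presmooth // 2
        y = np.convolve(np.pad(y, pad, mode="edge"), kernel, mode="valid")[: curve.times.size]
    t = np.arange(curve.times[0], curve.times[-1] + 0.5 * interp_ms, interp_ms)
    return t, CubicSpline(curve.times, y)(t)


def _upstroke_indices(t: np.ndarray, y: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Indices of the ascending limb between fractions lo..hi of peak-above-baseline."""
    ipk = int(np.argmax(y))
    if ipk == 0:
        raise ValueError("peak at first sample: no ascending limb")
    base = _baseline(y, ipk)
    span = y[ipk] - base
    if span <= 0:
        raise ValueError("no systolic pulse above baseline")
    rel = (y[: ipk + 1] - base) / span
    below = np.nonzero(rel <= lo)[0]
    start = below[-1] if below.size else 0
    seg = np.arange(start, ipk + 1)
    sel = seg[(rel[seg] >= lo) & (rel[seg] <= hi)]
    if sel.size < 2:
        # coarse sampling: fall back to every rising-limb sample above baseline
        sel = seg[rel[seg] > 0]
    if sel.size < 2:
        raise ValueError("ascending limb too short for the requested window")
    return sel


def _baseline(y: np.ndarray, ipk: int) -> float:
    """Median of pre-upstroke samples (before the 10 %-of-range crossing)."""
    lo_level = y.min() + 0.10 * (y[ipk] - y.min())
    below = np.nonzero(y[: ipk + 1] <= lo_level)[0]
    if below.size == 0:
        return float(y.min())
    return float(np.median(y[: below[-1] + 1]))


def foot_of_wave(
    curve: FlowCurve,
    interp_ms: float = 1.0,
    method: str = "intercept",
    window: tuple[float, float] = (0.20, 0.80),
    presmooth: int = 3,
) -> float:
    """Arrival time (ms) of the systolic upstroke.

    ``intercept`` (default): regression line through the 20-80 % ascending
    limb intersected with the diastolic baseline.  ``threshold``: time of the
    10 %-of-peak upward crossing (sub-sample, by inverse interpolation).
    ``sample``: the raw acquisition sample at which the 10 % level is first
    exceeded — no interpolation at all, so the answer is quantised to the
    native temporal resolution; kept to expose the transit-time imprecision
    of coarse acquisitions.
    """
    if method == "sample":
        y = curve.values
        ipk = int(np.argmax(y))
        if ipk == 0:
            raise ValueError("peak at first sample: no ascending limb")
        base = _baseline(y, ipk)
        level = base + 0.10 * (y[ipk] - base)
        rising = np.nonzero(y[: ipk + 1] >= level)[0]
        if rising.size == 0:
            raise ValueError("no upward threshold crossing found")
        return float(curve.times[rising[0]])
    t, y = _interpolated(curve, interp_ms, presmooth=presmooth)
    ipk = int(np.argmax(y))
    if ipk == 0:
        raise ValueError("peak at first sample: no ascending limb")
    base = _baseline(y, ipk)
    if method == "threshold":
        level = base + 0.10 * (y[ipk] - base)
        rising = np.nonzero((y[: ipk + 1] >= level))[0]
        if rising.size == 0:
            raise ValueError("no upward threshold crossing found")
        i = rising[0]
        if i == 0:
            return float(t[0])
        # linear inverse interpolation between bracketing samples
        frac = (level - y[i - 1]) / (y[i] - y[i - 1])
        return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    if method != "intercept":
        raise ValueError(f"unknown foot method: {method!r}")
    sel = _upstroke_indices(t, y, *window)
    slope, intercept = np.polyfit(t[sel], y[sel], 1)
    if slope <= 0:
        raise ValueError("non-positive upslope; cannot locate foot")
    return float((base - intercept) / slope)


def transit_time_foot(
    proximal: FlowCurve,
    distal: FlowCurve,
    interp_ms: float = 1.0,
    method: str = "intercept",
    presmooth: int = 3,
) -> TransitResult:
    """Foot-to-foot transit time: foot(distal) - foot(proximal)."""
    fp = foot_of_wave(proximal, interp_ms, method=method, presmooth=presmooth)
    fd = foot_of_wave(distal, interp_ms, method=method, presmooth=presmooth)
    return TransitResult(
        delta_t=fd - fp,
        method="foot",
        interp_ms=interp_ms,
        detail={"foot_proximal_ms": fp, "foot_distal_ms": fd},
    )


def transit_time_lsq(
    proximal: FlowCurve,
    distal: FlowCurve,
    interp_ms: float = 1.0,
    window: tuple[float, float] = (0.10, 0.95),
    max_shift_ms: float | None = None,
    presmooth: int = 3,
) -> TransitResult:
    """Least-squares upslope alignment after peak normalisation.

    Minimises sum_i (prox(t_i) - dist(t_i + d))^2 over the proximal upslope
    window, on a grid of d at the interpolation step, refined by parabolic
    interpolation of the objective around the grid minimum.
    """
    tp, yp = _interpolated(proximal, interp_ms, presmooth=presmooth)
    td, yd = _interpolated(distal, interp_ms, presmooth=presmooth)
    yp = yp / yp.max()
    yd = yd / yd.max()
    sel = _upstroke_indices(tp, yp, *window)
    t_win = tp[sel]
    dist_spline = CubicSpline(td, yd)
    if max_shift_ms is None:
        max_shift_ms = 0.5 * (proximal.times[-1] - proximal.times[0])
    deltas = np.arange(-max_shift_ms, max_shift_ms + 0.5 * interp_ms, interp_ms)
    cost = np.full(deltas.size, np.inf)
    for k, d in enumerate(deltas):
        tq = t_win + d
        inside = (tq >= td[0]) & (tq <= td[-1])
        if inside.mean() < 0.7:  # shifted window must mostly overlap the distal record
            continue
        resid = yp[sel][inside] - dist_spline(tq[inside])
        cost[k] = float(np.mean(resid**2))
    if not np.isfinite(cost).any():
        raise ValueError("upslope windows do not overlap for any candidate shift")
    k = int(np.argmin(cost))
    delta = deltas[k]
    if 0 < k < deltas.size - 1 and np.isfinite(cost[k - 1]) and np.isfinite(cost[k + 1]):
        denom = cost[k - 1] - 2 * cost[k] + cost[k + 1]
        if denom > 0:
            delta = delta + 0.5 * interp_ms * (cost[k - 1] - cost[k + 1]) / denom
    return TransitResult(
        delta_t=float(delta),
        method="lsq",
        interp_ms=interp_ms,
        detail={"window": window, "grid_cost_min": float(cost[k])},
    )


def centerline_length(points: np.ndarray) -> float:
    """Polyline length (mm) of ordered 3-D centerline points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("need at least two centerline points")
    length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    if length == 0.0:
        warnings.warn("degenerate centerline: coincident points, length 0", stacklevel=2)
    return length


def compute_pwv(
    length_mm: float, delta_t_ms: float, segment: str = "", condition: str = "", method: str = ""
) -> PWVResult:
    """PWV = segment length / transit time; mm/ms is numerically m/s."""
    if length_mm < 0:
        raise ValueError("segment length must be non-negative")
    if delta_t_ms <= 0:
        raise ValueError("transit time must be positive")
    return PWVResult(
        pwv=length_mm / delta_t_ms,
        delta_t=delta_t_ms,
        length=length_mm,
        segment=segment,
        condition=condition,
        method=method,
    )


def cf_pwv(distance_mm: float, delta_t_ms: float, condition: str = "") -> PWVResult:
    """Carotid-femoral PWV from tonometric distance and transit time, D/dt."""
    res = compute_pwv(distance_mm, delta_t_ms, segment="carotid-femoral", condition=condition)
    res.method = "tonometry"
    return res
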