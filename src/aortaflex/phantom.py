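"""Synthetic inputs with closed-form ground truth.

Everything the analysis consumes can be generated here: an analytic
area-vs-time waveform (raised-cosine systolic rise and diastolic recoil over
a flat baseline), rendered cine stacks of a pulsating near-circular lumen,
paired flow pulses with a controllable inter-plane delay, centerline slice
stacks of known arc length, and a simulated rest/stress cohort for the
statistics battery.

The raised-cosine family was chosen because the extrema of dA/dt have closed
forms: max upslope = dS*pi/(2*t_rise) and max downslope = -dS*pi/(2*t_decay)
with dS = a_max - a_min, which makes every derived index testable against an
exact value.  All randomness flows through one explicit seed per artifact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .biomech import AreaCurve
from .io import CineSeries, VelocitySeries
from .pwv import FlowCurve

SITES = ("AA", "PDA", "DDA", "CA")


# ---------------------------------------------------------------------------
# waveforms


@dataclass
class WaveformSpec:
    """Analytic area waveform parameters for one plane."""

    a_min: float  # mm2
    a_max: float  # mm2
    t_foot: float = 80.0  # ms, systolic onset
    t_rise: float = 120.0  # ms, upstroke duration
    t_decay: float = 260.0  # ms, recoil duration
    cycle_ms: float = 870.0

    def __post_init__(self) -> None:
        if not self.a_max >= self.a_min > 0:
            raise ValueError("need a_max >= a_min > 0")
        if min(self.t_rise, self.t_decay, self.cycle_ms) <= 0 or self.t_foot < 0:
            raise ValueError("all durations must be positive")
        if self.t_foot + self.t_rise + self.t_decay > self.cycle_ms:
            raise ValueError("rise + decay must fit within the cycle")

    @property
    def delta_s(self) -> float:
        return self.a_max - self.a_min

    @property
    def mrsd(self) -> float:
        """Closed-form maximum systolic upslope, mm2/ms."""
        if self.delta_s == 0:
            return 0.0
        return self.delta_s * np.pi / (2.0 * self.t_rise)

    @property
    def mrdr(self) -> float:
        """Closed-form maximum diastolic downslope (signed), mm2/ms."""
        if self.delta_s == 0:
            return 0.0
        return -self.delta_s * np.pi / (2.0 * self.t_decay)

    def area_at(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        a = np.full(t.shape, self.a_min)
        t1 = self.t_foot
        t2 = t1 + self.t_rise
        t3 = t2 + self.t_decay
        rising = (t >= t1) & (t < t2)
        a[rising] = self.a_min + 0.5 * self.delta_s * (1 - np.cos(np.pi * (t[rising] - t1) / self.t_rise))
        falling = (t >= t2) & (t < t3)
        a[falling] = self.a_min + 0.5 * self.delta_s * (1 + np.cos(np.pi * (t[falling] - t2) / self.t_decay))
        return a


@dataclass
class GroundTruth:
    """Everything the generators know, recomputable in closed form."""

    params: dict = field(default_factory=dict)
    areas_mm2: np.ndarray | None = None
    delta_s: float | None = None
    a_min: float | None = None
    a_max: float | None = None
    strain: float | None = None
    mrsd: float | None = None
    mrdr: float | None = None
    ac: float | None = None
    ad: float | None = None
    pp: float | None = None
    delay_ms: float | None = None
    length_mm: float | None = None
    seed: int | None = None


def make_area_waveform(spec: WaveformSpec, times: np.ndarray, site: str = "AA",
                       condition: str = "rest") -> AreaCurve:
    """Sample the analytic waveform on an acquisition time grid (one cycle)."""
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times[0] < 0 or times[-1] > spec.cycle_ms:
        raise ValueError("times must lie within one cycle")
    return AreaCurve(times=times, areas=spec.area_at(times), site=site, condition=condition)


def waveform_truth(spec: WaveformSpec, pp: float | None = None) -> GroundTruth:
    gt = GroundTruth(
        params={"waveform": spec.__dict__.copy()},
        delta_s=spec.delta_s,
        a_min=spec.a_min,
        a_max=spec.a_max,
        strain=spec.delta_s / spec.a_min,
        mrsd=spec.mrsd,
        mrdr=spec.mrdr,
    )
    if pp is not None:
        gt.pp = pp
        gt.ac = spec.delta_s / pp
        gt.ad = gt.ac / spec.a_min
    return gt


# ---------------------------------------------------------------------------
# cine rendering


@dataclass
class PhantomConfig:
    image_size: int = 128  # px, square
    pixel_mm: float = 1.0
    n_frames: int = 35
    lumen_intensity: float = 1.0  # bright-blood SSFP-like contrast
    wall_intensity: float = 0.4
    background_intensity: float = 0.2
    wall_thickness_mm: float = 2.5
    blur_sigma_px: float = 0.8
    noise_sd: float = 0.0
    center_xy: tuple[float, float] | None = None  # defaults to image center
    ellipticity: float = 1.0  # minor/major axis ratio; 1 = circle
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")
        if not 0 < self.ellipticity <= 1.5:
            raise ValueError("ellipticity must be in (0, 1.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.center_xy is None:
            self.center_xy = ((self.image_size - 1) / 2.0, (self.image_size - 1) / 2.0)


_OVERSAMPLE = 4  # sub-pixel grid for anti-aliased coverage


def _coverage(cx: float, cy: float, ax_px: float, bx_px: float, size: int) -> np.ndarray:
    """Fraction of each pixel inside the axis-aligned ellipse (a along x)."""
    n = size * _OVERSAMPLE
    coords = (np.arange(n) + 0.5) / _OVERSAMPLE - 0.5  # pixel-center convention
    x = coords[np.newaxis, :]
    y = coords[:, np.newaxis]
    inside = ((x - cx) / ax_px) ** 2 + ((y - cy) / bx_px) ** 2 <= 1.0
    return inside.reshape(size, _OVERSAMPLE, size, _OVERSAMPLE).mean(axis=(1, 3))


def render_cine(
    spec: WaveformSpec, cfg: PhantomConfig, pp: float | None = None
) -> tuple[CineSeries, GroundTruth]:
    """Render a cine stack of a pulsating elliptical lumen.

    Per frame: anti-aliased lumen of the analytic area on a wall annulus over
    background, Gaussian-blurred, plus seeded additive Gaussian noise.
    Negative intensities after noise are clipped to zero (count logged in the
    ground truth).
    """
    times = np.arange(cfg.n_frames) * (spec.cycle_ms / cfg.n_frames)
    areas = spec.area_at(times)
    # semi-axes in mm: area = pi * a * b, b = ellipticity * a
    a_major_mm = np.sqrt(areas / (np.pi * cfg.ellipticity))
    max_r_px = (a_major_mm.max() + cfg.wall_thickness_mm) / cfg.pixel_mm
    cx, cy = cfg.center_xy
    margin = min(cx, cy, cfg.image_size - 1 - cx, cfg.image_size - 1 - cy)
    if max_r_px > margin - 3:
        raise ValueError("vessel (incl. wall) must fit inside the image with a 3-pixel margin")

    rng = np.random.default_rng(cfg.seed)
    frames = np.empty((cfg.n_frames, cfg.image_size, cfg.image_size))
    for f in range(cfg.n_frames):
        a_px = a_major_mm[f] / cfg.pixel_mm
        b_px = a_px * cfg.ellipticity
        wall_px = cfg.wall_thickness_mm / cfg.pixel_mm
        cov_outer = _coverage(cx, cy, a_px + wall_px, b_px + wall_px, cfg.image_size)
        cov_lumen = _coverage(cx, cy, a_px, b_px, cfg.image_size)
        img = (
            cfg.background_intensity
            + (cfg.wall_intensity - cfg.background_intensity) * cov_outer
            + (cfg.lumen_intensity - cfg.wall_intensity) * cov_lumen
        )
        if cfg.blur_sigma_px > 0:
            img = ndimage.gaussian_filter(img, cfg.blur_sigma_px)
        frames[f] = img
    clipped = 0
    if cfg.noise_sd > 0:
        frames = frames + rng.normal(0.0, cfg.noise_sd, size=frames.shape)
        clipped = int(np.sum(frames < 0))
        np.clip(frames, 0.0, None, out=frames)

    series = CineSeries(
        frames=frames,
        pixel_mm=cfg.pixel_mm,
        frame_times=times,
        plane="phantom",
        provenance={"generator": "render_cine", "seed": cfg.seed},
    )
    gt = waveform_truth(spec, pp)
    gt.params["phantom"] = {**cfg.__dict__, "center_xy": list(cfg.center_xy)}
    gt.params["clipped_negative_px"] = clipped
    gt.areas_mm2 = areas
    gt.seed = cfg.seed
    return series, gt


def render_velocity(
    cfg: PhantomConfig,
    peak_velocity: float = 1.0,  # mm/ms at vessel axis, at pulse peak
    lumen_area_mm2: float = 400.0,
    onset_ms: float = 80.0,
    width_ms: float = 300.0,
    cycle_ms: float = 870.0,
    venc: float = 2.0,
) -> tuple[VelocitySeries, GroundTruth]:
    """Through-plane velocity stack with a parabolic (Poiseuille) profile.

    The axial velocity follows a half-sine pulse in time; the spatial profile
    is v_peak*(1 - rho^2) inside a fixed circular lumen.  Closed-form flow:
    integral v dA = v_axis * A / 2.
    """
    times = np.arange(cfg.n_frames) * (cycle_ms / cfg.n_frames)
    v_axis = np.zeros(cfg.n_frames)
    in_pulse = (times >= onset_ms) & (times <= onset_ms + width_ms)
    v_axis[in_pulse] = peak_velocity * np.sin(np.pi * (times[in_pulse] - onset_ms) / width_ms)
    r_mm = np.sqrt(lumen_area_mm2 / np.pi)
    cx, cy = cfg.center_xy
    yy, xx = np.indices((cfg.image_size, cfg.image_size), dtype=float)
    rho2 = ((xx - cx) ** 2 + (yy - cy) ** 2) * cfg.pixel_mm**2 / r_mm**2
    profile = np.where(rho2 <= 1.0, 1.0 - rho2, 0.0)
    frames = v_axis[:, np.newaxis, np.newaxis] * profile[np.newaxis]
    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_sd > 0:
        frames = frames + rng.normal(0.0, cfg.noise_sd, size=frames.shape)
    np.clip(frames, -venc, venc, out=frames)
    series = VelocitySeries(
        frames=frames, venc=venc, pixel_mm=cfg.pixel_mm, frame_times=times,
        plane="phantom", provenance={"generator": "render_velocity", "seed": cfg.seed},
    )
    gt = GroundTruth(
        params={
            "peak_velocity": peak_velocity, "lumen_area_mm2": lumen_area_mm2,
            "onset_ms": onset_ms, "width_ms": width_ms,
        },
        seed=cfg.seed,
    )
    gt.params["true_flow_mm3_per_ms"] = list(v_axis * lumen_area_mm2 / 2.0)
    return series, gt


# ---------------------------------------------------------------------------
# flow pulse pairs


@dataclass
class FlowPulseSpec:
    """Half-sine systolic pulse over a flat zero baseline."""

    peak: float = 300.0  # mm3/ms
    onset_ms: float = 100.0
    width_ms: float = 300.0
    cycle_ms: float = 900.0

    def __post_init__(self) -> None:
        if self.peak <= 0 or self.width_ms <= 0 or self.onset_ms < 0:
            raise ValueError("peak and width must be positive, onset non-negative")
        if self.onset_ms + self.width_ms > self.cycle_ms:
            raise ValueError("pulse must fit within the cycle")

    def at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.zeros(t.shape)
        inside = (t >= self.onset_ms) & (t <= self.onset_ms + self.width_ms)
        y[inside] = self.peak * np.sin(np.pi * (t[inside] - self.onset_ms) / self.width_ms)
        return y


def make_flow_pair(
    delay_ms: float,
    base_shape: FlowPulseSpec | None = None,
    sampling_ms: float = 28.0,
    attenuation: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FlowCurve, FlowCurve, GroundTruth]:
    """Proximal pulse and a copy delayed by exactly ``delay_ms``.

    Both are sampled on the same acquisition grid, so a sub-sample delay is
    preserved in truth even when it cannot be read off the raw samples.  The
    distal curve may be amplitude-attenuated; optional seeded Gaussian noise
    is added independently to both.
    """
    base_shape = base_shape or FlowPulseSpec()
    if delay_ms < 0:
        raise ValueError("delay must be non-negative")
    if sampling_ms <= 0:
        raise ValueError("sampling_ms must be positive")
    if base_shape.onset_ms + delay_ms + base_shape.width_ms > base_shape.cycle_ms:
        raise ValueError("delay pushes the distal pulse outside the cycle")
    times = np.arange(0.0, base_shape.cycle_ms + 0.5 * sampling_ms, sampling_ms)
    prox = base_shape.at(times)
    dist = attenuation * base_shape.at(times - delay_ms)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        prox = prox + rng.normal(0.0, noise_sd, size=times.shape)
        dist = dist + rng.normal(0.0, noise_sd, size=times.shape)
    gt = GroundTruth(
        params={"pulse": base_shape.__dict__.copy(), "sampling_ms": sampling_ms,
                "attenuation": attenuation, "noise_sd": noise_sd},
        delay_ms=float(delay_ms),
        seed=seed,
    )
    return (
        FlowCurve(times, prox, plane="proximal"),
        FlowCurve(times.copy(), dist, plane="distal"),
        gt,
    )


# ---------------------------------------------------------------------------
# centerline stacks


@dataclass
class ArcSpec:
    """Centerline geometry: a straight segment or a circular arc.

    ``line``: ``length_mm`` along +z.  ``arc``: circle of ``radius_mm`` swept
    by ``angle_rad`` in the x-z plane (pi = semicircle).
    """

    kind: str = "line"
    length_mm: float = 54.0
    radius_mm: float = 75.0
    angle_rad: float = float(np.pi)

    def __post_init__(self) -> None:
        if self.kind not in ("line", "arc"):
            raise ValueError("kind must be 'line' or 'arc'")
        if self.kind == "line" and self.length_mm <= 0:
            raise ValueError("length_mm must be positive")
        if self.kind == "arc" and (self.radius_mm <= 0 or not 0 < self.angle_rad <= np.pi):
            raise ValueError("need radius_mm > 0 and angle in (0, pi] (z must stay monotone)")


def make_centerline_stack(arc: ArcSpec, slice_gap_mm: float = 6.0) -> tuple[np.ndarray, GroundTruth]:
    """Centerline points on slices ``slice_gap_mm`` apart, plus analytic length.

    Slices are perpendicular to z; the user marks one center point per slice,
    which this emulates exactly (points lie on the analytic curve).
    """
    if slice_gap_mm <= 0:
        raise ValueError("slice_gap_mm must be positive")
    def _slice_positions(extent: float) -> np.ndarray:
        z = np.arange(0.0, extent + 1e-9, slice_gap_mm)
        if z.size < 2:
            raise ValueError("need at least 2 slices; extent shorter than one slice gap")
        if extent - z[-1] > 1e-6:  # a final slice is placed at the distal level itself
            z = np.append(z, extent)
        return z

    if arc.kind == "line":
        z = _slice_positions(arc.length_mm)
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        true_len = float(z[-1] - z[0])
    else:
        # arc in x-z plane: z = r*(1-cos(theta)), x = r*sin(theta), theta in [0, angle]
        z_max = arc.radius_mm * (1 - np.cos(min(arc.angle_rad, np.pi)))
        z = _slice_positions(z_max)
        theta = np.arccos(np.clip(1 - z / arc.radius_mm, -1.0, 1.0))
        x = arc.radius_mm * np.sin(theta)
        pts = np.column_stack([x, np.zeros_like(z), z])
        true_len = float(arc.radius_mm * arc.angle_rad)
    gt = GroundTruth(params={"arc": arc.__dict__.copy(), "slice_gap_mm": slice_gap_mm},
                     length_mm=true_len)
    return pts, gt


# ---------------------------------------------------------------------------
# cohort simulation

_DEFAULT_REST_MEDIANS = {
    # site -> metric -> rest median (scale of the published cohort)
    "AA": {"ac": 2.63, "ad": 6.0e-3, "a_max": 581.3, "a_min": 447.2, "mrsd": 2.03, "mrdr": -0.71},
    "PDA": {"ac": 1.33, "ad": 5.83e-3, "a_max": 301.2, "a_min": 240.3, "mrsd": 0.88, "mrdr": -0.36},
    "DDA": {"ac": 1.36, "ad": 7.38e-3, "a_max": 250.0, "a_min": 183.1, "mrsd": 0.81, "mrdr": -0.38},
    "CA": {"ac": 1.34, "ad": 7.4e-3, "a_max": 241.3, "a_min": 172.3, "mrsd": 0.94, "mrdr": -0.44},
}

_DEFAULT_STRESS_MULT = {"ac": 0.68, "ad": 0.75, "a_max": 0.97, "a_min": 0.95,
                        "mrsd": 1.9, "mrdr": 1.9}


@dataclass
class CohortSpec:
    n_subjects: int = 15
    sites: tuple[str, ...] = SITES
    rest_medians: dict = field(default_factory=lambda: {s: dict(m) for s, m in _DEFAULT_REST_MEDIANS.items()})
    stress_multipliers: dict = field(default_factory=lambda: dict(_DEFAULT_STRESS_MULT))
    hr_rest: tuple[float, float] = (69.0, 9.0)  # mean, sd (bpm)
    hr_stress: tuple[float, float] = (127.0, 17.0)
    sbp_rest: tuple[float, float] = (122.0, 9.3)  # mean, sd (mmHg)
    sbp_stress: tuple[float, float] = (153.0, 12.0)
    pp_rest: tuple[float, float] = (50.0, 7.0)
    pp_stress: tuple[float, float] = (74.0, 11.0)
    subject_sigma: float = 0.18  # log-sd of the per-subject multiplier
    noise_sigma: float = 0.10  # log-sd of per-measurement noise
    rpp_ad_rank_corr: float = -0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        if any(m <= 0 for m in self.stress_multipliers.values()):
            raise ValueError("stress multipliers must be positive")
        if not -1 <= self.rpp_ad_rank_corr <= 1:
            raise ValueError("rank correlation must be in [-1, 1]")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Tidy table of (subject, condition, site, metric, value) records.

    Per-metric values are lognormal around the site medians with a shared
    per-subject effect (paired design) times per-measurement noise; the
    stress condition applies the configured multipliers.  Distensibility is
    additionally coupled to a latent cardiac-drive variable shared with HR
    and SBP through a Gaussian copula, so that the rank correlation between
    the rate-pressure product and AD approximates ``rpp_ad_rank_corr``.
    Hemodynamic metrics (hr, sbp, pp, rpp) are site-independent and recorded
    under site "ALL".
    """
    rng = np.random.default_rng(spec.seed)
    rho_s = spec.rpp_ad_rank_corr
    # Spearman -> Pearson for a Gaussian copula, mildly inflated to offset
    # the attenuation from the independent SBP noise share.
    rho_p = float(np.clip(2 * np.sin(np.pi * rho_s / 6) * 1.05, -0.999, 0.999))

    rows: list[tuple] = []
    metric_names = list(next(iter(spec.rest_medians.values())).keys())
    subj_effect = {
        m: rng.normal(0.0, spec.subject_sigma, size=spec.n_subjects) for m in metric_names
    }
    for cond in ("rest", "stress"):
        hr_mu, hr_sd = spec.hr_rest if cond == "rest" else spec.hr_stress
        sbp_mu, sbp_sd = spec.sbp_rest if cond == "rest" else spec.sbp_stress
        pp_mu, pp_sd = spec.pp_rest if cond == "rest" else spec.pp_stress
        for i in range(spec.n_subjects):
            # latent AD driver (subject effect + noise, standardised) and the
            # correlated cardiac-drive latent
            v = rng.normal()
            w = rho_p * v + np.sqrt(1 - rho_p**2) * rng.normal()
            hr = max(30.0, hr_mu + hr_sd * w)
            sbp = max(60.0, sbp_mu + sbp_sd * (0.7 * w + 0.3 * rng.normal()))
            pp = max(10.0, pp_mu + pp_sd * rng.normal())
            rows.append((i, cond, "ALL", "hr", hr))
            rows.append((i, cond, "ALL", "sbp", sbp))
            rows.append((i, cond, "ALL", "pp", pp))
            rows.append((i, cond, "ALL", "rpp", hr * sbp))
            for site in spec.sites:
                medians = spec.rest_medians[site]
                for metric, med in medians.items():
                    mult = 1.0 if cond == "rest" else spec.stress_multipliers.get(metric, 1.0)
                    if metric == "ad":
                        # AD rides directly on the copula latent v
                        value = med * mult * np.exp(spec.noise_sigma * v)
                    else:
                        z = subj_effect[metric][i] + rng.normal(0.0, spec.noise_sigma)
                        value = med * mult * np.exp(z)
                    rows.append((i, cond, site, metric, float(value)))
    frame = pd.DataFrame(rows, columns=["subject", "condition", "site", "metric", "value"])
    return frame
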