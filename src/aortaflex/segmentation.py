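"""Automatic lumen contour tracing on cine frames.

The tracer needs a single user-supplied point near the vessel center on the
first frame.  Each frame is processed as: edge enhancement (facet-model
second-directional-derivative operator, then Gaussian smoothing, then a
contrast stretch), resampling of the edge map into polar coordinates around
the current center, and a globally optimal closed path through the polar map
found by dynamic programming with a per-angle-step radius-jump bound.  The
next frame reuses the previous contour's centroid as its center, so the whole
cycle is segmented from one click.

Radii are localised to sub-sample precision by parabolic interpolation of the
edge profile around the DP optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import CineSeries

# ---------------------------------------------------------------------------
# edge enhancement


def _facet_kernels() -> dict[str, np.ndarray]:
    """5x5 least-squares kernels for the bicubic facet model coefficients."""
    r, c = np.meshgrid(np.arange(-2, 3), np.arange(-2, 3), indexing="ij")
    r = r.ravel().astype(float)
    c = c.ravel().astype(float)
    basis = np.stack(
        [np.ones_like(r), r, c, r * r, r * c, c * c, r**3, r * r * c, r * c * c, c**3],
        axis=1,
    )
    proj = np.linalg.pinv(basis)  # (10, 25)
    names = ["k1", "kr", "kc", "krr", "krc", "kcc", "k7", "k8", "k9", "k10"]
    return {n: proj[i].reshape(5, 5) for i, n in enumerate(names)}


_KERNELS = _facet_kernels()


def enhance_edges(
    image: np.ndarray, method: str = "haralick", smooth_sigma: float = 1.0
) -> np.ndarray:
    """Non-negative edge-strength map, contrast-stretched to [0, 1].

    ``haralick``: cubic-facet first-directional-derivative magnitude, gated by
    a zero crossing of the second directional derivative along the gradient
    direction.  ``gradient``: plain Sobel magnitude.  Either response is then
    Gaussian-smoothed by ``smooth_sigma`` and stretched.  A constant image
    maps to all zeros.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite intensities")
    if np.ptp(image) == 0:
        return np.zeros_like(image)  # constant image: no edges, valid

    if method == "haralick":
        coef = {n: ndimage.correlate(image, k, mode="nearest") for n, k in _KERNELS.items()}
        grad = np.hypot(coef["kr"], coef["kc"])
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(grad > 0, coef["kr"] / np.maximum(grad, 1e-12), 0.0)
            c = np.where(grad > 0, coef["kc"] / np.maximum(grad, 1e-12), 0.0)
        # second directional derivative along the gradient direction
        f2 = 2.0 * (coef["krr"] * s * s + coef["krc"] * s * c + coef["kcc"] * c * c)
        rows, cols = np.indices(image.shape, dtype=float)
        f2_ahead = ndimage.map_coordinates(f2, [rows + s, cols + c], order=1, mode="nearest")
        f2_behind = ndimage.map_coordinates(f2, [rows - s, cols - c], order=1, mode="nearest")
        crossing = f2_ahead * f2_behind <= 0
        response = grad * np.where(crossing, 1.0, 0.3)
    elif method == "gradient":
        response = np.hypot(ndimage.sobel(image, axis=0), ndimage.sobel(image, axis=1))
    else:
        raise ValueError(f"unknown edge method: {method!r}")

    if smooth_sigma > 0:
        response = ndimage.gaussian_filter(response, smooth_sigma)
    peak = response.max()
    if peak <= 0:
        return np.zeros_like(response)
    return response / peak


# ---------------------------------------------------------------------------
# polar resampling


@dataclass
class PolarMap:
    """Intensities resampled on an (angle, radius) grid around a center."""

    samples: np.ndarray  # (n_angles, n_radii)
    angles: np.ndarray  # rad, uniform over [0, 2pi)
    radii: np.ndarray  # px from center, uniform step
    center_xy: tuple[float, float]
    out_of_image: np.ndarray  # bool mask, same shape as samples

    @property
    def n_angles(self) -> int:
        return self.samples.shape[0]

    @property
    def n_radii(self) -> int:
        return self.samples.shape[1]

    @property
    def radial_step(self) -> float:
        return float(self.radii[1] - self.radii[0]) if self.radii.size > 1 else float(self.radii[0])


def to_polar(
    image: np.ndarray,
    center_xy: tuple[float, float],
    n_angles: int = 180,
    n_radii: int = 60,
    radial_step: float = 0.5,
) -> PolarMap:
    """Bilinear resampling of ``image`` onto rays from ``center_xy``.

    Samples outside the image take the nearest edge value and are flagged in
    ``out_of_image``.
    """
    image = np.asarray(image, dtype=float)
    cx, cy = center_xy
    h, w = image.shape
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise ValueError("center must lie inside the image")
    angles = np.arange(n_angles) * (2 * np.pi / n_angles)
    radii = (np.arange(n_radii) + 1.0) * radial_step
    xs = cx + radii[np.newaxis, :] * np.cos(angles[:, np.newaxis])
    ys = cy + radii[np.newaxis, :] * np.sin(angles[:, np.newaxis])
    samples = ndimage.map_coordinates(image, [ys, xs], order=1, mode="nearest")
    oob = (xs < 0) | (xs > w - 1) | (ys < 0) | (ys > h - 1)
    return PolarMap(samples, angles, radii, (float(cx), float(cy)), oob)


# ---------------------------------------------------------------------------
# contour representation


def polygon_area(x: np.ndarray, y: np.ndarray) -> float:
    """Shoelace area of a closed polygon given its vertices in order."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("a polygon needs at least 3 vertices")
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


@dataclass
class Contour:
    """Closed per-angle radius profile around a center, in pixel units."""

    angles: np.ndarray  # rad
    radii_px: np.ndarray  # px, > 0
    center_xy: tuple[float, float]  # px
    pixel_mm: float = 1.0
    closed: bool = True

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.radii_px = np.asarray(self.radii_px, dtype=float)
        if np.any(self.radii_px <= 0):
            raise ValueError("contour radii must be positive")

    def vertices_px(self) -> tuple[np.ndarray, np.ndarray]:
        x = self.center_xy[0] + self.radii_px * np.cos(self.angles)
        y = self.center_xy[1] + self.radii_px * np.sin(self.angles)
        return x, y

    def vertices_mm(self) -> tuple[np.ndarray, np.ndarray]:
        x, y = self.vertices_px()
        return x * self.pixel_mm, y * self.pixel_mm

    @property
    def radii_mm(self) -> np.ndarray:
        return self.radii_px * self.pixel_mm

    @property
    def area_mm2(self) -> float:
        return contour_area(self)

    def centroid_px(self) -> tuple[float, float]:
        x, y = self.vertices_px()
        return float(x.mean()), float(y.mean())


def contour_area(contour: Contour, pixel_mm: float | None = None) -> float:
    """Polygon (shoelace) area of the contour vertices, mm2."""
    scale = contour.pixel_mm if pixel_mm is None else pixel_mm
    x, y = contour.vertices_px()
    return polygon_area(x * scale, y * scale)


@dataclass
class ContourSet:
    """One contour per cine frame plus acquisition timing and provenance."""

    contours: list[Contour]
    frame_times: np.ndarray
    provenance: dict = field(default_factory=dict)

    def areas_mm2(self) -> np.ndarray:
        return np.array([c.area_mm2 for c in self.contours])


# ---------------------------------------------------------------------------
# graph search


def find_contour(
    polar_edges: PolarMap,
    smoothness: int | None = 2,
    pixel_mm: float = 1.0,
    refine: bool = True,
) -> Contour:
    """Globally optimal closed radius profile through a polar edge map.

    Maximises the summed edge strength along one radius sample per angle,
    subject to ``|r(theta_{i+1}) - r(theta_i)| <= smoothness`` radial steps
    for every consecutive pair *including the wrap-around*.  The closure is
    enforced exactly by solving one dynamic program per candidate start
    radius and keeping the best; ties break toward the smaller radius.
    ``smoothness=None`` removes the constraint (columnwise argmax).
    """
    energy = np.asarray(polar_edges.samples, dtype=float)
    if energy.size == 0:
        raise ValueError("empty polar map")
    n_ang, n_rad = energy.shape

    if smoothness is None or n_ang == 1:
        idx = np.argmax(energy, axis=1)  # first (smallest-radius) maximum
    else:
        sm = int(smoothness)
        if sm < 0:
            raise ValueError("smoothness must be >= 0")
        idx = _closed_dp(energy, sm)

    radii = polar_edges.radii[idx].astype(float)
    if refine:
        step = polar_edges.radial_step
        for a in range(n_ang):
            r = idx[a]
            if 0 < r < n_rad - 1:
                lo, mid, hi = energy[a, r - 1], energy[a, r], energy[a, r + 1]
                denom = lo - 2 * mid + hi
                if denom < 0:
                    offset = 0.5 * (lo - hi) / denom
                    radii[a] += float(np.clip(offset, -1.0, 1.0)) * step
    return Contour(
        angles=polar_edges.angles.copy(),
        radii_px=radii,
        center_xy=polar_edges.center_xy,
        pixel_mm=pixel_mm,
    )


def _closed_dp(energy: np.ndarray, sm: int) -> np.ndarray:
    """Exact closed-path DP, vectorised over all start radii at once.

    State ``cost[s, r]`` is the best path value from angle 0 at radius ``s``
    to the current angle at radius ``r``.  Ties keep the smallest predecessor
    radius, so with np.argmax over (s, r) the smallest-radius solution wins.
    """
    n_ang, n_rad = energy.shape
    neg = -np.inf
    cost = np.full((n_rad, n_rad), neg)
    np.fill_diagonal(cost, energy[0])
    pred = np.zeros((n_ang, n_rad, n_rad), dtype=np.int16)

    offsets = np.arange(sm, -sm - 1, -1)
    for a in range(1, n_ang):
        best = np.full((n_rad, n_rad), neg)
        bestp = np.zeros((n_rad, n_rad), dtype=np.int16)
        for d in offsets:
            # candidate predecessor index p for target r: p = r - d; descending d
            # visits smaller p first, and strict > updates keep it on ties.
            p_lo = max(0, -d)
            p_hi = n_rad - max(0, d)
            if p_lo >= p_hi:
                continue
            tgt = slice(p_lo + d, p_hi + d)
            src = slice(p_lo, p_hi)
            cand = cost[:, src]
            upd = cand > best[:, tgt]
            best[:, tgt][upd] = cand[upd]
            bp = bestp[:, tgt]
            bp[upd] = (np.arange(p_lo, p_hi, dtype=np.int16)[np.newaxis, :] * np.ones((n_rad, 1), dtype=np.int16))[upd]
            bestp[:, tgt] = bp
        cost = best + energy[a][np.newaxis, :]
        pred[a] = bestp

    # wrap-around closure: end radius within sm of the start radius
    close_ok = np.abs(np.arange(n_rad)[np.newaxis, :] - np.arange(n_rad)[:, np.newaxis]) <= sm
    final = np.where(close_ok, cost, neg)
    if not np.isfinite(final).any():
        raise ValueError(f"no feasible closed path under smoothness bound {sm}")
    flat = int(np.argmax(final))
    s, r = divmod(flat, n_rad)
    path = np.empty(n_ang, dtype=int)
    path[-1] = r
    for a in range(n_ang - 1, 0, -1):
        path[a - 1] = pred[a, s, path[a]]
    return path


# ---------------------------------------------------------------------------
# frame-to-frame driver


@dataclass
class SegmentationParams:
    n_angles: int = 180
    radial_step: float = 0.5  # px
    max_radius_frac: float = 0.4  # of min image dimension
    smoothness: int = 2  # radial steps per angle step
    edge_method: str = "haralick"
    smooth_sigma: float = 1.0
    refine: bool = True


def segment_series(
    cine: CineSeries,
    seed_point_xy: tuple[float, float],
    params: SegmentationParams | None = None,
) -> ContourSet:
    """Trace the lumen on every frame starting from one seed point.

    Frame 0 is segmented around ``seed_point_xy``; every later frame is
    segmented around the centroid of the previous contour.
    """
    params = params or SegmentationParams()
    h, w = cine.frames.shape[1:]
    max_radius = params.max_radius_frac * min(h, w)
    n_radii = max(4, int(max_radius / params.radial_step))
    min_area_px = 4 * cine.pixel_mm**2

    center = (float(seed_point_xy[0]), float(seed_point_xy[1]))
    contours: list[Contour] = []
    for f in range(cine.n_frames):
        if not (0 <= center[0] <= w - 1 and 0 <= center[1] <= h - 1):
            raise RuntimeError(f"frame {f}: contour centroid drifted outside the image")
        edges = enhance_edges(cine.frames[f], method=params.edge_method,
                              smooth_sigma=params.smooth_sigma)
        polar = to_polar(edges, center, n_angles=params.n_angles,
                         n_radii=n_radii, radial_step=params.radial_step)
        contour = find_contour(polar, smoothness=params.smoothness,
                               pixel_mm=cine.pixel_mm, refine=params.refine)
        if contour.area_mm2 < min_area_px:
            raise RuntimeError(f"frame {f}: contour area collapsed below 4 pixels")
        contours.append(contour)
        center = contour.centroid_px()
    return ContourSet(
        contours=contours,
        frame_times=cine.frame_times.copy(),
        provenance={
            "seed_point_xy": list(seed_point_xy),
            "params": params.__dict__.copy(),
        },
    )
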