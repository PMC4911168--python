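"""Shared fixtures and phantom-construction helpers."""

from __future__ import annotations

import numpy as np
import pytest

from aortaflex import phantom, segmentation


def disk_image(size: int = 64, radius: float = 15.0, center: tuple[float, float] | None = None,
               inside: float = 1.0, outside: float = 0.2) -> np.ndarray:
    """Hard-edged disk on a constant background (pixel-center membership)."""
    if center is None:
        center = ((size - 1) / 2.0, (size - 1) / 2.0)
    yy, xx = np.indices((size, size), dtype=float)
    return np.where((xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2,
                    inside, outside)


def circle_contour(radius_px: float, center_xy: tuple[float, float], n_angles: int = 180,
                   pixel_mm: float = 1.0) -> segmentation.Contour:
    angles = np.arange(n_angles) * 2 * np.pi / n_angles
    return segmentation.Contour(
        angles=angles, radii_px=np.full(n_angles, radius_px),
        center_xy=center_xy, pixel_mm=pixel_mm,
    )


@pytest.fixture(scope="session")
def rest_waveform() -> phantom.WaveformSpec:
    """Waveform matching the rest exemplar scale (delta area 147 mm2)."""
    return phantom.WaveformSpec(a_min=397.1, a_max=544.1)


@pytest.fixture(scope="session")
def small_cine(rest_waveform):
    """Noiseless 10-frame cine phantom plus its ground truth (session-cached)."""
    cfg = phantom.PhantomConfig(image_size=112, pixel_mm=0.8, n_frames=10,
                                noise_sd=0.0, seed=7)
    return phantom.render_cine(rest_waveform, cfg, pp=56.1) + (cfg,)


@pytest.fixture(scope="session")
def noisy_cine(rest_waveform):
    """SNR-20 cine phantom (noise sd = 5 % of lumen-background contrast)."""
    cfg = phantom.PhantomConfig(image_size=112, pixel_mm=0.8, n_frames=10,
                                noise_sd=0.04, seed=11)
    return phantom.render_cine(rest_waveform, cfg, pp=56.1) + (cfg,)
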