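"""End-to-end orchestration: simulate -> segment -> analyze -> pwv -> stats.

The pipeline exercises every stage on phantom data with known truth and
writes tidy CSV results plus a JSON manifest (config, seeds, versions).  It
is deterministic under a fixed config: rerunning produces byte-identical
result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import biomech, phantom, pwv, segmentation, stats


@dataclass
class RunConfig:
    """Every stage's parameters with defaults; round-trips through YAML."""

    seed: int = 0
    sites: tuple[str, ...] = ("AA", "PDA")
    conditions: tuple[str, ...] = ("rest", "stress")
    # phantom imaging
    image_size: int = 128
    pixel_mm: float = 0.8
    n_frames: int = 35
    noise_sd: float = 0.04
    blur_sigma_px: float = 0.8
    cycle_rest_ms: float = 870.0
    cycle_stress_ms: float = 480.0
    # pressures (sbp, dbp) per condition
    pressures: dict = field(default_factory=lambda: {
        "rest": [122.0, 72.0], "stress": [153.0, 79.0]})
    # segmentation
    n_angles: int = 180
    radial_step: float = 0.5
    smoothness: int = 2
    edge_method: str = "haralick"
    # biomech derivative estimation
    smoothing_window: int = 5
    smoothing_poly: int = 3
    rate_interp_ms: float = 2.0
    # pwv: segment label -> [length_mm, delay_rest_ms, delay_stress_ms]
    segments: dict = field(default_factory=lambda: {
        "AA/PDA": [190.0, 40.0, 34.0],
        "AA/DDA": [237.3, 61.0, 57.0],
        "AA/CA": [300.0, 77.0, 71.0],
    })
    flow_sampling_ms: float = 28.0
    transit_interp_ms: float = 1.0
    # stats
    bonferroni_family: int = 6
    cohort_n_subjects: int = 15
    cohort_stress_ac_multiplier: float = 0.68

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.sites = tuple(cfg.sites)
        cfg.conditions = tuple(cfg.conditions)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["sites"] = list(self.sites)
        data["conditions"] = list(self.conditions)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _site_waveform(site: str, condition: str, cfg: RunConfig) -> phantom.WaveformSpec:
    med = phantom._DEFAULT_REST_MEDIANS[site]
    mult = phantom._DEFAULT_STRESS_MULT
    a_min = med["a_min"] * (1.0 if condition == "rest" else mult["a_min"])
    a_max = med["a_max"] * (1.0 if condition == "rest" else mult["a_max"])
    cycle = cfg.cycle_rest_ms if condition == "rest" else cfg.cycle_stress_ms
    t_rise = 120.0 if condition == "rest" else 90.0
    t_decay = min(260.0, cycle - t_rise - 60.0 - 10.0)
    return phantom.WaveformSpec(
        a_min=a_min, a_max=a_max, t_foot=60.0, t_rise=t_rise, t_decay=t_decay, cycle_ms=cycle
    )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage on phantom inputs and write results under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seg_params = segmentation.SegmentationParams(
        n_angles=config.n_angles, radial_step=config.radial_step,
        smoothness=config.smoothness, edge_method=config.edge_method,
    )

    index_rows = []
    area_frames = []
    for ci, condition in enumerate(config.conditions):
        sbp, dbp = config.pressures[condition]
        pair = biomech.PressurePair(sbp, dbp, sbp, dbp)
        pp = biomech.pulse_pressure(pair)
        for si, site in enumerate(config.sites):
            spec = _site_waveform(site, condition, config)
            pcfg = phantom.PhantomConfig(
                image_size=config.image_size, pixel_mm=config.pixel_mm,
                n_frames=config.n_frames, noise_sd=config.noise_sd,
                blur_sigma_px=config.blur_sigma_px,
                seed=config.seed * 1000 + ci * 10 + si,
            )
            cine, truth = phantom.render_cine(spec, pcfg, pp=pp)
            contours = segmentation.segment_series(cine, pcfg.center_xy, seg_params)
            curve = biomech.AreaCurve(
                times=contours.frame_times, areas=contours.areas_mm2(),
                site=site, condition=condition,
            )
            idx = biomech.elastic_indices(
                curve, pp, smoothing_window=config.smoothing_window,
                interp_ms=config.rate_interp_ms, smoothing_poly=config.smoothing_poly,
            )
            area_frames.append(pd.DataFrame({
                "site": site, "condition": condition,
                "frame": np.arange(config.n_frames),
                "time_ms": curve.times, "area_mm2": curve.areas,
                "true_area_mm2": truth.areas_mm2,
            }))
            index_rows.append({
                "site": site, "condition": condition,
                "delta_s": idx.delta_s, "ac": idx.ac, "ad": idx.ad,
                "strain": idx.strain, "mrsd": idx.mrsd, "mrdr": idx.mrdr,
                "pp": idx.pp, "a_min": idx.a_min, "a_max": idx.a_max,
                "true_ac": truth.ac, "true_ad": truth.ad,
                "true_mrsd": truth.mrsd, "true_mrdr": truth.mrdr,
            })
    pd.concat(area_frames, ignore_index=True).to_csv(out / "areas.csv", index=False)
    indices = pd.DataFrame(index_rows)
    indices.to_csv(out / "indices.csv", index=False)

    pwv_rows = []
    for label, (length_mm, delay_rest, delay_stress) in config.segments.items():
        for condition, delay in (("rest", delay_rest), ("stress", delay_stress)):
            prox, dist, _ = phantom.make_flow_pair(
                delay_ms=delay, sampling_ms=config.flow_sampling_ms, seed=config.seed
            )
            for method, est in (
                ("foot", pwv.transit_time_foot), ("lsq", pwv.transit_time_lsq)
            ):
                tr = est(prox, dist, interp_ms=config.transit_interp_ms)
                res = pwv.compute_pwv(length_mm, tr.delta_t, segment=label,
                                      condition=condition, method=method)
                pwv_rows.append({
                    "segment": label, "condition": condition, "method": method,
                    "length_mm": length_mm, "delta_t_ms": tr.delta_t,
                    "true_delta_t_ms": delay, "pwv_m_per_s": res.pwv,
                })
    pd.DataFrame(pwv_rows).to_csv(out / "pwv.csv", index=False)

    cohort_spec = phantom.CohortSpec(
        n_subjects=config.cohort_n_subjects,
        stress_multipliers={**phantom._DEFAULT_STRESS_MULT,
                            "ac": config.cohort_stress_ac_multiplier},
        seed=config.seed,
    )
    cohort = phantom.simulate_cohort(cohort_spec)
    cohort.to_csv(out / "cohort.csv", index=False)

    comp_rows = []
    for metric in ("ac", "ad"):
        for condition in config.conditions:
            fr = stats.friedman_sites(cohort, metric, condition)
            comp_rows.append({"test": fr.test, "label": fr.label, "statistic": fr.statistic,
                              "p": fr.p, "p_adjusted": fr.p_adjusted, "n": fr.n})
        for site in phantom.SITES:
            wc = stats.wilcoxon_paired(cohort, metric, {"site": site},
                                       n_comparisons=config.bonferroni_family)
            comp_rows.append({"test": wc.test, "label": wc.label, "statistic": wc.statistic,
                              "p": wc.p, "p_adjusted": wc.p_adjusted, "n": wc.n})
    comparisons = pd.DataFrame(comp_rows)
    comparisons.to_csv(out / "comparisons.csv", index=False)

    summaries = pd.concat(
        [stats.summarize(cohort, m) for m in ("ac", "ad", "mrsd", "mrdr", "hr", "pp")],
        ignore_index=True,
    )
    summaries.to_csv(out / "summaries.csv", index=False)

    cfg_dict = dataclasses.asdict(config)
    cfg_dict["sites"] = list(config.sites)
    cfg_dict["conditions"] = list(config.conditions)
    cfg_blob = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "package": "aortaflex",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_blob.encode()).hexdigest(),
        "wall_time_s": round(time.time() - t0, 2),
        "outputs": ["areas.csv", "indices.csv", "pwv.csv", "cohort.csv",
                    "comparisons.csv", "summaries.csv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "indices": indices, "pwv": pd.DataFrame(pwv_rows), "cohort": cohort,
        "comparisons": comparisons, "summaries": summaries, "manifest": manifest,
    }
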