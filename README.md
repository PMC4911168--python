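# aortaflex

Rest/stress aortic function analysis on cine and velocity-encoded MRI,
re-implemented as a tested Python pipeline with a synthetic phantom
generator providing closed-form ground truth.

The pipeline covers:

* **phantom** — analytic area/flow waveforms, rendered cine and through-plane
  velocity stacks of a pulsating near-circular lumen (anti-aliased, blurred,
  seeded noise), centerline slice stacks of known arc length, and a simulated
  15-subject rest/stress cohort with site-wise effects.
* **segmentation** — automatic lumen contour tracing from a single seed
  point: facet-model edge enhancement, polar resampling, and an exact
  closed-path dynamic program with a radius-jump smoothness bound;
  sub-sample radii by parabolic refinement.
* **biomech** — elastic indices from an area-time curve plus brachial
  pressures: delta area, compliance (mm²/mmHg), distensibility (mmHg⁻¹),
  strain, and the maximum rates of systolic distension / diastolic recoil
  (mm²/ms).
* **pwv** — segmental pulse wave velocity from paired flow curves: two
  transit-time estimators (foot-of-wave regression intercept and
  least-squares upslope alignment after peak normalisation), centerline
  length, and tonometric cfPWV (D/Δt).
* **stats** — Friedman, paired Wilcoxon with Bonferroni correction (exact
  small-sample null distributions), Spearman correlation, Bland-Altman
  agreement, and normality-gated summaries.
* **io / pipeline / cli** — NIfTI and TIFF+JSON series containers, tidy CSV
  tables, a deterministic end-to-end demo pipeline, and a Typer CLI.

Units everywhere: mm, mm², ms, mmHg; PWV in m/s (numerically mm/ms).

## CLI

```bash
aortaflex simulate cine --seed 1 --out work/          # phantom cine + truth
aortaflex segment --in work/cine.nii.gz --seed-x 63.5 --seed-y 63.5 --out work/seg
aortaflex analyze --areas work/seg/areas.csv --pressures pressures.json --out work/indices.csv
aortaflex simulate flow --seed 1 --out work/          # delayed flow pair
aortaflex pwv --proximal work/flow_proximal.csv --distal work/flow_distal.csv \
              --length-mm 237.3 --method foot --out work/pwv.csv
aortaflex simulate cohort --seed 1 --out work/        # rest/stress study table
aortaflex stats --table work/cohort.csv --out work/stats
aortaflex run --out work/full                         # whole demo pipeline
```

`aortaflex run` accepts a YAML config mirroring
`aortaflex.pipeline.RunConfig`; every stage parameter has a logged default
and reruns are byte-identical given the same config.

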