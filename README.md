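# circaquant

Circadian rhythm quantification for fluorescence-based phagocytosis assays
and proteoglycan (PG) disaccharide profiling.

Macrophage uptake of amyloid-beta (Aβ42) and the cell-surface levels of
heparan/chondroitin sulfate proteoglycans both oscillate over the circadian
day, in antiphase to one another. Demonstrating that requires a chain of
quantitative steps: measuring per-cell fluorescence in micrographs,
filtering and transforming the intensities, fitting a damped-cosine
oscillator to time courses sampled every 4 h after serum-shock
synchronization, gating the fit with multiple-testing-adjusted p-values,
judging group contrasts jointly by p-value and effect size, and
normalizing mass-spec disaccharide amounts to nanograms per cell through a
DNA-dye standard curve. `circaquant` implements that chain as a tested,
reusable Python package, together with a seeded synthetic-data generator
that produces every input with known ground truth.

It is intended for chronobiology and glycobiology labs analyzing
serum-shock time-course experiments, and for anyone who needs a
calibrated, scriptable damped-oscillator rhythm caller.

## The model

Each time series y(t), in hours post serum shock (PS), is fit by the
extended harmonic oscillator

```
y(t) = A · exp(−γ·(t−t0)) · cos(2π·(t−t0)/τ + φ) + C
```

with amplitude A, amplitude-change (AC) coefficient γ (h⁻¹; γ>0 damped,
γ<0 forced, γ≈0 harmonic), period τ (h), phase φ (rad) and equilibrium C,
after linear detrending and optional (1,2,1)/4 smoothing. A series is
called **circadian** only if

* 18 h ≤ τ ≤ 30 h,
* |γ| ≤ 0.15 h⁻¹, and
* the fit p-value and its Benjamini–Hochberg and Benjamini–Yekutieli
  adjustments (across all series analyzed together) are all < 0.05.

Two-group contrasts use Welch's unequal-variance t-test jointly with
Hedges' g (pooled-SD standardized mean difference with small-sample bias
correction): a contrast is significant only if p < α **and** |g| ≥ g_min
(defaults α = 0.05, g_min = 0.5) — a small effect negates a significant
p-value.

Time bases are convertible: sample index + 16 = PS hours, and circadian
time CT = PS − 12 (anchored by the PS20↔CT8 pairing of the reference
clock-gene phase).

## Worked example

Simulate an experiment (7 timepoints PS16–PS40 in triplicate, uptake
zenith at PS32; HS disaccharide rhythms peaking at PS20 in quadruplicate),
then run both analysis workflows:

```sh
circaquant simulate --seed 42 --out demo/sim
circaquant pg --pg-table demo/sim/pg_raw.csv \
              --standard-curve demo/sim/standard_curve.csv --out demo/pg
```

or, through the library:

```python
from circaquant.config import PipelineConfig
from circaquant.pipeline import run_pipeline

run_pipeline(PipelineConfig(workflow="simulate", output_dir="demo/sim", seed=42))
ph = run_pipeline(PipelineConfig(workflow="phagocytosis",
                                 input_dir="demo/sim/images",
                                 output_dir="demo/ph", seed=42))
pg = run_pipeline(PipelineConfig(workflow="proteoglycan",
                                 pg_table="demo/sim/pg_raw.csv",
                                 standard_curve="demo/sim/standard_curve.csv",
                                 output_dir="demo/pg", seed=42))
print(ph["summary"]["fits"][["circadian", "period", "p", "zenith_phase_ps"]])
print(pg["summary"]["fits"][["id", "circadian", "period", "zenith_phase_ps"]])
```

prints (seed 42):

```
   circadian     period         p  zenith_phase_ps
0       True  22.016956  0.000009        30.858779
         id  circadian     period  zenith_phase_ps
0     HS:0S       True  22.114571        20.095864
1     HS:NS       True  22.276016        19.944606
2   HS:TriS       True  22.480881        20.220391
3  HS:total       True  22.199201        20.073963
```

Both workflows recover circadian rhythms; the uptake zenith (~PS31) sits
~11 h from the heparan-sulfate zenith (~PS20) — the antiphase relationship
the synthetic experiment was built with (true separation 12 h; the small
shortfall reflects period bias at 7 timepoints, see `docs/methods.md`).
Each run directory contains per-stage CSVs, a text report and a
`manifest.json` recording the seed, config and input digests.

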