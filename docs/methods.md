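# Methods

## The rhythm model

All rhythm detection fits the extended harmonic oscillator

y(t) = A·exp(−γ(t−t₀))·cos(2π(t−t₀)/τ + φ) + C

to a series observed at hours post serum shock (PS). t₀ is the first
sampled time. Parameters and units:

| parameter | meaning | unit | default gate |
|---|---|---|---|
| A | amplitude | measurement units | A ≥ 0 (enforced by phase flip) |
| γ | amplitude-change (AC) coefficient | h⁻¹ | circadian requires \|γ\| ≤ 0.15 |
| τ | period | h | circadian requires 18 ≤ τ ≤ 30 |
| φ | phase | rad, reported in [0, 2π) | — |
| C | equilibrium | measurement units | — |

The AC bound is taken as inclusive and in h⁻¹ with the decay applied as
exp(−γ(t−t₀)); the threshold value is conventional, but its units and the
exact functional form were fixed here as a repository choice.

**Preprocessing.** A least-squares line over all observation points is
subtracted (free-run detrending); optionally the series is smoothed with a
centered (1,2,1)/4 moving average along each replicate's time-ordered
values, with endpoint weights renormalized over available neighbors. Both
steps default to on, matching the conventions the workflows assume. When a
workflow collapses replicates, the per-timepoint replicate means are taken
before smoothing. The smoothing kernel itself is a design choice; it
attenuates amplitude by a factor (1 + cos(2πΔ/τ))/2 at sampling interval Δ
and is one source of the period bias discussed under Limitations.

**Fitting.** For fixed (τ, φ, γ) the model is linear in (A, C), so the
multi-start search solves (A, C) in closed form on the grid
τ ∈ {18, 20, …, 30} × φ ∈ {0, π/2, π, 3π/2} × γ ∈ {−0.1, 0, 0.1}, then
polishes the three best starts with bounded trust-region least squares
(γ ∈ [−0.5, 0.5] h⁻¹, τ ∈ [max(2, span/20), 10·span], xtol 1e−10, at most
2000 evaluations per start). The constant model (A = 0, C = ȳ) is always a
retained candidate, so the returned SSE never exceeds the best constant
model's. A < 0 solutions are normalized by A → −A, φ → φ + π.

**Fit p-value.** The default is an F-test of the oscillator against the
constant model (df₁ = 4, df₂ = n − 5). When the curve is fitted to
collapsed timepoint means, the test is still evaluated against the
detrended replicate-resolved observations, so replicate noise contributes
residual degrees of freedom instead of being averaged away. The
alternative `pvalue_method="kendall"` — a one-sided exact Kendall
rank-correlation test of fitted versus observed values, the approach of
the published extended-oscillator tool this model family comes from — is
provided for comparability but is anti-conservative: it scores the fit on
its own training data, and a five-parameter oscillator fitted to a short
noise series almost always correlates positively with that series. On 200
flat-noise series of 13 timepoints, the Kendall default would call ~38%
circadian; the F-test default calls ≤ 5% before catalog gating and ~0%
after it. Neither test reproduces the original tool's p-values
numerically.

**Multiple testing.** Benjamini–Hochberg and Benjamini–Yekutieli step-up
adjustments are computed across the catalog of series fitted in one
invocation (all disaccharide species plus class totals, for example). The
circadian verdict requires raw, BH and BY p-values all below α = 0.05, on
top of the period and AC gates; reason codes name every failed gate.

**Zenith and nadir.** Reported two ways: the windowed argmax/argmin of the
fitted curve on a 0.01 h grid over the sampled window (flagged when an
extremum is clipped at a window boundary), and the carrier-phase zenith —
the analytic peak of the damped cosine, tan(θ*) = −γ/ω, folded into one
period. The second is the right quantity for phase comparisons between
fits: a fitted γ slightly below zero tilts the envelope upward so the
windowed argmax can land on the window edge rather than the carrier peak.
Times convert between bases as PS = index + 16 and CT = PS − 12.

## Two-group inference

Per-cell corrected intensities are preprocessed in a fixed single-pass
order: (1) values at or below the background signal are removed, (2)
survivors are log10-transformed (intensity dispersion is multiplicative),
(3) per timepoint, values outside the Tukey fences
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] of that timepoint's logged values are
removed. Quartiles use linear interpolation between order statistics; the
1.5 multiplier and the per-timepoint scope are documented conventions, and
a timepoint left with fewer than three values skips the fence step with a
flag. Contrasts are then judged by Welch's unequal-variance t-test
(two-sided; Welch–Satterthwaite df) together with signed Hedges' g
(pooled SD, bias-correction factor 1 − 3/(4(n₁+n₂) − 9)). Effect classes
use inclusive bands on |g|: ≥ 0.2 small, ≥ 0.5 medium, ≥ 0.8 large —
inclusive so the class boundary coincides with the joint gate |g| ≥ g_min.
A contrast is significant only when p < α and |g| ≥ g_min (defaults 0.05
and 0.5; a stricter g_min of 2.0 is appropriate for screening very large
cell-level samples, where p-values saturate).

## Image quantification

Objects are detected from a Gaussian-smoothed (σ = 1 px) Sobel gradient
magnitude thresholded at a fraction (default 0.25) of its maximum, closed
with a radius-2 disc, hole-filled, intersected with the global Otsu
foreground (so measured pixels are cell pixels, not edge halo), and
labeled. Components with area below `area_min` or above
`max_clump_size × area_max` are discarded; touching cells are kept as one
object whose clump size is ceil(area / area_max) capped at 4. Background
is the mean of sub-threshold pixels under Otsu's split; each object
reports area, mean, max, and background-corrected mean intensity. The
default size window (150–450 px² per cell) comes from the synthetic
generator's disc radius (~10 px) and must be recalibrated for real
micrographs, where cell size ratios depend on magnification.

## Proteoglycan normalization

Cell counts are back-calculated from CyQUANT-style fluorescence through an
OLS standard curve, count = dilution·(F − intercept)/slope, clamped at
zero with a flag for sub-intercept readings; cell-pellet amounts divide by
the count (ng/cell), while spent-media and ECM compartments stay in ng/ml,
and mixing units in one summary raises. Class totals sum all sulfation
codes of a class per sample; Z-score matrices standardize each species'
cross-replicate timepoint means with the sample (n−1) SD (constant rows
are zeroed and flagged). Per-species rhythm calls fit replicate-resolved
series (no collapsing) with BH/BY across every species fitted together;
species never detected (all zero) are excluded from fitting but contribute
zeros to totals.

## The synthetic-data generator

The generator emulates the study design end to end: scenes of hard-edged
discs (clumps of 1–4 rendered as chains of tangent discs, so clump area ≈
clump_size × single-cell area) on a uniform background with additive
Gaussian pixel noise; an uptake time course sampled every 4 h from PS16 to
PS40 in triplicate, with per-cell lognormal dispersion (default CV 0.10 —
a fixture parameter, not an estimate from real data) around a damped-
cosine mean clamped at zero; disaccharide tables over the HS/CS sulfation
vocabulary with rhythms peaking near PS20 in quadruplicate; a near-linear
fluorescence-vs-count standard curve; and a dense luminescence-style trace
for phase anchoring. Every generator is a pure function of its spec and
seed, ground truth is retained for every output, and negative draws are
clamped to zero with a recorded flag.

What the generator does **not** emulate: realistic optics (PSF,
bleed-through, uneven illumination), textured cells, 3-D stacks, partial
clump overlap beyond tangency, or the LC-MS quantification error
structure. Passing tests therefore demonstrate that the measurement and
inference chain recovers known truth under idealized imaging, not that the
segmentation defaults transfer to real micrographs.

## Problem sizes and measured behavior

The bundled checks use 50 series at the study design (7 timepoints,
triplicate, noise SD 10% of amplitude) for sensitivity, 200 flat-noise
series (13 timepoints over 48 h) for calibration, and 20 scenes of 12
objects for segmentation — sizes chosen so the whole suite reruns in well
under a minute of fitting time while keeping binomial uncertainty on the
measured rates a few percent.

## Known limitations

* **Period bias at sparse sampling.** With 7 timepoints spanning a single
  cycle, detrending plus (1,2,1)/4 smoothing biases the fitted period low
  by ~1.5–2 h (median fitted τ ≈ 22.3 h for a true 24 h rhythm). Rhythm
  verdicts and phase estimates are robust to this; period point estimates
  at the edge of the 18–30 h window are not.
* **No watershed splitting.** Touching cells are measured as clumps, as
  intended; cells touching at more than tangency merge into fewer, larger
  objects and can exceed the size window.
* **Zenith reporting near window edges.** The windowed argmax clips at the
  sampled window and is flagged; use the carrier-phase zenith for phase
  arithmetic.
* **The fit p-value is not the original tool's.** Results on real data
  will differ numerically from the published oscillator tool even where
  verdicts agree.
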