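# Methods

This note documents the models implemented in `scotomap`, the defaults and
why they were chosen, what the synthetic data generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Scotoma simulation from perimetry

Perimetric input is a grid of sensitivity deviations in decibels (≤ 0 is
loss) at visual-field test points; the shipped `layout_24_2()` provides the
54-point 24-2 pattern. Binocular integration takes, per location, the
maximum of the two eyes — the better eye dominates binocular detection of a
high-contrast stimulus. Loss maps to a contrast multiplier through the
decibel power convention `m = 10^(d/10)`, the only mapping consistent with
"−3 dB ⇒ 50% contrast" (10^(−0.3) = 0.501); positive deviations are clipped
to 1 because the simulation can attenuate but not boost native contrast.

Rasterization interpolates the **dB values** (not the multipliers) linearly
on the Delaunay triangulation of the test points and nearest-neighbor beyond
their convex hull, then applies the dB→contrast map pointwise. Interpolating
in dB keeps the mask inside [0, 1] without overshoot and is exact at the test
points. An optional `floor_db` (off by default) treats deviations at or
below a blindness threshold (clinically ≈ −15 dB) as zero contrast.

## Stimulus

The drifting-bar aperture movie uses the published run timing: bar width
1.75°, field radius 7°, 16 one-TR steps per full pass (24 s at TR 1.5 s),
followed by an 8-step half pass (12 s) and 12 s of blank; four full passes
(cardinal motion directions) interleaved with four truncated diagonal passes
give 128 design frames, preceded by 8 discardable dummy frames: 136 frames,
204 s. The exact interleaving of directions is not constrained by the run
timing and is a configuration default. The flickering checkerboard carrier
(0.5 cyc/°) is deliberately not rendered: pRF estimation operates on
apertures, so frames store contrast in [0, 1] and carrier parameters are
metadata. The default raster is 101 × 101 pixels over ±7° (≈ 0.14°/px),
balancing drive accuracy against fitting cost; cohort-scale statistical
analyses use a 41 × 41 raster (see "Problem sizes").

The scotoma-localizer preset reproduces only the published run length
(144 frames, 216 s) with a generic full-field on/off block design.

## Forward BOLD model

Per unit, the neural drive is the aperture-weighted Gaussian mass normalized
by the **full** Gaussian integral (2πσ² in pixel units). Normalizing by the
full rather than the on-raster mass keeps receptive fields that extend past
the stimulated field appropriately weak (a unit 3σ outside the field drives
< 1% of an in-field unit); for interior units the two normalizations agree to
discretization error. The HRF is the canonical double gamma (peak 5 s,
undershoot 15 s, ratio 6, 32 s support, peak-normalized), shared verbatim
between simulator and fitter so noiseless round trips are exact to machine
precision. Gains are expressed in percent signal at sustained full-field
drive (default 2.0%), which puts single-bar transients at realistic
sub-percent amplitudes.

Noise is AR(1) Gaussian (marginal SD `noise_sd`, coefficient 0.3) plus a
slow cosine drift at the run's lowest nonzero DCT frequency with per-unit
Gaussian amplitude (scale 0.1%), the minimal structure that the
discrete-cosine detrending step must contend with. Protocols acquire
several identical runs and average them before fitting (`n_runs`, default 4
as for the control conditions; the patient condition uses 6): signal repeats,
noise is drawn fresh per run.

**Reference noise.** `noise_sd = 0.25` was calibrated so that a single
simulated run of a default sheet, fitted by the conventional mapper, has a
median variance explained of ≈ 0.5 (measured 0.498 over three seeds at
n = 250/200) — the responsiveness regime reported for real early-visual-
cortex data. At this operating point the 4-run-average fit recovers
thresholded units with a median position error of 0.23° and a median
relative size error of −3% (signed; the absolute size scatter is ≈ 16%,
which a Cramér–Rao analysis of the 128-frame bar design shows is the
information floor, not an estimator deficiency).

## pRF estimation

Preprocessing drops the first 8 frames, converts to percent signal change
about the series mean (automatically skipped for data already centered), and
regresses out the discrete-cosine components below 0.001 Hz — on a single
192 s run only the constant survives that cutoff; longer series get a richer
basis.

Fitting is two-stage. The coarse stage scores every candidate on a 0.5°
(x₀, y₀) lattice over ±8° with σ ∈ {0.25, 0.5, 1, 1.5, 2, 3, 4}° by squared
prediction–data correlation (= VE with free amplitude and baseline),
computed efficiently by exploiting the separability of the isotropic
Gaussian (two small tensor contractions per σ instead of a raster sum per
candidate). Exact VE ties are broken toward smaller σ, then smaller
eccentricity, then (x₀, y₀) — the result is independent of candidate order.
The refine stage runs Nelder–Mead from the best candidate, bounded to ±10°
and σ ∈ [0.05, 10]°, and never reports a lower VE than the coarse optimum.
Zero-variance series yield a flagged degenerate record instead of an error.
Responsiveness thresholding keeps VE ≥ 0.15 and eccentricity 0–7°.

The scotoma-field (SF) variant differs from the full-field (FF) variant only
in the effective aperture (multiplied by the contrast mask); with an
all-ones mask the two code paths are bit-identical.

Micro-probing regresses a lattice of small fixed-σ Gaussians (0.5° probes at
1° spacing over the field) one at a time against each series, records the
per-probe VE as a weight, and summarizes each voxel by the weight-weighted
centroid and RMS spread. This is a deliberate simplification of the original
dense-probing technique, whose exact update rules are not reproduced here;
it preserves the property the reconstruction needs — weight mass
concentrated where the voxel samples the field.

## Visual-field reconstruction and normative maps

The sampling density at a field position is the VE-weighted sum of fitted
Gaussian receptive fields (β-weighting available), normalized to a maximum
of 1 and expressed as 10·log₁₀ (floor −40 dB) on a 0.25°-spaced disc lattice.
A subject map is classified per position by its empirical two-sided
percentile within the control group, using the boundary set
{90, 95, 98, 99, 99.5}% and reporting the outermost boundary violated. With
≈ 18 controls the 98–99.5% boundaries all saturate at the sample extremes
(a rank of 0 or n among 18 controls is beyond every boundary) — a
small-sample limitation inherited from the cohort size, documented rather
than smoothed away. The matched control (whose simulated scotoma corresponds
to the subject) is excluded from the norm. Under exchangeability a held-out
control lands outside the 5–95% band at 2/19 ≈ 10.5% of positions, which the
leave-one-out calibration test verifies.

## Pair-deviation statistics

Per-subject pRF properties become normalized histograms (eccentricity: 1°
bins over 0–7°; polar angle: 16 bins over [0, 2π); size: 0.5° bins over
0–6°). A pair's deviation is the per-bin signed difference with aggregate
Σ|Δ| (range [0, 2]); the glaucoma–control pair aggregate is mid-ranked
among the 18 leave-self-out control–control baselines, with one-sided
significance above the 95th percentile (so exactly rank 19 of 19 under the
null, giving a 1/19 ≈ 5.3% false-alarm rate; per-bin ranks are reported
alongside). The size bin width is the one genuinely free constructional
choice; 0.5° keeps ≈ 40 units per bin at n = 500 and was selected so the
statistic meets its intended operating characteristics (nominal null rate,
≥ 80% power against a ×1.5 single-quadrant size enlargement).

Severity correlations use `statsmodels` MixedLM with a random intercept and
slope per subject; degenerate designs (one subject, or fewer than two points
per subject) and non-converging fits fall back to OLS with a warning. The
reported r² carries the slope's sign. The group-level size comparison takes
per-participant median σ and a Welch t-test; identical groups return t = 0.

Quadrant assignment follows the polar convention θ = 0 at the upper vertical
meridian, increasing counterclockwise, with the upper-left quadrant spanning
(0, π/2]; each meridian belongs to the quadrant whose half-open interval it
closes.

## Fast analysis path (`sheet_to_models`)

Cohort-scale analyses (normative maps, rank calibration, power) would need
tens of thousands of refined fits per seeded replicate; instead, ground-truth
sheets are converted directly to model records with an analytically expected
VE — signal variance from the noiseless forward model divided by
signal-plus-noise variance, with noise variance reduced by the number of
averaged runs — and an optional estimation-noise perturbation (Gaussian
position scatter 0.19°/axis, lognormal size scatter 0.24) calibrated to the
mapper's measured recovery at reference noise. A cross-check with a real
(dense-grid) fitting pipeline showed the fast path does not overstate the
rank statistic's power. Full fitting is exercised directly by the recovery
and FF/SF tests.

## What the generator does and does not emulate

Emulated: eccentricity-dependent pRF size with lognormal scatter, uniform
field sampling, perimetry-linked gain loss with tunable exponent κ
(gain × (10^(d/10))^κ; κ = 1 by default — no quantitative link between dB
loss and BOLD gain is established empirically, so κ is a simulation knob,
not a biological estimate), shift/enlargement plasticity, HRF convolution, drift, AR(1)
noise, multi-run averaging, matched-pair cohort structure (19 pairs;
quadrant, arcuate and nasal-step scotoma archetypes of graded depth).

Not emulated: cortical magnification in unit density (available as neither
default nor requirement — binned analyses normalize counts), eye movements
and fixation instability, attention, session-to-session variability,
surface geometry and ROI delineation (sheets carry area labels directly),
and any retina-to-cortex nonlinearity beyond the gain law. Passing tests
therefore validate the analysis chain and its statistical calibration, not
the biological realism of any particular parameter value.

## Problem sizes

Unit and acceptance tests run on: 500-unit sheets for recovery (101 px
raster, 4 averaged runs), 19-subject cohorts at 500 units on a 41 px raster
for normative-map and rank analyses (200 null replicates, 50 power
replicates), and 300-unit 19-pair cohorts for the severity correlations.
These sizes reproduce the study's cohort dimensions while keeping a full
suite run in minutes on one CPU.
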