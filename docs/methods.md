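# Methods

## Overview

The package estimates sperm whale density and abundance from a
passive-acoustic line-transect survey and asks whether the population in the
surveyed area can sustain an observed rate of anthropogenic (ship-strike)
mortality. The chain is: biologging tag records → distributions of
echolocating/silent phase durations → Monte Carlo availability g(0);
towed-array bearings → perpendicular distances → detection function → ESHW;
then D̂ = n / (2 μ̂ L (1−o)) / g(0), N̂ = A·D̂, with propagated uncertainty
and the recruitment-vs-mortality comparison r_max·N̂ vs observed mortality.

## Vocal-availability model

A foraging sperm whale alternates between an **echolocating** phase of
duration t_e (regular "usual" clicks produced at depth) and a **silent**
phase t_ne (silent ascent + surface inter-dive interval + next silent
descent). Each whale is modelled as an independent *stationary alternating
renewal process* with i.i.d. phase draws from the pooled distributions.
Pooling across whales ignores within-whale autocorrelation of successive
cycles; the tagged-whale evidence is that dive cycling is highly stereotyped,
so the main consequence is a slight understatement of between-whale variance
in g(0), not of its mean.

A vessel travelling at speed v detects a whale on the track line iff the
whale is vocal at some instant while within ±ESHW along-track, i.e. during a
**detection window** of w = 2·ESHW/v (42.4 min at ESHW 4.168 km and
11.8 km/h). The simulator is event-driven: stationarity lets each whale's
window be identified with [0, w) of its own process, and since phases
alternate, the whale is missed *exactly* when its initial phase is silent
with residual life ≥ w. The initial phase is drawn from the equilibrium
state: echolocating with probability m_e/(m_e+m_ne), duration length-biased,
elapsed fraction uniform. Length-biased draws are exact for empirical
(probability ∝ duration) and exponential (Gamma(2, m)) sources, and by
capped rejection for parametric ones. Tests verify the collapsed rule
against an explicit interval-overlap detector and a 1-second time-stepped
brute force on the same phase timelines.

Each simulation run draws a track length L ~ U(100, 1000) km and a whale
count N ~ U{1..300}, places whales uniformly, and reports n/N; the estimate
is the mean over 2000 runs and its spread the across-run sd. The vessel path
is extended by one ESHW beyond each end of the line so every whale sees the
full window; with L ≥ 100 km the whales affected by the alternative
(truncated end windows) are < 5% of a run, and the extension removes an
arbitrary asymmetry. Because per-run N can be as small as 1, the across-run
sd is dominated by small-N binomial noise — that is the sd the estimate
reports, not the standard error of the mean (which is ~45× smaller at 2000
runs).

A closed form exists for exponential phases and anchors the simulator: the
whale is missed iff the window starts in a silent phase whose (memoryless)
residual exceeds w, so g(0) = 1 − [m_ne/(m_e+m_ne)]·e^(−w/m_ne).

## Phase-duration calibration

The tag generator and the parametric phase source share one calibration:

| quantity | family | default | rationale |
|---|---|---|---|
| echolocation period | log-normal, median 34 min, σ_log 0.10 | mean ≈ 34.2 min | matches the tagged-whale mean 34 min, range 25–45 |
| silent descent+ascent | log-normal, median 8 min, σ_log 0.30 | mean ≈ 8.4 min | per-whale medians 6–12 min |
| ordinary IDI | log-normal, median 9 min, σ_log 0.40 | mean ≈ 9.8 min | per-whale medians 8–12 min |
| extended rest | U(40, 180) min, probability 0.06 | mean 110 min | a handful of >100-min IDIs among ~80 cycles |

Together these give a silent-phase mean ≈ 24 min with range ~12–185 min, a
time budget of ~59% echolocating (inside the observed 55–65% band), and —
through the renewal model — g(0) ≈ 0.92 at the survey operating point. The
rest mixture is the load-bearing piece: ordinary silent phases almost never
exceed the 42-min window, so essentially all unavailability comes from the
rest tail (expected exceedance 0.06 × (110−42) min over a 58-min mean cycle
≈ 7–8%). Log-normals were chosen for right-skewed positive durations whose
published summaries are medians and ranges; only those summary statistics,
not the empirical histograms, are matched.

The generated depth trace is schematic (piecewise linear to 800 m): only
phase *timing* matters downstream, and the segmentation threshold (default
100 m, exposed) sits far below the surface and far above swell for any
plausible profile shape.

## Tag processing

A dive is a maximal excursion deeper than the threshold; the echolocation
period spans the first clicking sample to the first non-clicking sample
(end-exclusive, keeping discrete-grid duration errors under one sample
interval). t_ne runs from the end of one dive's clicking to the start of the
next dive's clicking, the stretch over which the whale is inaudible. Dives
without any clicking are retained as cycles but excluded from the usable
set; the first cycle after tagging and incomplete trailing cycles are
dropped by default (tag-reaction and censoring bias). Whales are pooled
per-cycle (each cycle one observation), not weighted per-whale.

## Localization

Bearings from a two-element towed array are conical: unsigned angles in
[0°, 180°] relative to the tow axis, ambiguous between port and starboard.
For each side hypothesis the bearing rays (anchored at the interpolated
vessel position, direction heading ± bearing) are intersected by linear
least squares — the point minimising the summed squared perpendicular
distances to the rays, the standard target-motion-analysis estimator and
robust to noise, unlike pairwise intersections. "Most coherent intersection"
is operationalised as the lower RMS point-to-ray residual; note that for a
*perfectly straight* track the two hypotheses are exact mirror images with
identical residuals, so side resolution relies on track curvature — the
perpendicular distance, which is all distance sampling consumes, is
identical either way. Gates: ≥ 2 bearings and ≥ 15° aperture (configurable);
below that the normal system is ill-conditioned and no fix is returned.
Geometry is planar in km; at a tens-of-km survey scale geodesic corrections
are far below bearing-noise effects.

Whales are assumed at the surface when crossing bearings. For a whale at
depth z and horizontal range x the resulting fractional over-estimate of
the perpendicular distance is (√(x²+z²)−x)/x — about 1.1% at z = 600 m,
x = 4 km — quantified by `surface_assumption_bias` and left uncorrected, as
it is negligible against the detection-function fit's variance.

## Detection function and ESHW

Keys: hazard-rate g(x) = 1−exp(−(x/σ)^−b) (b > 1) and half-normal; uniform
as a strip-transect reference. The conditional likelihood
Σ log[g(x_i)/μ(θ)], μ = ∫₀ʷ g, is maximised on (log σ, log(b−1)) with
L-BFGS-B from three deterministic starts (σ₀ ∈ {median, mean, w/2}) because
hazard-rate likelihoods can be multimodal at survey sample sizes. Exact
distances are used (no binning; 600-m bins only for plots). μ̂ is computed
by adaptive quadrature; its variance by delta method from the inverse
observed information (central-difference Hessian in natural parameters).
Model selection is minimum AIC, ties to fewer parameters. No series
adjustment terms are offered: the survey context selected a bare hazard-rate
key, and adjustments interact badly with the near-track dip produced by
surface-rotating dived whales, which the hazard-rate shoulder already
absorbs. Truncation default 9 km.

Flat (uniform-generated) data drive the half-normal σ̂ to the boundary of
identifiability; the fit then reports μ̂ ≈ w with a singular-information
warning rather than a spurious variance.

## Abundance and uncertainty

D̂ = n / (2 μ̂ L (1−o)) / g(0). The corner-overlap fraction o (area surveyed
twice at zigzag corners, with whales counted once) is applied as effort
deflation — the unique placement that reproduces the reference chain's
printed density from its printed n, μ̂, L. Encounter-rate variance uses the
between-transect estimator var(n/L) = K/(L²(K−1))·Σ l_k²(n_k/l_k − n/L)².
CVs combine in quadrature (encounter rate, ESHW, g0_sd/g0); intervals are
plain z = 1.96 log-normal, (est/C, est·C) with C = exp(z√ln(1+cv²)), with
no Satterthwaite df correction — reproducing published intervals to within
~1% (e.g. 2.29–7.83 vs a printed 2.27–7.89 per 1000 km², a known dialect
difference between implementations, documented rather than chased). All
intermediates stay unrounded; rounding happens once at report time.

Sustainability: maximum recruitment r_max·N̂ (r_max = 1.1%/yr for sperm
whale stocks) against observed annual mortality; the verdict is "exceeds"
when mortality ≥ recruitment. At N̂ = 224 the margin over a 2/yr stranding
rate is 0.5 whales/yr — nominally within capacity, but with no allowance
for undiscovered carcasses.

## What the synthetic data do and do not show

The generators reproduce the *statistical structure* the method rests on:
stereotyped dive cycling with a heavy rest tail, Poisson whale fields
thinned by a known detection function, conical bearings with Gaussian noise.
They do not emulate whale movement during the vessel pass (whales are
stationary, as the availability model assumes), acoustic propagation or
masking, group structure (distances are to individuals), or within-whale
correlation of successive dive cycles. Passing tests therefore demonstrate
the estimators are correct and calibrated *under the model's own
assumptions*, not that those assumptions hold for any particular ocean.

## Problem sizes and numerical choices

Test and analysis runs use 2000 Monte Carlo g(0) runs (MC se ≈ 0.001),
10000-cycle calibration logs, n = 5000 distance samples for
recovery/coverage checks (100 seeds), and 200 synthetic surveys of ~120
detections each for the end-to-end bias check — sizes at which the
finite-sample bias of the hazard-rate MLE (noticeable below ~50 detections)
is well below sampling noise. Quadrature tolerances are scipy defaults
(validated to 1e-6 against a dense trapezoid); the ray-crossing normal
system rejects condition numbers above 1e10; detection-fit Hessians use
relative steps of 1e-4.

## Known limitations

* g(0) reflects availability only; perception bias within the ESHW is
  assumed absent, as in the reference analysis.
* The ESHW for the along-track detection window is proxied by the
  perpendicular-distance ESHW.
* Per-run whale counts are drawn uniformly on {1..300}; the published
  description does not specify the distribution, and the across-run sd
  (though not the mean) depends on it.
* Empirical phase resampling treats the pooled sample as the population;
  with ~80 observed cycles the rest-tail mass carries most of the g(0)
  uncertainty.
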