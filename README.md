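# strikewatch

Availability-corrected passive-acoustic line-transect abundance estimation
for sperm whales, and a ship-strike sustainability assessment built on it.

## The problem

Sperm whales (*Physeter macrocephalus*) are surveyed acoustically: a vessel
tows a two-element hydrophone array along transect lines and detects the
regular echolocation ("usual") clicks the whales produce while foraging.
Conventional distance sampling turns the perpendicular distances of detected
whales into a density estimate

```
D̂ = n / (2 μ̂ L) × 1/g(0),        N̂ = A × D̂
```

where *n* is the number of whales detected, *μ̂* the effective strip
half-width (ESHW) from a fitted detection function, *L* the surveyed track
length, *A* the survey area, and *g(0)* the probability of detecting a whale
on the track line itself. For an acoustic sperm whale survey g(0) < 1 is an
**availability** problem: whales are silent during descent/ascent and during
surface inter-dive intervals, occasionally for hours during extended rests,
so a whale can pass through the detection window without ever being audible.

This package implements the full chain, each stage usable on its own:

1. **Tag processing** (`strikewatch.tags`) — segment biologging depth/acoustic
   records into dive cycles and extract echolocating (t_e) and silent (t_ne)
   phase durations.
2. **g(0) Monte Carlo** (`strikewatch.g0`) — whales as stationary alternating
   renewal processes on a model transect; a whale on the line is missed only
   if one silent phase covers the whole detection window
   (2 × ESHW / speed). Includes a closed-form exponential-phase oracle
   `1 − (m_ne/(m_e+m_ne))·exp(−w/m_ne)` and an ESHW × speed grid.
3. **Localization** (`strikewatch.localization`) — least-squares crossing of
   side-ambiguous towed-array bearings into whale positions and
   perpendicular distances.
4. **Detection function** (`strikewatch.detection`) — hazard-rate
   `g(x) = 1 − exp(−(x/σ)^−b)` and half-normal keys by maximum likelihood,
   AIC selection, ESHW with delta-method variance.
5. **Abundance** (`strikewatch.abundance`) — density/abundance with
   corner-overlap effort correction, CV propagation in quadrature,
   log-normal intervals, and the sustainability comparison of maximum
   recruitment r·N̂ against observed annual ship-strike mortality.
6. **Synthetic data** (`strikewatch.synthetic`) — calibrated dive-cycle tag
   records and ground-truthed survey scenarios that drive every test.

## Worked example

```python
from strikewatch import g0, abundance

# availability at the survey operating point: ESHW 4.168 km, 11.8 km/h
est = g0.simulate_g0(g0.G0SimConfig(
    phase_source=g0.LognormalMixturePhases(),   # echo ~34 min, silent ~24 min
    eshw_km=4.168, speed_kmh=11.8, n_runs=2000, seed=1))
print(f"g(0) = {est.g0_mean:.3f} (sd {est.g0_sd:.3f}, "
      f"window {est.window_min:.1f} min)")

D = abundance.estimate_density(n=83, mu_hat_km=4.168, L_km=2668,
                               o=0.042, g0=est.g0_mean)
N = abundance.estimate_abundance(D, A_km2=52933)
print(f"D = {D*1000:.2f} whales/1000 km^2, N = {N:.0f}")
```

prints

```
g(0) = 0.922 (sd 0.040, window 42.4 min)
D = 4.22 whales/1000 km^2, N = 224
```

i.e. a whale on the track line is audible at least once during the 42-minute
detection window with probability ~0.92 — the ~8% shortfall is driven almost
entirely by the rare extended surface rests — and correcting the density for
it raises the abundance estimate accordingly. At the sperm whale's maximum
rate of increase of 1.1%/yr, 224 whales can replace at most ~2.5 animals per
year, which is what makes an observed ship-strike mortality of ~2/yr a
conservation concern.

The `analysis/` directory holds the numbered study scripts
(`01_simulate_tag_records.py` … `06_abundance_sustainability.py`); each is a
thin driver over the package that prints what it found and writes tables and
figures under `results/`. A `strikewatch` command exposes the same stages
(`strikewatch g0 --phases phases.csv --eshw 4.168 --speed-knots 6.4`,
`strikewatch run --config run.cfg`, …).

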