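# tundragreen

Estimating decadal change in Arctic tundra greenness from sparse,
multi-sensor satellite reflectance time series — and knowing how much
to trust the answer.

`tundragreen` implements, as a tested Python library, the full analysis
chain used to ask whether tundra is greening or browning: per-site
annual maximum NDVI (NDVI_max) estimation from irregular clear-sky
summer scenes, cross-sensor NDVI calibration, nonparametric trend
detection and classification, Monte-Carlo propagation of radiometric /
calibration / smoothing uncertainty, attribution of trend classes to
environmental drivers with balanced random forests, and validation
against field measurements of plant productivity.  Because the real
inputs (a multi-decade satellite archive, gridded climate products,
field networks) cannot ship with a package, a first-class synthetic
generator produces all of them with known ground truth, so every stage
is testable end to end.

## The statistics at the core

**NDVI and its annual peak.** NDVI = (NIR − red)/(NIR + red).  For a
site *i* and year *y*, NDVI_max(*i*, *y*) is the seasonal peak of the
NDVI trajectory.  With only *k* clear-sky scenes per summer the raw
maximum max(o₁…o_k) is biased low, and the bias shrinks as *k* grows —
a densifying archive therefore fakes greening.  The package instead
fits a cubic smoothing spline *f*(doy) to scenes pooled over a 17-year
window (smoothing parameter spar ∈ [0.68, 0.72], R `smooth.spline`
convention) and adjusts each scene *o* at day *d* by the ratio to the
modeled peak:

    candidate = o · f(doy_peak) / f(d),   NDVI_max = median(candidates)

**Cross-sensor calibration.** Systematic NDVI offsets between sensors
are removed by pairing 15-day moving-median NDVI from overlap years at
each site and fitting a random-forest mapping (features: NDVI,
period midpoint DOY, site coordinates) trained on ⅔ of sites and
evaluated on the withheld ⅓.

**Trends.** Each screened site (mean NDVI_max ≥ 0.10, ≥ 10 years) is
tested with the Mann–Kendall statistic S = Σ_{i<j} sign(x_j − x_i)
(tie-corrected variance, exact null distribution for n ≤ 10,
trend-free pre-whitening optional) and the Theil–Sen slope (median of
pairwise slopes).  Sites are classed *greening* (slope > 0, p ≤ α),
*browning* (slope < 0, p ≤ α), or *none*, with α ∈ {0.05, 0.10}.

**Climate coupling.** The summer warmth index SWI_y = Σ_m T_{y,m} over
months with mean temperature > 0 °C; NDVI_max–SWI association uses
Spearman's r_s (current-year, two-year-mean, and detrended variants),
with structural uncertainty handled by resampling each grid cell's SWI
from one of several temperature data sets.

**Uncertainty.** Every statistic is re-computed across Monte-Carlo
draws (default 10³): reflectance perturbed uniformly within ±7/5/3%
per sensor, calibration refit, spar redrawn; the estimate is the
median with a [2.5th, 97.5th]-percentile CI.

## Worked example

Trend recovery on a 300-site synthetic network with injected class
fractions (37% greening, 5% browning), archive-like scene densities
and a +5 °C SWI warming (`python examples/03_trends_and_warming.py`):

```
285/300 sites pass screening (mean NDVI_max >= 0.10, >= 10 years)
recovered trend classes (injected 37% greening / 5% browning):
  browning: 7.0%
  none: 55.8%
  greening: 37.2%
greening:browning ratio: 5.3
NDVI_max-SWI r_s (current-year): 0.95
NDVI_max-SWI r_s (two-year-mean): 0.90
NDVI_max-SWI r_s (detrended): 0.72
```

The injected greening fraction is recovered almost exactly; browning is
mildly over-detected because two-sided false positives at α = 0.10
land on trendless sites.  The greenness–warmth correlation mixes the
shared warming trend with the injected interannual temperature
coupling; the detrended value isolates the latter.

The scene-count bias that motivates the phenology model
(`python examples/02_phenology_bias.py`):

```
mean signed error of annual NDVI_max vs scene count:
method  modeled     raw
n_obs
1        0.0006 -0.1188
2        0.0008 -0.0636
4       -0.0020 -0.0228
8       -0.0009 -0.0029
```

The raw maximum is ~0.12 NDVI low with one scene and climbs toward
zero as scenes accumulate; the modeled estimator stays within ~0.002
regardless of scene count.

Other examples: `01_simulate_archive.py` (the generator and its
ground truth), `04_uncertainty_ensemble.py` (Monte-Carlo CIs),
`05_drivers_and_validation.py` (balanced random-forest attribution and
field validation).  A thin CLI wraps the same pipeline:
`tundragreen simulate | calibrate | ndvimax | run-ensemble | trends |
correlate | drivers | validate | report`.

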