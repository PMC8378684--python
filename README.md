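# winterdisp

Analysis toolkit for the winter dispersal of geolocator-tracked seabirds,
built around the movement and trophic ecology of Magellanic penguins
(*Spheniscus magellanicus*) overwintering on the Patagonian Shelf.  It is
aimed at movement ecologists who work with light-level geolocators (GLS) and
need, from a single set of daily tag records, the full chain: positions →
track summaries → fisheries-overlap maps → stable-isotope niche and trophic
position.

## What it computes

**Probabilistic light-level geolocation.**  A GLS tag records daily sunrise
and sunset times; longitude follows from the timing of local solar noon and
latitude from day length via the hour-angle equation
`cos H = (sin a − sin φ sin δ) / (cos φ cos δ)` at the tag's twilight sun
elevation *a*.  Because *a* is uncertain and latitude is unidentifiable near
the equinoxes, the path estimator builds a daily cloud of candidate
positions over a range of solar angles, weights each candidate by travel
speed plausibility (gamma density, hard cap), agreement between the tag's
daily minimum water temperature and a satellite SST field (Gaussian kernel),
and land avoidance, then runs many seeded forward passes keeping one
candidate per day.  The most-probable path is the per-day geographic median
of the retained points, with the median great-circle distance to it as a
dispersion diagnostic.

**Track metrics.**  Inclusive trip durations from wet/dry records,
latitudinal range as the great-circle distance between the extreme-latitude
path points (sphere radius 6 378 137 m), per-sex mean ± SD summaries, a
two-group test with separate residual variances per group (Welch/varIdent
form: F = t², Satterthwaite df), and a Gaussian random-intercept model
`depth ~ sex + (1|bird)` with per-sex residual variances for repeated daily
dive depths.

**Fisheries overlap.**  Daily fixes are counted on a 2°×2° grid and
normalized per sex and month to the layer maximum; 0.5° monthly fishing
effort (hours at fishing speeds from vessel monitoring) is re-gridded by
exact nesting and binned into scores 0–5 (1: 0–60 h, 2: 60–200, 3: 200–800,
4: 800–6000, 5: >6000).  For every penguin-occupied cell the overlap flag
(score > 0) and the interaction score `density × score ∈ [0, 5]` are
tabulated; sexes are compared with a binomial GLM on the flag and a Gaussian
linear model on the interaction, separately per fishery.

**Isotopic niche and trophic position.**  From blood δ13C/δ15N: standard
ellipse areas SEA = π√det S, the small-sample correction
SEA_C = SEA·(n−1)/(n−2), a Bayesian SEA_B from the inverse-Wishart
covariance posterior, and numerical ellipse-overlap percentages.  Trophic
position is estimated against bivalve baselines of assumed TP 2 with blood
trophic discrimination factors (ΔN = 2.8 ± 0.2 ‰, ΔC = 0.9 ± 0.1 ‰): a
one-baseline δ15N model and a full two-baseline model where a mixing
proportion α ∈ [0, 1] combines two baselines in both elements, sampled by
MCMC; baseline δ13C values are Suess-corrected at −0.022 ‰ yr⁻¹.

**Synthetic data.**  A first-class generator produces ground-truthed inputs
at the scale of the 2017 Martillo Island season (5 female + 4 male tracks
April–September, 13 + 11 blood samples): sex-structured movement on the
shelf, tag records derived from the true tracks by solar geometry plus
noise, clustered effort fields for trawl and shrimp fisheries, and isotope
samples from the two-baseline mixing model with known TP and α.

## Worked example

```python
from winterdisp.environment import make_environment
from winterdisp.geolocation import GeolocationParams, estimate_path
from winterdisp.synthetic import SimulationConfig, simulate_tracks, simulate_tag_records
from winterdisp.sphere import haversine_km
import numpy as np

env = make_environment()
cfg = SimulationConfig()                     # 2017 study conditions
track = simulate_tracks(cfg, env)[0]         # ground truth, female F01
records = simulate_tag_records(track, env, cfg)
params = GeolocationParams(n_particles=2000, n_iterations=50, rng_seed=11)
path = estimate_path(records, env, params)

m = path.data.merge(track.positions, on="date", suffixes=("_e", "_t"))
lat_err = haversine_km(m.lat_e, m.lon_e, m.lat_t, m.lon_e)
lon_err = haversine_km(m.lat_t, m.lon_e, m.lat_t, m.lon_t)
print(f"median latitude error {np.median(lat_err):.0f} km, "
      f"longitude {np.median(lon_err):.0f} km")
```

prints

```
median latitude error 176 km, longitude 22 km
```

— the latitude error of the reconstructed full-season path sits inside the
~185 km solstice-period accuracy envelope expected of probabilistic
light-level geolocation, and longitude (driven by solar-noon timing rather
than day length) is an order of magnitude sharper.

The same dataset flows on through the pipeline:

```python
from winterdisp.pipeline import PipelineConfig, run_pipeline
manifest = run_pipeline(PipelineConfig(out_dir="run", seed=7))
```

which writes tag records, paths, trip summaries, overlap tables and the
isotope report (`run/isotope_report.json`), e.g. female trophic position
posterior 4.79 ± 0.21 with α ≈ 0.52 against a simulated truth of
TP = 4.8, α = 0.5, and male posterior 5.43 against a truth of 5.4.  Every
stage is seeded; rerunning with the same seed
reproduces identical output checksums (recorded in `run/manifest.json`).

A CLI mirrors the stages: `winterdisp run | simulate | geolocate | metrics |
overlap | isotopes` (see `winterdisp --help`).

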