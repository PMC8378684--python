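# Methods

This note documents the models and numerical choices behind `winterdisp`,
and what the synthetic study conditions do and do not establish about real
tag data.

## Solar geometry

Declination and the equation of time come from a low-precision solar
ephemeris (mean longitude and mean anomaly advanced from J2000, two
equation-of-centre terms, declination through the obliquity), accurate to a
few hundredths of a degree — two orders of magnitude below geolocator error.
Solar parameters are evaluated once per date at 12:00 UTC; the forward
twilight prediction and the inversion share this convention, so a noise-free
round trip is exact by construction.

The twilight inversion recovers longitude from the twilight midpoint (local
solar noon offset from 12:00 UTC at 15°/h after removing the equation of
time) and latitude by solving
`sin δ sin φ + cos δ cos H cos φ = sin a` in closed form (harmonic-addition
rearrangement, two candidate roots; an optional hint latitude disambiguates
the rare case where both lie in range).  A day is flagged
**degenerate in latitude** when |d(day length)/dφ| at the solution falls
below 2 min/degree (central difference) — at a 3-minute twilight noise this
marks the window of roughly ±10 days around each equinox where day length
carries no usable latitude information.  Day lengths inconsistent with every
latitude raise a no-solution error rather than returning a fabricated
position.

## Path estimator

Per day, `n_particles` candidates are proposed: each samples a solar
elevation angle uniformly from `solar_angle_range` (default [−7°, 0°] — the
tag's calibration angle is unknown and may drift seasonally), inverts the
twilight pair, and adds Gaussian jitter (defaults 0.5° lat, 0.2° lon).
Inside the equinox window (default ±12 days around 20 March / 22 September)
latitude proposals switch to a uniform band reachable from the previous
position at the speed cap.  Candidate weights multiply three factors:

* travel-speed plausibility — gamma density moment-matched to
  `speed_mean = 2 km/h`, `speed_sd = 1 km/h`, hard-capped at
  `speed_max = 8 km/h` sustained over 24 h;
* SST agreement — Gaussian kernel of (tag daily-minimum SST − satellite SST
  at the candidate), `sst_sd = 1.0 °C`;
* land avoidance — exactly zero on land cells.

One candidate per day is kept by weighted sampling; `n_iterations` seeded
forward passes (study scale: 2000 particles × 200 iterations; tests and the
acceptance run use 50 iterations, which already saturates accuracy at these
noise levels) yield per-day point sets whose geographic median is the
reported path, with the median great-circle distance to it as dispersion.
The geographic median uses a Riemannian Weiszfeld iteration (tangent-space
log/exp maps, 1 m tolerance) with the standard safeguard that an input point
beating the iterate is returned directly; a plain normalized
chord-weighted mean was measurably biased (~5 m) against a brute-force grid
oracle.

Degenerate days can strand a forward pass (e.g. every candidate beyond the
speed cap after a noisy longitude jump); the estimator then redraws
proposals up to four times, widens the speed cap and SST kernel, and as a
last resort drops the speed factor for that day.  These fallbacks trade a
locally inflated error for never silently fabricating or aborting a path.

Two diagnostics in the test suite are run with a *narrow* angle range
bracketing the true calibration angle: error monotonicity in twilight noise
and the equinox-window dispersion excess.  With the broad default range the
angle uncertainty — not twilight noise — dominates latitude spread, and both
effects are masked; the narrow-range runs isolate the property being
checked.

## Track metrics

Trip duration is inclusive, `(arrival − departure) + 1`: this convention
reproduces all nine published 2017 deployment durations from their printed
date pairs (the published male-duration SD of 14.57 days does not recompute
from that table — the dates give 4.57 — so it is documented, not asserted).
Latitudinal range is the haversine distance between the extreme-latitude
path points with full coordinates (the extremes may differ in longitude),
Earth radius 6 378 137 m.  The two-group comparison with per-group residual
variances is computed in its closed form (Welch t, F = t², Satterthwaite
df).  The repeated-depths model `depth ~ sex + (1|bird)` with per-sex
residual variances exploits the compound-symmetric block covariance for a
closed-form profile likelihood; variance parameters are fitted by REML
(plain ML visibly understated the between-bird variance at 8–9 birds) and
the sex contrast uses a t reference with (birds − 2) df.  A between-bird
variance driven to zero is reported as a singular flag, not an error.

## Overlap grids

The 2° analysis grid anchors cell edges at even integer degrees with
half-open cells `[edge, edge + 2)`, so the 0.5° effort grid nests exactly
(16 fine cells per coarse cell; totals conserved and checked).  Effort-score
bins are left-open/right-closed — (0, 60], (60, 200], (200, 800],
(800, 6000], > 6000 — with score 0 reserved for exactly zero hours,
resolving the shared printed endpoints deterministically.  Density is count
over the per-(sex, month) maximum; overlap rows exist only where penguin
density is positive, because the overlap flag is defined conditionally on
penguin presence.  The binomial sex test reports the likelihood-ratio
statistic (equal to the 2×2 G-statistic for a single binary covariate) with
residual df = rows − 2; complete separation is flagged rather than fatal.
Sexes are pooled across months per fishery, matching a single-model
analysis; trawl and shrimp never share rows.

## Isotopes

δ values are carried in ‰ throughout.  SEA is the area of the 1-SD standard
ellipse, π√det(S) with the n−1 sample covariance; SEA_B draws come from the
inverse-Wishart posterior IW(ν₀ + n, Ψ₀ + scatter) with a weak prior
(ν₀ = 3, Ψ₀ = 10⁻³ I).  Ellipse overlap is computed numerically from
1024-vertex polygons; the *joint* percentage is intersection over union and
the per-group percentages intersection over each ellipse's own area — the
convention under which a ~12 % joint overlap can coexist with 16 %/48 %
per-group fractions.

Trophic position models: TP ~ Uniform(2, 10), α ~ Beta(1, 1), baseline
means and discrimination factors normal at their reported values
(ΔN = 2.8 ± 0.2 ‰, ΔC = 0.9 ± 0.1 ‰), residual scales half-Cauchy(1)
sampled on the log scale with the Jacobian.  Baseline δ13C is
Suess-corrected at −0.022 ‰ yr⁻¹ from the baseline sampling year (2009) to
the blood year; baseline δ15N is treated as time-invariant.  Sampling uses
an affine-invariant ensemble (40 walkers, 5000 steps, 2000 burn-in by
default) with differential-evolution moves, which mix far better than
stretch moves for this correlated, prior-dominated posterior; convergence is
flagged by split-R̂ < 1.1 over walker half-chains.  Seeding the ensemble
state makes draws bit-reproducible.  Zero-variance inputs (all prior SDs
zero) are inverted analytically — one linear equation for one baseline, a
2×2 solve for (TP, α) with two — and returned as degenerate posteriors.
Baselines coincident in δ13C make α unidentifiable and are flagged.
Females are reported from the two-baseline model (Southern Patagonia +
Bahía Franklin bivalves), males from the one-baseline Northern Patagonia
model, following the sexes' distinct last-month foraging areas.

## Synthetic study conditions

The generator fixes the study scale: 5 female + 4 male recovered tracks over
April–September 2017, 13 + 11 blood samples, twilight noise 3 min (typical
of archival light tags), SST noise 0.3 °C, twilight calibration angle
−3.44°, travel speed 2 ± 0.7 km/h capped at 8 km/h, dive-depth medians
57.1 m (males) / 44.3 m (females) with lognormal spread 0.35, and isotope
truths TP = 4.8, α = 0.5 (females) and TP = 5.4, α = 1 (males) with 0.4 ‰
residual SDs.  Movement is a biased random walk toward sex-specific monthly
latitude bands (females reaching ~43°S in June, males staying ~4° south of
them mid-winter) in an offshore corridor, returning to the colony at least
two days before recording ends so the wet/dry trip detector has a sustained
dry tail.  Monthly latitude targets that cannot be reached within a month at
the speed cap are rejected up front, naming the offending month.

The environment is synthetic: a smooth SST climatology (0.55 °C per degree
of latitude, weak zonal term, seasonal cycle) and a coarse polyline
coastline on a 0.25° mask.  Fishing effort is gamma noise over configured
hotspot boxes — a trawl fishery spanning the shelf with a 45–40°S
high-effort band and a shrimp fishery confined to 50–43°S — with cells
outside a fishery's extent exactly zero.

What passing tests show: the estimator chain is internally consistent (it
recovers what the generator encodes, at the error scale the method is known
for), the arithmetic reproduces every printed deployment-table value, and
each statistical primitive matches an independent oracle.  What they do not
show: performance on real tags, whose twilight-error distributions are
heavy-tailed and weather-dependent, whose SST fields carry structured error,
and whose movement is not a biased random walk.  Published data-dependent
results (niche overlap percentages, observed posterior means, F/p values)
depend on the raw measurements and are covered only as parameter-recovery
and coverage properties at the published truths.

## Problem sizes

Tests and the acceptance script run the full 2000-particle cloud with 50
forward passes (accuracy is iteration-saturated well before 200) and the
credible-interval coverage study at 32 walkers × 1500 steps per replicate
(100 replicates).  Default library settings remain at the larger study
scale.
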