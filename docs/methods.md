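# Methods

This note documents the models behind `rfmap`, the assumptions they make,
the parameters that matter, and the choices taken where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and grid conventions

All geometry lives in a local projected metric frame (x, y in meters); no
geodesy. The analysis grid tiles the scene extent with square cells
(`cell_size`, default 100 m), row-major cell ids, predictions at cell
centers. Rasters are written as ESRI ASCII grids (plain text, rows north
to south, no-data −9999); vector layers as GeoJSON.

## Outdoor interpolation

**Model.** The downlink field E (V/m) is treated as lognormal:
Z = ln E is a stationary Gaussian field. The empirical semivariogram of Z
uses 15 distance bins up to half the point-cloud diameter, and a
parametric model — exponential by default, spherical or gaussian by
configuration — is fitted by least squares weighted by the square root of
per-bin pair counts.

**Range convention.** `range_m` is the *practical* range: the exponential
structure is 1 − exp(−3h/a) (95% of the sill at h = a), gaussian
1 − exp(−3h²/a²), spherical exact at a. The synthetic field generator
uses the same convention, so generator/estimator recovery is parameter-
for-parameter.

**Semivariance at the origin.** γ(0) = nugget throughout, including the
kriging-matrix diagonal. Consequences: the one-neighbor prediction
variance is exactly 2γ(d) − γ(0), and with zero nugget the predictor
interpolates samples exactly (asserted to 1e−9 in log space).

**Local neighborhoods.** Only points within `4 × range_m` of the target
enter the kriging system (a locally varying mean). Cells with an empty
neighborhood fall back to the global log mean with the total sill as
variance and carry a `no_neighbor` flag — the map stays total, the flag
preserves honesty. Duplicate coordinates are averaged in log space before
fitting; a singular system triggers deduplicate-then-retry with a logged
warning.

**Back-transform.** Exact lognormal moment identities (see README). The
test suite checks them against a 10⁶-draw Monte-Carlo oracle to 3
significant figures on the mean.

**Bands.** A drive test records five downlink bands per point; by default
they are combined into one total field per location by root sum of
squares before kriging (fields add in power), with per-band kriging
available by filtering the input frame. The interpolated surface is read
as a 900 MHz-equivalent total field; the 9.5 dB penetration default is
the literature mean for that band.

**Cross-validation.** Leave-one-out, optionally excluding all predictors
within `exclusion_radius` of the held-out point to emulate growing
unmeasured areas. Points left without predictors are counted and excluded
from the RMSE rather than failing the run.

**Recovery summary.** The weighted-LS range estimator is heavy-tailed on
single realizations (occasional boundary fits), so multi-scene recovery
is summarized by the *median* of per-scene fitted ranges; the acceptance
suite requires the median over 20 scenes of n = 1000 points (2 km domain,
true practical range 300 m) to land within 30%.

## Diurnal profiles and temporalization

η_i = E_i²/Ē²_day per node-day; Ē_day is by default the literal
arithmetic mean of E over the day. A configuration switch (`mode="rms"`)
normalizes by the mean of E² instead, under which the day-average of η is
exactly 1 — that is the variant whose hourly profile is the generator's
configured diurnal shape, so round-trip tests use it. Both are shipped
because the two readings of "average field value of the day" differ by a
day-level constant only.

Hours without samples are filled by circular linear interpolation and
flagged. All-zero days are skipped with a log entry.

`temporalize_cell` draws n = 20,000 base samples from
Normal(z̃, σ²) truncated at zero (negative draws are redrawn — fields are
nonnegative), picks an hour uniformly over 24 h (residential whole-day
exposure; hours are not coupled to time budgets) and a band by
`band_weights` (equal thirds by default; the weighting across band
profiles is user config), scales the squared sample by that profile
value, and returns square-rooted field samples. Gamma and normal are both
fitted by maximum likelihood; the family with the smaller KS statistic is
retained (the gamma location is pinned just below the sample minimum so
the fit stays a two-parameter shape/scale problem).

## Indoor surrogates

**Low-rank tensor approximation.** Univariate factors are orthonormal
Legendre polynomials (degree 4 by default) on inputs affinely scaled to
[−1, 1]. Fitting is greedy rank by rank: each rank-one term is fitted to
the running residual by alternating least squares (each dimension update
is an ordinary linear LS), sweeps stopping when the relative training-RMSE
change falls below 1e−8 or after 100 sweeps; non-convergence keeps the
best iterate and sets a warning flag. Two robustness layers sit on top of
the bare algorithm: each term starts from 7 deterministic initializations
(the constant function plus seeded random coefficient vectors, best
training error wins), and after the greedy pass 5 correction rounds
re-optimize every term against the residual of all the others with a
joint re-estimate of the normalizing constants b_l after each — this
removes most of the greedy suboptimality at negligible cost. Models
serialize to JSON (coefficients, bounds, basis spec) and reload with
bit-identical predictions.

**Synthetic SAR ground truth.** The training oracle emulates a child
moving in a 3 × 4 m room under a ceiling-mounted source (access points
and femtocells are wall/ceiling mounted; source height 2.4–2.8 m, child
torso center at 1.0 m):

    SAR = p0 · (1 + 0.3 cos θ) / max(d², 0.3²)

with d the source-torso distance, θ the child's rotation, p0 = 1.5
mW·m²/kg. The near-field clamp (0.3 m) bounds the dose; the elevated
source keeps the response smooth over the input domain, which is what a
low-rank separable surrogate can represent — the point of the oracle is
to provide a recoverable ground truth, not room electromagnetics.
Experimental designs are Latin-hypercube samples of the 5-D input domain.

**PCA + kriging map surrogate.** Training maps (one per known source
position, common grid) are centered and decomposed by linear PCA; the
smallest d components reaching the explained-variance threshold (default
0.99) are retained, and each component score is interpolated over
source-position space by ordinary kriging with a gaussian variogram
(range = source-domain diameter, partial sill = score variance) plus a
relative nugget of 1e−8 — a pure numerical regularizer, gaussian kriging
matrices being near-singular, small enough that training maps are
reproduced to ~1e−4 relative (exact to 1e−6 under full retention).
Negative reconstructed field values are clipped to zero and the
prediction flags source positions outside the training hull.

**Penetration.** V_I = V_O·10^(−dB/20), default 9.5 dB. Composing two
losses equals their dB sum exactly (group property, tested).

**Calibrated fallback.** Without a trained surrogate, WLAN + femtocell
and Wi-Fi-use doses are lognormals moment-matched to the published
reference profile means and SDs per tissue (and age for Wi-Fi). The
reference whole-body WLAN row prints a median below its first quartile —
an internal inconsistency of the source table — so calibration uses
mean/SD only. The child-calibrated WLAN profile also drives adults, a
deliberately conservative choice (child doses are the higher).

## Uplink dose

The formula is implemented verbatim, including the 0.25 leading factor in
both terms and the appearance of p3G in the data term; the factor's
physical meaning is not documented in the source material, so a
`quarter_factor=False` switch exists for sensitivity analysis, and the
default keeps fidelity. Homogeneity (degree 1 in t, V_d, P̄_v, P̄_d;
degree −1 in T̄) and voice/data additivity are exact and property-tested.

Calibrated mode: a person-level usage-intensity lognormal factor (median
1, log-variance 1.5) scales voice duration and data volume together and
is *shared across all population groups* — behavioral differences between
groups are deliberately not modelled; age enters only through the
transfer functions. Each (tissue, age) transfer entry carries a lognormal
spread sized so the total log-variance matches the published mobile
profile row, and its median is solved so the dose at median usage equals
the row's median. A two-parameter lognormal cannot match mean, median and
SD simultaneously; (mean, median) are honored and the SD falls where it
falls. Base usage: p3G = 0.8, p_v = 0.7, p_d = 0.6, t = 120 s/day,
V_d = 8×10⁸ bit/day (~100 MB), P̄ = 0.25 W, T̄ = 10⁶ bit/s — typical
smartphone-era magnitudes; they cancel out of the calibrated moments by
construction.

## Population and person-hours

Surface-ratio allocation per age class (children < 15 y, adults ≥ 15 y);
a building spanning several zones sums its per-zone contributions.
Housing area = 2D footprint × floors × (1 − office share); intersections
in the projected plane with slivers below 0.5 m² dropped. The
occupational population (15–64 y) is allocated over office areas from the
district aggregate. A populated zone without housing area is reported and
skipped, never fatal. When buildings fully cover the zones' housing area,
allocation conserves every population class exactly (tested to 1e−8
absolute).

Default time budgets (config, not constants): residents 21.5 h home /
2.5 h outdoor; workers 16 h home / 6 h office / 2 h outdoor — each group
sums to 24 h and puts ~90% of the day indoors, consistent with national
time-activity surveys. Workers' home hours accrue to their residences
(already counted through the residential groups), so only their office
and outdoor hours generate person-hours here. Outdoor person-hours attach
to the grid cell containing the building centroid; there is no mobility
model (a stated limitation of this approach), so cells without buildings
carry no person-hours and map to no-data.

## Aggregation

Per cell and tissue, 20,000 samples are apportioned across occupancy
components proportionally to person-hours (largest-remainder rounding) —
person-hours set sample *shares*, not absolute counts, which bounds cost
and preserves weights. Every drawn ambient sample receives an additive
uplink draw for its population group (mobile exposure is cumulative with
ambient exposure). Summary: vigintiles P5…P100 by linear interpolation
between order statistics, plus P99 (upper-tail results are conventionally
quoted there), mean and SD.

**Source attribution.** Each sample keeps its additive decomposition:
in-room device dose (class *indoor*), outdoor-source dose (class
*outdoor* — both the outdoor-microenvironment dose and the penetrated
outdoor field inside buildings, which originates from the same base
stations), and the uplink draw (class *mobile*). Contribution curves
report, within each vigintile band of the pooled distribution, each
class's share of the summed dose; district-wide curves pool cells with
person-hour weights (`method="pool"`), with per-cell share averaging
exposed as the alternative (`method="cells"`).

**Field→SAR.** Plane-wave power density S = E²/377 (free-space
impedance), SAR = tf × S with per-(tissue, age) transfer functions in
(mW/kg)/(W/m²). The defaults (whole body 4.7 adult / 8.0 child, whole
brain 10 adult / 11 child) are placeholders in the range plane-wave
dosimetry studies report, with the child-above-adult ordering and a
deliberately larger brain relativity so outdoor sources matter more for
the brain than for the whole body, mirroring published contribution
structure; they are user config and should be overridden with
model-specific values for any real assessment.

## Synthetic scene

The generator emulates, with one run-level seed and byte-identical
replay: a rectangular district partitioned into census zones (recursive
random splits) whose child/adult/worker counts are apportioned from the
configured district totals by housing area with largest-remainder
rounding (sums are exact); axis-aligned rectangular buildings with
declared use, floors and office share; a drive test whose points cluster
along random street segments with 4 m cross-street jitter (uneven
sampling density, as real campaigns have) over a Gaussian log-field with
exponential covariance (Cholesky factorization — exact at desk scale, up
to a few thousand joint locations) around a hotspot-modulated median
surface; per-band fields splitting the total power by fixed shares so the
root-sum-of-squares recombination is exact; sensor series
E = level·√shape(hour)·noise with lognormal node levels and
multiplicative noise; and Latin-hypercube surrogate training sets against
the analytic SAR oracle.

Default field parameters (median 0.6 V/m, log-variance 0.6, practical
range 250 m, two station hotspots plus a broad elevated band along the
southern edge) describe a dense urban district with localized
infrastructure concentrations. What the generator does *not* emulate:
real street networks, anisotropic propagation, building-height shadowing,
seasonal field trends, commuting flows, and correlated multi-band
structure beyond the fixed power split — so passing tests demonstrate
that the estimators recover the structure they assume, not that the
assumptions hold in any particular city.

## Problem sizes and runtime

Defaults were chosen so a full desk run stays interactive: 10 × 10 cells,
300 drive-test points, 10 nodes × 7 days of 15-min samples, 20,000
samples per cell, 5,000-sample indoor/uplink pools; the complete pipeline
runs in well under a minute and `scripts/acceptance.py` in about one
minute on a single CPU. All sizes are configuration, and the estimators
accept the larger inputs (1,100-point campaigns, 36-node networks,
30-day series) exercised in the test suite.

## Known limitations

- No mobility model: outdoor person-hours follow building populations, so
  unbuilt cells are no-data rather than low-dose.
- The uplink 0.25 factor is reproduced, not explained.
- Calibrated mode inherits every bias of the published reference
  statistics, including the inconsistent whole-body WLAN median it
  ignores.
- Downlink transfer functions are documented placeholders.
- GSM/4G/5G uplink technologies are out of scope; so are kriging with
  external drift, co-kriging and anisotropy.
- The synthetic indoor oracle stands in for full-wave electromagnetic
  simulation; surrogate accuracy against it says nothing about accuracy
  against a real room.
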