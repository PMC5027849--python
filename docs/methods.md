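# Methods

## The model

The area deprivation index (ADI) summarizes the socioeconomic disadvantage
of a small areal unit (ZCTA-like) from 17 census variables spanning
education, income/employment, housing, and household characteristics.
`localadi` builds the composite as

    raw_score(u) = Σ_v w_v · d_v · z_v(u)

where `z_v(u)` is the z-score of variable `v` across the reference units
(population standard deviation, `÷ n`, for determinism), `d_v ∈ {+1, −1}`
orients every variable so that larger means more deprived (income, home
value, rent, mortgage, owner-occupancy, high-school attainment and
white-collar share are reversed), and `w_v` are weights. The published ADI
refinements derive weights from a factor analysis whose coefficients are
not redistributable, so the default is equal weights 1/17; `AdiWeights`
accepts any published loading vector. Standardization is computed within
the supplied region (a national z-scoring would require national data the
package does not assume).

Scores are converted to percentiles with the weak-inequality rule

    percentile(u) = 100 · #{v : score(v) ≤ score(u)} / n,

so ties share the highest applicable percentile and the maximum is always
at 100. A unit is flagged as highly deprived when its percentile lies
**strictly above** `100 − threshold_pct` (default threshold 15, i.e. the
top 15%). The strict boundary is this package's convention: with `n`
unique scores it flags exactly `n − floor(0.85·n)` units (15 of 100), so
the flagged fraction never exceeds the nominal threshold; a unit sitting
exactly at the cut percentile is not flagged. Under total ties every unit
has percentile 100 and all are flagged — a uniform region is uniformly
"deprived relative to itself", which users should know before applying a
threshold to near-degenerate windows.

## Calibration scales

*Regional*: percentiles over the whole study region.
*Local (moving window)*: for each unit, percentiles over the units whose
centroids lie within a radius (defaults 10, 20, 30 km). The window always
contains the central unit: a percentile of a value within a set is only
well defined if the value belongs to the set, and inclusion makes the
radius → ∞ limit coincide exactly with the regional calibration
(`include_self` is configurable). Distances are centroid-to-centroid:
great-circle on the authalic sphere (R = 6371.0088 km) for lon/lat input,
Euclidean for projected meters. Windows smaller than `min_window`
(default 10 units) yield a percentile but an *indeterminate* flag — a
top-15% cut among a handful of neighbors is not meaningful — and such
units are excluded from association analyses with a logged count.

## Age adjustment

Hospitalization counts are grouped by 3-digit ICD-9 root into respiratory
(460–519), circulatory (390–459), mental disorders (290–319), and total;
V- and E-codes are excluded from all categories including total by default
(configurable, logged). Multi-year counts are averaged arithmetically
(a missing year counts as zero, logged). Indirect standardization per unit:

    expected = Σ_s rate_std(s) · pop(s),   SMR = observed / expected,
    adjusted_rate = SMR · crude_std

Age strata default to eighteen five-year bands (0–4 … 85+), configurable by
label list; the standard population is an input table (or derived
region-wide when absent), not a hard-coded reference.

## Association

Exposure is the unit-level deprivation flag; outcome is "hospitalized at
least once in the averaged period" (averaged fractional counts are rounded
half-up before table assembly — an odds ratio needs a binary person-level
outcome). Per age stratum the 2×2 cells are summed over units in each arm,
capping events at population with a warning. The age-adjusted OR is the
Mantel–Haenszel estimator with the Robins–Breslow–Greenland variance for
the CI of ln(OR); strata with degenerate margins carry no information and
are skipped (counted). MH is the default because it is closed-form and
reproducible; a grouped-logistic fit with stratum indicators is provided
as a cross-check utility. Crude ORs use the Haldane–Anscombe 0.5
correction when any cell is zero; the MH estimator tolerates zero cells,
with a zero denominator reported as an infinite estimate. Confidence level
defaults to 95%. Note the ecological caveat: with large aggregated
populations the intervals can overstate significance, and unit-level
associations do not license person-level inference.

## Synthetic scenarios

The simulator emulates the statistical structure the analysis assumes, not
any real geography or census marginals. Latent deprivation is
`L(u) = trend + pocket + 0`: a linear west–east gradient across a square
extent plus disc-shaped pockets of excess deprivation. Each census
variable is a monotone transform of `d_v·L` plus Gaussian noise
(sd 0.3 per variable): logit-linear for percentages around realistic base
levels (e.g. 10% family poverty, 65% owner-occupancy), log-linear for
dollar amounts (e.g. $55,000 median family income). Populations are
Poisson around `mean_unit_pop` (1000), split multinomially over the age
bands with gently declining shares. Events per (unit, stratum, category)
are Binomial(pop, p) with
`logit(p) = logit(baseline_s · share_cat) + effect_log_or · D(u)`, where
baseline stratum rates are U-shaped in age (3%–30% per year, with an
early-childhood excess), category shares are respiratory 0.15, circulatory
0.25, mental 0.10, other 0.50 (total = their sum), and `D(u)` is the
deprivation signal on the configured scale: latent deprivation centered on
the unit's local window mean (`local`), on the region mean (`regional`),
or zero (`none`).

Presets: `null` (200 units, 45-km extent, no effect), `regional-effect`
(same geography, effect on regionally centered deprivation, log-OR 0.7),
and `local-pockets` (400 units, 60-km extent, 8 pockets of 3-km radius,
trend amplitude 2, pocket amplitude 1.5, effect on 10-km locally centered
deprivation, log-OR 0.7). The `local-pockets` geometry is chosen so the
structure matches its name: pockets are small relative to the smallest
analysis window (3-km pockets vs 10-km windows, so a pocket never
dominates its own window), the trend is broad relative to the largest
window, and unit density (~0.11/km²) gives 10-km windows of ~30 units so
the minimum-window floor rarely binds. Binomial (not Poisson) events keep
the person-level outcome well defined for OR assembly.

What passing the synthetic checks does **not** show: real census variables
are not conditionally independent given one factor, real events are
overdispersed and spatially autocorrelated beyond the latent field, and
real ZCTAs have irregular shapes and population-weighted centroids. The
simulation validates the machinery and the qualitative scale-sensitivity
phenomenon, not any numeric odds ratio from real data.

## Problem sizes and numerical choices

The shipped analyses use 100 replicates of the 400-unit `local-pockets`
scenario and several hundred replicates of the 200-unit `null` scenario —
enough that the coverage check's binomial standard error (~1% at 500
replicates) resolves the 93–97% band, while a full run stays in the tens
of seconds on one core. All randomness flows through
`numpy.random.default_rng` seeded from the scenario config; events use a
seed sequence derived from the same seed so regions and events are
independently reproducible. Zero-variance census variables (relative
variance below 1e-12) contribute zero to every score with a warning.
CSV output uses `%.10g` floats; round-tripping through files preserves
values to that precision.

## Known limitations

- Equal default weights are a reproducible convention, not the published
  factor loadings; rank correlations with the published ADI will be high
  but not perfect.
- Windows are radius-based on centroids only; polygon adjacency,
  k-nearest-neighbor and population-weighted windows are out of scope.
- The OR treats unit-aggregated counts as independent persons; no
  spatial or multilevel error structure is modeled.
- Whether real analyses of this design include the central unit in its
  own comparison window, or standardize variables nationally vs
  regionally, are genuinely open conventions; this package documents and
  defaults both (self-inclusion, regional standardization) rather than
  guessing hidden choices.
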