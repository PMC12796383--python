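# Methods

## Growth model

Disc volume over developmental time t (h AEL) follows the three-parameter
logistic `V(t) = Asym / (1 + exp((tmid − t)/scal))`: `Asym` is the
asymptotic maximum volume (carrying capacity; volume units), `tmid` the
inflection time at which `V = Asym/2` (h AEL) and `scal` the steepness
time-scale (h). Volumes are first made dimensionless by dividing by the
mean volume at the earliest timepoint, so fitted `Asym` reads as fold
growth over the starting size; `tmid`, `scal` and the entire rate curve
are invariant to this (or any) rescaling.

Fitting is ordinary nonlinear least squares (Levenberg–Marquardt with an
analytic Jacobian). Starting values are generated from the data: a
provisional asymptote `Asym₀ = 1.05 × max(V)` (any factor > 1 works; the
factor is an argument), then `tmid₀, scal₀` from a linear regression of
`logit(V/Asym₀)` on t. At least 4 distinct timepoints and strictly
positive, non-constant volumes are required; optimiser failure raises
rather than returning a flagged result silently.

The relative growth rate `(dV/dt)/V` is computed from the closed form
`(1/scal)·(1 − V(t)/Asym)` — the exact derivative of the logistic divided
by the curve — rather than by numeric differentiation, so it is noise-free
and strictly decreasing for any valid fit. Two identities pin the
implementation: `rate(tmid) = 1/(2·scal)` exactly, and `rate → 1/scal` far
before `tmid`.

Uncertainty ribbons come from stratified case bootstrap: disc measurements
are resampled with replacement *within* each timepoint (preserving the
unequal per-timepoint design), the model refit, and the per-time SD across
successful refits reported. Resampling units and replicate counts are a
convention here, as is `n_boot` (default 500); refits that fail are
dropped and counted, and more than 20% failures abort the ribbon. The
default evaluation grid is 0.5 h steps over the observed range.

## Correlation screen

The screen consumes an already-normalised gene × (timepoint, replicate)
matrix (columns `<timepoint>_rep<k>`); upstream read alignment and
count normalisation are out of scope. Replicates are averaged per
timepoint before correlating — one profile per gene, seven points in the
default design — and the growth rate is evaluated at the matrix's
timepoints from the continuous fitted curve, not interpolated from plotted
values. Pearson r uses the standard product-moment form, vectorised over
genes; constant profiles have undefined r and are flagged `undefined`
rather than propagating NaN. Classification uses strict inequalities at
the ±0.8 default threshold (a gene at exactly 0.8 is unselected), so
positive/negative/unselected/undefined partition the gene list.

For display, profiles are scaled to their per-gene maximum (row max = 1,
idempotent; all-zero rows are rejected by name) and clustered with Ward's
minimum-variance linkage on Euclidean distances, the "ward.D2" convention
in which unsquared input distances enter the Lance–Williams recurrence.
The linkage delegates to scipy's nearest-neighbour-chain implementation;
merge heights are deterministic, but the order of exactly tied merges
follows scipy's traversal rather than a smallest-index rule — ties at
different heights do not occur in continuous data, and heights and cluster
composition are unaffected.

Over-representation of selected genes in user-supplied gene sets (GMT) is
the one-sided hypergeometric tail `P(X ≥ overlap)` after intersecting each
set with the analysis universe. The default is the plain tail; an EASE
variant (overlap decremented by one, `p = 1` when overlap ≤ 1) is provided
because web annotation tools conventionally use it. Benjamini–Hochberg q
values are reported across tested sets, but the retention flag mirrors the
conventional raw `p < 0.05` rule.

## Sensor calibration

The reporter's dose-response is modelled as two regimes on
normoxia-normalised mean intensity: `I = m·O₂ + k` over the responsive
range (default 5.0–18.0% O₂, m < 0 for a functioning sensor) and the
constant `I = c` over the plateau (default 18.0–20.9%), with `c` the plain
mean of plateau points (a zero-slope regression). Intensities are first
divided by the normoxia-group (20.9% O₂) mean, per batch when requested,
which makes all derived quantities unit-free.

By default the regression uses per-level mean intensities ("average
intensities"); replicate-weighted regression is available via
`per_level_mean=False`. The 18.0% boundary level is assigned to the
plateau only: the plateau is defined by the sensor no longer responding
there, and including a plateau-valued point in the line fit would bias the
slope (an `include_boundary_in_both=True` switch restores the overlapping
assignment). A fit with m ≥ 0 is flagged non-responsive and the derived
quantities withheld.

The sensitivity breakpoint is the intersection `(c − k)/m` of the two
regimes — the mildest hypoxia the sensor detects — and the dynamic range
is the fold-increase `(m·floor + k)/c` from the breakpoint down to a floor
of 5% O₂. An optional percentile bootstrap (resampling replicates within
level) attaches a CI to the breakpoint; this is an extension beyond the
basic calibration.

## Quantification

All image operations work on a single 2-D plane with binary masks of the
same shape (row-major, 0-based); z-stack reduction is explicit
pre-processing, and compartment masks are inputs (anterior/posterior
boundaries are drawn from a lineage marker, not inferred). The signal mask
of an ROI is its pixels strictly above a threshold — Otsu on the ROI
histogram by default, or a fixed value for reproducibility — and mean
intensity is taken over signal pixels only. Area fractions are
signal-pixel counts as a percentage of compartment pixels. P/A ratios
divide the posterior mean by the anterior mean (perturbed compartment over
internal control). Red/green ratios are computed per nucleus over
connected components of the nuclear mask (touching nuclei are not split —
a documented limitation); nuclei with zero green mean are excluded and
flagged. Trichome density is the mean socket count over four equally sized
inter-vein ROIs divided by ROI area; any other ROI count must be
acknowledged with an override flag. Pupariation T50 is the time at which
the cumulative pupariated fraction reaches 0.5 — exactly at an observation
when one lands there, otherwise linearly interpolated between the
bracketing observations; cohorts that never reach 50% are reported
censored.

## Synthetic data

Generators emulate each input with planted truth attached, under
study-condition defaults: the expression design is 7 timepoints (80, 88,
96, 104, 112, 116, 118 h AEL) with 3 replicates except 2 at 80 h; the
volume design is 4-h sampling from 72 h plus a final 118 h point with 6
discs per timepoint (5 at 84 h). The planted logistic is parameterised so
the normalised curve starts at V = 1 and its relative growth rate runs
from 0.09 /h at 72 h to 0.02 /h at 118 h (`scal ≈ 10.60 h`,
`tmid ≈ 104.08 h`, `Asym ≈ 21.64`); the planted sensor has its regimes
intersecting at 17.09% O₂ with a 4.0-fold range at 5% O₂, the operating
characteristics the calibration is designed to recover. Calibration levels
default to {5, 8, 11, 14, 18, 20.9}% O₂ — both regimes covered with ≥ 2
levels each.

Noise is multiplicative log-normal everywhere (positive, heteroscedastic
data): `x·exp(ε)`, `ε ~ N(0, σ)` with `σ = sqrt(ln(1 + cv²))` so the
sample CV matches the requested `noise_cv`. Default CVs (5% for
volumes/intensities, 10% for expression) are conventions chosen to
resemble tight biological replicates, not measured values. Tracking /
anti-tracking genes are positive / negative affine transforms of the rate
profile plus noise; null genes draw per-timepoint levels independently of
the rate. Disc images plant the positive posterior pixels
deterministically in raster order so planted area fractions are exact;
pupariation times come from a logistic CDF (closed-form quantiles, clean
spread → 0 degeneracy). Fixed seed and parameters give byte-identical
outputs.

What passing tests show — and don't. The generators reproduce the *model
structure* of the real data (logistic trajectories, affine rate-coupled
expression, two-regime dose-response, two-level images), not its
pathologies: no batch effects, no count overdispersion beyond log-normal,
no segmentation error, no developmental staging error. Recovery results on
synthetic data therefore validate the estimators' correctness, not their
robustness to those artefacts.

## Problem sizes and tolerances

Recovery checks use 50 seeded cohorts for growth endpoints (median
relative error ≤ 15%) and sensor characteristics (median breakpoint error
≤ 0.5% O₂; median fold error ≤ 5%); the bootstrap-coverage study uses 100
cohorts × 500 resamples on a 2-h grid (±2 SD covering the planted rate at
≥ 90% of grid points); the grid-search fit oracle spans
Asym ∈ [Vmax, 3·Vmax], tmid ∈ [60, 130], scal ∈ [1, 40] with a
Nelder–Mead polish. Exact identities are asserted at 1e-12, analytic-vs-
finite-difference agreement at 1e-6 relative. These sizes keep the whole
suite to a couple of minutes on one CPU while holding Monte-Carlo error
well inside the asserted tolerances.
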