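# Methods

## Scope and data model

The package analyses one *system* at a time: a set of 2° grid cells and
the species present in them. A system is either the whole grid or one of
up to fourteen (region × coastal/high-seas) units from a cell partition;
species absent from a system are excluded from that system's analysis
entirely, and index scaling, quartiles and the null model all operate on
the system's own species pool. Assemblage columns are the system cells
with at least one presence after thresholding — empty cells carry no
information under a fixed-margins null and are omitted.

Grid cells are half-open squares `[edge, edge + 2°)` anchored at
(−90, −180), so every finite coordinate maps to exactly one cell;
latitude +90 is clamped into the top row and longitudes are wrapped to
[−180, 180). Occurrence thresholding is strict (`probability > t`), and a
single record suffices for presence in a 2° cell (any-presence rule).

## Rarity indices

Restrictedness is the complement of relative occupancy, raw
Res_i = 1 − GE_i/TOT, then min–max rescaled over the pool so the most
restricted species scores exactly 1 and the most widespread exactly 0.
The complement form (rather than literal subtraction of one from a ratio)
is the standard definition in the functional-rarity index literature and
is isolated in one function so it can be swapped. A constant score column
cannot be rescaled; it maps to zeros with a warning.

Functional distances are Gower: continuous traits contribute
|x_i − x_j| / range (ranges over the system pool, zero-range traits
contribute 0), categorical traits a 0/1 mismatch, averaged with equal
weights over traits. No transformation is applied to skewed continuous
traits before distance computation (a documented, switchable choice — drop
or pre-transform columns in the `TraitTable` if needed). Distinctiveness is
the mean distance to all other species in the pool, computed from
presence/absence membership only (not abundance-weighted, not per-cell);
uniqueness is the nearest-neighbour distance. Both are min–max rescaled.

Rare species are those at or above the 75th percentile of restrictedness
*and* of the chosen functional index. Percentiles use linear interpolation
between order statistics (the default of the common statistical
environments, so results are portable), and the cutoff is inclusive:
ties at Q3 count as rare. With continuous uncorrelated scores this flags
~6.25% of the pool; perfectly correlated scores give 25%. Degenerate
constant columns make everyone tie; the condition is warned and reported
rather than masked.

## Trait filtering and imputation

Traits with more than 30% missing entries are dropped (inclusive
boundary: exactly 30% is retained). Remaining gaps are filled by
iterative random-forest imputation in the missForest style: missing cells
are seeded with the trait median/mode, then each incomplete trait is
re-predicted from all others (random-forest regression for continuous,
classification for categorical, `max_features="sqrt"` and small leaf
sizes to keep variance down at a few hundred species) for three sweeps.
Observed values are never altered, categorical imputations stay inside
the declared level sets, and runs are deterministic under a fixed seed.
The contract is not bit-level agreement with any particular
implementation but the substantive property that imputation error on
held-out entries beats mean imputation, which the test suite checks on
masked complete tables.

## Null model

The curveball trade picks two species uniformly at random, pools the cells
held by exactly one of them, and re-deals the pool randomly while keeping
each species' count — preserving all row and column sums exactly. One
sequential chain is run per fit: a burn-in of `5 × max(n_species,
n_cells)` trades, then one sample every `n_species` trades (both
overridable; the iteration count is the number of samples, 2000 by
default). The chain always randomizes the *full* matrix, rare and
non-rare species together, so cell richness constraints transfer to the
null; rare identity stays attached to species labels. SES uses the sample
standard deviation (n−1). Z = 0 cells are flagged degenerate — SES is 0
when X = Y and a signed-infinity sentinel otherwise — and excluded from
SES-based maps and profiles. Hotspots are cells with SES strictly
greater than 2.

## Downstream analyses

Geographic distances are planar Euclidean in decimal degrees (matching
the convention of grid-based congruence work); this overstates east–west
distances at high latitude and is a documented limitation. Each MPA point
is assigned to its nearest cell centroid (ties broken by lowest cell id)
and kept only when the distance is strictly below 0.75°. The primary
congruence figure is the percentage of hotspot cells containing at least
one assigned MPA; the percentage of assigned MPAs landing in hotspot
cells is emitted as a secondary view.

The habitat-specialization test builds the 2 × k table of water-column
categories for rare vs non-rare species; G = 2 Σ O ln(O/E) with zero
cells contributing nothing, p from χ² on (k−1) df, and Cramér's V from
the Pearson χ² (no bias correction). Latitudinal profiles report centroid
latitudes of cells with SES ≥ 2 and a Gaussian KDE over latitude alongside
the richness–latitude profile. Distance decay pairs a reference cell with
all others and fits linear quantile regressions (τ = 0.5, 0.9) by pinball
loss; it is a diagnostic, and no particular slope is asserted.
Trait-removal sensitivity recomputes distances and both functional indices
without each named trait and reports Pearson/Spearman correlations with
the full-table scores.

## Synthetic worlds

The generator emulates the statistical shape of the real inputs on a
contiguous window of 2° cells centred on (0, 0), 20 × 20 cells (400) by
default. Background species (280 of 300 by default) get axis-aligned
rectangular ranges, 2–6 cells per side, with centroid latitudes weighted
by exp(−s·|lat|/lat_max) — an equatorial richness gradient of strength
s = 1.5 by default, 0 for structureless calibration worlds. In-range 2°
cells emit 1–3 half-degree records with probabilities Uniform(0.92, 1);
per species, 8% of out-of-range cells emit one noise record with
probability Uniform(0, 0.5), so the 0.9/0.7/0.5 thresholds all recover
the intended ranges and threshold nesting is exercised.

Planted rare species (20 by default) occupy 3 cells each, drawn from a
compact block of 5 hotspot cells; generation fails loudly if the planted
range size is not below the background first-quartile range size, which
guarantees planted species land in the top restrictedness quartile.
Their continuous traits are offset ±4 background standard deviations on
every trait, each planted species with its own distinct random sign
pattern: under Gower's L1 geometry this puts them far from the bulk *and*
at least 8 SD from each other on some trait, so both distinctiveness and
uniqueness stay high (a single shifted direction would let planted
species cluster and collapse uniqueness). Categorical traits are
multinomial with one level reserved at low background frequency; planted
species draw a 50/50 mixture of that reserved level and background
levels — enriched enough to drive the habitat test, mixed enough to keep
planted species mutually distinct. For the habitat trait the reserved
level is the scarcest of the seven declared water-column classes rather
than an invented eighth.

Background continuous traits are multivariate normal with a moderately
correlated life-history block (growth coefficient, generation time,
length at maturity, |r| = 0.5–0.6) and a depth–temperature correlation of
−0.5 — realistic covariation that also gives the forest imputer signal to
learn from. Missingness is MCAR with *exact* per-trait counts
(round(f·n) masked entries, default f = 0.2), so realized missingness
matches the configuration to rounding on every run; no species loses all
its traits. MPAs (60 by default) are placed at uniformly chosen cell
centroids with ±0.5° jitter, keeping each inside the 0.75° assignment
radius of its own cell. The partition splits the window into seven
longitude-band regions whose outer columns are "coastal" and interior
columns "high seas".

What the generator does *not* emulate: coastlines and bathymetry,
environmental-envelope occupancy probabilities, non-rectangular or
wrap-around ranges, abundance, temporal dynamics, and MAR/MNAR
missingness. Passing tests therefore demonstrate correctness of the
pipeline's statistics and its ability to recover planted structure of the
stated effect sizes — not performance on the idiosyncrasies of real
distribution databases.

## Calibration behaviour

On structureless worlds the SES distribution is approximately centred
(mean within ±0.1 of 0, averaged over five worlds) but mildly
overdispersed: roughly 5–11% of cells per world reach SES ≥ 2 against the
~2.3% normal expectation. The overdispersion is real structure, not a
chain defect — species ranges are spatially contiguous while the
fixed-margins null scatters presences independently, so cells in
multi-range overlaps legitimately exceed the null; raising the thinning
from 300 to 5000 trades per sample leaves the tail unchanged. Calibration
checks therefore average over seeds.

## Problem sizes and numerical choices

Default test and acceptance runs use 300 species × ~400 cells with 100–500
null samples, sizes at which a full fit takes seconds and the entire
pipeline remains exact rather than approximated; production-style runs
simply raise `n_iterations` (2000 is the default in `fit`). Quantile
method, inclusive cutoffs, strict thresholds, tie-breaking by lowest cell
id, and the degenerate-cell sentinels above are the deliberate
determinism choices; with a fixed seed the whole pipeline is reproducible
byte-for-byte, which the test suite asserts on written CSVs.
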