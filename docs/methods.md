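# Methods

This note records the statistical model the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Responses

**Taxonomic structure.** The site-by-species count matrix Y is
Hellinger-transformed: x̄_ij = sqrt(y_ij / y_i·). Rows have unit sum of
squares, so Euclidean geometry on the transformed matrix respects
community-profile distances and down-weights species that are rare at a
site and infrequent overall. Sites with no individuals are rejected as
input errors rather than silently dropped.

**Functional / phylogenetic structure.** A species score vector u is the
first principal-coordinate axis of the species distance matrix (Gower for
traits, cophenetic for the phylogeny): Gower-centre −½D∘D, take the
eigenvector of the largest positive eigenvalue scaled by √λ. Sign is fixed
by making the largest-magnitude entry positive (rounded to 12 decimals
before the argmax so ties break toward the earlier species). A distance
matrix with no positive eigenvalue (all species identical) is a degenerate
input. One axis is the default because a single dominant axis is what the
decomposition below consumes; the species-scores object carries its
eigenvalue so callers can judge axis dominance.

**Composition and dispersion.** Cell weights link abundance to the score
vector: the default scheme is w_ij = y_ij · o_j, where o_j is the number of
sites species j occupies — the occurrence multiplier damps species that are
both rare and infrequent. Alternatives (`presence_occurrence`, plain
`abundance`) are selectable and recorded in every output, because the exact
cell-weight formula used by the original Matlab routine is not recoverable
from its description. With normalised weights w̃_ij,

- composition m_i = Σ_j w̃_ij u_j (community-weighted mean position),
- dispersion s_i = sqrt(Σ_j w̃_ij (u_j − m_i)²) (weighted SD; the variance
  is also emitted in the response metadata).

The identity Σ_j w̃_ij u_j² = m_i² + s_i² holds to numerical precision and
is asserted in tests. A one-species site has s_i = 0 exactly.

**Decomposition summary.** The site-weighted total sum of squares of the
scores is redistributed into a between-site part Σ_i ω_i (m_i − m̄_ω)²
(composition) and a within-site part Σ_i ω_i s_i² (dispersion), with site
weights ω_i proportional to the site's total cell weight. The reported
shares are these two components over their sum. This is the means-vs-
variances redistribution reading of the decomposition; the raw between-site
variances of the m and s vectors are kept as diagnostic columns.

## Species distances

**Gower.** Attribute weight is 1/(n_axes_used × n_attrs_in_its_axis), so
every niche axis contributes equal total weight — chosen because there is
no a-priori ranking of niche axes and it blunts redundant attributes.
Mensural contributions are |Δ|/range with the range taken over the analysed
species set (standard Gower; SD scaling would be an alternative but range
scaling is the classical convention and is what the config flags). Binary
contributions are 0/1 mismatches. Zero-range mensural attributes are
excluded with a warning and the weights renormalised. Should missing values
survive imputation, pairs are compared over their shared attributes with
weight renormalisation (defensive only; the pipeline imputes first).
Restricting to a single axis reproduces unweighted Gower on that axis's
attributes, which is how the per-axis dispersion analyses are run.

**Imputation.** Missing mensural cells are predicted by OLS of the
attribute on body mass fitted within the species' subfamily (intercept
included; ≥ 2 donors required, otherwise an error naming the cell);
predictions are floored at 0 to respect the nonnegativity contract.
Missing categorical cells are copied from a congener; among several the one
at smallest cophenetic distance wins, alphabetical first when no phylogeny
is supplied — the tie rule is logged. Observed cells are never altered and
every imputed cell is listed in a report.

**Cophenetic.** Patristic distances via dendropy. Species absent from the
tree may be mapped to congener tips through a substitution table; two
species sharing a tip get distance 0 with a logged warning (their
phylogenetic distinction is below the tree's resolution).

## Spatial predictors

Connectivity: Euclidean distances, minimum spanning tree, threshold = the
longest MST edge, W_ij = 1 for 0 < d_ij ≤ threshold. This guarantees a
connected graph. The paper-side ambiguity (user threshold validated against
the MST vs MST-longest-edge) is resolved in favour of MST-longest-edge, the
parameter-free reading. A distance-decay dialect 1 − (d/threshold)² is
available behind a flag; binary is the default because nothing in the
source method indicates weighting.

MEM basis: eigenvectors of (I − 11ᵀ/n) W (I − 11ᵀ/n), computed on the
orthogonal complement of the constant vector so all n − 1 returned
eigenvectors sum to zero exactly, sorted by descending eigenvalue, signs
fixed as for species scores. The default spatial predictor is the first
eigenvector (largest positive eigenvalue — a landscape-wide trend of
positive autocorrelation); the config can widen the block to the leading k
eigenvectors, reflecting the observation that nearby choices of MEM give
similar results.

Moran's I: I = (n/S0)·zᵀWz/zᵀz on centred values with binary W. For a
unit-norm MEM eigenvector this equals (n/S0)λ, which the tests exploit as
an algebraic oracle. The permutation test is two-sided on |I| by default
(nperm ≥ 99), one-sided via `alternative="greater"`.

## Variation partitioning

Three fits per partition: E∪S, E alone, S alone. Matrix responses use the
redundancy-analysis R² (fitted SS over total SS across all columns after
column centring — equivalent to per-column OLS, which is the test oracle).
Vector responses use weighted least squares with the structure module's
per-site total weights by default (unweighted OLS selectable); R² is on the
weighted scale. Intercepts are always included. Collinear predictor columns
are dropped by pivoted QR with a warning and the fit's p reflects the
retained rank; p ≥ n − 1 is an error. Each R² is Ezekiel-adjusted,
1 − (1 − R²)(n − 1)/(n − p − 1), with each fit's own p, and the fractions
follow from inclusion–exclusion. Raw fractions may be negative (correlated
predictors with opposing effects); clamped copies are provided for display.
All environmental columns are used per focal scale — no forward selection —
matching the source analysis; a selection mode is deliberately out of
scope.

**Tests.** Taxonomic unique fractions: partial pseudo-F of adding the
tested block over the other block, null distribution from permuting whole
response rows, p = (hits + 1)/(nperm + 1). Reduced-model residual
permutation is implemented but not the default: at the study's own
geometry (15 sites, 9 environmental predictors, 1 MEM) the reduced model
leaves ~5 residual degrees of freedom, the residuals are far from
exchangeable, and measured type-I error drops to ~1% — direct row
permutation calibrates at 3–6.5%. Trait responses: two null distributions
per fraction — site rows of the tested predictor block permuted, and the
score vector permuted across species with the composition/dispersion
decomposition recomputed each draw — combined as max(p_site, p_species),
the conservative convention for trait–environment association tests. The
whole-environment model [ab] is tested the same way (key `env_model`),
since with spatially structured environment the signal sits largely in the
shared fraction [b]. Constant score vectors are rejected up front: the
dispersion response would be identically zero.

## Synthetic generator

What it emulates: 15 sites on a plane with a minimum spacing of 0.0875 of
the unit extent (the study's 3.5 km over a ~40 km landscape), 9
environmental columns drawn from a Gaussian process with exponential
covariance (default range 0.5 — broad-scale structure like clustered land
use; range 0 gives i.i.d. columns) plus independent noise (sd 0.25); a
pure-birth ultrametric phylogeny of 34 species scaled to unit depth; 27
trait attributes in 7 niche axes (4 binary axes — diet, foraging location,
foraging strategy, roost type — and 3 mensural — body size, masticatory,
aerodynamic), binary traits from a threshold model on a Brownian liability
(heritability 0.8, random per-attribute thresholds for varied prevalence),
mensural traits as lognormal transforms of Brownian draws, body mass ~20 g
median as the first body-size attribute. Baseline log-abundances are
Normal(log 5, 0.8), giving right-skewed rank-abundance profiles and site
totals of roughly 100–250 individuals, in the range of a season of mist-net
effort. Counts are Poisson (negative-binomial-style overdispersion behind a
gamma-mixing knob); all-zero site rows are redrawn.

Mechanisms:

- `filtering`: log-intensity β_j − e·(g_i − opt_j)²/2 with g the first
  (standardised) environmental column and opt_j a Brownian niche-optimum
  trait — composition turns over along the gradient.
- `dispersion_gradient`: the pool is split at a mid-sized clade (1/3–2/3 of
  species) whose mean on the leading functional axis is closest to the
  remainder's; the lower-spread side is the "core" (a trait-compact group
  of relatives, like the dominant frugivore genera), abundant everywhere
  with baseline lognormal(log 8, 0.5). Peripheral species (lognormal(log 4,
  0.5)) scale with a logistic niche-availability score expit(e·g_i) — the
  spread of trait values tracks the environment while the weighted mean
  stays put. The availability score is the per-site "true niche breadth"
  recorded in the truth object.
- `spatial_only`: intensities follow the site layout's own leading MEM
  (β_j + e·t_i·opt_j/2). A generic smooth trend was rejected during design
  because it correlates with the autocorrelated environmental columns and
  contaminates the unique-environment fraction; the MEM trend is the
  canonical "space, not measured environment" pattern.
- `null`: sites exchangeable by construction.

Effect size defaults to 2, where the dispersion-gradient recovery
correlation (truth availability vs realised s_F) averages ~0.87 and both
recovery rates used in acceptance run at ≥ 96%.

What it does not emulate: mist-net detection and effort, seasonality,
lunar-illumination sampling gaps, true landscape rasters or the real
correlation structure among the nine landscape indices (columns are
independent GP draws), or realistic Phyllostomid abundance distributions
beyond rank-abundance skew. Passing recovery tests therefore show the
inference chain recovers known mechanisms under this idealised sampling,
not that field data of this size always identify them.

Genus/subfamily labels for imputation testing come from lineage cuts of the
tree at depths 0.7 and 0.35; monotypic genera are merged with their nearest
relative's genus so that masked categorical cells always have a potential
donor, and the missingness injector redraws masks that would leave any cell
un-imputable — the missingness emulated is the estimated-or-replaced kind,
not irrecoverable gaps.

## Numerical conventions and problem sizes

Determinism: every stochastic step takes a seed; scenario generation
derives independent substreams (sites/pool/abundances) from the scenario
seed via SeedSequence, and the pipeline derives per-combination seeds from
the run seed, so reruns are byte-identical. R² values are clipped to
[0, 1] before adjustment; per-site variances are floored at 0 before the
square root; symmetric matrices are symmetrised after centring to guard
eigensolver input. Distance-matrix symmetry is enforced to 1e-12, MEM
centring/orthogonality to 1e-10, fraction identities to 1e-10.

Test-suite problem sizes: calibration runs 200 null replicates × 199
permutations for both permutation procedures, and mechanism recovery runs
50 replicates per scenario at the default study dimensions — sizes at which
the binomial bands quoted in the tests are meaningful while the whole suite
stays in the low minutes on one CPU. The acceptance script uses the same
sizes.

## Known limitations

- One ordination axis: trait structure orthogonal to the leading axis is
  invisible to the decomposition (per-axis runs mitigate this).
- The max-p double permutation is conservative; its measured null rejection
  is ~2.5–7% at nominal 5%.
- Adjusted-R² fraction algebra can place [b] outside [0, 1] at small n;
  interpretation of raw negative fractions is the user's responsibility
  (clamped values are provided).
- MEM predictors assume projected planar coordinates; geographic
  coordinates trigger only a flat-earth warning, not a reprojection.
- With p approaching n (e.g. 9 predictors, 15 sites) adjusted R² is
  high-variance; this mirrors the source design rather than a recommended
  practice.
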