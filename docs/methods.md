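# Methods

This note documents the models, defaults and numerical choices behind
`mfsoil`, and what the synthetic-data experiments do and do not demonstrate.

## Gas-flux estimation

Microcosm headspace series are modelled as first-order decay toward a
compensation point, χ(t) = χ_floor + (χ₀ − χ_floor)·e^(−kt), for H₂ and CO
uptake, and as a straight line for CO₂ production. "Integration of the mole
fraction time series" is operationalized as log-linear OLS: k is minus the
slope of ln(χ(t) − χ_floor) against t. The reported flux is the *initial*
rate k·n₀/m, with n₀ the molar quantity above the compensation point at
t = 0 from the ideal gas law (P = 101,325 Pa, T = 298.15 K and headspace
volume 0.48 L by default — a 500 ml bottle minus 20 g of soil at a bulk
density of 1.0 g cm⁻³; all configurable). An interval-averaged rate is the
natural alternative convention; the initial-rate default is exposed, not
asserted as the only correct reading. Uptake fits require ≥ 5 points
(within ~1 h), production fits ≥ 4 points (72 h span); mixing ratios at or
below the floor make the log undefined and raise. Fluxes are reported as
positive magnitudes (nmol g(dw)⁻¹ h⁻¹ for H₂/CO, μmol g(dw)⁻¹ h⁻¹ for CO₂).
The coefficient of variation is 100·SD(n−1)/mean, rounded to integer
percent only at report time.

## Multifunctional classification

Variables are standardized (mean 0, SD 1 with the n−1 denominator) once,
globally; all downstream distances and tests operate in that space (nodes
are *not* re-standardized — the alternative is not documented anywhere we
know of and would make sibling tests incommensurable). UPGMA is implemented
directly (Lance–Williams average-linkage update) so that the tie-break is
specified: among equidistant pairs, the pair whose sorted minimum leaf
indices are lexicographically smallest merges first. Heights are the
average inter-cluster distance at the merge and are monotone toward the
root; the Newick export writes branch lengths as parent height minus child
height with SIMPROF p-values as `[&p=…]` comments.

SIMPROF follows the similarity-profile construction: the observed profile
is the sorted vector of pairwise Euclidean distances; null profiles permute
each variable independently across the node's samples; the expected profile
is the pointwise mean of 999 null profiles; π = Σ|observed − expected|; the
p-value compares π against an independent batch of 999 null statistics with
the +1 correction on both counts (p can never be 0). Nodes with fewer than
3 samples are untestable and return p = 1. Delineation is top-down with
sequential stopping and no multiplicity correction across nodes (standard
SIMPROF practice): a rejected node (p ≤ α, α = 0.05) is split, an accepted
or untestable node becomes one class. Class labels are Roman numerals in
dendrogram leaf order; the *disturbance ranking* — Euclidean distance of
each class centroid from the reference-sample centroid — is reported
separately, since leaf order need not follow disturbance.

The PCA is a correlation PCA (SVD of the standardized table), with
Kaiser–Guttman retention (eigenvalue above the mean eigenvalue, i.e. above
1 for standardized data). The equilibrium circle uses the textbook radius
√(d/p) on scaling-1 descriptor coordinates; the plain ratio d/p is
available behind a flag for comparison with reports that print it that way.
The default descriptor set has p = 10 variables: C, N, pH, sand, silt,
clay, H₂ uptake, CO uptake, CO₂ production and bacterial 16S rRNA gene
abundance. C:N is deliberately not in the default set (it is a deterministic
function of C and N); any variable list can be configured.

Univariate screens transform gas exchange rates logarithmically and
bacterial abundance by square root before Shapiro–Wilk, Pearson/Spearman
correlation, one-way ANOVA and Bonferroni-corrected pairwise t-tests. Note
that with 10 variables screened at α = 0.05, about one spurious ANOVA
rejection per dataset is expected under the null; "no variable significant"
is the typical, not the guaranteed, outcome on null data.

## OTU processing

Rarefaction is an exact multivariate hypergeometric draw (subsampling
without replacement), one draw per seed; it conserves the target depth
exactly and is unbiased for OTU proportions. The rare-OTU filter drops OTUs
below floor(fraction × library size) reads — 8 reads at the 0.005 % default
and a 166,040-read depth. The fractional phrasing is ambiguous between a
per-library and a table-wide reading; the default keeps an OTU that reaches
the threshold in *at least one* sample, and the table-total rule is
available (`rule="table-total"`). Filtering requires an equalized table and
says so. Shannon diversity is in nats; ACE uses the standard rare-group
cutoff of 10 and falls back to Chao1 with a warning when every rare read is
a singleton (coverage 0). Multivariate dispersion embeds the distance
matrix by principal coordinates keeping negative eigenvalues and applies
the usual sign correction (squared distances on negative axes subtract);
singleton groups get dispersion 0 with a warning.

## Constrained ordination

RDA centers Y, regresses it on the (centered) explanatory matrix by least
squares and takes the SVD of the fitted values; eigenvalues are SS/(n−1) so
canonical plus residual eigenvalues sum to the total variance of Y (checked
to 1e-9 in the tests). R² = SS_fit/SS_total, adjusted by Ezekiel's formula.
The permutation test permutes Y rows freely against fixed X (residual
permutation for partial models: both Y and the candidate are residualized
on the conditioning set); pseudo-F = (SS_fit/m)/(SS_resid/(n−m−1)); +1
convention throughout. Species scores use a scaling-2 (correlation-style)
convention; "extreme" OTUs are the top-k by score-vector norm in the
retained plane with identifier-order tie-breaks.

Forward selection applies the double-stopping rule strictly: the global
model must reject first, and a candidate is admitted only if its marginal
permutation p ≤ α *and* the candidate model's adjusted R² does not exceed
the global model's. One documented consequence: when the remaining
candidates are pure noise, the submodel's and global model's adjusted R²
coincide in expectation, so the bound blocks even a genuine driver in
roughly half of such runs (verified against vegan's `ordiR2step`, which
applies the same strict pre-check). The procedure therefore under-selects
in the single-strong-driver edge case; the tests assert the attainable
properties (drivers enter first and in added-R² order, noise is rarely
admitted, pure noise yields an empty model) rather than certain recovery.

## Indicator analysis

IndVal uses class *mean* abundances for specificity (A), so unequal class
sizes do not bias it, and within-class prevalence for fidelity (B); the
default statistic is the group-equalized √(A·B), with the classic A·B
product available. Significance comes from 999 permutations of the class
labels; p-values are exact-level on the 1/1000 grid. Classes with a single
sample are processed but flagged untestable (the minimum attainable p for a
singleton-restricted OTU is ≈ (1 + n_perm/n)/(1 + n_perm) ≈ 0.07 > α).
Indicator search runs on equalized, filtered *counts*, not the Hellinger
matrix. Per class, the significant indicator with the highest total read
count is flagged representative (identifier-order tie-break). No
multiplicity correction is applied by default across OTUs (a
Benjamini–Hochberg flag is available, affecting only the significance
decision, not the reported p-values); with thousands
of background OTUs this means ≈ α of them will be spuriously significant,
and an unrestricted "most abundant significant" pick can land on such a
false positive — representative flags are therefore most meaningful on a
candidate set the analyst trusts (e.g. class-restricted OTUs), and the
recovery experiments evaluate the selection rule on the planted candidates.

## Synthetic data

The generator emulates the study design it is meant to exercise: a complete
block design (3 blocks × 5 treatments: unlogged reference, simple and
double trenching, inversion, mound; 10 replicate samples pooled to one
composite per plot). Replicate-level biogeochemical values are
truncated-normal draws (percentages in [0,100], pH in [0,14], rates and
abundances ≥ 0, rejection sampling) from per-treatment means/SDs; the
shipped defaults describe loamy-sand boreal podzol microsites in a young
larch plantation and are defaults, not fitted parameters. Composites are
the arithmetic mean of their replicates — the numerical analogue of
physically pooling soil. Variables are drawn independently by default; an
optional within-treatment correlation matrix (Cholesky transform, bounds
enforced by clipping) is available but deliberately not parameterized —
no defensible default exists for one, and the classification method itself
does not assume any covariance structure.

For recovery experiments, `generate_classed_biogeochem` plants a known
class structure: every composite draws from the reference parameters and
then receives its class's offset vector. Offsets for non-reference classes
are mutually orthogonal random directions (QR of a Gaussian matrix) scaled
to a per-variable RMS magnitude of 3 composite-level SDs (composite SD =
replicate SD/√10 — the spread the classifier actually sees); orthogonality
guarantees every class *pair* is separated by at least that magnitude,
which independent random directions do not (two could be nearly parallel).
The default class layout mirrors a 1/2/3/9 partition with the reference
plots as their own class.

OTU tables are multinomial draws per composite from a shared lognormal
relative-abundance vector (200 OTUs by default) plus planted indicators at
5×10⁻⁴ relative abundance — inside the rare biosphere (< 0.1 %) — present
only in their class's samples and exactly absent elsewhere; the
configuration rejects indicator fractions ≥ 0.1 %. Library sizes are
uniform in a configurable range (default fixed at 166,040 reads; the
recovery experiments use 20,000 to keep them fast). An option emulates a
failed DNA extraction by dropping one composite's library and substituting
a detection-limit floor for its bacterial abundance.

One global seed expands into per-generator child seeds through
`numpy.random.SeedSequence(entropy=seed, spawn_key=…)`; identical seeds give
bit-identical outputs everywhere, including the full pipeline manifest.

### What the synthetic experiments show — and what they do not

Passing recovery tests show that the implementation finds structure of the
planted kind at the planted strength under multinomial/Gaussian noise. Real
soil data differ in ways the generator does not emulate: variables are
correlated, class structure is not orthogonal-offset Gaussian, communities
are overdispersed relative to multinomial sampling, and spatial
autocorrelation between plots exists. Two intrinsic behaviors of the
methods surface clearly in the experiments and would equally affect real
data: (1) SIMPROF's column-permutation null is blind to structure carried
by a *single* variable (the permutation preserves each marginal exactly),
so classes separated along one axis only are undetectable by design, and
its sequential use on the children of a false split is anticonservative —
about 7 % of recovery seeds end with a split or merged class (mean adjusted
Rand index ≈ 0.95 at the default planting strength); (2) the forward-
selection adjusted-R² bound halves power at the last informative step (see
above).

## Problem sizes

The test suite and the acceptance script use the study's own design sizes
(15 composites, 10 variables) with 999 permutations for SIMPROF/IndVal;
Monte-Carlo summaries use 200 runs for type-I calibration, 100 series for
gas-rate recovery and 50 seeds for structure/indicator recovery, with
community sizes of 150–200 OTUs at 20,000 reads — sizes at which every
quantity stabilizes well inside its tolerance while the whole suite runs in
well under a minute.
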