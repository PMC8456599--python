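# Methods

This note documents the models, estimators, defaults, and numerical
conventions behind `oilcomm`, and what the synthetic-data experiments do
and do not establish.

## Data model

Abundance tables hold non-negative taxon × sample values in `counts` or
`proportions` mode; proportions are computed per sample with no
pseudocount (pseudocounts appear only where an operation needs them and
are stated there). The canonical on-disk orientation is taxa as rows,
samples as columns — the common ASV-table export layout — with a
transpose flag on read. Trees are rooted newicks with branch lengths;
a missing branch length is an error rather than an implied zero, so
UniFrac stays well-defined. Sample metadata carries treatment ∈ {FSC,
SW, SWBS, SWD, WAF, BEWAF, CEWAF}, incubation day ∈ {0, 3, 7, 14, 28}
(absent for the in-situ FSC baseline), and replicate; days off the
design grid are rejected unless a free-design flag is set. Results are
written as TSV plus a JSON manifest recording seed, configuration, and
package version; floats use 12 significant digits, which round-trips
every quantity the pipeline produces.

No rarefaction is applied by default: library-size effects are absorbed
by per-sample proportion normalization, and a `rarefy` utility exists
only for sensitivity checks.

## Diversity and variance partitioning

Shannon entropy is reported in nats (the log base is a convention; nats
are the default here). Bray-Curtis uses scipy's implementation on
proportions. UniFrac is computed by explicit per-branch accumulation:
for every non-root branch b with length l_b, the unweighted form takes
Σ l_b over branches leading to exactly one sample's leaves divided by
Σ l_b over branches leading to either sample's leaves; the weighted form
is Σ l_b |A_b − B_b| with A_b the fraction of sample A's abundance
descending through b, divided (in the default normalized variant) by
Σ l_b (A_b + B_b) so the distance is bounded by 1. The normalized
variant is the default because bounded distances ordinate cleanly; the
raw variant is switchable.

PCoA eigendecomposes the Gower-centred matrix of −d²/2 and scales
eigenvectors by √eigenvalue. Negative eigenvalues — expected for
non-Euclidean dissimilarities like Bray-Curtis — are reported in a note
and excluded from the proportion-explained denominator; requesting more
axes than there are positive eigenvalues truncates with a warning.

PERMANOVA partitions SS_total = Σ_{i<j} d²_{ij}/n through the centred
matrix using projection (hat) matrices built from factor dummy columns,
with *sequential* (Type-I) sums of squares in the given term order —
`(treatment, day)` by default, mirroring adonis-style reporting.
Reordering terms changes the per-term split but not its sum, and the
implementation asserts R² terms + residual = 1. p-values come from free
permutation of sample labels; an exhaustive mode enumerates all n!
permutations for n ≤ 8 and is what the oracle tests compare against.
Permutation p-values throughout the package are (b+1)/(m+1) with b the
count of null statistics at least as extreme as observed. A residual
sum of squares of exactly zero (perfect separation) yields an infinite
pseudo-F, which compares correctly against permuted values.

LCBD_i = G_ii / SS_total from the same centred matrix; per-sample
p-values permute each taxon's abundances independently across samples
and recompute the distance matrix. Pairwise alpha-diversity contrasts
between treatments use Welch t-tests with Benjamini-Hochberg
correction — a deliberate choice where the post-hoc procedure was
otherwise unspecified.

## Phylogenetic community structure

MPD is the mean pairwise cophenetic distance among present taxa and
MNTD the mean distance to the nearest present neighbour;
abundance-weighted variants (pair weight p_i·p_j, taxon weight p_i) are
the default since the analysis concerns relative-abundance structure,
with presence-based forms switchable. NRI = −(MPD_obs − mean_null)/sd_null
(NTI analogously from MNTD), so positive values mean clustering. The
null shuffles taxon labels across the cophenetic matrix restricted to
the *sampling pool* — taxa observed anywhere in the dataset — not the
full tree, matching a closed microcosm pool. Null draws with zero
spread (for example, a presence-based sample containing the entire
pool, which a label shuffle cannot change) are flagged undefined rather
than reported as ±∞. NRI/NTI are invariant to rescaling all branch
lengths, since the scale cancels in the standardized effect size.

The ±2 thresholds are annotations, not enforcement: samples are labeled
clustered / stochastic / overdispersed, and a one-sided one-sample
t-test of replicate NTI values against +2 is provided for the
"significantly greater than +2" style of claim, whose exact form
(per-sample cutoff versus replicate-level test) was an open choice.

## Driver analyses

**Best-subset regression.** Candidate predictors are treatment and day
indicator variables. Selection is hierarchical: stage 1 enumerates
subsets of the factor *blocks* (treatment, day) and keeps the
criterion-minimal model (AIC or BIC; BIC default); stage 2 exhaustively
enumerates subsets of individual indicators within the selected blocks
(up to `max_terms`) and refits by OLS. The block gate exists because
minimizing BIC over ~11 individual indicators directly selects a
spurious indicator roughly 30% of the time under pure noise at n = 90
(the per-indicator χ²₁ > ln n event compounds across candidates),
whereas a 5-degree-of-freedom block must clear 5·ln n. Exact-fit
models leave numerically tiny residuals whose log-ratios are float
noise, so RSS is clamped relative to the response scale and exact-fit
models of different sizes tie, letting the smaller model win.

**Minimal driver-subset search.** The objective is the Pearson
correlation r between the lower triangles of the subset and full-table
Bray-Curtis matrices. Subset distances are computed on the subset's
columns of the *full-table* proportions without renormalization: the
numerator and denominator are then sums of fixed per-taxon pair
matrices, making greedy evaluation incremental, and the one-taxon table
trivially reproduces itself with r = 1. Exhaustive search over
thousands of ASVs is combinatorially impossible, so the search is
greedy forward selection — each accepted taxon must strictly increase
r — with restarts that re-seed the first pick among the top marginal
candidates; an exhaustive mode (≤16 taxa) validates the greedy result
on small instances. Solutions are ranked minimal-cardinality-first
among those reaching the conservation floor (default r ≥ 0.95, exposed
as `--target-r`), then by r; each reported subset is also scored by
PERMANOVA of its own distance matrix against the time factor.

**Differential abundance.** Per taxon: the log₁₀ ratio of group median
proportions (a floor of 1/(2·max library size) replaces a zero median
before the ratio), a two-sided Wilcoxon rank-sum test on per-sample
proportions, and BH adjustment with a q < 0.05 flag. A negative-
binomial count model is deliberately *not* fitted: the rank test plus
median-ratio display statistic is the package's differential-abundance
method, trading parametric power for robustness to the heavy replicate
overdispersion the generator (and real triplicate data) exhibit.

## Taxa-function robustness

The functional profile of a composition c under genome content G is
F(c) = normalize(cᵀG). A perturbation of magnitude m removes taxa in
random order until the removed relative abundance is the smallest
achievable ≥ m, then reassigns the removed mass uniformly across as
many replacement taxa, drawn from the pool minus the removed set, as
were removed. The response curve collects R replicates at each
magnitude of a grid (default m ∈ {0.05, …, 0.5}, R = 50): taxonomic
shift t = Bray-Curtis(c, c′) (weighted UniFrac optional; Bray-Curtis
default so t and f share a scale), functional shift
f = Bray-Curtis(F(c), F(c′)), and per-pathway relative shifts
|F′_P − F_P| / max(F_P, 10⁻⁶).

Attenuation is α = 1/s from the least-squares fit f = s·t through the
origin over samples with t ≤ t_max (default 0.5). When s < 0.01 —
functional shifts indistinguishable from zero, as under fully redundant
content — α is capped at 100 and flagged. The removal/replacement
scheme and the through-origin-slope definition are this package's
operational rendering of the response-curve idea (an initial-slope
versus whole-curve parameterization is genuinely open); both sit behind
the `perturb_community` / `attenuation` interfaces so alternatives can
be substituted without touching the rest. Per-treatment analysis uses
the replicate-mean composition per (treatment, day) by default and
offers replicate-level curves, which feed Welch tests (BH-adjusted) of
per-pathway attenuation between treatments. Two identities anchor the
scale: identity content forces f = t and α = 1; identical content rows
force f = 0 and the cap.

## Hydrocarbon biomarkers

Branched isoprenoids (pristane, phytane) and methylated PAHs degrade
slower than their linear or parent counterparts, so within-sample
peak-area ratios track biodegradation extent without calibration:
Pr/nC17 rises with alkane degradation, nC18/Ph and P/9MP fall,
(3+2)MP/(9+1)MP and 3MP/9MP resolve PAH isomer preferences. The default
orientation is Pr/nC17 (a flag inverts to nC17/Pr exactly, matching the
alternative labeling convention). Ratios are scale-invariant to any
per-sample area rescaling; zero or missing denominators flag the ratio
undefined for that sample rather than erroring. Day-to-day comparisons
use Welch t-tests on replicate ratios with the direction interpreted
per ratio; single replicates get descriptive statistics only. A fixture
generator plants exponential decay (fast on n-alkanes/parent PAHs, 10×
slower on isoprenoids) with log-normal replicate noise.

## Synthetic experiment generator

The generator is the package's study-design stand-in and its defaults
are fixed, not tuned: 6 treatments × 5 days × 3 replicates + 1 in-situ
baseline = 91 samples, 300 taxa, 500 gene families, 50 000 reads per
sample, Dirichlet-multinomial concentration θ = 50 (chosen once to
emulate visible triplicate overdispersion).

*Phylogeny*: pure-birth (Yule) tree rescaled to unit mean root-to-tip
depth. *Genome content*: the first ⌈ρ·n_functions⌉ functions are core
(copy 1 everywhere; ρ default 0.3); accessory functions evolve as a
symmetric two-state Markov process at rate λ (default 1) from a
Bernoulli(½) root, flip probability (1 − e^{−2λt})/2 per branch.
*Expected composition* per (treatment, day): softmax of a latent
log-abundance = Brownian-on-tree baseline (σ = 1) + i.i.d. noise
(σ = 0.5) − φ·mean-squared distance of a 5-dimensional Brownian trait
to the treatment optimum (an anchor taxon's trait vector or the first
responder clade's centroid). The trait is multivariate because
similarity in several independent Brownian dimensions at once implies
relatedness far more strongly than in one (convergence is unlikely in
all dimensions simultaneously), which is what makes the Gaussian
fitness kernel produce *phylogenetically* clustered filtering that
NRI/NTI can detect. Responder clades and planted drivers override
their taxa's shares with bloom trajectories
share(d) = carrying·(1 − e^{−rate·(d−start)})·e^{−decay·(d−start)},
and the background is rescaled to the remaining mass, so configured
target shares are exact expectations. Counts are drawn
Dirichlet-multinomial at fixed depth, so column sums equal the depth
exactly.

Default treatment settings are qualitative calibrations to the
observed trajectory shapes, chosen once: early-bloom-then-decline
clades in all amended bottles, late-bloom specialist clades in the
oil+biosurfactant and oil-only treatments, a sustained opportunist
clade in the synthetic-dispersant treatments, and filtering strength φ
increasing from controls (0.5–1) through oil treatments (2) to the
synthetic-dispersant treatments (3); the in-situ baseline is
unfiltered. A separate two-group generator plants per-taxon fold
changes at median baseline rank — keeping the planted mass small so
compositional renormalization does not convert background taxa into
genuine changes — for false-discovery calibration.

What the generator does *not* emulate: sequencing error and chimeras,
taxon–taxon interactions (e.g. predator–prey dynamics), temporal
autocorrelation within a bottle beyond the deterministic trajectories,
and any coupling between the community and the chemistry module.
Passing tests therefore demonstrate statistical correctness and
recovery of planted structure under the stated noise model, not
performance on real amplicon data.

## Problem sizes and numerical choices

Calibration experiments run at sizes chosen to estimate the relevant
moments tightly while staying desk-scale: neutral-assembly SES
calibration at 500 communities × 199 nulls in the test suite (200 in
the acceptance script), planted-filtering detection at 50 communities
of 300 taxa (φ = 8, depth 10 000, alongside an unfiltered treatment so
the sampling pool spans the tree, as it does when all treatments share
one ASV table), driver recovery at 50 seeded runs, greedy-vs-exhaustive
comparison at 10 taxa × 40 instances, redundancy sweeps at 20 seeds per
ρ, and false-discovery calibration at 100 simulations.

All randomness flows from `numpy.random.default_rng`; the pipeline
spawns one child seed per stage from a single master seed via
`SeedSequence(master, spawn_key=(stage_index,))`, so stages re-run in
isolation reproduce their outputs and two runs with the same master
seed are byte-identical (timings are logged to stderr, never written
into outputs). Ties in the greedy subset search are explored via
restarts rather than jitter; equality comparisons on permutation
statistics use a 10⁻¹² slack so exact ties count as exceedances.

## Known limitations

- NTI's sensitivity to filtering saturates when sequencing depth makes
  every taxon present in every sample (the nearest-taxon structure
  stops changing); detection needs realistic sparsity, which the
  defaults provide.
- Attenuation is a single-parameter summary; intercept/buffering-style
  extensions are out of scope.
- The heat-tree statistic is tabular only (per-taxon log-ratios and
  q-values); no taxonomic-tree aggregation or rendering.
- The chemistry module starts from integrated peak areas; chromatogram
  processing, retention-time alignment, and instrument effects are out
  of scope.
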