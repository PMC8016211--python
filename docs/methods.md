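# Methods

## Alignment handling

Per-locus alignments are stored upper-case over {A,C,G,T,-,N} plus the
IUPAC ambiguity codes; RNA `U` is mapped to `T` on input. Harmonization
restricts all loci to the strain-id intersection (or an explicit id list);
column trimming is never inferred — if the loci were trimmed to match
reference sequences, the coordinates must be supplied explicitly per locus
(`trim[locus] = (start, end)`), because guessing trim windows is not
reproducible. Concatenation records half-open per-locus column intervals.

Site classification and distances use unambiguous bases only. A column is
*conserved* when exactly one distinct base is present (gaps/ambiguity
ignored), *variable* with ≥ 2 distinct bases, *parsimony-informative* when
≥ 2 bases each occur in ≥ 2 sequences, and a *singleton* otherwise;
columns with no unambiguous base fall in no class. Distances use pairwise
deletion by default (a complete-deletion option drops any column with a
gap/ambiguity in any row). Model corrections are the closed forms

- JC69: d = −(3/4)·ln(1 − 4p/3)
- K2P: d = −(1/2)·ln(1 − 2P − Q) − (1/4)·ln(1 − 2Q)
- T92: d = −h·ln(1 − P/h − Q) − ((1−h)/2)·ln(1 − 2Q), h = 2θ(1−θ)

with p the mismatch proportion, P/Q transition/transversion proportions and
θ the alignment GC content. A non-positive log argument raises a saturation
error naming the pair rather than returning a non-finite value.

ANI is computed as alignment-fraction identity over the shared MLSA loci
("MLSA-ANI", 100·(1 − p-distance)), not whole-genome ANI; the conventional
> 95% species-membership heuristic applies to these values.

## Trees and clade support

Neighbor joining follows Saitou & Nei with two determinism rules: the
Q-matrix minimum is tie-broken by lowest (row, column) index, and negative
branch-length estimates are clamped to zero with the deficit moved to the
sister branch so the pair's summed length is preserved. Bootstrap supports
resample alignment columns with replacement; the support of an internal
edge is the percentage of replicate trees containing the same bipartition,
with bipartitions canonicalized as the side not containing the smallest
leaf label (invariant to rooting and child order). Supports are stored as
percentages; raw replicate counts are kept alongside. Rooting for clade
logic is by outgroup when configured, otherwise midpoint.

## Likelihood engine

Site likelihoods use Felsenstein pruning with pattern compression (unique
columns weighted by multiplicity). Rate matrices are reversible
(Q_ij = s_ij·π_j) and normalized to one expected substitution per site.
Rate heterogeneity uses the discrete-gamma approximation with category
rates equal to the means of equal-probability quantile bins (4 categories
by default); the invariant-sites class is a zero-rate mixture component,
with the variable categories rescaled by 1/(1−p_inv) so the mixture mean
stays 1. Ambiguity codes enter as indicator partial likelihoods over their
compatible bases; gaps are uninformative.

Optimization is coordinate ascent: each sweep recomputes tipward and
rootward partials once, reduces every branch to a cheap one-dimensional
problem solved by bounded Brent search (branch lengths in [1e-8, 10]), and
then optimizes each free model parameter by bounded scalar search. Partials
go stale within a sweep as branches update, so each sweep ends with an
exact recomputation and reverts wholesale if it failed to improve; the
reported lnL trace is therefore non-decreasing. Convergence is declared
when a sweep improves lnL by less than the tolerance (1e-6 by default;
non-convergence at the round cap is flagged on the result, not an error).
GTR base frequencies are taken as empirical counts; the GT exchangeability
is fixed at 1 for identifiability, leaving 5 free exchangeabilities + 3
frequencies (8 parameters), K2P has 1 and T92 has 2 (κ and GC).

Topology search is best-improving NNI: candidate swaps are scored at
current branch lengths, the best accepted, branches re-optimized, repeated
to a local optimum. Model selection optimizes each candidate on the same
tree and ranks by BIC (default) or AICc, with
BIC = −2lnL + k·ln(n) and AICc = −2lnL + 2k + 2k(k+1)/(n−k−1), n = columns.

Simulation draws root states from the stationary frequencies, assigns each
site a rate category (possibly invariant), and propagates states through
per-branch transition matrices; it is deterministic under a fixed seed.

### Congruence test

The congruence test is a parametric bootstrap of the likelihood gain of a
free gene tree over the multilocus reference topology. The constrained fit
optimizes branch lengths and model parameters on the reference topology
pruned to the locus' taxa; the free fit is an NNI hill climb from the
locus' own NJ tree, reusing the constrained fit's model parameters as
shared nuisance parameters. δ = lnL_free − lnL_constrained (clamped at 0;
the same clamping is applied to the null replicates, keeping the comparison
symmetric). B data sets are simulated under the constrained fit, δ*
recomputed for each with the same reduced-effort optimizer settings, and
p = (1 + #{δ* ≥ δ})/(1 + B) — the +1 correction keeps Monte-Carlo p-values
strictly positive. B ≥ 19 is enforced as the minimum resolution.

## Genospecies assignment

For each query leaf the assignment walks rootward and anchors at the first
(hence smallest) clade whose edge support exceeds the threshold (60 by
default) and which contains at least one reference strain. Terminal edges
are trivially supported, so a query forming a cherry with a reference
anchors at the cherry's parent. The label is the clade's reference species;
when several species occur in the anchor clade, the species of the
patristically closest reference is used and the ambiguity recorded. A query
whose only qualifying clade is the whole tree is labelled
`unclustered:<id>`; maximal supported clades consisting entirely of such
queries become `novel:<k>` genospecies, numbered in decreasing size.

The genospecies × symbiovar cross-tabulation always recomputes margins
from the cells (printed tables can carry margin errors); strains lacking
the symbiotic locus are dropped with a recorded count. The composition
test between collections is a Fisher-style exact test of homogeneity on
the 2×K count table: full network enumeration when the number of tables
with the observed margins is ≤ 1e6 (p = total conditional probability of
tables no more probable than observed), otherwise fixed-margin Monte Carlo
with the +1 correction.

## Diversity

π is the mean pairwise p-distance (pairwise deletion). Haplotypes are
exact sequence matches after masking columns containing any gap/ambiguity
within the group; locus diversity is Nei's unbiased h per locus averaged
across loci — this definition reproduces the boundary behaviour of
published per-group tables (h = 1.000 for two distinct haplotypes at n = 2,
0.000 for monomorphic loci). Shannon uses natural logarithms. Group
comparisons use a two-sided permutation test on the metric difference with
the +1 correction.

## Spatial statistics

Geographic distances are haversine great-circle distances at Earth radius
6371.0088 km. The Mantel statistic is the Pearson correlation of
upper-triangle entries, with a one-sided (greater) permutation p by
simultaneous row/column permutation — one-sided because isolation by
distance predicts positive association; a two-sided alternative is a flag.
The partial Mantel correlates the residuals of both matrices after linear
regression on the covariate matrix, permuting the focal matrix and
re-residualising per draw. Exact collinearity with the covariate raises an
error rather than returning 0/0.

PCoA is Gower double-centering (−½·J·D²·J) followed by
eigendecomposition; coordinates are eigenvectors scaled by √λ on positive
axes, negative eigenvalues are reported but their axes omitted.

The sliding-window curve moves an 80 km window in 10 km steps over pair
geographic separations; the observed value per window is the mean genetic
distance of randomly drawn eligible pairs (a single pair by default,
matching the resampling design the package emulates; `n_resamples` is
exposed because one pair per window yields high-variance curves), and the
null draws the same number of pairs irrespective of distance. Windows with
no eligible pair are reported absent (NaN), never zero. The species-level
pair distance is the 0/1 same-genospecies indicator — the minimal
consistent choice for a categorical level.

PERMANOVA is sequential (Type-I) distance-based partitioning in the
McArdle–Anderson trace form: SS_j = tr(H_{1..j}G) − tr(H_{1..j−1}G) on the
Gower-centred matrix G, pseudo-F_j = SS_j / (SS_res/df_res). p-values use
Freedman–Lane permutation of residuals under the reduced model
(G* = H_r G H_r + P(I−H_r)G(I−H_r)Pᵀ). The SS column is exported as
"pseudo-χ²" to mirror the conventional table layout for distance-based
environmental ANOVA. Covariates are z-scored; complete cases only.

## Synthetic studies

The generator emulates a two-collection regional survey: 95 strains by
default in 8 genospecies with a dominance structure (two lineages at ~1/3
each, a tail of rare clades), four housekeeping loci of 548/461/349/784 bp
and one 465-bp symbiotic locus, GTR+G (α = 0.5) with mildly asymmetric
exchangeabilities and frequencies. The genospecies tree is a random-join
ultrametric backbone (root-to-crown 0.05 substitutions/site) with
random-join within-genospecies subtrees (crown-to-tip 0.005), giving
within-clade π near 0.01 and between-clade divergence near 0.1 — the
order-of-magnitude separation seen in housekeeping-gene surveys of
*Rhizobium*. One reference strain per genospecies sits inside its clade;
off-panel references (3 by default) are extra deep lineages, so reference
panels are more diverse than the local sample.

Horizontal transfer: with probability `hgt_probability` (0.3 by default) a
strain's symbiotic locus belongs to a uniformly chosen donor genospecies;
the symbiotic tree is built with transferred strains grafted into the
donor clade before simulation, so gene trees are genuinely incongruent
rather than post-hoc sequence swaps. One genospecies (the
*Agrobacterium*-like cluster, index 7) lacks the symbiotic locus entirely.

Geography: with spatial decay λ = 0 (the default null) coordinates are a
single uniform field over a 400 km region; with λ > 0 each genospecies
gets a Gaussian cluster with σ = extent/(1 + 3λ). The two collections have
contrasting soil pH ranges (4.68–6.44 and 6.0–8.78); one genospecies
(index 4) is pH-restricted: it only occurs above pH 6.5 — just over the
first collection's ceiling — so it appears only in the high-pH collection,
reproducing a composition difference attributable to a single clade.

What the generator does *not* emulate: within-locus recombination,
coalescent demography, indels, rate variation among loci, sampling gaps,
or sequencing error. Passing tests therefore demonstrate that the
statistics recover the signals they target under a clean generative model,
not that real surveys of equal size have equal power.

## Validation problem sizes

The recovery harnesses run at desk scale: assignment accuracy and the
composition test use one full-size study (95 strains, 100 bootstrap
replicates); Mantel type-I error uses 100 null studies of 60 strains
(5 × 400-bp loci) and power uses 25 studies at the calibrated λ = 2.0 — a
clustering strength at which same-genospecies strains co-occur within a
fraction of the region, chosen with a small pilot grid before freezing;
the congruence harness uses five replicate 12-strain studies (6
genospecies × 2 strains, 400-bp loci, B = 19, K2P+G) with hgt = 0.3,
scoring the symbiotic locus' flag rate against the clonal loci's rejection
rate. These sizes keep the whole validation suite within a few minutes
while leaving comfortable statistical margins.

## Numerical and degenerate-input choices

Site likelihoods are clipped at 1e-300 before logs. Brent searches use
xatol 1e-4 (branch lengths and model parameters). Distances of identical
sequences are exactly 0; distance matrices are symmetrized against
floating-point drift. A Mantel test on a constant matrix (e.g. the
haplotype level when every strain is unique) is undefined and raises; the
pipeline records such rows as absent and continues. All stochastic stages
draw their seeds from one master seed via `numpy.random.SeedSequence`
spawning, making the pipeline summary byte-identical across reruns.
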