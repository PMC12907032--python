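# Methods

`halo` implements a null-model analysis chain for sediment microbial
communities sampled along a salinity gradient: niche-breadth
classification of taxa, inference of community assembly processes,
community diversity statistics, and signed co-occurrence networks, plus a
synthetic community generator used to validate every stage against known
ground truth.

## Niche-breadth classification

For each taxon *j* the proportional distribution *p&#8321;…p_R* of its
reads over *R* environments (by default every sample is its own
environment; salinity categories are an optional coarser grouping)
yields three indices:

* Levins' niche width `B_n = 1 / (R · Σ pᵢ²)`, bounded in `[1/R, 1]`;
  1 means perfectly even habitat use, `1/R` means confinement to one
  environment;
* occurrence, the number of environments with at least one read;
* habitat Shannon entropy `−Σ pᵢ ln pᵢ` (nats).

The permutation null redistributes each taxon's total read count across
samples by a multinomial with probabilities proportional to sample totals
(after rarefaction, uniform): taxon totals are preserved exactly and
sample totals in expectation. An exact fixed-fixed alternative (random
contingency tables with both margins preserved, Patefield sampling via
`scipy.stats.random_table`) is available for sensitivity analysis. A
taxon is labelled *specialist* when its observed index falls below the
equal-tailed 95% interval of its own null distribution, *generalist*
when above, *non-significant* otherwise. The default "triple" mode
requires all three indices to deviate in the same direction; `bn_only`
applies the Levins rule alone. Intervals are per-taxon because the null
width depends strongly on a taxon's total abundance.

**Power asymmetry (important limitation).** Any null that preserves a
taxon's own read total and places reads with expected proportionality to
sample totals concentrates the null indices at the *even* end of their
range. An observed taxon can therefore fall below the interval
(specialist) with high power, but can exceed it only at the nominal
false-positive rate, whatever its true breadth: sampling noise alone
separates a genuinely even taxon from the null's near-even draws.
Generalist calls from this family of nulls are consequently
near-powerless against smooth broad-niche taxa, and the classifier
should be read as a calibrated specialist detector with a conservative
generalist arm. The type-I rate of the whole procedure is verified on
neutral simulations; specialist recovery and label monotonicity are
verified on planted niches.

## Community assembly inference

For every unordered sample pair:

* **βMNTD** — the mean over taxa present in one community of the
  patristic distance to the nearest taxon in the other, averaged over
  both directions; abundance-weighted by default (each taxon weighted by
  its relative abundance within its own community), presence/absence by
  flag. The abundance-weighted definition matches
  `picante::comdistnt(abundance.weighted=TRUE)` exactly; the unweighted
  variant averages the two directional means (picante pools them).
* **βNTI** — the z-score of observed βMNTD against a null that shuffles
  taxon labels across the tips of the phylogeny (taxa swap positions;
  abundances untouched), 999 randomisations by default. The
  randomisation pool is every taxon in the analysed table, so βNTI
  should be computed on the full table and subset to pairs of interest
  afterwards. Pairs with identical taxon sets are degenerate (observed
  and all null βMNTD are 0) and reported as NaN with a warning. βNTI is
  invariant to uniform rescaling of branch lengths. Internally each
  randomisation computes one per-sample vector of taxon-to-community
  minimum distances and obtains all pairs by a single matrix product,
  which keeps 70-sample × 999-randomisation problems in seconds.
* **RC_bray** — Raup–Crick on Bray–Curtis. Null communities preserve
  each sample's observed richness and read total: taxa are drawn without
  replacement with probability proportional to occupancy frequency
  (Gumbel top-k, distributionally identical to successive weighted
  sampling), each drawn taxon receives one read, and the remaining reads
  are allocated multinomially proportional to metacommunity relative
  abundance. `RC = 2·[#(null BC < obs) + ½·#(ties)]/n_null − 1 ∈ [−1, 1]`,
  ties at half weight.

Processes are assigned with the standard thresholds: βNTI > 2
heterogeneous selection; βNTI < −2 homogeneous selection (the
literature's occasional misprint "|βNTI| < −2" is unsatisfiable and is
implemented as the signed rule); otherwise RC_bray > 0.95 dispersal
limitation, RC_bray < −0.95 homogenising dispersal, else undominated.
Per-category summaries use only pairs whose two samples share the
category, since a mixed pair has no single category.

## Diversity statistics

PERMANOVA is the multi-term sequential (Type-I) sum-of-squares
distance-based linear model: Gower-centred `−D²/2`, per-term SS by
projection onto the cumulative QR design, pseudo-F against the residual,
p from free permutation of sample labels,
`p = (1 + #{F* ≥ F}) / (n_perm + 1)`. Continuous covariates, factors and
`a:b` interactions are supported; term order matters for correlated
covariates (total SS is invariant), matching `vegan::adonis2(by="terms")`
— agreement with adonis2 is asserted in the test suite. Saturated models
(zero residual SS) report infinite F and the design's smallest achievable
p. A VIF diagnostic on the continuous covariates is provided.

Alpha diversity: richness, Shannon entropy (nats), and Faith PD (total
branch length of the rooted subtree spanning the present tips, path to
the root included — the common QIIME convention). Wilcoxon rank-sum
tests use the exact distribution for min(n) ≤ 25 without ties, else the
tie-corrected normal approximation; identical multisets return p = 1.

Distance–decay regressions fit community similarity (1 − Bray–Curtis) by
OLS on haversine geographic distance (sphere radius 6371.0088 km) or on
absolute differences of z-standardised salinity, per season stratum and
pooled. Pair-level OLS ignores the pseudo-replication of pairwise
designs; a matrix-level Mantel permutation p can be reported alongside
the pooled fit.

## Co-occurrence networks

Counts are filtered at a total relative abundance threshold (0.01% by
default) within the sample set under analysis, CLR-transformed
(`log(count + 0.5)` centred per sample), and a sparse signed
conditional-dependence graph is inferred by neighbourhood selection:
every taxon is lasso-regressed on all others along a 20-point log-spaced
penalty path; an edge exists where either coefficient is nonzero (OR
rule; AND by flag) and its sign and weight come from the symmetrised
coefficients. The penalty is selected by StARS: 20 random 80% subsamples
per penalty, edge instability `2θ(1−θ)` averaged over node pairs,
monotonised from the sparse end, and the smallest penalty with
instability ≤ 0.05 is kept. This is an in-house neighbourhood-selection
implementation of sparse compositional network inference; no numeric
parity with any particular existing tool is claimed. Validity is checked
by false-positive control on independent data and by F1 ≥ 0.8 recovery
of a planted 10-node chain precision matrix at n = 500.

Topology summaries: degree, density, path length and diameter on the
largest connected component (sign-ignored, unweighted), mean local
clustering, eigenvector centrality on |weight| computed per connected
component, modularity of a deterministic greedy partition on absolute
weights, and positive/negative edge percentages partitioned by endpoint
niche labels into four mutually exclusive classes (generalist-involving
= at least one generalist and no specialist; specialist-involving
symmetrically; generalist–specialist; others), as percentages of all
edges so the classes of each sign sum to that sign's total.

## Synthetic community generator

The generator produces the statistical structure the analysis assumes,
with ground truth for recovery tests:

* **Tree** — Yule pure-birth, ultrametric, rescaled to unit height.
* **Niche optima** — Brownian motion along branches with an early-burst
  damping `exp(−c·depth)` (default conservation c = 1), then min–max
  mapped onto the salinity range. The damping concentrates trait
  divergence on deep branches so salinity preference clusters by clade,
  the signature of a deeply conserved trait; c = 0 recovers
  rate-homogeneous Brownian motion, and a zero Brownian rate collapses
  all optima to the root value.
* **Niche breadths** — two-component: a planted generalist fraction
  (default 20%) receives σ ≈ 60 g/L, the rest σ ≈ 8 g/L, lognormal
  jitter 0.15. These are the planted labels against which classification
  is scored.
* **Design** — nine sites × four seasons × replicates over 0–150 g/L.
  Default site layout groups sites into three monotone salinity clusters
  (estuarine / intermediate / hypersaline), the geometry of a lagoon
  whose categories each contain several similar-salinity sites; a
  uniform layout is available. Seasonal offsets span ±10 g/L (autumn
  high, winter low), coordinates follow a gentle ~100 km arc so
  geographic and salinity distances correlate without coinciding, and
  temperature, pH, dissolved oxygen and organic matter co-vary with
  season and salinity plus noise.
* **Counts** — expected relative abundance mixes a deterministic
  Gaussian-niche term `A_j · exp(−(s_i − μ_j)²/2σ_j²)` (with a hard
  tolerance cutoff at suitability 10⁻³ of the optimum, i.e. ±3.7σ) with
  a shared lognormal metacommunity at neutral weight `w ∈ [0, 1]`;
  multinomial sampling at a fixed library size (11,400 by default).
  `w = 1` is the neutral limit with identical expected composition in
  every sample; `w = 0` is pure environmental filtering.

What the generator does *not* emulate: overdispersion beyond
multinomial sampling, true dispersal kernels or drift chains (the
neutral component is a shared metacommunity draw, sufficient to create a
stochastic-assembly signal without per-sample history), patchy
cosmopolitan taxa, sequencing error, or the ~10⁴–10⁵-taxon pools of real
amplicon data. Passing tests therefore demonstrate calibration and
recovery under clean compositional sampling, not robustness to real-data
artefacts.

**Problem-size note.** The magnitude of βNTI grows with the size of the
taxon pool and the volume of between-sample turnover (the null's
coefficient of variation shrinks roughly with the square root of the
number of unshared taxa). The deterministic-assembly demonstrations
therefore use pools of ~1200 taxa with narrow conserved niches, where
within-category pairs show strong phylogenetic clustering; at a few
hundred taxa with a neutral component, βNTI magnitudes are intrinsically
compressed even under real filtering — a scale effect, not an
implementation artefact, and the reason real whole-ASV-table analyses
(tens of thousands of taxa) resolve selection so sharply.

## Numerical and reproducibility choices

* Rarefaction is multivariate-hypergeometric (without replacement);
  samples below depth are dropped with a warning.
* Salinity categories are half-open: [0, 40) low, [40, 100) mid,
  [100, ∞) high; the boundary values belong to the upper bin.
* All randomised stages take integer seeds; the pipeline derives
  per-stage seeds from one master seed via `SeedSequence.spawn`, records
  them in the run manifest with sha256 checksums of every artifact, and
  is bit-reproducible for a fixed configuration.
* RC ties are detected at 10⁻¹² absolute tolerance; unclassifiable
  (NaN) pairs get an explicit `unclassified` sentinel.
* Unrooted input trees are midpoint-rooted with a logged notice;
  missing branch lengths are treated as zero.

## Known limitations

* Generalist detection is near-powerless under total-preserving
  permutation nulls (see above); reported generalist fractions should be
  treated as lower bounds.
* The greedy modularity partition is deterministic but not optimal;
  modularity values are comparable across runs of this package, not
  across community-detection algorithms.
* Sequential-SS PERMANOVA inherits order dependence on correlated
  covariates by design; put the focal covariate first or compare both
  orders.
* The network inference assumes approximately Gaussian CLR profiles and
  n not too far below p; with few samples per category the stability
  selection returns conservative, sparse graphs.
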