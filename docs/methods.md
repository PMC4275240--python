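# Methods

## Data model

Three delimited-text inputs: a genetic map (marker, chromosome, position in
cM; positions strictly increasing within a chromosome), a lines x markers
genotype table over the two parental alleles of a RIL cross (no
heterozygotes; missing entries allowed), and a traits x samples matrix of
normalized expression intensities whose sample headers encode
`line:replicate`. Genotypes are stored as parent-1/parent-2/missing codes;
allele letters are configurable at read time.

### Expression filter

Array intensities for unexpressed genes cluster at a background level, so
the per-trait **mean intensity over all samples** is fitted with a
two-component univariate normal mixture by EM (k-means initialization with a
fixed seed; variance floored at 1e-4 of the data sd; convergence on relative
log-likelihood change). Traits with posterior probability > 0.5 of the
lower-mean component are removed. The mean was chosen as the per-trait
summary because it is the simplest statistic that separates background from
expressed traits; the fitted mixture is returned so the same decision rule
can be re-applied (the filter is idempotent under a fixed fit). A fit is
flagged *degenerate* — and nothing is removed — when the trait means carry
essentially no variance, since no second component is then supported.

## Co-expression modules and meta-traits

Pearson correlation over samples -> unsigned soft-threshold adjacency
`a_ij = |r_ij|^beta` (default `beta = 6`, the canonical unsigned-network
default; exposed as a parameter) -> topological-overlap dissimilarity

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),   d_ij = 1 - TOM_ij

with `l_ij` the shared-neighbour sum and `k_i` the node connectivity, ->
average-linkage hierarchical clustering.

The branch cut is a deliberately simple top-down approximation of dynamic
tree cutting: a static cut at the 0.99 quantile of merge heights gives a
rough segmentation; a cluster is split recursively when its dendrogram root
separates two branches of at least `min_module_size` (default 5) traits
whose mean between-branch dissimilarity exceeds the larger within-branch
mean by more than `split_gap` (default 0.05) of the cluster's dissimilarity
spread; undersized clusters are merged into the module with the nearest
average dissimilarity. The separation criterion is measured relative to the
spread because TOM dissimilarities of weakly connected networks compress
into a narrow band just below 1; an absolute or root-relative gap cannot see
structure there. The procedure recovers planted partitions (2 x 15 blocks at
correlation 0.9, and the simulation design's 4 x 15 blocks at correlation
0.4 with n = 211) exactly or with adjusted Rand >= 0.9; on unstructured data
it returns large merged modules rather than inventing structure.

Each module's **meta-trait** is the first principal component of its
standardized traits (zero mean, unit sd per trait, so the PCA is on the
correlation scale and variance-explained is comparable across modules). The
PC sign is anchored to correlate positively with the module's mean
standardized expression, removing the sign indeterminacy that would
otherwise flip downstream effect signs between runs.

## The two-locus NOIA model for RILs

With only two homozygous genotype classes per locus there is no dominance
term. The statistical (frequency-centered) coding assigns
`code(P1) = -2 p2`, `code(P2) = 2 p1` from the allele frequencies observed
in the fitted sample, which satisfies zero mean and span 2, reducing to the
±1 design under balanced frequencies. Two loci combine by the Kronecker
construction into the design `(1, x_A, x_B, x_A x_B)`; under between-locus
independence the columns are orthogonal and `X'X` is diagonal.

The fit is ordinary least squares; replicates enter as independent
observations sharing a design row (no random line effect is modelled; a
per-line averaging flag is not provided because observation-level OLS uses
the replicate information directly). The epistasis test is the two-sided
t-test on the interaction coefficient (equivalent to the 1-df F-test).
Heritability per effect is its sequential sum of squares (order: intercept,
A, B, AxB, computed from the QR decomposition) over the total sum of
squares; under an orthogonal design this equals the marginal decomposition
and always sums exactly to the model R². Under linkage disequilibrium the
decomposition is order-dependent and the fit is flagged non-orthogonal.
Degenerate inputs are refused: monomorphic markers (no additive contrast),
zero-variance traits, fewer than 5 jointly observed samples, and
(near-)aliased pairs with `|cor(x_A, x_B)| > 0.99`, which scans skip and
log rather than abort on.

## Hierarchical scan and tree FDR

Framework markers are selected greedily per chromosome: keep the first
marker, then the first marker at least `spacing_cm` (default 10) beyond the
last kept one. Every marker is assigned to the region of its nearest
framework marker (cM distance, ties to the earlier marker), so regions
partition each chromosome.

Level 1 tests all (trait-unit, framework-pair) combinations — including
intra-chromosomal pairs — as **one** BH family. Each rejected level-1
hypothesis opens a level-2 family: the same unit against all pairs from the
cross product of the two parent regions, excluding the already-tested
parent pair. Both levels use the BH linear step-up procedure at

    q* = q / (2 delta),

and the report records the realized full-tree FDR bound
`2 * delta * pi_hat * q*` (`pi_hat = 1` by default, the conservative
choice). `delta` has three modes: the universal bound 1.44 (default), a
user-supplied value, or a permutation estimate. The permutation estimate
relabels lines of the trait matrix relative to the genotypes (preserving
replicate structure), reruns the two-level procedure, and averages the
realized per-family factor over families with at least one rejection. The
realized factor is defined here as `R_f^(1/R_f)` for a family with `R_f`
rejections: its supremum over integers is `e^(1/e) ~ 1.4447`, consistent
with the universal bound, it approaches 1 for families with many
discoveries, and full-null resamples average just above 1.

The direct (non-hierarchical) baseline tests all dense marker pairs in a
single BH family at level `q`.

## Simulation engine

The generator emulates a two-parent RIL eQTL study:

- **Map** (default): 3 chromosomes x 4 framework regions at 10 cM spacing,
  6 markers per region at 0.9 cM spacing (kept inside half the region
  spacing so nearest-framework assignment preserves the regions). A
  5-chromosome, 493-marker variant at the same sub-cM density provides
  study-scale combinatorics (47 framework markers at 10 cM).
- **Genotypes**: per chromosome a Markov chain; first marker parent-1 or
  parent-2 with probability 0.5, then switches with probability
  `R = 2r/(1+2r)`, `r = 0.5 (1 - e^(-2d/100))` for map distance `d` —
  the accumulation of recombination over repeated selfing.
- **Traits**: 4 clusters x 15 traits (defaults), 211 lines x 2 replicates.
  Two clusters are epistatic: 13 of their 15 traits share a cluster-specific
  marker pair (one inter-chromosomal and one intra-chromosomal pair, placed
  on framework markers) carrying 0, 1 or 2 main effects of 0.4 and an
  interaction coefficient of about -0.2 on ±1-coded genotypes; the two
  remaining traits are noise, emulating imperfect cluster assignment.
  Noise is Gaussian with sd 2.5; inside non-epistatic clusters a shared
  factor induces trait-trait correlation 0.4. Epistatic clusters receive
  independent noise by default (their correlation arises from the shared
  genetic effects); a flag extends the 0.4 factor to them, but doing so
  swamps the pooled interaction signal and collapses meta-trait power.
  The baseline mean (8.0, a typical normalized-intensity level) is
  inconsequential for every statistic computed.
- **Scoring**: the detection unit is the trait (single mode) or meta-trait
  (meta mode). A unit counts as detected if it appears in at least one
  discovery at either level; power is the detected fraction of truly
  epistatic units, and the per-run false-discovery proportion uses the
  `max(1, detections)` convention. Heritability statistics average the
  fitted interaction heritability over true-positive discoveries.

Experiments run `n_reps` independent replicates (default 200, giving
standard errors of ~0.01-0.03 on power) from seeds spawned off one master
seed, so the hierarchical and direct runners see identical data when given
the same configuration. Meta-trait runs use the true cluster assignments by
default (the clustering step has its own planted-partition validation);
full WGCNA-style clustering can be run on simulated data through the
library API. The simulation scans use q = 0.2 and the fixed bound
delta = 1.44.

## Known limitations

- The synthetic map has evenly spaced, equally sized regions; real RIL maps
  have irregular marker density, so secondary-marker families there vary in
  size (roughly 100-200 pairs at study scale versus exactly 35 here) and
  linkage between a framework marker and its region is less uniform.
  Consequences measured on the synthetic design: with densely packed
  near-equivalent secondary pairs, the direct single-family BH baseline
  gains rejections from blocks of correlated true pairs, which narrows (and
  at small effects can invert) its power gap to the hierarchical scan.
- The meta-trait is a *sample* first PC. When the only within-cluster
  correlation is a weak shared genetic effect (no main effects, interaction
  ~0.2 against noise sd 2.5), the leading eigenvalue sits below the
  detection threshold at p = 15 traits and n = 422 samples, the PC aligns
  poorly with the equal-weight signal direction, and meta-trait power drops
  well below what a perfectly aligned average of the cluster traits would
  achieve. Passing tests on the generator therefore demonstrate pipeline
  correctness under the stated generative design, not that a sample PC
  recovers arbitrarily weak pooled signals.
- EM filtering uses trait means only; bimodality inside a trait's sample
  distribution is not modelled.
- Trees deeper than two levels, signed networks, soft-threshold selection by
  scale-free fit, dominance terms and >2-locus interactions are out of
  scope.
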