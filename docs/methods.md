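# Methods

`clonodiverge` analyses discrete morphological characters (chiefly setal
counts and presence/absence states) scored on individuals from a panel of
clonal strains.  Because all individuals of a clonal strain are
genetically identical, between-strain variation is genetic variation;
within-strain variation is developmental and environmental noise.  The
pipeline quantifies divergence per character, partitions variance into a
broad-sense heritability, codes the divergent characters into a binary
taxon matrix, and infers relationships among strains by exact maximum
parsimony and by UPGMA clustering with multiscale-bootstrap support.

## Character models and divergence tests

Each character is modelled with a generalized linear model with the
strain label as the only covariate:

* **binomial / logit** for two-state characters (presence/absence, or
  counts grouped into two states — see *Character coding*);
* **Poisson / log** for wide-range setal counts.

Divergence between strains is the analysis-of-deviance likelihood-ratio
statistic, `χ² = D(intercept-only) − D(strain-factor model)`, referred to
a chi-square with `(#strains with data − 1)` degrees of freedom.  A
single χ² per character on k−1 df is what a model-comparison test
produces; a Wald test would give per-level statistics instead.  No
multiple-testing correction is applied: per-character raw p-values with a
fixed α = 0.05 gate are the interface, and the gate is configurable.

The IRLS fitter is written out explicitly (canonical links, convergence
when the relative deviance change drops below 1e-10, at most 100
iterations).  The one numerical subtlety is complete separation: a strain
whose cell is all-0 or all-1 has its MLE at infinity on the link scale.
The linear predictor is clamped at ±30, which puts the fitted cell
deviance within ~1e-10 of its boundary limit — LR statistics stay finite
and equal their supremum for all practical purposes, and the saturated
model's deviance is 0 to well below 1e-8.  Degenerate cells are reported
with their exact boundary mean and a flagged (undefined) Wald interval.

Missing observations are dropped per character (complete case): every
character is analysed on the individuals where it was visible.  Bilateral
characters contribute one observation per scored body side, treated as
independent; this matches per-side reporting conventions and keeps the
test's degrees of freedom a function of the strain count only.

## Broad-sense heritability

For clonal lineages the relevant summary is H² = σ²G / (σ²G + σ²E) with
σ²G the between-strain variance.  σ²G is estimated on the link (latent)
scale from a random-intercept GLMM; σ²E is fixed by the standard
latent-scale convention so H² is comparable across characters:

* binomial/logit: σ²E = π²/3 ≈ 3.2899 (logistic residual variance);
* Poisson/log: σ²E = ln(1 + 1/λ̄) with λ̄ the grand mean count
  (lognormal–Poisson approximation).

Estimation is a two-stage scheme.  Stage one is penalized
quasi-likelihood: iterate (a) the IRLS linearization (working response
and weights) and (b) REML estimation of σ²G on the working linear mixed
model, until σ²G changes by less than 1e-6.  The REML criterion uses the
Woodbury identity per strain block, so each evaluation is O(n); the
dispersion is fixed at 1 (the sampling models are exactly binomial and
Poisson here).  The σ²G = 0 boundary is permitted, with no jitter.

Stage two exists because PQL's linearization shrinks extreme strain
effects: with binary data and high intraclass correlation, strains fixed
at all-0/all-1 cap their working residuals and σ²G is biased downward
(we measured mean Ĥ² ≈ 0.74 at a true 0.80 with 50 strains × 50
individuals).  Since the model is an intercept plus one random effect,
the exact marginal likelihood is a one-dimensional integral per strain;
it is computed by adaptive Gauss–Hermite quadrature (per-strain posterior
mode and curvature by Newton steps, 25 nodes) and maximized over
(μ, log σ) starting from the PQL solution, with an explicit comparison
against the σ² = 0 boundary.  After refinement, mean Ĥ² recovers the
generative value within ±0.03 across both families and H² ∈
{0.2, 0.5, 0.8} at 50 strains × 50 individuals.  Stage one remains the
default initializer and is available alone via `refine=False`.

Only characters whose divergence test is significant enter the
heritability table; a `H2_high` flag marks values above 0.78, a
conventional cut separating the strongly strain-fixed characters.

## Character coding

Two codings are distinguished:

1. **Outlier grouping.**  Count characters whose distribution is nearly
   two-valued ("almost binomial": most mass on two adjacent counts, rare
   excursions) are grouped by a per-character integer threshold: values
   ≤ cut map to state 0, values above it to state 1.  The rule is total
   and monotone, so outliers automatically join their nearest common
   state.  Thresholds are part of the character specification (CSV
   column `cut`).  A threshold written as an overlapping pair of ranges
   (e.g. "≤2 / ≥2") is not a valid rule; when ingesting such a
   description the cut is placed at the boundary consistent with the
   character's variant range (here: between 2 and 3), and characters
   analysed as Poisson need no cut at all.

2. **Cladistic matrix.**  Restricted to significant characters, the
   per-strain response-scale means (sample proportions/means, equal to
   the GLM estimates) are centred by their unweighted across-strain
   average and scaled to unit sd (n−1).  The binary state is the sign:
   1 where the scaled mean is strictly above 0, else 0 — strains below
   the average mean carry state 0, and the exact boundary goes with
   "not greater".  Scaling cannot flip a sign, so the parsimony matrix
   depends only on the centring; it matters only for the distance
   analysis.  Constant columns are flagged uninformative (they are
   retained in parsimony scoring, where they add zero length, and
   dropped from the scaled clustering matrix, where they cannot be
   standardised).

## Maximum parsimony

Characters are unordered, equally weighted and reversible, so tree
length is Fitch parsimony, computed by the two-pass set-intersection
algorithm on an arbitrary rooting.  Internally each taxon's states are
packed into 2-bit fields of a single integer, making the inner loop
allocation-free.

The search is exact branch and bound: stepwise taxon addition generates
every unrooted binary topology at most once (taxon k inserts on each of
the 2k−3 edges), pruning a partial tree when its length plus an
admissible bound — one guaranteed change for every character state not
yet attached — exceeds the best complete length.  The initial bound is a
greedy addition tree; ties are kept (pruning uses strict inequality), so
the full set of most-parsimonious trees is returned.  Taxa are added in
a deterministic max-distance-first order (largest Hamming distances
first, label tie-breaks): front-loading divergent taxa makes partial
lengths grow early and tightens pruning several-fold, and the resulting
tree set is independent of the order.  With pruning disabled the same
code is an exhaustive enumerator, and the equality of both modes is part
of the test suite.

Tie structure can be degenerate: if several taxa share identical rows,
every resolution among them is equally short and the number of
most-parsimonious trees grows combinatorially (an 8-character matrix
whose columns all equal one bipartition of 12 taxa has 1,091,475 MP
trees).  `branch_and_bound` therefore takes a `max_trees` guard, and
`mp_consensus` streams the same exact enumeration through a running
split-set intersection without materializing trees, returning the strict
consensus, the optimal length and the tree count.  The pipeline uses the
materialized set when it is small and falls back to the streaming
consensus otherwise.

The strict consensus contains exactly the nontrivial splits present in
every MP tree (multifurcating where they disagree).  Rooting between two
externally specified clades (they come from prior molecular work, so
they are config data, not code) picks the edge whose split has clade A
on one side and clade B on the other; taxa outside both clades stay on
whichever side they attach to, and when several edges qualify — the
stray taxa sit on the path between the clades — the edge adjacent to
clade A's side is chosen deterministically, grouping the extras with
clade B.  If no edge separates the clades the library raises (listing
near-miss edges) and the pipeline keeps the consensus unrooted with a
warning.

## Distance analysis

The same scaled strain-mean matrix (significant characters, centred,
unit sd) feeds Euclidean distances and UPGMA (unweighted average
linkage): at each step the pair of clusters with the smallest
size-weighted average distance merges at height distance/2, giving an
ultrametric dendrogram whose cophenetic distances reproduce ultrametric
inputs exactly.  Ties break on the lexicographically smallest member
labels, documented because tie order can change topology on degenerate
inputs.

Cluster support is multiscale bootstrap resampling with characters
(columns) as the resampling unit — strains are the objects being
clustered, characters the replicated measurements.  For each scale
r ∈ {0.5, 0.6, …, 1.4}, `n_boot` (default 1000) resamples of
round(r·m) columns are drawn with replacement, re-standardised by
default (a toggle exposes the unscaled variant), and the dendrogram is
rebuilt; BP_r of an observed cluster is the fraction of resamples
containing it.  The scale-dependence is summarized by weighted least
squares of ψ_r = Φ⁻¹(1 − BP_r) on (√r, 1/√r) with binomial weights
n·φ(ψ)²/(BP(1−BP)), using only scales with 0 < BP_r < 1; the
approximately unbiased p-value is AU = 1 − Φ(v − c) and BP is reported
at r = 1.  Clusters recovered in every resample get AU = 1, never
recovered AU = 0, and fewer than two usable scales leaves AU undefined
(flagged).  All randomness flows from one seed; reruns are
bit-identical.

## Synthetic data generator

The generator emulates the study design the statistics were built for:
a dozen strains, about 8–12 individuals each, 18 characters of three
kinds (pure binary; near-binary counts with rare outliers; wide-range
counts), strain-level latent effects on the link scale, optional
two-clade structure, bilateral characters scored per side, and sporadic
missingness.  Per character, strain effects are Normal(0, σ²G) plus a
clade shift (±clade_coef·clade_effect/2 for clades A/B); individuals
(and sides) are independent Bernoulli/Poisson draws through the
canonical link.  Outliers on thresholded count characters are rare
outward excursions of 2–3 units past the common pair — single-occurrence
variants, the pattern the threshold rules exist to absorb — so
binarization still maps them to their nearest common state.  Sides are
conditionally independent given the strain effect: no left–right
correlation parameter, since the statistics model none.

The truth record stores every latent value and the implied latent-scale
H² per character — true H² uses the generative σ²G plus the population
variance of the clade offsets over the conventional residual, a realized
variant uses the drawn effects — so recovery tests never re-simulate.

Two preset designs are provided.  `study_default_config` is a realistic
reference panel: per-character families and baselines spanning the three
character kinds, σ²G back-computed from target heritabilities (from
~4% for noisy counts to ~94% for strain-fixed two-state characters) via
the latent-scale convention, half of the between-strain variance carried
by the clade split for the clade-patterned characters, four subcoxal
counts with no strain structure, and one sexual strain outside both
clades.
`two_clade_config` is the tree-recovery benchmark: 12 strains in clades
of 5 and 7, eight binary characters, clade separation 2.0 on the logit
scale over within-clade sd 0.5 (separation 4× the sd — the
strong-separation regime).  Under those conditions the rooted parsimony
consensus and the UPGMA dendrogram each recover the clades in ≥90% of
seeds; the study-shaped default carries deliberately weaker clade signal
and often yields a partly unresolved consensus, which is the realistic
behaviour for characters whose variance is mostly within-clade.

What the generator does **not** emulate: strain-by-strain distributions
of any real dataset, left–right correlation, age or culture-condition
effects, and observer error beyond random missingness.  Passing tests
therefore demonstrate correctness of the estimators and searches under
the stated generative model, not agreement with any particular empirical
dataset.

## Numerical and design choices

* GLM convergence: relative deviance change < 1e-10, ≤100 iterations;
  weights floored at 1e-12; link-scale clamp ±30.
* REML inner step: scalar optimization of log σ² on [log 1e-10, log 1e4]
  (bounded Brent, xatol 1e-9) with an explicit σ² = 0 comparison.
* PQL outer loop: ≤200 iterations, σ²G tolerance 1e-6, non-convergence
  flagged rather than silent.
* Wald intervals use ±1.96 exactly.
* Type-I calibration of the LR test at the study's size (12 strains × 10
  individuals) is ≈6% at α = 5% — the usual mild small-sample
  anticonservatism of deviance tests.
* Problem sizes used by the acceptance script: 20 GLM oracle instances;
  ~1000 null characters; 20 replicates per heritability condition at 50
  strains × 50 individuals (grid monotonicity at 25 × 25); 20 seven-taxon
  matrices against all 945 topologies; 20 eight-taxon UPGMA oracle
  matrices; 50 two-clade recovery seeds.
* All simulations take a single integer seed; every reported number is
  recomputed at run time.

## Known limitations

* H² for extremely strain-fixed binary characters (true σ²G ≳ 30 on the
  logit scale) is weakly identified at a dozen strains; estimates are
  honest but have wide sampling spread at the study's own size.
* The Poisson latent-residual convention ln(1 + 1/λ̄) ties σ²E to the
  observed grand mean; characters with strong clade structure shift λ̄
  and hence the H² denominator slightly.
* Branch and bound is exact but exponential; it is intended for ≤ ~15
  taxa.  The streaming consensus extends the feasible tie regime, not
  the taxon count.
* Multifurcating trees are scored by sequential pairwise Fitch, an upper
  bound on the multifurcating (Hartigan) length; all search-internal
  scoring is on binary trees, where the two-pass algorithm is exact.
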