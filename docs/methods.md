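# Methods

This note records the modeling choices, defaults and known limits of the
package. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Read-count model and EM

Alt-read counts at mutation *i* are Binomial(n_i, p_s(i)) with
p_s = ρ m φ_s / (ρ C_T + 2(1 − ρ)) for the clone *s* carrying the mutation.
The default model is diploid with multiplicity m = 1 (p_s = ρ φ_s / 2);
calls at loci with major + minor copy number ≠ 2 are excluded by default.
An `include_cn=True` flag keeps them using the general per-locus
denominator, with the M-step then a weighted approximation to the
heterogeneous-denominator MLE. Full multiplicity inference and
copy-number segmentation are out of scope: purity and allele-specific copy
numbers are inputs.

EM details:

- **Initialization**: φ from descending k-quantiles of the observed
  2·VAF/ρ, clipped to (0, 1], assigned to nodes by (depth, index) so the
  root receives the largest value; `restarts` (default 10) re-runs with
  multiplicative log-normal jitter (σ = 0.15). Mixture weights start
  uniform.
- **Constraint**: after each M-step, φ is projected onto the feasible cone
  by top-down subtree scaling so that Σ children ≤ parent and φ(root) ≤ 1.
  If a projection ever lowers the log-likelihood, the previous iterate is
  kept and the fit stops; the recorded log-likelihood trace is therefore
  non-decreasing by construction (and asserted in tests).
- **Stopping**: |Δ log L| < 1e-6 or 500 iterations; non-convergence returns
  the best iterate with a warning, never an exception.
- φ is floored at 1e-4 and success probabilities clipped away from {0, 1}
  to keep the log-pmf finite.

## Model selection and topology identifiability

All rooted tree shapes with 1–5 nodes (1, 1, 2, 4, 9 shapes) are fitted and
compared by BIC with 2k − 1 parameters for k nodes; a `criterion="ml"` flag
selects by raw likelihood instead (which is non-decreasing in k, hence the
BIC default).

Single-sample diploid data cannot distinguish topologies by likelihood
alone: any feasible branching prevalence set is also exactly representable
as a chain, so the chain's fit always ties or beats the branching fit. The
package resolves near-ties (Δ log L ≤ 0.5) by preferring the topology whose
implied clone proportions q(v) = φ(v) − Σ φ(children) maximize the minimum
clone, treating differences below 0.03 as no evidence, in which case the
topology with fewer leaves wins. The rationale: reading a balanced
branching pair as a chain forces an implausibly small intermediate clone,
whereas a dominant-founder chain read as branching never increases the
smallest clone. Consequences, verified by the recovery experiments:

- chains with a dominant founding clone are recovered as linear;
- branching trees with near-balanced siblings are recovered as nonlinear;
- **skewed (shallow-type) branching is structurally confounded with
  chains** in this data regime. Approaches with per-mutation multiplicity
  and copy-number information can break this tie; this package does not
  claim to. Shallow-vs-deep classification in the pipeline therefore
  operates on tree *shape features*, downstream of whatever reconstruction
  produced the trees.

**Recovery panel.** The seeded panel used in validation draws S ∈ {1, 2, 3}
tumors at depth 200, purity 0.7, ~25 mutations per clone: linear trees with
dominant, well-separated proportions, and branching trees with founder
proportion in (0.26, 0.33) and sibling prevalence gap in (0.15, 0.19). The
gap window is a power choice, fixed in advance of the experiments: below
~0.15 the two binomial mixture components are statistically unresolvable at
this depth (overlapping components carry far less likelihood-ratio
information than their separation suggests), while the gap must stay
clearly below the smallest clone for the tie-break to identify branching.
Configurations outside this window are not "wrong"; they are simply not
identifiable from one sample, which is why the panel excludes them.

After hard assignment, zero-mutation clones are pruned (children reattach
to the grandparent) and q is renormalized, so every reported clone carries
at least one mutation.

## Tree features

Natural logarithms throughout; normalization divides each entropy by log S
(its maximum), with S = 1 trees defined to have all entropies 0. The
correlation feature is the standard Pearson correlation of Q and M, defined
as 0 when either vector has zero variance (deterministic and neutral for
clustering); a `literal=True` variant implements the single-square-root
denominator as printed in some formula renderings, which is not
variance-normalized and may leave [−1, 1]. ITH defaults to the
*unnormalized* product ME × PE, the scale on which example-tree values
above 1 are quoted. Zero-mutation clones cannot reach the feature stage
from the in-package inference; external trees with empty clones receive a
0.5 pseudo-count with a warning so the ratio feature stays finite.

## Classifier

Forest: 1000 trees by default, √9 = 3 features per split, minimum terminal
size 1, no depth cap — the classical unsupervised-RF defaults. Proximity is
the fraction of trees (of the whole forest) in which two real rows share a
terminal node. k-means consumes the proximity rows as coordinate vectors
with random centers, n_init = 20, max 10 iterations; each of the 20
augmentations redraws both the synthetic class and the forest, and the
assignment with the lowest within-cluster sum of squares wins. All nine
features enter unscaled. Rows are sorted canonically before the stochastic
pipeline and the assignment mapped back, making the result exactly
equivariant under input permutations at a fixed seed. Labeling uses
normalized mean ME/PE; exact m-ties (a measure-zero event) break toward the
cluster with larger mean PE, then the lower index, with a warning.

With every tree sharing the same S, normalized and unnormalized features
differ by one positive constant per column; random-forest splits and the
derived proximities are invariant to per-column monotone transforms, so the
two pipelines produce identical assignments in that special case.

## Stability

Each bootstrap replicate resamples rows with replacement, reruns synthetic
class → forest → k-means → m-labeling on the replicate (one augmentation
per replicate, matching the resampling pseudo-code; configurable), and
cross-tabulates original vs replicate labels over the resampled indices
with multiplicity. The affinity score is the log odds ratio with
Haldane-Anscombe +0.5 in every cell, so it is always finite; because
labeling is orientation-free, agreement always scores positive. Replicate
"p-values" are permutation p-values: the share of label shuffles (margins
preserved, default 200) scoring at least the observed value. Default
B = 1000.

## Exact r×c test

Recursive margin-constrained depth-first enumeration in log space, summing
the probabilities of all tables at most as probable as the observed one
(log-space tie tolerance 1e-7, which stabilizes floating-point ties without
admitting any genuinely more-probable table at the table sizes involved).
Degenerate all-zero rows/columns are dropped first. Grand totals above 200
require the seeded Monte-Carlo variant (random tables with the observed
margins via permutation, add-one estimator, default 100 000 samples).

## Survival and other statistics

The k-group log-rank uses the hypergeometric variance with ties and a
generalized inverse on the first k − 1 groups; the stratified version sums
within-stratum O − E vectors and covariance matrices before forming the
chi-square, so a single stratum reproduces the plain test exactly. Strata
containing one group contribute nothing (warned). Kruskal-Wallis delegates
to scipy with the all-identical-values case defined as H = 0, p = 1. The
signature permutation test uses the two-sided statistic |mean(A) − mean(B)|
per signature and the add-one estimator p = (1 + #{≥ observed}) / (n_perm + 1),
so p ∈ [1/(n_perm+1), 1].

## Synthetic cohorts: what they emulate, and what not

One master seed spawns a named substream per stage (trees, reads, clinical,
immune, signatures, drivers), so cohorts are bit-reproducible and stages
independently so. Defaults (the package's standing study conditions):

- **Trees**: linear proportions Dirichlet(5) sorted descending (dominant
  founder), shallow Dirichlet(0.3) (skewed), deep Dirichlet(50)
  (near-balanced); branching shapes drawn uniformly from the non-chain
  shapes on S nodes. Mutation totals Poisson with mean 12 (linear) vs 25
  (branching) — linear tumors carry notably fewer mutations — split
  multinomially with the same concentration, floored at one per clone.
- **Reads**: purity Uniform(0.5, 0.9), depth Poisson(150) truncated ≥ 1.
- **Clinical**: exponential event times with hazards 0.02 / 0.04 / 0.08
  per month for linear / shallow / deep and independent Uniform(0, 120)
  administrative censoring. An alternative `censor_rate` mechanism censors
  a sample with fixed probability strictly before its event, realizing the
  fully-censored limit exactly. No accrual pattern is modeled; clinical
  parameters are calibrated to reproduce orderings, not any real survival
  curve.
- **Immune**: Dirichlet(1) over the 22 reference cell types with the three
  B-lineage concentrations multiplied by (1 + bcell_shift), default shift
  1.0, for linear tumors.
- **Signatures**: Dirichlet(1) over a 14-name synthetic catalogue with one
  mismatch-repair-like signature up-weighted in linear tumors. No
  trinucleotide spectra are simulated.
- **Drivers**: a linear-driver gene placed in the founding clone with
  probability 0.9 for linear (0.05 otherwise) and a TP53-like nonlinear
  driver with probability 0.8 for branching tumors; a 0.05 background rate
  places drivers subclonally. Gene names and coordinates are synthetic.

Because synthetic shallow trees (α = 0.3) are *more* skewed than real
shallow-branching tumors, their entropies — and hence ITH — fall below the
linear class's in synthetic cohorts; real cohorts show linear as the
lowest-ITH class. Passing tests on this generator demonstrate correctness
of the algorithms under the stated statistical structure, not fidelity to
any real cohort's effect sizes.

## Experiment sizes

Validation experiments run at sizes chosen for single-CPU turnaround:
forests of 100–200 trees and 1–5 augmentations in the clustering and
stability experiments (defaults remain 1000 and 20 for analyses), B = 200
bootstrap replicates for the headline stability mean and B = 20 across the
20-seed contrast, 4000 replicates for test calibration (Monte-Carlo sd
~0.0035), and 10–20 master seeds per recovery experiment. The acceptance
script mirrors these sizes and completes in a few minutes.

## Known limitations

- Single-sample reconstruction: no longitudinal or multi-region joint
  trees; topology identifiability is limited as described above.
- No mutation-multiplicity inference; non-diploid loci excluded by default.
- The clustering is strictly two-group among nonlinear trees; cohorts whose
  nonlinear trees form one homogeneous cloud will still be split in two
  (the stability score is the guard against over-interpreting such splits).
- Exact-test enumeration is exponential in principle; the grand-total cap
  (200) with the Monte-Carlo fallback bounds worst cases.
- Benjamini-Hochberg-adjusted p-values are emitted for convenience in the
  driver scan but no multiple-testing claim is made by default.
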