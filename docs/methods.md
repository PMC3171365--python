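# Methods

## The restricted Gaussian Bayesian network

Expression of p genes is modelled as a multivariate Gaussian whose density
factorizes along a DAG with maximum indegree 1 (an oriented forest): each
gene is a linear Gaussian regression on at most one parent gene.  The
restriction has two purposes: it controls the degrees of freedom of a model
that must be fit inside a permutation loop on small samples, and it makes
the topology search exact.  For a fixed topology the profile
log-likelihood is a function of sufficient statistics only (per-gene means,
ML variances, pairwise correlations):

    L̂(G) = Σ_i −(n/2) (log(2π m̂_i) + 1),
    m̂_i  = σ̂_i²                   (root)
          = σ̂_i² (1 − r²_{i,pa})   (child)

Two consequences drive the implementation:

* **Orientation invariance.**  L̂ depends on G only through its undirected
  edge set, since the edge factors (1 − r²) are symmetric.  Any orientation
  of an optimal tree is optimal; the package always orients from node 0,
  which fixes reporting only.
* **MST equivalence.**  Because log(1 − r²) ≤ 0, attaching a parent never
  hurts, so the optimum over all indegree-1 DAGs is a spanning tree, and
  maximizing L̂ is exactly minimizing Σ_edges log(1 − r²_ij) — a minimum
  spanning tree problem.  `fit_ml_network` is therefore an *exact* ML
  structure search, verified against brute-force enumeration of every
  acyclic parent vector for small p.

Numerical choices: variances use the ML (divide by n) scaling so that
likelihood identities (duplicated-sample additivity, T = 0 on identical
groups) hold exactly; (1 − r²) and variances are clamped below at 1e−12 so
perfectly collinear columns — which balanced permutation replicates of
small samples can produce — give finite likelihoods; the full Gaussian
constant is retained per node so graph log-likelihoods are meaningful on
their own, not only in differences.  MST ties are broken deterministically
(Kruskal on edges sorted by (w, i, j)); the optimizing graph is in general
not unique, but its likelihood is.  Constant genes are a hard error
(correlations are undefined), as are missing values — the model assumes
complete replicates, and imputation is out of scope.

## The two-sample test

T = L̂_A + L̂_B − L̂_pooled ≥ 0, with the pooled term computed once per
dataset (it is permutation invariant).  Calibration is by balanced label
permutations: the permuted group A contains k members of the original A,
k uniform on {⌊n1/2⌋, ⌈n1/2⌉}, and n1 − k of the original B.  Balancing
reduces spurious variability when a real difference exists, at a price:
balanced permutations do not form a group, so exact finite-sample validity
is only approximate (see Limitations).  An unrestricted shuffle is
available (`permutation="plain"`) for sensitivity analysis.  The p-value
is the add-one estimator (1 + #exceedances)/(1 + B).  Degenerate
replicates (a constant gene within a permuted group) are redrawn, up to
100 times, from a retry substream; each replicate b draws from an RNG
derived from (seed, b), making results order-independent and letting the
fixed and stopped procedures share identical replicate streams.

## Sequential stopping and multiple testing

The exceedance indicators are Bernoulli(p) with p the true permutation
p-value, so Wald's SPRT applies with surrogate simple hypotheses p = p0
versus p = p1.  Defaults: p0 = 0.04, p1 = 0.06 (bracketing the working
0.05 level), α = β = 0.05, truncation n_max = 5000 (the fixed procedure's
replication count).  For multiple testing only the upper boundary is kept
— small p-values must remain estimable — giving the linear rule "stop when
Σ I_i ≥ c0 + c1 n" with c0 ≈ 6.90, c1 ≈ 0.0494 at the defaults.  An early
stop certifies a large p-value; it is assigned p = 1 (the conservative
choice that makes the embedding argument pathwise exact), with the
empirical (1 + Σ)/(1 + τ) reported alongside as a diagnostic and available
via `early_p="empirical"`.  Because stopped p-values dominate fixed ones
replicate-for-replicate, and step-up/step-down adjustments are monotone in
the raw p-values, the stopped procedure's rejection set is always a subset
of the fixed procedure's: it inherits the fixed MTP's error control while
typically sampling null sets for only tens of replicates.  Step-up and
step-down adjustments are parameterized by the rank multiplier c(i, m)
supplied as a function (BH: m/i step-up; Holm: m − i + 1 step-down), and
the BH path is cross-checked against statsmodels to 1e−12.

A two-boundary variant (`sprt_single_test`) resolves a single hypothesis
at a fixed level without needing small-p estimates; at truncation it falls
back on the add-one estimate.

## Gene-set pipeline

GCT v1.2 / CLS / GMT parsing follows the GSEA file conventions; plain TSV
is accepted as an alternative matrix format.  Expression values are used
as-is — log-scaling, normalization and probe-to-gene collapsing are
deliberately out of scope and must happen upstream.  Sets are intersected
with the matrix; the analyzed size must fall in [5, 500] (configurable) or
the set is skipped with a logged note.  Per-set seeds derive from
(master seed, CRC32 of the set name), so adding or removing sets never
perturbs other sets' results, and fixed/stopped runs of the same
configuration share streams set-by-set.  Raw p-values are BH-adjusted
across all tested sets at FDR 0.25 by default.  Companion analyses use
pooled-variance t statistics (two-sided throughout): the sum-of-squared-t
set statistic runs in the same permutation engine as a DE-based
comparator, and per-pair correlation equality uses the Fisher z transform
with statistic (z1 − z2)/√(1/(n1−3) + 1/(n2−3)).  Degenerate cases are
clamped and flagged: |t| at 1e6 for zero pooled variance, |r| at 1 − 1e−12
before atanh.

On the dispersion of a null correlation: `null_correlation_sd` reports the
Monte-Carlo standard deviation of a sample correlation between independent
normals on the variance-stabilized Fisher scale (sd(atanh r) ≈ 1/√(n−3),
0.267 at n = 17 — the scale on which correlation confidence intervals are
built); `scale="raw"` gives sd(r) ≈ 1/√(n−1) = 0.25 at n = 17.  At the
sample sizes typical of two-class expression studies, graphical structure
estimated from ~0.25-sd-noisy correlations varies considerably under the
null — which is exactly why significance must be assessed by permutation
rather than by comparing separately fitted graphs.

## Synthetic data

The generator emulates the situation the test is built for:
tree-structured Gaussian coexpression with controllable between-group
differences.  A uniform labelled tree (Prüfer-decoded) is sampled per
dataset; ancestral sampling gives each node its declared marginal sd and
each edge its declared correlation.  Scenarios: `null` (both groups one
model), `decorrelate` (a fraction `strength` of group-B edge correlations
set to 0 — coexpression present in one class, absent in the other),
`rewire` (group B on an independent tree).  Default conditions throughout
tests and the acceptance script: p = 10 genes, n1 = n2 = 25 samples, edge
correlation ρ = 0.9, zero means, unit sds — a strong, clean coexpression
signal at realistic two-class sample sizes.  Problem sizes used by the
heavier checks are 500 all-null datasets at B = 199 for calibration, a
50-set battery (20 decorrelated) at B = 500 for the embedding comparison,
and 50 datasets at B = 999 for the power contrast; these sizes give
binomial standard errors comfortably inside the asserted bands while
keeping a full run in minutes on one CPU.

What the generator does *not* emulate: heavy-tailed or skewed expression
distributions, mean shifts confounded with correlation changes,
non-tree (e.g. hub-dense or cyclic) dependence, overlapping gene sets, and
probe-level noise.  Passing tests therefore demonstrate correctness of the
machinery and its behavior under tree-Gaussian conditions, not robustness
to real-array artifacts.

## Known limitations

* Balanced permutations are slightly anticonservative at small group
  sizes (they exclude near-identity relabelings, and the balanced set is
  not a permutation group).  At the default study conditions
  (25 + 25 samples) the measured type-I rate at the 0.05 level is within
  the binomial band around nominal and all-null BH rejections stay below
  the nominal FDR; at 15 + 15 a mild inflation (~15% relative) of small
  p-values is measurable.  Use `permutation="plain"` where exact validity
  matters more than power.
* The indegree-1 restriction summarizes coexpression by p − 1 correlation
  parameters; dependence structures that differ only in ways invisible to
  pairwise correlations (or only through higher indegree) will not be
  detected.
* The early-stop p-value assignment of 1 discards information: stopped
  runs cannot distinguish p = 0.2 from p = 0.9.  That is by design — the
  embedding guarantee is bought with exactly this conservatism — and the
  empirical estimate is reported alongside for diagnostics.
* Per-set tests are treated as independent by BH; overlapping gene sets
  violate that, as they do for every GSEA-family method.
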