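# Methods

## The problem

Given a series of K two-sample genome-wide expression datasets (for
example, one paired tumor/non-tumor cohort partitioned into K ordered
subsets by a reference gene's expression ratio, or K independent
cancer cohorts), some genes behave *discordantly*: up-regulated in at
least one dataset and down-regulated in at least one other.  The
package asks which gene sets (pathways) are *enriched* in such clearly
discordant behavior — more discordant genes than the genome-wide rate
predicts.

Only lists mixing "up" and "down" count as discordant.  Lists mixing
"null" with one direction do not: the sign of a z-score cleanly
separates up from down, but a weak up is statistically hard to tell
from null, so counting null/up or null/down mixtures would make the
event ill-defined.

## From expression to z-scores

Per gene and dataset, a paired t-statistic is computed on the
case-minus-control differences.  A one-sided upper-tail p-value is
taken from a permutation null: each permutation flips every pair's
labels independently with probability 1/2 (a sign flip of that pair's
difference vector, shared across genes), and all m × n_perm permuted
statistics are pooled into a single null sample so that p-values much
smaller than 1/n_perm are resolvable.  The pooled p-value uses the
continuity-corrected count p = (1 + #{pooled ≥ t}) / (1 + m·n_perm),
additionally clamped below 1 so the next step never produces an
infinite score (an observed t below every pooled value would otherwise
give p = 1 exactly).

The signed z-score is z = Φ⁻¹(1 − p_upper).  Strong up-regulation
(small upper-tail p) maps to a large positive z; under the null, p is
uniform and z is standard normal.  Note the transform is applied to
1 − p: applying Φ⁻¹ to the upper-tail p itself would negate the score
and break the "positive means up" reading.

Defaults: n_perm = 1000 (seeded), expression on the ratio scale
(log2 applied by `log2_paired_ratio`; a `scale="log2"` flag takes
differences instead).

The cohort-partition utility clusters the reference gene's per-pair
log2 ratios (1-D, Euclidean distance, median agglomeration), cuts the
tree at a user cut height, merges singleton clusters into the cluster
with the nearest centroid (iterating until none remain), and numbers
the final clusters by increasing median ratio so subset 1 is the most
down-regulated.  The singleton-merge and ordering rules are this
package's design choices; the linkage and cut are standard.

## The two-level mixture model

Each gene's row of K z-scores follows

    f(z) = λ f_CC(z) + (1 − λ) f_CI(z),

where both components are built from the same per-dataset state
densities N(μ_{j,k}, σ²_{j,k}), j ∈ {0 null, 1 up, 2 down}:

* CC (complete concordance): one state j ~ π shared by all K datasets,
  f_CC = Σ_j π_j Π_k φ(z_k; μ_{j,k}, σ²_{j,k});
* CI (complete independence): states drawn independently per dataset
  with probabilities ρ_{·,k},
  f_CI = Π_k Σ_j ρ_{j,k} φ(z_k; μ_{j,k}, σ²_{j,k}).

The null state is pinned at N(0, 1) — p-values of truly null genes are
uniform, so their z-scores are standard normal by construction.  A
`free_null_variance` option re-estimates σ²_{0,k} (mean stays 0) for
data whose empirical null is over- or under-dispersed.  Free-parameter
count is 1 + 2 + 6K: linear in K, against 3^K − 1 for an unstructured
K-dimensional three-state mixture.

### EM

The E-step computes, per gene, E(ω) (CC membership), E(ω ξ_j) (CC
membership in state j) and E((1−ω) η_{j,k}) (CI membership in state j
for dataset k) by Bayes' rule; the M-step re-estimates λ, π, ρ by
normalized responsibility sums and μ_{j,k}, σ²_{j,k} (j = 1, 2) by
responsibility-weighted means and variances, where a state's weight in
dataset k combines its CC and CI responsibilities.

Numerical choices:

* everything in log space with log-sum-exp (tail z-scores at K ≈ 10
  underflow double precision otherwise);
* convergence when |Δ log-likelihood| < 1e−4 (default), capped at
  2000 iterations;
* sign clamps μ_{1,k} ≥ +0.01 and μ_{2,k} ≤ −0.01 preserve component
  identity without relabeling churn when a component drifts across 0;
* variance floor 1e−4 and proportion floor 1e−8 guard against
  component collapse;
* auto-initialization: λ = 0.5, π = ρ columns = (0.8, 0.1, 0.1),
  μ_1 = mean of positive z-scores beyond their 90th percentile
  (fallback +2), μ_2 mirrored, σ² = 1 — an overdispersed, null-heavy
  start matching genomic reality.  The fit is deterministic given the
  data and the start.
* a minimum of 50 genes is required; below that the 3 + 6K free
  parameters are not meaningfully constrained.

EM monotonicity of the log-likelihood is asserted in the test suite to
a 1e−8 tolerance.

## Discordance quantities

**θ (discordance proportion).**  Under the fitted model, the
probability that a random gene's latent list has ≥1 up and ≥1 down.
Enumerating the complement (3 concordant lists, plus lists mixing only
{null, down} and only {null, up}) telescopes into subset products:

    θ = (1 − λ) [1 + Π_k ρ_{0,k} − Π_k (ρ_{0,k}+ρ_{1,k})
                   − Π_k (ρ_{0,k}+ρ_{2,k})],

evaluated in O(K) instead of 3^K.  θ ≤ 1 − λ always, and θ = 0 at
K = 1 (one dataset cannot contain both directions).

**ζ (per-gene posterior).**  The conditional probability, given the
gene's observed z-row, that its latent list is discordant.  The same
telescoping applied to the density-weighted lists gives

    ζ = (1−λ) [Π_k(Σ_j w_j) − Π_k(w_0+w_1) − Π_k(w_0+w_2) + Π_k w_0] / f(z),

with w_j = ρ_{j,k} φ(z_k; μ_{j,k}, σ²_{j,k}); computed in log space
and clamped to [0, 1] against roundoff.  ζ is computed once per gene
from the genome-wide fit; gene-set membership only selects ζ values.

**DES.**  For a set S of m_S genes with posteriors ζ_i, the
Discordance Enrichment Score is the tail probability

    DES_S = Pr(Σ_i U_i > m_S θ),  U_i ~ Bernoulli(ζ_i) independent,

a heterogeneous-Bernoulli (Poisson-binomial) tail.  Default evaluation
is the exact O(m_S²) dynamic-programming convolution of the count
distribution — cheap at pathway scale (m_S up to a few hundred).  A
Monte-Carlo estimator (B = 2000 default, seeded) is provided for
fidelity with the original procedure and for very large sets.  The
event is strict: when m_S·θ is an integer c the count must reach
c + 1; a `tie="ge"` option gives the ≥ semantics (integer detection
uses a 1e−9 tolerance on m_S·θ).

**FDR.**  Each DES is a true-positive probability, so the expected
false-discovery proportion of a reported top-T list is
FDR = 1 − mean(DES of the top T).  It is reported at every rank
(running prefix means) rather than only at a chosen cutoff, since the
cutoff (the conventional report lists sets with DES > 0.80) is a
report parameter, not part of the model.

Sets are ranked by decreasing DES, ties broken by set name.  Gene IDs
are matched between GMT and the z-score universe by exact string match
after whitespace trimming (case-sensitive by default); sets with empty
intersection are skipped with a warning, and the intersection size is
what enters as m_S.

**Clear-discordance flag.**  A descriptive utility flags genes with at
least one z > 4 and one z < −4 (threshold configurable) — the eyeball
definition used on the 9×6 worked example (`table1_fixture`), where it
flags exactly genes G4–G8, 5 of 9.

## Synthetic data

The generator draws rows exactly from the generative process above
(ω ~ Bernoulli(λ); state(s) from π or ρ; z from the state normals) and
returns the full latent truth, so θ can be checked as a population
proportion, ζ against latent labels, and set detection against planted
ground truth.  Gene sets are planted by *latent-label-aware sampling*:
a planted (m_S, rate) set draws round(rate·m_S) members from truly
discordant genes — z values are never shifted, so the generative model
and every oracle built on it stay valid.  Scenarios serialize to JSON
for replay.

Default study conditions: K = 5, λ = 0.6, π = (0.8, 0.1, 0.1), all
ρ columns (0.6, 0.2, 0.2), μ = ±2.5, σ² = 1 — a null-heavy regime with
well-separated directions, θ ≈ 0.169.  The parameter-recovery
experiment uses m = 20000 genes; the planted-set experiment uses
m = 2000 genes, one set planted at discordant rate 0.8 with m_S = 40,
and 50 uniform background sets of 40 genes, scored under the truth
parameters (the experiment isolates the enrichment machinery; fitting
quality is assessed separately by the recovery experiment).

What the generator does *not* emulate: inter-gene correlation (real
pathway genes are co-expressed, so real DES values are effectively
computed on fewer independent genes than m_S suggests), heavy-tailed
or asymmetric empirical nulls, and the upstream noise of the
permutation pipeline (synthetic z-scores are drawn directly from the
mixture).  Passing tests therefore demonstrate correctness of the
model's own computations and power under the model's assumptions, not
robustness to their violation on real data.

### A note on background-set calibration

A uniformly drawn 40-gene background set truly exceeds the m_S·θ
discordance threshold roughly half the time — the latent discordant
count fluctuates binomially around m_S·θ.  DES is a calibrated
posterior of exactly that event, so an informative model correctly
assigns DES > 0.95 to a nontrivial fraction of random sets; those are
true statements about latent counts, not false positives.  The
false-positive experiment in the test suite therefore scores calls
against the latent truth: among background sets whose true discordant
count does not exceed m_S·θ, fewer than 5% receive DES > 0.95, and the
empirical false-discovery proportion among high-DES background calls
matches the ≤ 5% that calibration promises.

## Known limitations

* Three states per dataset; finer regimes (strong/weak up and down)
  would extend the state space but are not implemented (a hook exists
  in the parameter layout).
* λ and the all-null CI configuration overlap in what they explain
  (a CC-null gene and a CI all-null gene have the same density), so λ
  is estimated with more variance than the other proportions; the
  recovery experiment's tolerances reflect this.
* The paired t / sign-flip permutation assumes exchangeable pairs; no
  moderated statistics are provided beyond the plug-in seam.
* The FDR is model-based (an expectation under the fitted mixture),
  not a frequentist guarantee; model misfit propagates into it.
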