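# Methods

## Model

`karyorate` models the joint evolution of a lineage's haploid chromosome
number *i* and its centromere regime *c* ∈ {monocentric (M), holocentric
(H)} as a continuous-time Markov chain on states (i, c), i ∈ [n_min,
n_max]. Four event classes are permitted:

| event        | transition | rate (per regime)   |
|--------------|------------|---------------------|
| fission      | i → i + 1  | γ_M, γ_H            |
| fusion       | i → i − 1  | δ_M, δ_H            |
| polyploidy   | i → 2i     | ρ_M, ρ_H            |
| regime switch| c → c′     | q_MH, q_HM          |

The full model has eight rates; the constrained model pins ρ_M = ρ_H = 0.
There is no state-dependent diversification (no speciation/extinction
coupling), no aneuploidy class distinct from fission, and no
demi-polyploidy. Transitions that would leave the state space are absent
rather than truncated: a polyploidy event from i with 2i > n_max simply has
rate zero, which keeps the generator honest (no silent inflation of the
rate into the top state) and makes boundary behaviour testable. When two
event classes target the same state (i = 1: fission and polyploidy both
reach 2), their rates add, as independent event intensities do in a CTMC.

State ordering is fixed — the monocentric block by ascending i, then the
holocentric block — so state indices are reproducible across runs.

### State-space bounds

Bounds are data-driven by default: n_min = max(1, observed minimum − 1) and
n_max = observed maximum + max(5, ⌈0.2 × observed maximum⌉). The padding
gives fission and polyploidy headroom above the data; both bounds are
overridable in the run configuration. Rate estimates can be sensitive to
very tight bounds, which is why the choice is surfaced rather than buried.

## Likelihood

The log-likelihood of tip observations is computed by the pruning
(post-order dynamic programming) algorithm. Conditional-likelihood vectors
are renormalized at every internal node with accumulated log-scalers, so
underflow cannot occur and the result is independent of where rescaling
happens.

Trees must be ultrametric (relative tolerance 1e-6) and are rescaled to
unit root-to-tip height before fitting; the original height in Myr is
retained as the back-transformation scale, and all reported rates are
samples divided by that height (events per Myr). "Unit height" rather than
"unit total branch length" is the interpretation used, because the
back-transformation to per-Myr units is only coherent for a height
rescaling of a time tree. Non-ultrametric trees are rejected unless the
caller explicitly opts into rescaling by maximum root-to-tip depth (with a
logged warning).

At the root, state frequencies are either uniform (`flat`) or proportional
to each state's share of the root conditional likelihood (`fitzjohn`, the
default, matching the common convention of likelihood-based trait-model
software). Both modes are supported and tested against the same oracle.

### Numerics

Two implementations of the branch propagation exist and are tested to
agree within 1e-8:

* a dense path computing exp(Qt) by scipy's scaling-and-squaring matrix
  exponential, memoized per unique branch length within one call;
* the default fast path, which propagates each conditional vector through
  exp(Qt)·v by uniformization inside a compiled (numba) kernel: with
  μ ≥ max_i(−Q_ii), A = I + Q/μ is substochastic and exp(Qt)v =
  Σ_k Poisson(μt)_k A^k v. The series is truncated when the accumulated
  Poisson mass exceeds 1 − 1e-15 (the tail bounds the error directly, since
  A does not increase the sup-norm of non-negative vectors); branches with
  μt > 30 are split into substeps to keep the weights in a safe range. The
  generator is compressed to sparse rows (≤ 5 non-zeros each), so one
  likelihood evaluation is O(branches × states × series terms).

Data with probability zero under the model (e.g. different tip states with
all rates zero) yield −inf, which the samplers treat as a rejected region;
NaN raises immediately with context.

## Prior and posterior

Each free rate carries an independent exponential prior with rate λ = 0.5
(mean 2) on the per-unit-tree scale. (The prior's parameter is sometimes
called a "shape"; the exponential family has only a rate, and λ = 0.5 is
the interpretation adopted — it is configurable, and results for weakly
informed rates shift noticeably between λ = 0.5 and λ = 2, so sensitivity
should be reported rather than assumed.) The prior's role is mild
regularization: the likelihood is nearly flat at biologically absurd rates
and an uninformative prior lets chains wander there.

## MCMC protocol

One chain per tree in the posterior tree set. Each chain is initialized
with independent Uniform(0, 1) draws for the free rates, runs a fixed
number of generations — one generation sweeps every free parameter once —
and discards a fixed burnin; the post-burnin portions of all chains are
pooled into the posterior estimate. Defaults are 50 generations with
burnin 25, over 100 trees (2,500 pooled samples). For taxa with several
chromosome records, each tree's chain sees one record drawn uniformly at
random, so record uncertainty is integrated over the tree set. The master
seed spawns a tree-index-keyed substream per tree: adding trees does not
perturb earlier trees' results.

The default parameter update is univariate slice sampling with
stepping-out (width 1.0), which self-tunes to the local scale and mixes
well enough that short chains are informative — the reason a 50-generation
protocol is meaningful at all. A one-parameter-at-a-time random-walk
Metropolis variant (Gaussian step 0.3, reflected at zero so the proposal
stays symmetric) exists primarily so detailed balance can be unit-tested
against analytic targets. Convergence is not formally diagnosed (one chain
per tree); sampler statistics are logged per chain so users can audit.

## The ΔR statistic

For each post-burnin sample, ΔR_x = rate_x(H) − rate_x(M) for mechanism
x ∈ {fission, fusion, polyploidy}, computed on per-Myr rates so samples
pooled across trees of different heights are commensurable. The summary
reports the per-sample distribution, its mean and median (either reading
of a "mean rate difference" is thereby covered), the 95% highest posterior
density interval, and the fraction of samples strictly above zero (exact
zeros are counted separately). Decision rule: HPD entirely positive →
holocentric rates are higher; entirely negative → monocentric higher;
otherwise no supported difference.

The HPD is the shortest contiguous window of the sorted pooled samples
containing ⌈0.95·n⌉ samples, leftmost window on ties; endpoints are actual
sample values. HPDs are computed on pooled samples (not per-tree then
averaged); a per-tree audit table is emitted alongside.

## Order-level (single-regime) fits

Clades fixed for one centromere regime are fit with a single rate set
(γ, δ, ρ or γ, δ) and no switching rates, on a single-regime state space.
Subsets with ≤ 20 matched taxa are refused by default — rate estimates
from small clades are unreliable — with an explicit override that logs a
warning. The threshold comparison is strict (> 20) by default with an
inclusive (≥ 20) variant in the configuration. Named clades are checked
for monophyly against each tree unless the subset is declared an explicit
tip list.

## Synthetic data

The simulator emulates the *structure* of a real comparative dataset, not
any particular empirical one:

* **Trees**: pure-birth (Yule) topologies — the root is the first split,
  inter-split waits are Exp(kλ), and a final Exp(nλ) stretch follows the
  last split so terminal branches are never zero — linearly rescaled to a
  target height (default 100 Myr, 200 tips).
* **Histories**: Gillespie simulation along each branch using the same
  generator definition as the likelihood (forward/inverse consistency is
  tested by comparing empirical short-branch transition frequencies with
  exp(Qt)). Every event is logged so recovery tests can count events
  directly. Default true rates (per Myr): γ_M = 0.01, γ_H = 0.03,
  δ_M = δ_H = 0.01, ρ = 0, q_MH = q_HM = 0.005; root state (12,
  monocentric), i.e. a realistic insect-like karyotype with rare regime
  switches so regimes cluster in clades.
* **Records**: each taxon's first record is its true terminal state;
  optional extra records jitter the count by a uniform integer in
  [−j, +j] (clipped to bounds), never the regime (regime assignment is
  clade-level in real data). Note the fitted model has no measurement-error
  component: jittered duplicate records act as unmodelled noise and inflate
  both fission and fusion estimates. Recovery tests therefore use exact
  single records; multi-record sampling is exercised by the pipeline and
  bootstrap tests.
* **Posterior tree sets**: branch lengths of one fixed topology are
  multiplied by i.i.d. lognormal factors (median 1, log-sd 0.1 by
  default); terminal branches are re-extended to the common height, and an
  internal node that jitter would push below the present is clamped just
  above it. Topology is never jittered — tree-set uncertainty here is a
  branch-length phenomenon.
* **Bootstrap**: each replicate draws one tree uniformly and one record
  per taxon, mirroring how real analyses propagate phylogeny and record
  uncertainty.

What passing tests therefore show: the estimator recovers the generating
process when the model is correctly specified and tree uncertainty is
branch-length-shaped. What they do not show: robustness to topology error,
diversification-rate coupling, sampling bias in which species get
karyotyped, or measurement error in chromosome counts.

## Problem sizes and runtime choices

Statistical end-to-end checks run at deliberately scaled-down sizes chosen
to finish on one CPU while retaining power: recovery and null-coverage
suites use 10 replicates of (200 tips, 10 posterior trees, 200 generations
with burnin 100, constrained model); the likelihood oracle uses 200 random
instances with ≤ 5 tips and ≤ 10 states (where brute-force enumeration
over internal-node states is exact and fast); prior recovery pools 10^4
post-burnin samples. The acceptance script runs one contrast and one null
condition at the same per-dataset sizes.

## Known limitations

* One chain per tree with no formal convergence diagnostics (by protocol);
  pathological multimodality would go unnoticed.
* The uniformization kernel's truncation makes likelihood values
  reproducible to ~1e-9 rather than machine epsilon; the dense matrix
  exponential path is available where exactness matters.
* Single-regime and two-regime fits share no information; there is no
  hierarchical pooling across orders.
* Model choice (full vs no-polyploidy) is by explicit configuration, not
  marginal-likelihood comparison.
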