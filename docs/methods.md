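# Methods

## The significance test

For an observed biadjacency matrix **B** (m agents × n artifacts) the
projection weight P_ij counts artifacts shared by agents i and j.  Each
null model defines a distribution for the random weight P*_ij, and an edge
enters the backbone iff Pr(P*_ij ≥ P_ij) < α/2 — the upper half of a
two-tailed test at level α, with the inequality strict and ties (P* = P)
counted toward the tail.  Significantly *small* weights are not extracted.
No multiple-testing correction is applied by default, matching how the
evaluation studies compare raw significance levels; practitioners can apply
their own correction to the returned p-value matrix.

## Exact null distributions

* **FRM** (agent degrees fixed): rows are independent uniform subsets, so
  the overlap of sizes r_i and r_j among n artifacts is hypergeometric
  (evaluated via `scipy.stats.hypergeom`).
* **FCM** (artifact degrees fixed): each weight-c_k column covers a fixed
  agent pair with probability q_k = c_k(c_k−1)/(m(m−1)); the overlap is the
  Poisson-binomial sum of these indicators, identical for all pairs.
* **SDSM** (independent Bernoulli cells): Poisson-binomial with
  π_k = p*_ik p*_jk.
* **FFM** (fill fixed): the pmf is evaluated by conditioning on the
  hypergeometric count K of ones landing in the two focal rows and
  counting arrangements, pmf(t) = Σ_K Hg(K) · C(n,t) C(n−t, K−2t) 2^(K−2t)
  / C(2n,K), computed with log-binomials in O(n²).  This is algebraically
  equivalent to summing over the two single-coverage column counts
  separately, but stays tractable at n = 1000.

Poisson-binomial pmfs use exact sequential convolution (O(n²)).  Every pmf
must sum to 1 within 1e−9 (renormalized if the deviation exceeds 1e−12);
larger deviations raise, so formula errors surface instead of hiding.
During backbone extraction only the lower CDF up to the observed weight is
needed, and the convolution recurrence is lower-triangular, so the per-pair
computation truncates at the observed weight; a numba kernel performs this
across all pairs (a pure-NumPy fallback is selected at import when numba is
missing).  All four exact pmfs are validated against brute-force
enumeration of their ensembles on every matrix shape with ≤ 12 cells.

## FDSM sampling

The fixed-degree-sequence null has no closed form and is sampled with
curveball trades: two rows pool the artifacts held by exactly one of them
and randomly re-partition the pool, preserving all degrees.  One Markov
chain is run with a burn-in of 10·m trades and 5·m trades between retained
samples (the source literature on curveball mixing suggests a few trades
per row suffice; the sample count, 1000 by default, is the quantity the
studies fix).  Empirical p-values are raw proportions
count(P* ≥ P)/samples — at 1000 samples their granularity is 0.001, which
bounds how finely an FDSM backbone can discriminate near α/2.  Chain
uniformity is verified by χ² tests against enumerable ensembles.

## SDSM cell probabilities

The target is Pr(B*_ik = 1) over the fixed-margin ensemble, computable
exactly by enumeration for small margins (recursive column-by-column
construction with Gale–Ryser pruning; deterministic lexicographic order).
Estimators:

* **BiCM** (default): p_ik = x_i y_k/(1+x_i y_k) with multipliers solving
  both margin constraints.  Solver: damped (0.5) fixed-point iteration on
  degree-compressed classes, initialized at x_i = r_i/√f, tolerance 1e−10
  on the worst margin residual; dense near-degenerate margins that make the
  fixed point crawl are finished by a damped Newton step on the
  log-multipliers (the residual is the gradient of the concave
  log-likelihood, so this converges quadratically; the product gauge
  direction is absorbed by least-squares).  Empty/full rows and columns are
  peeled off and fixed to 0/1 before solving, since their multipliers
  diverge.
* **RCF**: r_i c_k / f truncated to [0,1]; coincides with BiCM in the
  sparse limit.
* **LPM / Logit / Logit-I**: regressions of the cell value on the margins
  (and optionally their product) over all m·n cells, via OLS with clipping
  or a binomial GLM; degenerate fits (constant outcome, separation) fall
  back to clipped or constant predictions with a warning.

On the enumerable margin universe the mean absolute deviation from the
exact probabilities orders BiCM ≤ Logit ≤ Logit-I, and BiCM reproduces the
worked [1,1,2]/[1,1,2] example to three decimals (MAD 0.028).

## Synthetic networks

`generate_bipartite(m, n, density, agent_shape, artifact_shape)` draws
latent weights u_i, v_k from beta distributions — right-tailed β(1,10),
left-tailed β(10,1), uniform β(1,1), constant β(10⁴,10⁴), normal β(10,10) —
apportions the target fill (density·m·n, largest-remainder rounding, capped
at the opposite dimension) into *exact* integer degree sequences
proportional to the weights, realizes them by the Gale–Ryser greedy
construction, and randomizes with 20·m curveball trades.  Fixing the
degree sequences exactly is a deliberate design choice: the degree-shape
conditions of the evaluation studies (notably "constant degrees") are then
true by construction, whereas filling cells independently with
weight-product probabilities overlays binomial degree noise that blurs the
conditions — under that variant even constant/constant networks give
tuned-SDSM-vs-FDSM Jaccard ≈ 0.8 rather than the expected 1.  The
Bernoulli-cell variant remains available via `margins="bernoulli"`.
`generate_regular` produces exactly d-regular square matrices (circulant
start, curveball shuffle) for equivalence checks.

What the generator does *not* emulate: empirically observed nestedness or
block structure beyond the planted construction, degree–degree
correlations, and any artifact covariates.  Passing tests therefore show
agreement between the models under controlled margins, not performance on
any particular empirical network.

Planted two-block structure: agents and artifacts are split into equal
halves at random, then checkerboard swaps (exchanging the 1s of a
10/01 2×2 pattern, degree-preserving) are proposed blindly and accepted
whenever they do not decrease the within-group edge fraction, until that
fraction reaches W within ±0.005.  Accepted neutral swaps churn plateaus
and keep unlocking improving swaps that purely greedy pairing exhausts;
heavily skewed degree sequences can still cap the reachable W (a node whose
degree exceeds its own block's capacity forces cross-group edges), in which
case the generator raises with the fraction achieved.

## Evaluation studies and problem sizes

The four study harnesses in `bibackbone.studies` are deterministic given
(config, seed) and default to desk scale; paper-scale runs are pure
configuration changes.

1. **Estimator accuracy** — all feasible non-degenerate margin pairs of
   lengths 2–5 (cell count ≤ 25), deduplicated up to permutation by sorting
   descending.  The interaction logit depends on the realized matrix, not
   just the margins, so its MAD is averaged over up to 30 evenly spaced
   ensemble members; margin-determined estimators are computed once.
2. **Statistical power** — 196×100, density 0.08, right/right networks;
   FDSM (1000 samples) at α = 0.05 vs an SDSM sweep over α ∈ [0.01, 0.30]
   in 0.005 steps; 10 networks by default.
3. **Similarity across degree shapes** — 100×100, density 0.1, all 25
   agent×artifact shape combinations; FFM/FRM/FCM/SDSM vs FDSM at α = 0.05,
   plus the per-network SDSM-optimal α; 10 replicates per condition in the
   test suite, 5 in the acceptance script (with extra replicates in the
   artifact-normal column).
4. **Community recovery** — planted 200×1000, density 0.1, right/right
   networks, W from 0.5 to 0.8; Newman–Girvan modularity (via networkx)
   of each backbone against the planted agent partition, with SDSM read at
   both α = 0.05 and the liberal α = 0.13; 5 replicates per W.

## Numerical and design notes

* Jaccard of two empty backbones is 1 (identical edge sets); empty vs
  nonempty is 0.  Modularity of an empty backbone returns 0 with a warning
  so sweeps never abort.
* The projection diagonal (equal to the agent degrees) is stored but
  ignored by every downstream operation.
* Rows are agents throughout; transposition is the caller's (or the CLI
  flag's) job.
* `sweep_alpha` computes the p-value matrix once and re-thresholds; its
  argmax breaks ties toward the smallest α (conservative, deterministic).
* All randomness flows from a single `numpy.random.Generator` (or integer
  seed); FDSM results record the chain seed.  Identical (config, seed)
  runs are byte-identical.
* Matrix Market input uses 1-based indices per that standard; internal
  indices are 0-based; labels, not indices, appear in user-facing output.
  Duplicate edge-list rows collapse to a single 1 with a warning.

## Known limitations

* FDSM p-values inherit Monte-Carlo error; family-wise error control would
  require more samples than the default 1000 (the sample count is a plain
  configuration knob).
* The FFM pmf costs O(n²) log-space terms; beyond n ≈ 10⁴ artifacts it
  becomes the slowest exact model.
* The Poisson-binomial convolution is exact but quadratic; a
  refined-normal approximation for very long rows is deliberately not the
  default and not implemented — at the scales studied (n ≤ 1000) exactness
  is cheap.
* Lower-tail ("significantly sparse") backbones, weighted backbones, and
  artifact-mode projections (transpose the input instead) are out of scope.
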