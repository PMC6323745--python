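# Methods

`grnkit` infers undirected gene–gene association networks from expression
matrices under a Gaussian graphical model (GGM): genes are jointly
multivariate normal, and an edge between genes *j* and *h* means
ω<sub>jh</sub> ≠ 0 in the concentration (inverse covariance) matrix
**Ω** = **Σ**⁻¹, i.e. the two genes are conditionally dependent given all
others.  Edge strength is usually reported as the partial correlation
ρ<sub>jh</sub> = −ω<sub>jh</sub>/√(ω<sub>jj</sub>ω<sub>hh</sub>).  All
estimators assume standardized input (per-gene mean 0, variance 1, divisor
n−1); `standardize()` enforces this and rejects constant genes.

## The simulator

The synthetic-data generator emulates co-expression data over a
scale-free interaction structure:

1. **Structure.** Preferential attachment (Barabási–Albert) on *p* genes,
   each incoming node attaching with `attachment` edges.  This stands in
   for curated protein–protein-interaction topologies: heavy-tailed degree
   distribution, a few hubs, many leaves.  The default `attachment = 2`
   (average degree ≈ 4) matches the edge density of curated interaction
   networks.  `attachment = 1` (a tree) is available but interacts badly
   with the concentration recipe below: a leaf's single off-diagonal entry
   always rescales to exactly ±1/1.5, and the transpose-averaging step
   then gives high-degree hub rows absolute off-diagonal sums well above
   1, so a substantial fraction of tree structures admits no
   positive-definite draw at all.  At `attachment = 2` no failures were
   observed over hundreds of structures.
2. **Concentration matrix.** ω<sub>jj</sub> = 1; for each edge one weight
   is drawn from the equal mixture ½·Uniform(−1, −0.5) + ½·Uniform(0.5, 1)
   and placed symmetrically (one draw per unordered edge; an independent
   draw per direction could cancel in the averaging step and silently
   delete an edge from the support).  Each row's off-diagonals are divided
   by 1.5× the row's absolute off-diagonal sum (rows with no edges are
   skipped — they would divide by zero); the matrix is averaged with its
   transpose; non-zero entries with magnitude below 0.1 are set to
   magnitude 0.1 *keeping their sign* (discarding the sign would flip
   negative dependencies).  Consequently every on-edge magnitude lies in
   [0.1, 1/1.5].  Positive definiteness is not guaranteed by this recipe;
   the generator checks the smallest eigenvalue and redraws the edge
   weights with an incremented seed (up to 100 attempts) rather than
   projecting onto the PD cone, which would change the support.
3. **Covariance and sampling.** **A** = **Ω**⁻¹ is correlation-scaled,
   δ<sub>jh</sub> = α<sub>jh</sub>/√(α<sub>jj</sub>α<sub>hh</sub>), giving
   **Σ** with unit diagonal; samples are i.i.d. draws from
   MN(0, **Σ** + ε²**I**).  ε is measurement noise outside the GGM; the
   study conditions are ε ∈ {0, 0.1, 0.5}.

What the simulator does *not* emulate: non-Gaussian marginals, count
noise, batch effects, missing values, directed regulation.  Passing tests
therefore certify recovery of conditional-dependence structure under the
model's own assumptions, not performance on raw RNA-seq counts.

## Estimators

* **Shrinkage partial correlation** (tuning-free).  The sample correlation
  matrix is shrunk toward the identity, R* = (1−λ*)R, with the analytic
  intensity λ* = Σ<sub>j≠h</sub> V̂ar(r<sub>jh</sub>) / Σ<sub>j≠h</sub>
  r<sub>jh</sub>² clipped to [0, 1] (Schäfer–Strimmer-style), then
  pseudo-inverted and converted to partial correlations.  The shrinkage
  intensity is deterministic — no bootstrap — because downstream use only
  needs a continuous |ρ| score.
* **Neighborhood selection (NS).**  One lasso regression per gene,
  objective 1/(2n)‖y − Xβ‖² + λ‖β‖₁ (scikit-learn convention, tolerance
  1e−7, up to 10⁴ sweeps).  Symmetrization is the OR rule with
  max-magnitude strength: an edge needs only one of its two directions
  selected.  OR is the more inclusive published convention and supplies a
  continuous strength for rank aggregation.
* **SPACE.**  Joint regression with the symmetric parameterization
  β<sub>j←h</sub> = ρ<sub>jh</sub>√(ω<sub>hh</sub>/ω<sub>jj</sub>):
  cyclic coordinate descent over the p(p−1)/2 pairs (uniform regression
  weights, residual precisions initialized at 1), alternating with
  re-estimation of ω<sub>jj</sub> = 1/var(residual); 3 outer alternations
  by default (2 inside the path sweep, which warm-starts across the grid).
* **GLASSO.**  max log det Ω − tr(SΩ) − ρ‖Ω‖₁(off-diagonal), with S the
  divisor-n (MLE) covariance so that ρ→0 recovers S⁻¹.  Scalar penalties
  are solved by scikit-learn's coordinate-descent graphical lasso with a
  tight inner tolerance (duality gap below 1e−6 at the tested penalties).
  Entrywise penalty matrices (needed below) use an in-package block
  coordinate descent whose convergence test is the entrywise subgradient
  condition; at uniform penalties it agrees with scikit-learn to ~1e−4.
* **GLASSO-SF.**  Iteratively reweighted GLASSO approximating a concave
  log-row penalty that favors hubs.  Iteration 1 is plain GLASSO at ρ;
  iteration t>1 penalizes entry (j,h) by the average of the row weights
  ρ/(‖Ω̂<sup>(t−1)</sup> row j off-diag‖₁ + ε₀), ε₀ = 1e−4; 5 reweights by
  default.  The exact schedule (ε₀, symmetrization by row-weight
  averaging) is this package's instantiation of the reweighting idea.
* **Bayesian GLASSO.**  Double-exponential prior (rate λ, fixed default
  λ = 1 — no hyperprior) on off-diagonals, Exp(λ/2) on diagonals; block
  Gibbs sampling one column/row at a time with inverse-Gaussian latent
  scales; every draw is positive definite by construction (the Schur
  complement is sampled from a Gamma).  Defaults: 5000 iterations, 1000
  burn-in, thinning 2.  Output is the posterior-mean partial correlation
  matrix — continuous and tuning-free for the caller.  The sampler is
  restricted to p ≤ 100: its per-iteration cost grows cubically and it is
  orders of magnitude slower than the point estimators.
* **PCACMI.**  Path consistency on Gaussian (conditional) mutual
  information, MI(j;h|C) computed from correlation-submatrix determinants
  (natural log, nats; unconditionally −½log(1−r²)).  Order 0 deletes pairs
  with MI < α; at order L each surviving pair is tested against every
  size-L subset of its common neighbors and keeps the *maximal* CMI —
  an edge dies only if even its most supportive conditioning set shows
  independence (the conservative reading; the mean rule is the obvious
  alternative and is not used).  Deletions within an order are
  simultaneous.  α defaults to 0.03 (the published default for this
  algorithm family, in nats); `max_order` defaults to 2 — higher orders
  essentially never fire at p ≤ 50 and their cost is combinatorial.

## Ensemble aggregation with a permutation null

Each method's network is converted to ranks over the p(p−1)/2 pairs by
|strength|, strongest = rank 1, average ranks on ties.  The consensus
statistic is the harmonic mean r̃<sub>jh</sub> = K/Σ<sub>k</sub>
(1/rank<sub>k</sub>), which rewards pairs that at least one method ranks
very highly.  Significance: each gene's values are permuted independently
across samples (destroying gene–gene dependence, preserving marginals —
the standard construction of a dependence null), the full ensemble is
re-run with *unchanged* tuning parameters (so observed and null statistics
are exchangeable), and all pair-level harmonic means over M permutations
are pooled into F<sup>null</sup>.  A pair's p-value is the add-one
left-tail quantile p = (1 + #{null ≤ r̃})/(1 + M·p(p−1)/2) — small
harmonic rank means a strong consensus edge, and the add-one keeps p > 0
at finite M, which Benjamini–Hochberg adjustment (over all pairs) assumes.
M defaults to 100.  The default ensemble is NS, GLASSO, GLASSO-SF,
PCACMI, SPACE and Bayesian GLASSO; the shrinkage estimator is excluded
from the default set because it is uniformly the weakest in the benchmark.

## Evaluation protocol

ROC curves are built the way each method family allows: continuous-score
methods (shrinkage, Bayesian GLASSO, the ensemble consensus) sweep a
threshold over all distinct |score| values; MI methods sweep the retained
entropy scores (α = 0.03 governs only the structure-pruning stage);
penalized methods contribute one (FPR, TPR) point per tuning-parameter
value on a descending log grid from the saturation penalty (largest
absolute off-diagonal covariance entry) downward, with (0, 0) and (1, 1)
appended.  Points are sorted by FPR and integrated trapezoidally with no
hull smoothing; path curves can be mildly non-monotone and are integrated
as drawn.  AUC of inverted scores is 1 − AUC by construction.

The benchmark harness pairs conditions: per-replicate seeds depend only on
the master seed and replicate index, so the same structures (and
underlying normal draws) are reused across sample sizes and noise levels,
which sharpens the noise/sample-size comparisons at small replicate
counts.  Method failures become NaN cells, not aborts.

### Reduced-scale defaults

The shipped study grid is p = 30 genes, n ∈ {30, 100, 200}, ε ∈ {0, 0.1,
0.5}, 10 replicates, with desk-scale solver settings: 10-point penalty
grids, 2 reweighting passes for GLASSO-SF, 2 outer alternations for
SPACE, and 300 Gibbs iterations (60 burn-in) for Bayesian GLASSO.  These
sizes keep the whole grid to minutes on a single CPU while leaving the
qualitative orderings (noise hurts, samples help, the ensemble never
trails the weakest ensembled method) clearly resolvable.  Full-scale
settings remain reachable through configuration.

## Numerical choices and degenerate inputs

* Variance divisor is n−1 everywhere except inside the likelihood module,
  which uses the divisor-n MLE covariance (documented because the ρ→0
  oracle depends on it).
* Weighted networks are made bitwise symmetric by transpose averaging at
  construction; binary networks store pairs smaller-index-first.
* Precision entries below 1e−10 in magnitude are treated as structural
  zeros when extracting supports.
* Constant genes, non-positive penalties, empty nulls, unknown hub
  identifiers, and truth networks that are empty or complete (undefined
  FPR/TPR) all raise immediately with the offending name in the message.
* All stochastic entry points take an integer seed and are
  bit-reproducible; internal stage seeds are spawned via
  `numpy.random.SeedSequence`.

## Hub-gene hook

`apply_hub_weights` builds an entrywise penalty matrix that multiplies the
base penalty by a confidence factor in (0, 1] on every pair incident to a
declared hub gene; confidence 1 is a neutral prior (identical to the
uniform run), smaller values encourage hub connectivity monotonically.
This is an experimental, deliberately minimal penalty-rescaling
interpretation of hub-informed estimation; it is not a reimplementation
of the published hub-extended estimators.

## Known limitations

* The Gibbs sampler's posterior means at a few hundred iterations carry
  Monte-Carlo error of a few hundredths; chain-agreement checks use 5000
  iterations.
* PCACMI's entropy scores mix conditioning orders across pairs; they are
  comparable enough for ranking but are not a calibrated statistic.
* The permutation null destroys all dependence, so its p-values test the
  global null per edge; they are not adjusted for the network-wide
  selection effect beyond Benjamini–Hochberg.
* Path-based ROC resolution is bounded by the grid size; AUC from a
  10-point grid is systematically slightly below the score-sweep AUC of
  the same method family.
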