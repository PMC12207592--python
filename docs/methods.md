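# Methods

This document defines the models, conventions and numerical choices used by
`cvrefine`.  Units throughout: positions in Å, energies in kcal/mol, with
`kT` carried explicitly; the CV is treated as dimensionless.

## 1. Shape-GMM model

A structural state `j` is a Gaussian over the centered particle positions
`x ∈ R^{N×3}` with mean `μ_j` and Kronecker-structured covariance
`Σ_j = Σ_{N,j} ⊗ I₃` (one `N×N` particle covariance shared by the three
Cartesian axes).  A `K`-state model has mixture weights `φ_j`.

Rigid-body degrees of freedom are removed by alignment, not by modeling:
before evaluating component `j`'s density, each frame is translated to its
geometric center and rotated by the *Mahalanobis-optimal* rotation

    R* = argmax_R tr(R A),   A = x_cᵀ P_j μ_j,   P_j = (Σ_{N,j} + δI)⁻¹,

solved in closed form by the SVD construction also used for Kabsch
superposition (Kabsch is the special case `P = I`).  Because the objective
is linear in `R`, correctness of the solver is testable against an
exhaustive rotation-grid search.

A small ridge `δ = 1e-6` Å² is added to every covariance before inversion
(`COVAR_REGULARIZATION`); all density arithmetic is in log space.

### Frame-weighted EM

Each frame `i` carries a statistical weight `w_i ≥ 0`, `Σ w_i = 1`
(uniform when absent).  The E-step computes responsibilities that sum to
`w_i` per frame; the M-step uses the per-component aligned frames:

    φ_j ∝ Σ_i γ_ij,
    μ_j = Σ_i γ_ij y_ij / Σ_i γ_ij,
    Σ_{N,j} = Σ_i γ_ij (y_ij − μ_j)(y_ij − μ_j)ᵀ / (3 Σ_i γ_ij),

with `y_ij` frame `i` aligned to component `j` and the outer product
averaged over the three axes.  Uniform weights reduce every formula to the
unweighted algorithm exactly; duplicating a frame while splitting its
weight changes nothing (both are tested identities).  Initialization is a
weighted k-means++ seeding; the fit is restarted from several seeds and the
best final log-likelihood kept.  The cluster-count scan holds out a
fraction of frames and reports cross-validated log-likelihood per `K`.

## 2. Weighted position LDA

Given aligned frames, integer state labels and weights, the weighted
within- and between-class scatter matrices are

    S_W = Σ_c Σ_{i∈c} w_i (x_i − m_c)(x_i − m_c)ᵀ,
    S_B = Σ_c W_c (m_c − m)(m_c − m)ᵀ,

with weighted class means `m_c`, class totals `W_c` and global mean `m`.
With `equal_state_weights` each class's weights are renormalized to an
equal share first, enforcing equal influence of the states regardless of
how much sampling each received.

The discriminant maximizes the Fisher ratio `vᵀS_B v / vᵀS_W v`.  `S_W` of
positional data is singular: centered, gauge-fixed frames span at most
`3N − 6`–`3N − 7` dimensions.  The solver therefore whitens `S_W` through
its eigendecomposition and **discards** eigendirections below a relative
spectral cutoff (`1e-10` of the largest eigenvalue) rather than flooring
them: eigenvectors of the numerical null space are arbitrary, and keeping
them makes the solution sensitive at the `1e-3` level to `1e-16` input
rounding.  The returned direction is unit-norm, oriented so state A (the
first ensemble) projects to negative values, and for the workflow's
two-state case reduces to a single vector `v ∈ R^{N×3}`.

### On-the-fly evaluation and gradient

    l(x) = v · (R(x)(x − x̄) − μ_ref),

where `x̄` is the frame's geometric center and `R(x)` the
Mahalanobis-optimal rotation onto the coordinate's reference mean with the
pooled within-class particle covariance as metric.  `l` is exactly
invariant under rigid transforms of `x`.  The gradient includes the
rotation response `∂R/∂x` by implicit differentiation of the Procrustes
stationarity condition (`RA` symmetric): with `T = RA`, solving
`(tr T · I − T) b = 2a`, `a` the axial part of `vᵀy`, gives
`∇l = vR + ½ P μ (b̂ᵀR)`, projected onto the centering constraint.  It is
verified against central finite differences to `1e-6` relative.

## 3. State matching

States fitted in different sessions are matched by the Bhattacharyya
distance between their Gaussians.  Means are centered and one state is
aligned onto the other with the pooled-covariance metric first, so the
distance is invariant to the arbitrary pose of either model.  For the
Kronecker covariances the distance decomposes per axis; the implementation
is tested against per-coordinate quadrature of `−ln ∫ √(p q)` on isotropic
instances.  Matching is greedy: each reference takes its nearest cluster;
if both prefer the same cluster, the closer pairing wins and the other
reference takes its runner-up (logged as a warning).

## 4. Biasing and free-energy estimation

**WT-MetaD** (`WTMetaDState`): Gaussian hills of width `σ` deposited every
`pace` steps at the current CV value, with height
`h = h0 · exp(−V(s)/kΔT)`, `kΔT = (γ−1) kT`.  At a continually revisited
point the heights follow the well-tempered `kΔT / n` decay.  The FES
estimate from the final bias is `F(s) = −γ/(γ−1) V(s)`.

**OPES-MetaD** (`OPESState`): fixed-bandwidth kernels accumulated with
on-the-fly reweighting heights `exp(V(s)/kT)` form a density estimate
`P(s)`; the bias is `V(s) = kT(1 − 1/γ) ln(P(s)/Z + ε)` with
`ε = exp(−ΔE/(kT(1 − 1/γ)))`, which caps `|V| ≤ ΔE` at every point of the
deposition history.

**Reweighting**: final-bias weights `w_i ∝ exp(+V(s_i)/kT)` feed the
weighted histogram `F = −kT ln Σ w` on a fixed grid (empty bins are NaN).
Profiles are min-shifted to zero.  The convergence metric `fes_mae`
averages `|ΔF|` over bins where the *reference* profile stays below
7.5 kcal/mol, excluding unsampled bins.

Quadratic walls `κ(s − bound)²` confine the CV to `wall_offset` beyond the
coordinate's training range.

## 5. The synthetic test bed

`make_two_state_system` builds a particle system whose Boltzmann density is
exactly a two-component shape-GMM, so clustering, LDA, biasing and FES
estimation all have closed-form references.  The template is a ring in the
xy-plane plus an out-of-plane puckering pattern (the chirality carrier),
orthogonalized against rigid tilts so that reflection through the xy-plane
produces a genuinely distinct (non-superimposable) mirror state.  In the
mirror-symmetric configuration the second mean is that reflection with
identical covariance and equal weight, so the marginal free-energy profile
along the inter-state axis is exactly symmetric.  The state separation is
calibrated by root-finding so the barrier of the exact 1-d two-Gaussian
marginal equals `barrier_kT · kT`.

Dynamics are first-order overdamped Langevin,

    x ← x − (dt/friction) ∇(U + V(l(x))) + √(2 kT dt / friction) η,

with the bias force propagated through the CV's analytic gradient.  Frames,
CV values and bias energies are recorded for the *same* configuration at
save time (the reweighting pairs them).  A time-step stability precheck
(`dt · max curvature / friction < 0.5`) and a coordinate sanity bound guard
the integration.  `sample_iid` provides exact independent draws from the
mixture for estimator tests.

## 6. The iterate workflow

`run_protocol` executes: short unbiased runs in each state → initial
discriminant → [bias along current coordinate → reference-coordinate FES by
final-bias reweighting → convergence check → frame-weighted re-clustering →
Bhattacharyya matching → weighted discriminant refit] × iterations.

Key conventions:

- The FES used for cross-iteration comparison lives on a *fixed reference
  coordinate* (the generator's inter-state axis), because the biased
  coordinate changes between iterations.
- Biased sampling runs in chunks until at least `min_round_trips` round
  trips between the basins are seen on the reference coordinate, or
  `max_steps` is reached.  The default floor of 2 round trips is the
  cheapest budget under which re-clustering reliably sees both states; FES
  asymmetry statistics improve with the square root of the number of round
  trips, and the acceptance measurement uses a floor of 10.
- All randomness derives from `SeedSequence([seed, iteration, stage])`, so
  checkpoint/resume (`workdir`) reproduces an uninterrupted run bit for
  bit.
- `export_coefficients` writes the coordinate as plain text (17 significant
  digits, bit round-trippable), a reference-mean PDB plus full-precision
  companion, the reference particle covariance, and a JSON manifest
  recording normalization and sign conventions.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| `gamma` (bias factor) | 8 | standard WT-MetaD practice for few-kT barriers |
| `hill_height` | 0.7 kcal/mol | &lt; kT·(γ−1)/γ at kT=1: gentle filling |
| `sigma_fraction` | 0.05 of CV range | resolves the basin widths |
| `pace` | 500 steps | ≫ CV decorrelation at these frictions |
| `wall_kappa`, `wall_offset` | 125, 10 | confinement without touching basins |
| `deltaE` (OPES cap) | 10 kcal/mol | ≳ barrier + margin |
| `mae_tol` | 0.5 kcal/mol | matches the acceptance symmetry bound |
| `fes_bins`, `fes_margin` | 61, 1.5 | grid spans 1.5× the state centers |
| `subsample_cap` | 4000 frames | EM cost control, weights renormalized |

## 7. Known limitations

- The closed-form FES oracle for the biased coordinate linearizes `l(x)`
  (rotation frozen at the reference): on realistic trajectories the rms
  difference between `l` and its linearization is ≈ 0.14 CV units, so
  estimator-vs-closed-form comparisons carry a few tenths of a kcal/mol of
  model error in addition to sampling noise.
- K exceeding the true number of states converges to split local optima
  with substantial inter-component Bhattacharyya distance; the
  cross-validated `scan_num_clusters` table, not the fit itself, is the
  guard against over-clustering.
- Matching is greedy over two references; it does not solve a general
  assignment problem for K > 2 references.
- The toy integrator is first-order (Euler–Maruyama); its stationary
  density carries an O(dt) discretization bias that is small but visible in
  very tight estimator tolerances.
- No interfaces to external MD engines are provided; the exported
  coefficient files are engine-agnostic plain text.
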