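# Methods

## Model

Tau seeds `u ∈ R^N` on an atlas of `N` brain regions evolve by

    du_i/dt = -ρ Σ_j L_ij (1 + ε A_j) u_j + k − λ u_i ,

where `W` is the symmetric, normalized structural connectivity,
`L_ij = −W_ij + δ_ij Σ_k W_kj` its graph Laplacian (column sums zero),
`A_j ≥ 0` the regional anomaly level (FDG or amyloid PET SUVR, used raw),
and `ε` the anomaly coupling strength.  The right-multiplication
`L (I + ε diag A)` scales *outgoing* transport by the source region's
anomaly; column sums remain zero, so transport conserves mass and the
production/degradation balance fixes the stationary total exactly:
`Σ_i u*_i = N k / λ`.

Key regimes, each asserted by tests:

- `ε = 0`: plain connectome diffusion; the stationary state is uniform at
  `k/λ` on any connected graph.
- `ρ → ∞` (transport-dominated): `u*` collapses onto the zero-eigenvector
  of the anomaly-weighted Laplacian, whose components are
  `v_i/(1 + ε A_i)` with `v` constant for symmetric `W` — stationary
  seeding then depends on the anomaly pattern only, not on topology.
- At the default parameters transport dominates production, so predicted
  seeding is governed by the anomaly gradient while the connectome shapes
  transients.

Assumptions: linear kinetics (appropriate for the low seed densities of
the pre-pathology stage; no aggregation nonlinearity), undirected
connectivity, spatially uniform production and degradation, and an anomaly
field frozen in time.

### Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| `epsilon` | anomaly coupling strength | – | 5 |
| `rho` | transport coefficient | 1/time | 1.0 |
| `k` | seed production rate | conc/time | 0.02 |
| `lam` | seed degradation rate | 1/time | 0.2 |
| `u0` | uniform initial concentration | conc | 0.1 (= k/λ, unbiased start) |
| `t_end` | integration horizon | model time | 15 |
| `time_rescale` | display-time factor | – | 0.7 (display only; never enters the dynamics) |
| `abs_tol`, `rel_tol` | integrator tolerances | – | 1e-10 |

The defaults put the model in the transport-dominated regime with a
production-to-degradation ratio matching the initial condition.  `k = λ =
0` is accepted for pure mass-conserving transport simulations; the
stationary solve requires `λ > 0` and refuses otherwise.

### Numerics

Stationary states are obtained by the direct dense solve
`(ρ L (I + ε diag A) + λ I) u* = k·1` (LU; nonsingular for `λ > 0`), with
the max-norm residual recorded and required below 1e-8.  This is the path
used by all inference (fast and deterministic).  Trajectories use an
adaptive explicit Runge-Kutta scheme (DOP853, order 8) at the configured
tolerances; positivity is asserted post hoc rather than enforced by the
scheme, and the terminal state is cross-checked against the linear solve
(agreement within 1e-6 max-norm at long horizons).  An optional
mean-normalization of the anomaly field exists as a sensitivity switch and
is off by default — SUVRs enter raw.

## Connectome

Raw fibre-count matrices are averaged element-wise, symmetrized as
`(M + Mᵀ)/2`, the diagonal zeroed (self-loops contribute nothing to
inter-regional transport and would distort the Laplacian degree term),
divided by the maximum entry, and entries are kept only if strictly
greater than the cutoff (default 0.01).  Disconnection after filtering is
a hard error, not a warning: the stationary theory requires a single zero
Laplacian eigenvalue.  Loading an already-normalized CSV accepts
asymmetry only below 1e-12 relative tolerance; anything larger must go
through the build path explicitly.

## Atlas

The bundled atlas has 84 regions (68 cortical Desikan-Killiany regions, 16
subcortical), explicit `-L`/`-R` hemisphere suffixes, Braak-stage
membership (stage 1 = bilateral entorhinal cortex; stages 2/3 pooled),
four composite sets (amyloid cortical summary; tau MTL = entorhinal +
amygdala; tau neocortical = inferior + middle temporal; unstable regions =
frontal pole, temporal pole, banks of the superior temporal sulcus) and an
anatomical-adjacency neighbour map for the unstable-region correction.
Atlases ship as JSON data files rather than code so small synthetic
atlases reuse the same validated type.  Validation enforces bilaterality
of staged structures and stage-1 being exactly the entorhinal pair.

The hippocampus is staged 2/3 and participates fully in model-side
analyses; it is excluded (via a flag) only when comparing against
empirical tau PET, where tracer off-target binding in the adjacent choroid
plexus corrupts the signal.

## PET cohort conventions

- Unstable-region correction: each unstable region's SUVR is replaced by
  the unweighted mean over `{self} ∪ neighbours`, all replacements reading
  pre-correction values (simultaneous update, no cascade).  The plausible
  alternative reading — midpoint of self and the neighbour mean — was
  rejected as not matching the operation's description.
- Positivity: strict `>` at amyloid 1.11 (cortical summary), tau MTL
  1.375, tau neocortical 1.395.  Thresholds are constants here; their
  Gaussian-mixture derivation is out of scope.
- Groups: amyloid-negatives pool regardless of tau status; amyloid-
  positives subdivide by tau MTL/neocortex; the rare discordant
  `Aβ+ τMTL− τNEO+` profile is excluded.
- Pairing: ±12 months is implemented as ±365 days.  Among eligible
  cross-modality pairs the tau-scan date decides (earliest or latest by
  cohort convention); remaining ties break by smallest absolute gap, then
  earliest primary date — the tie-breaks are this package's own
  convention.
- Centiloid values are pass-through metadata; no SUVR→Centiloid
  conversion is implemented.

## Permutation inference

The null shuffles the anomaly values uniformly over all regions (no
hemisphere restriction), recomputes the stationary state per shuffle and
pools all `n_perm × N` concentrations.  One global seeding threshold is
taken as the midpoint of the largest gap between adjacent values strictly
above the pooled median; gap-size ties resolve toward the
highest-concentration gap, and if fewer than two values lie above the
median the maximum is returned as a degenerate guard.  Observed and
per-permutation Braak-family counts (stage 1; stages 1–3) are evaluated
against that single threshold.  p-values use the add-one estimator
`(1 + #{null ≥ obs})/(n_perm + 1)`; the z-score is `(obs − mean)/sd` of
the per-permutation null counts (a reconstruction — the natural
permutation z — since no formula is canonical), with a `+inf` sentinel and
warning when the null counts are degenerate.  For `N ≤ 8` an enumeration
mode replaces sampling with all `N!` permutations, making p exact; tests
compare Monte-Carlo at 10,000 shuffles against this oracle within 99%
binomial error bars.

## Cohort statistics

Welch's t (Satterthwaite df, two-sided) for all unordered group pairs with
Bonferroni `m = #pairs`; OLS (via statsmodels) for simple and adjusted
(age, sex, APOE4) regressions of empirical tau on predicted seeding, both
averaged over the bilateral entorhinal target (or Braak 2/3 minus
hippocampus).  Standardization z-scores continuous terms and the outcome
and leaves 0/1 indicators raw, so `std_beta = raw_beta·sd(x)/sd(y)` holds
for continuous terms.  Missing covariates are handled by complete-case
deletion.  Marginal-effect lines fix covariates at their sample means; the
slope equals the raw seeding coefficient identically.  Power is estimated
by with-replacement bootstrap of whole subjects at a target n, refitting
the adjusted model and counting rejections — a stated reconstruction of a
procedure whose details are not standardized.  Welch and OLS outputs are
cross-checked in tests against hand-written closed-form oracles to 1e-10.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
any real cohort's empirical distributions.  Connectomes are
Bernoulli-lognormal random graphs with a seeded random ring guaranteeing
connectivity, passed through the standard build pipeline.  Subject scans
are group mean profiles plus spatially correlated Gaussian noise (an
exponential kernel in connectome hop distance, spectrum-clipped to a valid
correlation; correlation length 1 hop by default, 0 = independent),
truncated positive.  Group mean profiles are constructed so that
noise-free cohorts classify exactly into their intended biomarker groups:
the amyloid-negative profile sits below the 1.11 cortical threshold,
positive groups carry a graded neocortical elevation sparing the
entorhinal cortex, and tau composites sit on the intended side of the
1.375/1.395 cutpoints.  Default cohort size is 457 subjects in four
biomarker groups (285/47/37/88) with graded APOE4 rates and diagnosis
mixes along the AD continuum, ages ~N(72, 7²), 47% female, education
~N(16.2, 2.6²); about 10% of subjects receive a primary scan outside the
±365-day window to exercise pairing.

Tau outcomes are generated directly at the region level:
`target tau = a + b·(predicted seeding) + N(0, sd)` with predictions
computed through the same correction-then-predict path the analysis uses,
so the generative slope `b` is recoverable without attenuation and is
recorded in the scenario manifest.  Defaults `a = 1.0`, `sd = 0.25`, and
`b = 6.7` (FDG scenario) or `b = 11.3` (amyloid scenario) give
weak-to-moderate associations of the kind observed in PET cohorts.  The
two presets differ in which modality drives the model: `PART_like` places
the entorhinal pair distinctly lowest in the FDG profile (0.55/0.57
against a 1.1–1.5 cortical spread); `AD_like` elevates neocortical amyloid
while sparing the entorhinal cortex.

What passing tests on these cohorts do **not** show: robustness to
real-data features the generator omits — site/scanner effects,
longitudinal drift, heavy-tailed or spatially structured artefacts beyond
the smooth kernel, diagnosis-dependent atrophy, or misregistration.
Results on synthetic cohorts validate the machinery and its calibration,
not clinical effect sizes.

## Problem sizes used in validation

Stationary-solve checks run on the 84-region atlas; permutation oracles on
5-region graphs where all 120 permutations are enumerable; recovery and
type-I calibration on 200 replicate cohorts of n = 450 subjects;
end-to-end preset checks at 10,000 permutations.  These sizes give exact
or tight-binomial comparisons while keeping the full suite around a
minute of CPU.

## Known limitations

- Undirected connectivity means stationary seeding is topology-independent
  in the transport-dominated limit; only transients carry connectome
  information.
- The anomaly field is static; activity/amyloid dynamics and their
  feedback on transport are out of scope.
- The regional-shuffle null ignores spatial autocorrelation;
  autocorrelation-preserving nulls (e.g. spin tests) are not implemented.
- No nonlinear aggregation kinetics, no per-subject connectomes, no
  image-space processing — SUVR tables are the input boundary.
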