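# Methods

This note documents the model, the numerical choices and the defaults of
`studyopt`, and what the synthetic evaluator does and does not emulate.

## Problem statement

A study design **x** lives in a mixed domain Θ = Θ_c × Θ_d of continuous,
integer, boolean and categorical variables. The optimizer seeks

    argmin_x  E_{q~Q} [ λ·g(x) + L_q(x) ]   s.t.  f(x) ≤ b,  f(x) ≥ 0,

where g is a deterministic normalized cost, f a budget function compared
componentwise against a cap b, and L_q a stochastic loss evaluated on one
realization q of a somatic-evolution process per call. The expectation is
approximated by a single fresh realization per evaluation (a config
option, `Schedule.replicates`, is reserved for averaging); repeat
evaluations of the same design are aggregated by the ranking step
instead, which reports the arithmetic mean of observed scores per design.

## Encodings and distance

Continuous and integer variables are affinely rescaled to [0, 1]; decoding
rounds integers. Categorical levels are mutually equidistant: the mixed
distance is d(x, x′) = sqrt(Σ Δz_i² + #{differing categorical variables}),
the Euclidean combination of the encoded numeric distance and a unit
Hamming contribution per level variable. This is a metric (each
categorical variable embeds as simplex vertices at unit mutual distance)
and is used by the maximin criterion and the kernels alike.

## Initialization

Latin hypercube sampling stratifies every numeric variable into n₀ equal
intervals of its range with exactly one draw each; integer variables draw
a uniform integer inside each stratum (strata narrower than the integer
spacing fall back to the nearest admissible value; this can only occur
when the range is smaller than n₀). Categorical columns cycle the level
set and are shuffled, so n₀ = 6 over a boolean gives exactly 3 per level.
Maximin improvement proposes within-column value swaps between two rows —
stratum occupancy is invariant under such swaps — and accepts a swap iff
the minimum pairwise mixed distance does not decrease (and, when a budget
constraint is supplied, iff both modified rows stay feasible). Designs
violating f ≤ b are rejected and regenerated until the target count is
reached; the default rejection cap is 100 × n_target, after which an
infeasibility error reports the observed acceptance rate.

## Surrogate model

The score surrogate is a zero-mean GP (after centering/scaling y) with a
product kernel:

* numeric part: Matérn 3/2, k = σ²(1 + √3·θ·d)·exp(−√3·θ·d), with a
  single smoothness parameter θ on the encoded coordinates. Integer
  variables participate in this factor — treating counts like coverage
  as continuous for modeling purposes while the proposal machinery keeps
  them integral.
* each categorical/boolean variable: a homoscedastic correlation matrix
  over its levels, parameterized through the hypersphere decomposition of
  its Cholesky factor (unit diagonal, PSD by construction). Angles are
  constrained to (0, π/2), giving positive correlations. Above five
  levels a single exchangeable correlation replaces the full angle set to
  bound the parameter count.

Hyperparameters maximize the marginal likelihood with σ² profiled out
analytically; log θ ∈ [log 0.01, log 100] and the angles are optimized by
L-BFGS-B from 3 seeded restarts. The relative nugget defaults to 1e-6 of
the standardized variance (loss observations are stochastic) and is
escalated ×10 on factorization failure. The posterior uses the standard
variance-*reducing* conditional

    μ(x*) = k(x*,X)ᵀ(K+ηI)⁻¹y,    σ²(x*) = k(x*,x*) − k(x*,X)ᵀ(K+ηI)⁻¹k(x*,X),

clipped at zero; tests assert equivalence with a dense independent solve
to 1e−8 and agreement with scikit-learn's GP on continuous-only data.
When the cost lacks a closed form (`cost_is_closed_form=False`) separate
loss and cost GPs are fitted and combined as T̂ = L̂ + λ·ĝ with variance
Var(L̂) + λ²·Var(ĝ); the combined-score GP is the default otherwise.

## Proposals

* **Exploration**: a feasible LHS pool of `pool_size` (default 200)
  candidates is scored by the lower confidence bound μ − α_v·σ
  (α_v default 1.0) and the ⌊e_j·n_j⌋ lowest values are kept.
* **Mesh search**: around the incumbent, candidates are drawn first from
  the continuous neighborhood {x_c + Δ_j·d_j} (directions default to the
  ±coordinate vectors — the minimal positive spanning set), then from
  discrete neighbors (every alternative categorical level; integer
  offsets up to ⌈ball_fraction·range⌉, default 0.05 with a minimum of one
  step), then — with spare local budget — from combined
  continuous-step × discrete-substitution candidates. Ordering within
  each pool is uniform-random under the round seed. Steps are clipped to
  the encoded unit cube; candidates clipping back onto the center are
  dropped. Any budget violation among the picks halves Δ (at most 6
  times, minimum fineness 1e-4) before resampling; on underflow the
  feasible subset found so far is returned with a warning flag.
* **Gradient descent**: from the n_g lowest-scoring evaluated designs
  (observed scores, not surrogate minima), the gradient of the surrogate
  mean is estimated by central differences with per-variable perturbation
  γ·range (default γ = 0.05; integers are perturbed by at least one unit
  and rounded so they stay integral). By default the step moves a fixed
  encoded distance α_g along the negative normalized gradient — scale-free
  across heterogeneous ranges; `normalize=False` applies the literal
  update x − α_g·∇T̂ in raw units. Infeasible steps halve α_g up to 6
  times, then return the start point flagged unmoved. Spaces with no
  numeric variables skip gradient steps entirely.

## Schedules and stopping

Defaults: M = 150 total evaluations, n₀ = 30, n_j = 20, e₀ = 0.5 tapered
by 0.8 per round (floor 0.05), Δ₀ = 0.1 tapered by 0.9 (floor 1e-3),
α_g = 0.1 tapered by 0.9 (floor 1e-3); the exploitation remainder splits
evenly between mesh and gradient points. The loop stops when evaluations
reach M or when the best score has not improved by `improvement_tol`
(default 1e-3 of the observed score spread) for `patience` = 5
consecutive rounds. Mesh centers always use the global best design.
Per-design evaluation seeds derive from SeedSequence(master, round,
index), so ledgers are byte-identical across runs and across evaluator
parallelism settings.

## Objectives

* Mutation discovery: loss = 1 − (SNVrecall + SVscore)/2, with SNVrecall
  = |called ∩ truth|/|truth| and SVscore the per-chromosome fraction of
  truth intervals overlapped by ≥ 1 called interval (half-open interval
  intersection), combined across chromosomes by a weighted mean with
  weights |C_i| + |D_i|. Both the orientation (the printed source form is
  recall-like, i.e. higher-is-better, which contradicts score
  minimization; `oriented=False` restores it) and the SV weighting (the
  source formula is typographically corrupted; the chosen reading matches
  its prose description) are documented interpretations.
* SV rate: |SV_C − SV_A| / SV_A.
* Power threshold: with u = PoissonCDF(SV_C; mean SV_A), loss 0 if
  |u − 0.5| ≤ threshold, else 2; caller failure is the sentinel 3. The
  inverse-cdf notation of the source is read as the quantile *level* of
  the observed count — the only reading under which comparison with the
  median is meaningful. A mid-p correction (u − pmf/2) is available and
  off by default.
* Cohort recall: 1 − mean over patients of |Z_i ∩ C_i|/|Z_i| (oriented as
  above).
* Costs: biopsy cost g = c·s/300 (bounded in [0, 1] by the 100×/3-sample
  maxima); a generic linear + pairwise-product family over numeric
  variables for sequencing cost models, with example coefficients
  (0.004/coverage-unit, 0.05/sample, 0.01/single-cell, 0.001 per
  coverage×sample) standing in for proprietary price sheets.

## Synthetic evaluator

The evaluator emulates the *structure* of a read-level simulator plus
calling pipeline, not its values: SNV/SV counts are Poisson (defaults 100
and 30) over a 5-subclone random branching tree whose cell fractions set
per-variant detectability; detection probability is p_max·u/(u + c_half)
with u = coverage·fraction·(1 + 0.05·single_cells), c_half = 20, times a
read-length saturation (half-point 500 bp) and paired-end boost for SVs,
combined across samples as 1 − (1−p)^s; false calls are Poisson in the
error rate; whole-exome designs mask 98% of variants; the informatics
level rescales p_max (callerA 1.0, callerB 0.85). The liquid-biopsy
cohort draws 10 training and 7 test patients with ~40 variants each
appearing from a random one of three timepoints onward; subsampling a
design picks s timepoints at random and detects with a sharper
saturation (half-point 5) so that low-coverage designs remain
informative. All constants are configuration: passing tests demonstrates
that the optimizer recovers *monotone structure* (high coverage wins when
cost is off; cheap designs win under λ = 0.5) — they say nothing about
absolute recall levels of any real pipeline, and the evaluator has no
read-level error profiles, alignment artifacts, breakpoint-resolution
effects or inter-caller disagreement beyond the p_max rescaling.

## Known limitations

* A single scalar θ (no ARD) and a constant-mean GP; high-dimensional or
  strongly anisotropic score surfaces will fit poorly.
* The score GP treats the 0/2/3-valued power-threshold loss as
  continuous; the surrogate is accordingly crude for that query, which
  matches the source experiment's observation that very few designs pass
  the threshold.
* Expectation over Q by one realization per evaluation makes ranking
  noisy for flat score surfaces; the ranked report's observation counts
  indicate how much averaging supports each entry.
* No provable convergence claims; tapering follows direct-search
  convention.
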