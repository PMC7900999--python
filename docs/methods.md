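# Methods

`tracermc` quantifies uncertainty in a model of tracer (gadobutrol)
transport through brain interstitial fluid. This note records the model,
the numerical choices, what the synthetic surrogate does and does not
emulate, and the design decisions taken where the design was genuinely
open.

## Model

The tracer concentration c(t, x, ω) in the parenchyma G obeys the
convection–diffusion–reaction equation

    ∂c/∂t + ∇·(v c) − ∇·(D* ∇c) + r c = 0,

with random coefficient fields D*(x, ω) (effective diffusivity), v(x, ω)
(bulk ISF velocity) and a drainage rate r ≥ 0. The boundary splits into the
pial/SAS interface, where the concentration is prescribed, and the
ventricular interface, which is zero-flux. The SAS value is

    c = c_CSF(t) · h(t, x),    h = 1/2 + arctan(−a (x_z − z0 − v_z t))/π,

an upward-moving smoothed front (a = 20 1/m, z0 = −0.2 m,
v_z = 1.5·10⁻⁵ m/s; x_z is the vertical coordinate, the last axis).
c_CSF is constrained by conservation of the injected amount
n₀ = 0.5 mmol over a CSF volume V_CSF = 140 mL:

    ∫_G c̄ dx + c_CSF V_CSF + ∫₀ᵗ ∫_G r c̄ dx dτ = n₀,

where c̄ is the solution of the deterministic problem with all random
coefficients replaced by their means. `precompute_csf_drive` tabulates
c_CSF once per configuration on the finest mesh with an explicit
(one-step-lagged) boundary update and trapezoidal drainage accumulation;
because c_CSF(tⁿ) is then *defined* by the balance relation, the tracer
accounting holds to machine precision at every tabulated step, which the
conservation test asserts at 10⁻¹² relative tolerance.

Output functionals: total amounts Q_g, Q_w (mol) in gray/white matter and
average concentrations q_g, q_w (mol/m³) over two small probe subregions,
evaluated on a grid of observation times (default every 30 minutes).

## Random coefficients

**Diffusivity.** D* = 0.25 D_Gad + F⁻¹(Φ(X)), where X is a standard Matérn
field and F is the gamma(shape 3, scale 0.75 D_Gad/3) CDF, so that
E[D*] = D_Gad = 1.2·10⁻¹⁰ m²/s with a strict positivity floor at
0.25 D_Gad and values above 3 D_Gad attained with probability
P(Γ > 2.75 D_Gad) ≈ 2%.

**Model 1 (glymphatic circulation).** v = v_base + v_dir with
v_base = v_avg · s · U · ∇×F, where F collects independent standard Matérn
fields (three components in 3D; in 2D a single stream function with the
rotated gradient in place of the curl — a documented 2D analog), U is an
independent uniform amplitude and v_dir is a fixed large-vessel drift.
Because the curl components are zero-mean Gaussian, E[v_base] = 0 and
E[v] = v_dir pointwise. The scale s has two modes: `paper` uses λ/8;
`calibrated` (default) fixes s by a one-off pilot (its own fixed seed,
64 field draws) so that the domain-averaged E[|v_base|²]^{1/2} equals
v_avg = 0.17 μm/s; `fixed` uses the λ/8 constant quoted for this
normalization in the glymphatic-modelling literature. The two
prescriptions are not equivalent — λ/8 under this construction yields an
RMS below v_avg — so the normalization target, being the physically
meaningful statement, is the default. Drainage r = 0.

**Model 2 (capillary filtration).** v(x) = v̄(ω) w(x) with a radial inward
bump profile w(x) = exp(−3(R−q)²/(R²−(R−q)²))(x_c − x), q = |x − x_c|,
R = 8 cm, defined as zero at q = 0, and a gamma(2, θ) amplitude v̄. The
printed form of the profile is typographically ambiguous in its source;
this parsing (a smooth bump vanishing at the center with inward direction
everywhere) is the adopted reading. θ is calibrated deterministically
(quadrature only, no sampling) from E[v̄²] = k(k+1)θ² so the
domain-averaged RMS speed equals v_avg. Drainage r = 10⁻⁵ 1/s.

## Matérn sampling by the SPDE route

Standard Matérn fields (σ², ν, λ; κ = √(8ν)/λ) are sampled by solving

    (I − κ⁻²Δ)^k u = η Ẇ,   ν = 2k − d/2,

on an embedding box with homogeneous Dirichlet walls, k successive P1 FEM
Helmholtz solves per draw (sparse LU cached per level). The scaling

    η = σ κ^{−d/2} (4π)^{d/4} √(Γ(ν + d/2)/Γ(ν))

matches the free-space marginal variance to σ²; it is verified against a
Monte Carlo oracle in the tests. Near the box walls the covariance is only
approximately Matérn (the error decays exponentially with distance), so
the box must contain the domain with margin at least one correlation
length; a warning enforces this. Since ν = 2k − d/2 must make k an
integer, 2D configurations use ν = 3 where the 3D reference value is 2.5.

White noise is realized element-locally: each cell contributes its local
mass-matrix Cholesky factor applied to d+1 iid standard normals, giving a
load vector b with Cov(b) = M exactly. On nested hierarchies the coarse
load is the prolongation-transpose of the fine load, whose covariance is
exactly the coarse mass matrix — the multilevel coupling is an exact
linear restriction, with no supermeshing. Cells of a red-refined hierarchy
are stored children-contiguously, so consuming QMC coordinates in cell
order assigns the leading (most important) dimensions to the largest
spatial scales; scalar random inputs occupy the first coordinates, and
uniforms map to normals by the inverse CDF (preserving coordinate-wise
low-discrepancy structure). This ordering is a simple documented
convention standing in for the full orderings of the specialised
literature, with the same stated goal.

## Surrogate geometry

At full scale this model class runs on MRI-derived anatomical brain
meshes, which are not part of this package. The synthetic surrogate
preserves the physical parameter
regime instead of the anatomy: a disk/ball of radius 0.07 m (the ~0.084 m
half-diameter scale of a human brain) with a concentric ventricular cavity
of radius 0.02 m, a 4 mm gray shell, and two probe subregions — one in the
gray shell, one in the white core — tagged as unions of whole cells so the
integration regions are identical on every level. Hierarchies are built by
uniform red refinement (triangles → 4, tetrahedra → 8 by Bey's rule), so
each level partitions its parent cells exactly: coarse P1 functions
prolong exactly and white-noise loads restrict exactly. Boundary vertices
are *not* snapped to the circle under refinement — the polygonal domain is
fixed by the coarsest mesh — so level differences measure discretization
error on a fixed domain rather than geometry change. Per-level time steps
are Δt_ℓ = 15·2^{−ℓ} minutes with a 1-day horizon by default.

The 2D surrogate carries an out-of-plane slab thickness of 0.1 m, chosen
so its tissue "volume" (area × thickness = 1.4·10⁻³ m³) equals the 3D
surrogate shell volume and sits in the physiological ~10:1 ratio to
V_CSF = 140 mL. Without this, 2D area integrals are dimensionally
inconsistent with the conservation relation and the SAS reservoir
saturates unphysically.

The default 3D embedding-box margins reproduce a 0.16 × 0.21 × 0.17 m
sampling box around the 0.14 m domain.

What the surrogate does **not** emulate: cortical folding (isotropic
covariances see no sulci), anatomical gray/white geometry, graded box
meshes, or the probe placements of anatomical studies (the surrogate's
probe positions are conventions, not reproductions). Passing tests therefore demonstrate the correctness of
the sampling, coupling, solver and estimator machinery in the stated
parameter regime — not anatomical fidelity.

## Transport discretization

P1 continuous elements with a lumped (row-sum) mass matrix; the convection
weak form (∇·(v c), s) is expanded as (v·∇c + (∇·v) c, s) and integrated
with vertex quadrature, consistent with the lumping and second-order
accurate. Time stepping is the implicit midpoint rule with the SAS
Dirichlet value c_CSF(tⁿ) h(tⁿ, x) imposed by partitioned elimination.
Because the initial state c ≡ 0 is incompatible with the boundary data
switching on, the undamped midpoint rule alone retains a first-order
oscillatory startup error; the first two steps are therefore taken as
backward-Euler half-steps (Rannacher startup), which restores measured
second-order convergence in time. Each realization factorizes its
(time-independent) system matrix once; the stepping is back-substitution
only. Linear solves use sparse LU (direct), so the 10⁻⁸ iterative
tolerance of the full-scale study is met trivially.

No convection stabilization is applied. The scheme is reliable for
worst-case cell Péclet numbers up to roughly 10; beyond that the coarse
discretization can amplify oscillations, which matters when random
amplitudes have heavy upper tails (see the rate study below). A cell-Pe
report is provided as a diagnostic.

The CSF drive uses a time step of one quarter of the finest transport step
by default; a much smaller step (e.g. 30·2⁻⁶ min) is selectable for
high-accuracy tabulation. The drive is first-order in time by construction
and shared by all levels, so its error cancels to leading order in level
differences.

Coarse meshes under-resolve the boundary layer at full-scale coefficients
and undershoot below zero near the SAS boundary; mass lumping reduces the
effect and refinement removes it (asserted in the tests), matching the
behavior reported at full scale.

## Estimators

All estimators treat the functional set as a vector and drive stopping and
allocation by the worst functional (max convention), with the MSE budget
split as bias² ≤ θ ε² and variance ≤ (1−θ) ε², θ = 0.5 by default; values
tuned to resource-capped hierarchies (small θ when the bias is small,
large when finer levels are unavailable) can be set in configuration but
are not defaults.

* **MC**: sample mean on a fixed level, N grown until the CLT variance
  bound meets its budget.
* **Randomized QMC**: M = 32 independently scrambled Sobol streams
  (scrambling chosen because the source literature does not fix a
  randomization), N doubling until the across-scramble variance of the
  stream means meets the budget. The variance-vs-N trajectory is recorded
  so one run yields the sample count needed at any looser tolerance.
* **MLMC**: telescoped coupled pairs Y_ℓ = Q_ℓ − Q_{ℓ−1} (Q₀ ≡ 0), sample
  counts by N_ℓ = (1−θ)⁻¹ ε⁻² (Σ √(V_l C_l)) √(V_ℓ/C_ℓ) with a floor of 2,
  re-allocation only ever adds samples, rates α̂, β̂, γ̂ by least squares on
  log₂ statistics of level differences (ℓ ≥ 2), bias by the geometric-tail
  extrapolation max_Q |mean Y_L|/(2^α̂ − 1), and level extension until the
  bias share is met or the hierarchy is exhausted (failed convergence is
  reported with the best achievable tolerance).

Pseudo-costs C_ℓ = c₃ 2^{γℓ} with γ = 4 (the full-scale cost growth,
β = γ regime) are used for method comparisons; wall-clock cost can be
recorded but is not used for acceptance. Reproducibility under
re-allocation comes from counter-based per-(level, sample-index) RNG
streams spawned from the root seed.

The estimator-variance of Q itself (for SD error bars in reports) is
obtained by telescoping second moments, Σ_ℓ E[Q_ℓ² − Q_{ℓ−1}²] − (E Q)²,
verified on a toy problem.

## Scaled-down reference studies

The full-scale experiments (10⁸-cell meshes, ~10⁴ samples) are far beyond
a desk machine; the canned studies in `tracermc.experiments` reproduce the
*methodology* at desk scale. Their conditions are fixed once, on
asymptotic-regime grounds:

**Rate study** (decay exponents of the coupled level differences, expected
α = 2 and β = 2α = 4 for the second-order scheme): 3-level 2D surrogate at
5 mm base resolution; diffusivity scaled to 100 × D_Gad so that the
resolution ratio h₁/√(D T) ≈ 0.3 matches the full-scale coarse mesh (at
desk resolutions the physical diffusivity leaves the 3 mm penetration
depth unresolved and every level pre-asymptotic); RMS velocity 4·10⁻⁷ m/s
so that even rare ~5×-mean draws of the gamma(2) amplitude keep worst-case
cell Péclet inside the scheme's clean range (larger targets produce
heavy-tailed level differences whose variance decays well below 2α);
field correlation length 0.04 m with ν = 3, sampled on a box refined two
levels beyond the parenchyma (κh ≤ 0.31 everywhere — the strong error of
white-noise FEM sampling is otherwise the variance-decay bottleneck);
600/300/150 coupled pairs on levels 1/2/3; 12-hour functional window.
Model 2 is used: in full-scale anatomical runs of this model class the
capillary-filtration model exhibits the theoretical rates, while the
glymphatic model's bias decays in a faster pre-asymptotic regime.

**Cost comparison** (MLMC < QMC < MC at equal tolerance): same scaled
coefficients on a 1 cm-resolution 3-level hierarchy (box kept one
refinement coarser so the QMC dimension stays below the Sobol generator
limit); pilot pairs estimate level variances; MC cost is extrapolated from
the finest-level variance, QMC measured on the second-finest level and
charged at finest-level cost (the full-scale procedure), MLMC allocated
optimally. Tolerances are set relative to the pilot standard deviation of
the finest-level functional.

**Velocity studies**: Model 1 mean-zero and RMS recovery run on a
2-level default-resolution surrogate with λ_v = 0.01 m — the full-scale
1020 μm is unresolvable at desk resolutions, and both statements
(E[v_base] = 0; calibrated RMS = v_avg) are independent of λ.

**Conservation study**: full-scale coefficients (Model 2) on the
default-resolution 2D surrogate; asserts the drive balance at 10⁻¹².

## Known limitations

* Isotropic covariances ignore tissue topology (shared with the full-scale
  study); the 2D analog replaces the curl with a rotated gradient.
* No convection stabilization: configurations beyond cell Pe ≈ 10 on the
  coarsest level are unreliable; a finer base mesh, not a stabilizer, is
  the supported remedy.
* The explicit CSF-drive update is first-order; its step must stay well
  below the CSF exchange timescale (a NaN guard suggests reducing it).
* Non-nested hierarchies are unsupported: the exactness of the white-noise
  coupling is tied to nested red refinement.
* The QMC route is limited to ~21 000 random dimensions by the Sobol
  generator; fine 3D boxes exceed that, as in the full-scale study, where
  QMC was run at reduced resolution.
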