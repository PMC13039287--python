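# Methods

`nernstfit` estimates the sarcolemmal membrane potential (Em) and the
mitochondrial inner-membrane potential (ΔΨm) of intact tissue from the
kinetics of a lipophilic cationic radiotracer (e.g. Tc-99m sestamibi),
measured as a time–activity curve (TAC) after a bolus injection.

## Model

**Electrochemistry.** A monovalent lipophilic cation distributes across a
membrane held at potential E according to the Nernst relation; at tracer
(sub-nanomolar) concentrations activities equal concentrations, so the
equilibrium constant is K = exp(−FE/RT). Because the equilibrium constant of
a first-order exchange is the ratio of its rate constants, the reverse rate
across each membrane is slaved to the forward rate and the potential:
k₋ = k₊·exp(FE/RT). This is how the two voltages enter the kinetics. The
resting sarcolemmal potential itself can be predicted independently from ion
gradients with the Goldman–Hodgkin–Katz (GHK) voltage equation
(`biophysics.ghk_voltage`); with standard cardiac K⁺/Na⁺/Cl⁻ concentrations
and permeabilities at 310 K it gives −74.5 mV.

**Kinetics.** Three serial compartments — plasma (c_p), cytosol (c_c),
mitochondria (c_m) — exchange tracer:

    dc_p/dt = k_f U(t) − (k₁ + k_f + k′) c_p + k₁ e^{FEm/RT} c_c
    dc_c/dt = k₁ c_p − (k₁ e^{FEm/RT} + k₂ + k′) c_c + k₂ e^{FΔΨm/RT} c_m
    dc_m/dt = k₂ c_c − (k₂ e^{FΔΨm/RT} + k′) c_m

with a gamma-variate arterial input U(t) = A₀(t−t₀)^α e^{−β(t−t₀)} (zero
before t₀), radioactive decay k′ = ln2/half-life fixed at the Tc-99m value
(3.206×10⁻⁵ s⁻¹, not fitted), and measured signal
S(t) = V_p c_p + V_c c_c + (1−V_p−V_c) c_m + B.

**Parameters** (fit order): k_f, k₁, Em, k₂, ΔΨm, t₀, α, β, A₀, V_p, V_c, B.
Rates in s⁻¹; voltages carried as positive magnitudes in volts inside the
fitting machinery and reported as negative mV at every public surface;
volume fractions dimensionless with V_p + V_c ≤ 1; B a baseline offset in
signal units. Default initial vector
[0.5, 0.1, 0.05, 0.01, 0.1, 1.0, 12.0, 4.0, 1.0, 0.3, 0.3, 0.05] with box
bounds init/5 … init×5.

## Solver

The system is linear and time-invariant, dc/dt = A c + b U(t) with
b = (k_f, 0, 0)ᵀ, and the compartmental matrix A has a real, simple spectrum
for physiological parameters. `solve_model` therefore offers a closed-form
path: eigendecompose A and evaluate each mode's convolution with the
gamma-variate as a regularized lower incomplete gamma function, in log space
to avoid overflow. This is exact (no discretization), ~50× faster than
time-stepping, and is used automatically when β+λᵢ > 10⁻³ for every
eigenvalue, the spectrum is simple, and the eigenbasis is well conditioned;
otherwise a stiff LSODA integration (rtol 1e−6, atol 1e−9, analytic constant
Jacobian) takes over. The numerical path caps the step size at √α/β while
the bolus is active — before t₀ every derivative is zero and an
unconstrained error estimator can step clean over the input — and integrates
the washout without a cap. The two routes agree to solver tolerance; the
suite cross-validates them.

Frame-mode acquisitions (variable frame durations) are predicted at frame
midpoints; the error is second order in the frame duration, which for ≤10 s
frames against hours-long kinetics is negligible. A trapezoid
frame-averaging mode exists for validating that approximation.

## Estimation

**Weighted least squares.** TACs are peak-normalized (A₀ and B absorb the
scale). Residuals are Poisson-weighted, (obs − pred)/√max(pred, ε) with
ε = 10⁻⁶ of the observed peak; the model prediction rather than the data in
the denominator avoids zero-count division. Positivity is enforced by a log
transform per coordinate; the volume pair (V_p, V_c) goes through an
additive log-ratio transform, so any unconstrained point maps to a valid
simplex interior. Box bounds are mapped into the transformed space (the
volume box approximately, with out-of-simplex corners rescaled just inside).
Optimization uses scipy's trust-region reflective algorithm with regularized
LSMR steps and unit scaling: the model Jacobian is rank-deficient (see
*Identifiability*), and minimal-norm steps leave the unidentified parameter
combinations at their initial values instead of letting them wander along
the ridge, which measurably stabilizes the estimates across noise
realizations. A solver failure inside the loss returns large finite penalty
residuals. The reported covariance is s²(JᵀJ)⁻¹ (pseudo-inverse,
symmetrized) propagated from transformed to fit-space coordinates; a
rank-deficient Jacobian flags the result degenerate. Parameters can be
pinned (`fixed={"B": 0.0}`, the simulation-study convention — also required
because log 0 is undefined).

**Posterior sampling.** The likelihood is Poisson on reconstructed counts:
y = round(count_scale × observed), μ = count_scale × predicted, where
count_scale is the pre-normalization peak count recorded in the TAC
metadata (or supplied by the user). Priors are independent Gaussians in the
transformed space, centred at the transformed least-squares estimate, with
default width ln(5)/2 ≈ 0.80 per coordinate so that ±2σ spans the same 5×/÷5
box the least-squares stage searches — the sampler itself is unbounded, and
on directions the data do not constrain, the prior plays the box's role.
The sampler is adaptive Metropolis: Gaussian random walk whose covariance is
(i) initialized from the Laplace approximation
(count_scale·JᵀJ + prior precision)⁻¹, (ii) adapted during burn-in to the
running chain covariance with Haario scaling 2.38²/d plus 1e−10 jitter and a
Robbins–Monro global step-size factor targeting 23.4% acceptance, and
(iii) frozen after burn-in. Defaults follow the reference protocol: 3 chains
× 10,000 iterations, burn-in 1,000 (27,000 retained draws), thin 1; chain c
seeds its generator with seed + c and starts from an independent Gaussian
perturbation (σ = 0.05) of the least-squares estimate. Convergence is
assessed with the classical per-parameter Gelman–Rubin factor; summaries
(mean, median, SD, MAP) are computed on pooled post-burn-in draws mapped
back to physical units. Fit and between-subject errors combine in
quadrature.

## Synthetic data

The generator reproduces the validation study: ground truth A₀=1, α=12,
β=4, t₀=1 s, k₁=0.1, k₂=0.01 s⁻¹, V_p=V_c=0.3, B=0, Em=−50 mV,
ΔΨm=−100 mV, with the flow rate constant k_f swept over 0.01–2.0 s⁻¹.
Because Poisson noise on a peak-normalized (≤1) curve is not count-valued,
the noise-free curve is scaled to `count_scale` expected counts at its peak
(default 10⁴) before drawing, then renormalized to unit peak with the scale
recorded in the metadata so the count statistics stay recoverable. Sampling
grids: the ex-vivo detector grid (0.2 s for 30 min, 9001 points), the
in-vivo frame schedule (1 s/5 s/10 s over 2.5 h, 1560 frames), and a reduced
validation grid that uniformly subsamples the 30-min acquisition to 600
points (3 s spacing). On the reduced grid the bolus transit is sparsely
sampled, so the input-shape parameters are weakly identified there; the
washout, which carries the voltage information, is fully covered. Sweeps
derive child seeds as seed + index. What the generator does **not** emulate:
detector dead time, scatter, attenuation, partial-volume effects, regional
heterogeneity, or physiological drift — passing tests demonstrate correct
inference under the model's own assumptions, not robustness to those
effects.

## Identifiability (known limitation)

The measured curve determines only the three eigenvalues of A, the three
mode amplitudes, the input shape (α, β, t₀) and the baseline — 10
observables against 12 parameters. The model is therefore structurally
non-identifiable along an exactly 2-dimensional manifold that mixes k_f,
k₁, Em, A₀ and the volume fractions (the ΔΨm direction is nearly
orthogonal to it and is recovered tightly in practice; Em lies partly along
it). Numerically: the model Jacobian at the simulation truth has two zero
singular values, and the profile likelihood of Em is flat to within 0.1
log-likelihood units from −40 to −80 mV on a 600-point curve with 10⁴ peak
counts. Practical consequences, all reproduced by the test suite:

- the fitted *curve* is recovered essentially exactly on noise-free data,
  but individual parameters (k₁, A₀, V_p in particular) can sit tens of
  percent from truth at identical cost; minimal-norm optimization keeps the
  estimates near the initial vector's physiological values;
- posterior uncertainty along the flat directions is set by the prior, not
  the data; the reported SD for Em should be read with that in mind;
- the flat manifold is *curved* in the transformed space, so a
  frozen-covariance random walk cannot traverse it within a few thousand
  iterations: multi-chain R̂ on ridge-coupled parameters stays well above
  1.1 at the reduced validation scale even though the recovered potentials
  lie comfortably within 3 posterior SDs of truth. Genuinely converged
  sampling of this posterior would need either a sampler adapted to curved
  ridges or external information (fixing k_f, A₀ or a volume fraction)
  that breaks the degeneracy.

Estimates of Em and ΔΨm remain useful because the *combination* the data do
pin — the eigenvalues and amplitudes — constrains both potentials to
physiologically narrow ranges when the fit is started from, and the prior
centred on, the standard initial vector; the simulation study (low-flow
bias ≫ high-flow bias) quantifies the remaining sensitivity.

## Parameter defaults that matter

| parameter | default | units | why |
| --- | --- | --- | --- |
| temperature | 310 | K | mammalian body temperature; overridable per call |
| k′ | ln2/6.006 h | s⁻¹ | Tc-99m decay; fixed, not fitted |
| bound factor | 5 | — | reference protocol (xIn/5 … 5·xIn) |
| count_scale | 10⁴ | counts at peak | makes Poisson noise on normalized curves well defined |
| prior width | ln(5)/2 ≈ 0.80 | log units | ±2σ ≡ the 5×/÷5 search box |
| chains / iterations / burn-in | 3 / 10,000 / 1,000 | — | reference protocol; the validation suite runs 3 × (1,000 + 3,000) |
| weight floor ε | 10⁻⁶ × peak | signal | avoids dividing by a zero prediction |
| solver rtol / atol | 1e−6 / 1e−9 | — | stiff path; closed form is exact |

## Degenerate and edge inputs

All-zero curves are rejected at normalization. A flat (uninformative) curve
yields a degenerate-flag or kinetic coefficients of variation ≫ 1 rather
than an error. Proposals that break the solver return −∞ log-likelihood and
are rejected; 1,000 consecutive rejections shrink the step and warn.
Ties/boundaries: transforms are undefined exactly on the simplex boundary
(strictly-inside inputs required); upper volume bounds outside the simplex
are rescaled to 1−10⁻⁹.
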