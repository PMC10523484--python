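# Methods

This note documents the models implemented in `qtrap`, the defaults they
use, and what the synthetic benchmarks do and do not establish.

## Scientific setting

The m.3460G>A mutation of mitochondrially encoded ND1 substitutes Thr for
Ala52 at the entry of the CoQ10 binding channel of respiratory complex I.
Three quantitative questions follow from equilibrium and steered MD of the
wild-type and mutant channel, and this package implements the inference
chain that answers them from simulation outputs (not the MD itself):

1. **Binding thermodynamics.** How much less strongly does the mutant bind
   CoQ10? Answered by alchemical free-energy perturbation composed into a
   thermodynamic cycle, ΔΔG_bind = ΔG_mut^unbound − ΔG_mut^bound, with
   per-window estimates from Bennett's acceptance ratio (BAR).
2. **Egress kinetics.** How much harder is it to pull CoQ10 (or its reduced
   form) out of the mutated channel? Answered by binning steered-pulling
   work traces into W(z) profiles (mean, Jarzynski, second-cumulant
   estimators) and converting barrier differences to Boltzmann rate
   factors e^(−ΔΔW/kB·T).
3. **Electron-transfer kinetics.** How much faster is tunneling when the
   quinone headgroup sits closer to the N2 iron–sulfur cluster? Answered
   by kernel-density mode detection on headgroup–N2 distance series and an
   exponential distance-decay (nonadiabatic/Marcus) rate model.

## Work-profile estimation

Work is binned **by restraint center** (spacing 0.1 Å by default): the
center is the protocol variable, identical across trajectories of a
schedule, which makes binning reproducible; the instantaneous coordinate
fluctuates. Each trace's work curve is linearly interpolated onto the bin
grid and anchored to zero at the first bin it covers, so only profile
*differences* carry meaning; with per-trace anchoring the Jensen bound
jarzynski ≤ mean_work holds bin-wise exactly, and all estimators are
exactly 0 at the first bin.

Per bin the three estimators are ⟨W⟩ (with standard error), the Jarzynski
estimate −kB·T·ln⟨e^(−βW)⟩ (evaluated with a log-sum-exp guard), and the
second-order cumulant ⟨W⟩ − β·Var(W)/2. The Jarzynski estimator is
exponentially biased upward at finite sample size when dissipation is
large; the package therefore reports all three, and the synthetic
benchmark keeps mean dissipation at ~2 kT where 200 trajectories suffice.

Temperatures: estimators default to 310 K (the simulation temperature);
barrier reports can be re-quoted in kT at any temperature (e.g. 298 K,
"room temperature") — the kcal/mol value is temperature-independent, only
the kT conversion changes.

## BAR and the thermodynamic cycle

With ΔU = U(λ_to) − U(λ_from) in both ensembles, BAR solves

    Σ_F f(β(ΔU_F − C)) = Σ_R f(β(C − ΔU_R)),  f(x) = 1/(1+e^x),
    ΔG = C + kB·T·ln(n_F/n_R).

The left side is strictly increasing and the right side strictly
decreasing in C, so the root is unique; it is found by bisection on a
bracket spanned by the forward and reverse Zwanzig estimates and expanded
geometrically until the residual changes sign (tolerance 1e-8 kcal/mol,
default cap 1000 iterations). The asymptotic standard error uses the
standard variance expression kB·T²·[(⟨f²⟩/⟨f⟩² − 1)/n_F + (same for
reverse)/n_R]. Because that expression is blind to *complete* ensemble
separation (all Fermi weights equally tiny), the mean Fermi weight at the
solution is used as an overlap diagnostic; below 1e-6 the estimate is
flagged `converged=False` with a warning. One-sided data fall back to
exponential averaging (Zwanzig), which is also the cross-check estimator.

The 11-value λ schedule (0, 0.03125, 0.0625, 0.125, 0.25, 0.5, 0.75,
0.875, 0.9375, 0.96875, 1) defines 10 windows — denser near the endpoints
where the alchemical transformation is stiffest. Window estimates sum to
leg totals (standard errors in quadrature) after verifying that the
windows tile [0, 1] exactly; when both directions are present the
difference between one-sided forward and reverse compositions is reported
as hysteresis. The cycle convention fixes λ = 0 at the wild-type (Ala)
endpoint, and ΔΔG_bind = ΔG_mut^unbound − ΔG_mut^bound, so a positive
value means weaker binding by the mutant.

### kNN endpoint corrections

When sidechains are frozen during the alchemical legs, each endpoint needs
a configurational-density correction measured from the distances of
sampled configurations to the frozen reference. The density at the
reference is estimated from the k-th nearest-neighbor distance r_k (k = 4
by default) as ρ̂ = e^{ψ(k)} / (n·V_d(r_k)), with V_d the d-ball volume
and ψ the digamma function. The e^{ψ(k)} normalization (rather than the
naive k) makes ln ρ̂ asymptotically unbiased, which is the right target
because the correction enters as −kB·T·ln(ρ̂_a/ρ̂_b); the normalization
cancels in the ratio, leaving only variance properties affected. The
effective dimension d of the frozen-coordinate space is a required input,
not a guessed constant, and the distance metric is caller-supplied (the
module never computes 3-D geometry). Corrections are applied as matched
endpoint pairs, one additive term per leg.

## Distance modes and tunneling ratios

Mode detection uses a Gaussian KDE evaluated on a 0.01 Å grid, bandwidth
by Silverman's rule (0.9·min(σ̂, IQR/1.34)·n^(−1/5)) unless overridden.
Modes are strict local maxima; maxima within one bandwidth of a stronger
mode are merged into it, and maxima below 1% of the tallest mode are
discarded as kernel noise from sparsely sampled tails. Modes are reported
in order of descending density height (prominence). KDE was chosen over a
mixture-EM fit because the target quantity is the peak position of a
plotted density, which KDE mirrors directly; a two-component EM fit is
provided as a cross-check utility.

Rate ratios come in two flavours: peak-based, k_alt/k_ref =
e^{β·(d_ref − d_alt)}, and ensemble-based, ⟨e^(−βR)⟩_alt/⟨e^(−βR)⟩_ref,
which tempers the peak value when only part of the ensemble visits the
short-distance conformations. The distance-decay constant β defaults to
1.8 Å⁻¹ — a typical protein-medium value, and the value at which the
0.6 Å peak shift (14.1 → 13.5 Å) corresponds to a factor e^1.08 ≈ 3; it is
an explicit, configurable calibration, not a fitted quantity. The full
nonadiabatic rate k ∝ |H(R)|²(4πλ_r·kB·T)^(−1/2)·e^(−(ΔG°+λ_r)²/(4λ_r·kB·T))
with H(R) = H₀e^(−β(R−R₀)/2) is provided up to its ℏ prefactor; when only
R varies it reduces exactly to the peak-based ratio. Distances are
center-to-center; no edge-to-edge conversion is attempted.

## Synthetic data: what it emulates, and what it does not

The generator layer produces inputs with the statistical structure the
estimators assume, with analytically known answers:

* **Pulling** is overdamped (Brownian) dynamics of a single coordinate in
  a model potential under a moving harmonic restraint, x ← x −
  Δt(U′+k(x−c))/γ + √(2kB·T·Δt/γ)·ξ, with work accumulated per restraint
  step as W += k(c−x)Δc (position taken before the step). Overdamped
  rather than inertial dynamics was chosen because the analysis layer
  consumes only work traces, and the quasi-static limit is reachable at
  desk scale. The timestep must satisfy Δt < 0.1·γ/k (the overdamped
  stability bound for the stiffest restoring force); violations are
  rejected before running. The default schedule mirrors the extraction
  protocol (10 → 58 Å; "fast" 3 ns with a 10×-slower variant), with the
  restraint stiffness defaulting to the study's 2 kcal/mol/Å².
* **Alchemical samples** are Gaussian forward/reverse pairs with means
  ΔG ± σ²/(2kB·T) and common variance σ², which satisfy the Crooks
  relation exactly; BAR is asymptotically unbiased on them by
  construction, and (mean_f + mean_r)/2 recovers ΔG exactly in
  expectation.
* **Distances** are Gaussian mixtures; the benchmark shapes are a
  unimodal wild-type-like component at 14.1 Å and a mutant-like 60/40
  mixture at 13.5/14.1 Å (sd 0.15 Å).

The parameter-recovery benchmark for the work profile uses a quartic
double well (wells 1.0 and 3.0 Å, barrier 3 kB·T at 310 K), friction
γ = 1 kcal·ns/mol/Å² (D ≈ 0.6 Å²/ns), a stiff k = 300 kcal/mol/Å² spring
pulled 0.5 → 3.5 Å over 6 ns (the fast comparison variant uses 0.6 ns),
Δt = 2×10⁻⁴ ns, 0.5 ns of pre-equilibration, and 200 trajectories. The
stiff spring keeps the center-binned profile within a fraction of kT of
the bare potential (the spring-convolution error shrinks as kB·T·U″/k);
mean dissipation at the slow schedule is ~2 kT, which 200 Jarzynski
samples correct to ≲0.3 kT RMSE.

These generators emulate the *estimator-facing statistics* of pulling and
alchemical simulations — not molecular reality: there is no membrane, no
3-D geometry, no force field, work distributions are closer to Gaussian
than real SMD tails, and the distance mixtures have no autocorrelation.
Passing recovery tests therefore demonstrates correctness of the
estimators and pipeline plumbing under their stated assumptions, not
agreement of any particular MD study with experiment. Reanalysis of real
trajectories enters through the `smd_log`/`fepout`/TSV readers, at
whatever scale those data carry.

## Numerical choices and degenerate inputs

* Exponential averages (Jarzynski, Zwanzig, ensemble rate ratios) always
  go through log-sum-exp; no overflow for any input magnitude.
* BAR bisection tolerance 1e-8 kcal/mol; antisymmetry (swapping and
  negating the two sample sets negates ΔG) holds to the solver tolerance.
* Single-trace profiles make the three estimators coincide identically;
  single-sample variance is defined as 0 (ddof=1 otherwise).
* Flat schedule segments (repeated centers) are collapsed to their last
  sample before interpolation; repeated time stamps are rejected.
* Empty interior bins raise a gap error listing the offending centers;
  empty *edge* bins produced by grid rounding are trimmed silently.
* KDE on a constant series, automatic bandwidth with < 100 samples, λ
  outside [0, 1], non-positive distances, k-th neighbor distance of 0,
  and n ≤ k all raise typed errors rather than returning NaN.
* All generators take integer seeds; the CLI expands its single `--seed`
  into per-module streams by `SeedSequence.spawn` in a fixed order, so
  every subcommand is bit-reproducible.

## Known limitations

* The Jarzynski estimator's finite-sample bias grows exponentially with
  dissipation; profiles pulled far from equilibrium will underestimate
  barriers even when the Jensen ordering holds. The fast-schedule variant
  exists precisely to expose this trend.
* BAR standard errors are asymptotic; at poor overlap they are
  optimistic, which is why the overlap diagnostic exists.
* The kNN density estimator at k = 4 has ~70% single-draw relative
  spread; corrections from single short endpoint runs carry that noise
  (averaging over replicate endpoint ensembles is recommended).
* Mode positions from KDE are biased toward each other when components
  overlap within a few bandwidths; the EM cross-check is the better tool
  in that regime.
* The ensemble rate ratio assumes the conformational exchange is slow
  compared with electron transfer attempts (static-disorder averaging of
  k(R), not of the barrier).
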