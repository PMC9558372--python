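# Methods

This note documents the models, numerical choices and validation strategy
behind cphkit, and what the synthetic test conditions do and do not show
about real simulations.

## The λ-potential model

A titratable site is a particle of mass 5 amu (the production default for
λ-coordinates) moving on

    V(λ) = V_env(λ) + V_MM(λ) + V_pH(λ) + V_bias(λ)

* `V_env` — the force-field deprotonation free-energy profile of the
  environment. In this package it is an explicit input (polynomial
  coefficients or a tabulated curve, converted internally to an
  interpolating polynomial): the toy analogue of the molecular-mechanics
  environment, not a claim about any real force field.
* `V_MM(λ) = −∫₀^λ fit(λ′) dλ′` — the correction potential, minus the
  antiderivative of the polynomial fitted to ⟨∂V/∂λ⟩, with integration
  constant `V_MM(0) = 0`. With this sign convention a perfect fit makes
  `V_env + V_MM` flat.
* `V_pH(λ) = ln(10)·k_B·T·(pKa − pH)·λ` — linear in λ, exactly zero at
  pH = pKa, favouring the deprotonated state (λ = 1) when pH > pKa.
* `V_bias` — a barrier between the end states plus confining walls. The
  barrier is the smooth compact-support bump
  `B·exp(1 − 1/(1 − u²))`, `u = (λ − ½)/½`: it equals the nominal barrier
  height exactly at λ = ½ and is exactly zero at λ = 0 and 1 with all
  derivatives continuous, so the end states feel no spurious force. (A
  truncated Gaussian cannot satisfy the end-state-zero contract exactly;
  the bump is this package's choice and is configurable.) Quartic walls of
  stiffness 10⁴ kJ/mol per λ⁴ rise outside [−0.1, 1.1] — soft enough that
  a thermal particle penetrates ≈ 0.1 λ-units, keeping the wall curvature
  resolvable at the default 2 fs step. Buffer sites use a flat bias
  (barrier 0).

Units: kJ/mol, ps, amu, K, radians internally (degrees only at the I/O
boundary); k_B = 0.0083144621 kJ mol⁻¹ K⁻¹. In these units kinetic energy
is ½mv² directly.

## Correction-potential fitting

The reference grid spans λ = −0.1 … 1.1 in steps of 0.05 (25 points,
including the unphysical margins, which are part of the fit domain;
uniformity diagnostics use only [0, 1]). Raw per-point samples are reduced
to means with block-averaged standard errors (5 blocks by default), which
is robust to the time correlation of MD output; the fixture generator has
an AR(1) mode to exercise exactly that. The fit is unweighted least
squares by default (an optional 1/σ² weighting flag exists) because the
reference data have near-homogeneous noise.

Numerically the fit is solved in the Chebyshev basis mapped onto the grid
interval, with two steps of iterative refinement, and converted to
ascending monomial coefficients at the end. The monomial normal equations
are catastrophically ill-conditioned at orders 7–8 on this domain
(equivalent monomial coefficients reach 10⁵); the Chebyshev route keeps
coefficient errors at the 10⁻⁹ level for noiseless data. For the same
reason the synthetic truth curves are *represented and evaluated* as
Chebyshev series — evaluating their monomial form in double precision
would destroy ~7 digits through cancellation before any fitter sees the
data.

Two error metrics are reported per order: mean absolute error in
derivative space, and in integral space against minus the trapezoid
integral of the grid means (the model-free reference). `select_order`
additionally predicts, from the residual between the fitted `V_MM` and a
cubic-spline integral of the means (an O(h⁴) reference, since the
trapezoid's own O(h²) error is comparable to the sub-kT effects being
judged), the Boltzmann λ-distribution at pH = pKa, and accepts the
smallest order with integral error < 0.5 kJ/mol and predicted
uniformity KSS < 0.01. The flatness default is calibrated so that for the
built-in truth family every Chebyshev component that carries ≳ 0.1 kJ/mol
of free-energy structure is resolved — i.e. an order-d curve genuinely
requires an order-d fit. On failure the scan returns `max_order` with an
explicit failure flag.

### The synthetic mean-force family

`asp_like_dvdl_chebyshev(degree)` is a linear (linear-response) part,
−280 + 160λ kJ/mol, plus Chebyshev components T₂…T₈ with amplitudes
130, 85, 50, 32, 20, 13, 13 kJ/mol. The family emulates a carboxylate-like
site: the curve spans several hundred kJ/mol, a 1st-order fit leaves an
integrated error above 10 kJ/mol, a 3rd-order fit ≈ 3.5 kJ/mol, and
higher components stay individually significant up to degree 8 (the
amine-like regime where an 8th-order fit is needed). What these fixtures do
*not* model: time-correlated sampling noise with λ-dependent variance,
conformational hysteresis between grid points, and multisite coupling of
the reference simulations.

## Toy samplers

λ-dynamics uses leapfrog with a per-step stochastic velocity-rescaling
thermostat (Bussi-style; exact single-degree-of-freedom update
K′ = (√(cK) + √((1−c)k_BT/2)·R)², c = e^(−Δt/τ)), defaults Δt = 2 fs,
τ = 2 ps, T = 300 K; a BAOAB Langevin thermostat is the alternative. The
"2.0 ps⁻¹" time-constant notation seen in the field is read as τ = 2.0 ps
(a time constant has units of time). Trajectories are recorded every
0.5 ps by default and are bit-reproducible from the seed (kernels are
numba-jitted; randomness uses the legacy RandomState stream seeded inside
the kernel). |λ| > 10 raises a blow-up error naming the step.

For the multisite representation (e.g. histidine's three coupled states)
forces and velocities are projected off the (1,…,1) direction every step
and the coordinate sum is renormalized, so Σλ = 1 holds to machine
precision; the thermostat then acts on n−1 degrees of freedom.

The dihedral sampler is overdamped Langevin using the Leimkuhler–Matthews
scheme (successive-noise averaging), which has second-order configurational
accuracy: with mobility D/k_BT and the default D = 1 rad²/ps the sampled
variance in a 418.4 kJ mol⁻¹ rad⁻² umbrella window is exact to < 1% at
Δt = 1–2 fs. An inertial BAOAB option exists. Umbrella restraints use the
minimum-image angular difference wrapped to (−π, π].

Thermostat-accuracy tests use τ = 0.2 ps: kinetic and configurational
observables then decorrelate in ~0.4 ps, giving ≈ 5000 effective samples
per 10⁶ steps and ~1–2 % standard error on a variance — which is why the
equipartition check averages three seeds against a 3 % band.

## Torsion corrections and ε optimization

Corrections are −(ε/2)(1 + cos(nφ − δ_c)) with δ_c aligned numerically so
the correction minima sit on the base-profile maxima; for a correction
sharing the base multiplicity this lowers every barrier by exactly ε and
cannot move the minima until ε exceeds twice the base amplitude
(overshoot inverts the profile, which the new-minimum detector flags by
position). Extrema are found from sign changes of forward differences on
the periodic grid with persistence merging below 0.1 kJ/mol — an
operational replacement for visual inspection of shoulders. A per-dihedral
`allow_shape_change` flag disables the new-minimum veto for the carboxyl
H–O–C–O case, where an altered barrier shape is acceptable (the proton
tunnels through such barriers in reality).

The ε driver scans ε = 0, Δε, 2Δε, … (default step 1 kJ/mol) — a plain
upward scan keeping the audit trail faithful to the published "gradually
increase" procedure — running replicas with distinct seeds (identical
seeds are refused) started in different wells, and accepts the first ε
with pairwise circular KSS < 0.03 and no new minima. The audit records
every iteration's KSS matrix and extrema counts; hitting ε_max returns an
explicit failure, never a silent success. In the validation conditions
(40 kJ/mol barrier, 4 ns overdamped replicas with D = 3 rad²/ps) the
driver needs ε ≈ 32–36: the replicas are ~25× shorter than production MD,
so equilibrating well occupancies to 3 % needs the residual barrier down
to ~2 kT. The scan bound ε_max = 38 is just below the flattening limit
2k = 40.

KSS on angles rotates the origin to the midpoint of the largest gap in the
pooled sample before comparing ECDFs (flagged: the statistic retains a
mild origin dependence). The two-sample KSS itself is computed exactly on
the pooled points with integer cross-multiplication, so worked examples
like 1/3 are exact; thresholds are strict (<). No p-values are attached —
KSS is used as a descriptive similarity measure.

## Umbrella sampling and WHAM

`run_umbrella_protocol` places n equally spaced windows (default 36 at 10°
spacing, k = 418.4 kJ mol⁻¹ rad⁻²), each with its own derived seed and a
10 % burn-in. `wham` performs the standard periodic 1-D self-consistent
iteration on 72 bins (5°), tolerance 10⁻⁸ k_BT on window free energies,
cap 10⁵ iterations, with window connectivity checked through jointly
sampled bins (disconnected groups raise an error naming the gap);
non-convergence sets a flag and warns. Profiles are reported relative to
their minimum; unsampled bins are NaN. The tests cross-check the iteration
against an independent route — direct BFGS minimization of the WHAM
log-likelihood — and against histogram inversion in the single-window
k = 0 limit.

## Titration

Frames classify as protonated (λ < 0.2) or deprotonated (λ > 0.8) with
strict inequalities; λ ∈ [0.2, 0.8] is physically ambiguous and excluded
from both counts (the symmetric rule applies to the multisite
doubly-ambiguous case). The Henderson–Hasselbalch fit is one-parameter
nonlinear least squares on replica-mean fractions, initialized at the pH
whose fraction is nearest ½; per-replica fits give the pKa spread, and the
residual statistic is the RMS between calculated and fitted fractions over
all pH values and replicas. pH values with no classifiable frames are
dropped with a warning; fully saturated data (all 0 or all 1) raise a
non-identifiability error. The titration fixture emits λ = 0.05/0.95
Bernoulli frames so classification is unambiguous; the default ladder is
15 pH values in [1, 8].

## Buffers

Per frame, buffer charge = −(Σ site charge)/n_buffers, so the box is
neutral to machine precision by construction; frames outside the optimal
per-buffer range [−0.5, 0.5] e are flagged but not fatal (buffers carry a
flat bias). The worst-case sizing rule is
n_buffers = ⌈(n_sites/2)/min(hi, −lo)⌉, which equals n_sites for the
default range. The buffer Lennard-Jones constants used in production
(σ = 0.25 nm, ε = 4 kJ/mol) are recorded for reference only — no Cartesian
interactions are modelled here.

## Problem sizes in tests and the acceptance script

Sampler validations use 10⁶-step runs (2 ns at 2 fs) with up to three
seeds; the ε driver uses five 4 ns replicas per candidate ε; WHAM uses
36 × 60 ps windows. These sizes put the statistical noise of each check
well below its tolerance (e.g. KS noise ~0.006 against a 0.02 band) while
the whole suite runs in about half a minute.

## Known limitations

* The samplers are 1-D (per coordinate): no coupling between λ and
  dihedral dynamics, which in real systems is precisely the convergence
  bottleneck the torsion corrections address. Passing tests show the
  machinery is correct, not that any particular force field converges.
* `select_order` judges fits against the grid data themselves; systematic
  errors shared by all grid points (e.g. unconverged reference runs) are
  invisible to it.
* The circular KSS origin rule is a convention; two near-uniform angular
  samples can shift the rotation point between runs (the statistic itself
  stays small).
* WHAM bin width (5°) bounds the resolution of recovered profiles; errors
  quoted on well-sampled bins (≥ 100 counts) only.
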