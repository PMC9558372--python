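# cphkit

Parametrization and analysis toolkit for **λ-dynamics constant-pH molecular
dynamics (MD)**.

In constant-pH MD every titratable site (Asp, Glu, Lys, His, the termini)
carries an auxiliary coordinate λ ∈ [0, 1] that interpolates between the
protonated (λ = 0) and deprotonated (λ = 1) states and evolves dynamically
with its own mass and thermostat. Running such simulations accurately
requires a parametrization layer that this package implements and validates:

* **Correction potentials** `V_MM(λ)`. The force-field deprotonation free
  energy must be cancelled analytically so that only the pH term and the
  biasing potential shape λ-sampling. `cphkit.ti_fit` builds the
  thermodynamic-integration grid (λ = −0.1 … 1.1 in steps of 0.05), fits
  ⟨∂V/∂λ⟩ with a polynomial of configurable order (an order-*n* fit
  integrates to an order-(*n*+1) `V_MM`), and quantifies the fit error as a
  function of order. Low-order (linear-response) fits leave errors above
  10 kJ/mol; `select_order` finds the smallest order whose residual
  landscape would still give a uniform λ-distribution at pH = pKa.
* **Torsion-barrier corrections.** Force-field side-chain torsion barriers
  are often too high for dihedral (and hence protonation) degrees of freedom
  to converge. `cphkit.torsion` adds cosine corrections
  −(ε/2)(1 + cos(nφ − δ_c)) aligned with the barrier tops (n = 2 for
  conjugated, 3 for aliphatic bonds), and optimizes ε iteratively until
  replica dihedral distributions agree (pairwise Kolmogorov–Smirnov
  statistic < 0.03) without introducing new minima. Umbrella sampling
  (36 windows, 418.4 kJ mol⁻¹ rad⁻²) with periodic 1-D WHAM verifies the
  resulting free-energy profiles.
* **Titration analysis.** `cphkit.titration` classifies λ-frames
  (protonated below 0.2, deprotonated above 0.8), forms deprotonation
  fractions S = N_deprot/(N_prot + N_deprot) — including the three-state
  multisite rule for histidine — and fits the Henderson–Hasselbalch curve
  S(pH) = 1/(1 + 10^(pKa − pH)) to obtain pKa values with replica spreads.
* **Box neutrality.** `cphkit.simulate.buffer_charges` spreads the summed
  site charge over buffer particles, flags frames that leave the optimal
  per-buffer range [−0.5, 0.5] e, and `recommend_buffer_count` sizes the
  buffer set for the worst-case charge swing.
* **Diagnostics.** `cphkit.diagnostics` provides exact two-sample
  Kolmogorov–Smirnov statistics (with a circular variant for dihedrals),
  replica-consistency matrices, and uniformity/Boltzmann checks.
* **Toy samplers.** `cphkit.simulate` contains a leapfrog λ-dynamics
  engine (λ mass 5 amu, stochastic velocity-rescaling thermostat, the
  multisite constraint Σλ = 1) and an overdamped Langevin dihedral sampler.
  They sample the Boltzmann distribution of any supplied 1-D landscape and
  serve as the validation harness for everything above.

## Worked example

Fit a correction potential to synthetic mean-force data, then check that
λ-dynamics at pH = pKa samples uniformly:

```python
import numpy as np
from cphkit import (
    asp_like_dvdl_chebyshev, asp_like_dvdl_coeffs, gen_dvdl_data, build_grid,
    average_dvdl, select_order, fit_dvdl, LambdaSite, PHPotentialParams,
    BiasPotentialParams, PotentialSet, SimConfig, run_lambda_dynamics,
    uniformity,
)

grid_pts = build_grid(-0.1, 1.1, 0.05)               # 25 lambda points
truth = asp_like_dvdl_chebyshev(7)                   # carboxylate-like curve
data = gen_dvdl_data(truth, grid_pts, noise_sigma=1.0, n_per_point=1000, seed=1)
grid = average_dvdl(list(data), lambda_points=grid_pts)

sel = select_order(grid, max_order=10)
print(sel.recommended_order)                          # -> 7
cp = fit_dvdl(grid, sel.recommended_order)

env = np.polynomial.polynomial.polyint(asp_like_dvdl_coeffs(7))
pot = PotentialSet(env=env, correction=cp,
                   ph=PHPotentialParams(pH=4.0, pKa=4.0),
                   bias=BiasPotentialParams(0.0))
traj = run_lambda_dynamics(LambdaSite("asp", pKa_ref=4.0), pot,
                           SimConfig(n_steps=1_000_000, seed=1, stride=10))
print(round(uniformity(traj.lambdas, (0, 1)).kss, 4))  # -> 0.0083
```

The recommended order is 7: lower orders leave a rugged residual landscape
(a 1st-order fit on the same data gives a uniformity KSS above 0.8, i.e. λ
trapped in spurious wells), while the 7th-order fit cancels the free-energy
profile and the λ-distribution is flat to within sampling noise.

The same workflow is available from the shell:

```bash
cphkit fixtures dvdl --seed 1 --n 1000 -o dvdl.csv
cphkit fit dvdl.csv --order-scan 9 -o correction.json
cphkit titrate titration.csv -o curve      # pKa from lambda-trajectories
```

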