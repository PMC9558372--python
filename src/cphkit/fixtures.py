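"""Synthetic-data generators emulating the reference simulations.

These generators stand in for the MD simulations that would normally feed
the parametrization layer: fixed-lambda thermodynamic-integration runs
producing dV/dlambda samples, and constant-pH production runs producing
lambda-trajectories at a ladder of pH values.  Every generator takes a
mandatory seed and is bit-reproducible.

The default mean-force curve :func:`asp_like_dvdl_coeffs` is built from a
linear (linear-response) part plus shifted-Legendre components of
decreasing amplitude, emulating a carboxylate-like titratable site: the
curve spans a few hundred kJ/mol, a first-order fit leaves an integrated
error above 10 kJ/mol, a third-order fit around 4-5 kJ/mol, and every
component up to the chosen degree remains thermodynamically significant
(so an order-d fit is genuinely required for a degree-d curve).
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import Chebyshev, Polynomial
from numpy.polynomial import polynomial as npoly

from .model import LambdaSite
from .simulate import LambdaTrajectory
from .titration import henderson_hasselbalch

__all__ = [
    "asp_like_dvdl_chebyshev",
    "asp_like_dvdl_coeffs",
    "asp_like_reference_grid",
    "gen_dvdl_data",
    "gen_titration_set",
    "DEFAULT_PH_VALUES",
]

#: 15 equidistant pH values from 1.0 to 8.0, the standard titration ladder
DEFAULT_PH_VALUES = tuple(np.round(np.linspace(1.0, 8.0, 15), 3))

#: domain of the reference lambda-grid (the fit domain of V_MM)
GRID_DOMAIN = (-0.1, 1.1)

# amplitudes (kJ/mol) of the Chebyshev components T_k on the grid domain;
# chosen so each component up to degree 8 remains thermodynamically
# significant while monomial coefficients stay numerically recoverable
_CHEB_AMPS = {2: 130.0, 3: 85.0, 4: 50.0, 5: 32.0, 6: 20.0, 7: 13.0, 8: 13.0}


def asp_like_dvdl_chebyshev(degree: int = 7) -> Chebyshev:
    """Default <dV/dlambda> truth as a Chebyshev series on the grid domain.

    ``degree`` 0 gives a constant mean force, 1 the pure linear-response
    curve, and higher degrees add one Chebyshev component each up to
    degree 8.  This representation evaluates without the catastrophic
    cancellation the equivalent monomial form would suffer, so it is what
    the data generators use.
    """
    if degree > max(_CHEB_AMPS):
        raise ValueError(f"degree must be <= {max(_CHEB_AMPS)}")
    if degree == 0:
        return Chebyshev([-280.0], domain=list(GRID_DOMAIN))
    c = np.zeros(degree + 1)
    lin = Chebyshev.cast(Polynomial([-280.0, 160.0]), domain=list(GRID_DOMAIN)).coef
    c[:2] = lin
    for k in range(2, degree + 1):
        c[k] += _CHEB_AMPS[k]
    return Chebyshev(c, domain=list(GRID_DOMAIN))


def asp_like_dvdl_coeffs(degree: int = 7) -> np.ndarray:
    """Monomial (ascending power) coefficients of the default truth curve."""
    return asp_like_dvdl_chebyshev(degree).convert(kind=Polynomial).coef


def asp_like_reference_grid(degree: int = 7):
    """Noiseless :class:`~cphkit.ti_fit.ReferenceGrid` of the default truth."""
    from .ti_fit import ReferenceGrid, build_grid

    grid = build_grid(GRID_DOMAIN[0], GRID_DOMAIN[1], 0.05)
    mean = asp_like_dvdl_chebyshev(degree)(grid)
    return ReferenceGrid(grid, mean, np.zeros_like(grid))


def gen_dvdl_data(
    truth,
    grid,
    noise_sigma: float,
    n_per_point: int,
    seed: int,
    ar1: float = 0.0,
) -> np.ndarray:
    """Per-grid-point dV/dlambda samples around a known truth polynomial.

    Noise is i.i.d. Gaussian by default; ``ar1`` in (0, 1) adds lag-one
    autocorrelation (an AR(1) process with the same marginal sigma), which
    emulates the time correlation of real MD output and exercises the
    block-averaging error estimate.  Returns an (n_points, n_per_point)
    array.
    """
    if n_per_point < 2:
        raise ValueError("n_per_point must be >= 2")
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((len(grid), n_per_point))
    if ar1:
        if not (0.0 < ar1 < 1.0):
            raise ValueError("ar1 must be in (0, 1)")
        corr = np.empty_like(eps)
        corr[:, 0] = eps[:, 0]
        fac = np.sqrt(1.0 - ar1**2)
        for j in range(1, eps.shape[1]):
            corr[:, j] = ar1 * corr[:, j - 1] + fac * eps[:, j]
        eps = corr
    if callable(truth):
        means = np.asarray(truth(grid), dtype=float)
    else:
        means = npoly.polyval(grid, np.atleast_1d(np.asarray(truth, dtype=float)))
    return means[:, None] + noise_sigma * eps


def gen_titration_set(
    pKa_truth: float = 4.0,
    pH_values=DEFAULT_PH_VALUES,
    n_frames: int = 1000,
    n_replicas: int = 10,
    seed: int = 0,
    site: LambdaSite = None,
) -> dict:
    """Synthetic lambda-trajectories at a pH ladder, ``{pH: [traj, ...]}``.

    Frames are Bernoulli draws with the Henderson-Hasselbalch probability
    of deprotonation at each pH, emitted as lambda = 0.95 (deprotonated)
    or 0.05 (protonated) so every frame is unambiguous under the 0.2/0.8
    classification thresholds.
    """
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    if site is None:
        site = LambdaSite(name="synthetic", pKa_ref=pKa_truth)
    rng = np.random.default_rng(seed)
    out = {}
    for pH in pH_values:
        p = float(henderson_hasselbalch(pH, pKa_truth))
        trajs = []
        for r in range(n_replicas):
            deprot = rng.random(n_frames) < p
            lam = np.where(deprot, 0.95, 0.05)
            trajs.append(
                LambdaTrajectory(site=site, lambdas=lam, pH=float(pH), replica_id=str(r))
            )
        out[float(pH)] = trajs
    return out
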