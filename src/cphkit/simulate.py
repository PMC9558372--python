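"""Toy stochastic dynamics engines and charge-neutrality bookkeeping.

Two samplers are provided:

* :func:`run_lambda_dynamics` — leapfrog dynamics of a lambda-particle
  (mass 5 amu by default) on V_env + V_MM + V_pH + V_bias, thermostatted
  with stochastic velocity rescaling (or Langevin), including the
  constrained multisite case where the per-state lambdas sum to 1.
* :func:`sample_dihedral` — Langevin sampling of a 1-D periodic torsion
  profile, overdamped by default, with an optional wrapped harmonic
  restraint for umbrella sampling.

Both are exact stand-ins for the lambda/dihedral degrees of freedom of a
real constant-pH MD engine: they sample the Boltzmann distribution of the
supplied 1-D landscape, which is all the parametrization layer needs.

Buffer-charge bookkeeping keeps the periodic box neutral: each frame the
summed charge change of the titratable sites is spread with opposite sign
over ``n_buffers`` buffer particles, and frames where the per-buffer
charge leaves its optimal range (default [-0.5, 0.5] e) are flagged —
never fatal, because the buffers carry a flat bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .constants import kt
from .errors import IntegrationBlowupError, SeedCollisionError
from .model import BiasPotentialParams, LambdaSite, PotentialSet, TorsionModel

__all__ = [
    "SimConfig",
    "LambdaTrajectory",
    "BufferLedger",
    "run_lambda_dynamics",
    "apply_multisite_constraint",
    "buffer_charges",
    "recommend_buffer_count",
    "sample_dihedral",
]


@dataclass
class SimConfig:
    """Integration settings for the toy samplers.

    ``stride`` frames are recorded every ``stride`` steps; by default every
    0.5 ps of simulated time.  ``seed`` is mandatory: every trajectory is a
    deterministic function of its inputs and seed.
    """

    n_steps: int
    seed: int
    dt: float = 0.002  # ps
    temperature: float = 300.0  # K
    tau_thermostat: float = 2.0  # ps
    thermostat: str = "velocity-rescale"
    stride: int = None
    friction: float = 5.0  # ps^-1, Langevin thermostat only

    def __post_init__(self):
        if self.dt <= 0 or self.temperature <= 0 or self.tau_thermostat <= 0:
            raise ValueError("dt, temperature and tau_thermostat must be positive")
        if self.thermostat not in ("velocity-rescale", "langevin"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.stride is None:
            self.stride = max(1, int(round(0.5 / self.dt)))

    def to_dict(self) -> dict:
        return {
            "n_steps": int(self.n_steps),
            "seed": int(self.seed),
            "dt": float(self.dt),
            "temperature": float(self.temperature),
            "tau_thermostat": float(self.tau_thermostat),
            "thermostat": self.thermostat,
            "stride": int(self.stride),
            "friction": float(self.friction),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class LambdaTrajectory:
    """Time series of a lambda coordinate (or lambda-vector for multisite)."""

    site: LambdaSite
    lambdas: np.ndarray  # (n_frames,) or (n_frames, n_states)
    pH: float = float("nan")
    replica_id: str = "0"
    frame_dt: float = 0.5  # ps between recorded frames
    mean_kinetic_energy: float = float("nan")

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)

    @property
    def is_multisite(self) -> bool:
        return self.lambdas.ndim == 2


def _total_dpot_coeffs(pot: PotentialSet) -> np.ndarray:
    """Ascending coefficients of d(V_env + V_MM)/dlambda."""
    from numpy.polynomial import polynomial as npoly

    env = pot.env_coeffs()
    denv = npoly.polyder(env) if len(env) > 1 else np.zeros(1)
    if pot.correction is not None:
        dvmm = npoly.polyder(pot.correction.vmm_coeffs)
        n = max(len(denv), len(dvmm))
        d = np.zeros(n)
        d[: len(denv)] += denv
        d[: len(dvmm)] += dvmm
        return d
    return np.atleast_1d(denv)


def run_lambda_dynamics(
    site: LambdaSite,
    potentials,
    cfg: SimConfig,
    x0=None,
    replica_id: str = "0",
) -> LambdaTrajectory:
    """Sample the lambda coordinate(s) of ``site`` on the given potentials.

    ``potentials`` is a :class:`~cphkit.model.PotentialSet` (single-site) or
    a list of one PotentialSet per state (multisite; a single set is
    broadcast).  Raises :class:`IntegrationBlowupError` if |lambda| > 10.
    """
    kT = kt(cfg.temperature)
    if site.representation == "single":
        pot = potentials if isinstance(potentials, PotentialSet) else PotentialSet(**potentials)
        bias = pot.bias if pot.bias is not None else BiasPotentialParams(0.0)
        dpot = _total_dpot_coeffs(pot)
        ph_slope = pot.ph.slope if pot.ph is not None else 0.0
        x_init = 0.5 if x0 is None else float(x0)
        frames, count, blow, mean_ke = _kernels.lambda_leapfrog(
            x_init,
            0.0,
            site.lambda_mass,
            cfg.dt,
            int(cfg.n_steps),
            kT,
            cfg.tau_thermostat,
            int(cfg.seed),
            np.ascontiguousarray(dpot),
            float(ph_slope),
            float(bias.barrier_height),
            float(bias.center),
            float(bias.half_width),
            float(bias.wall_bounds[0]),
            float(bias.wall_bounds[1]),
            float(bias.wall_stiffness),
            int(cfg.stride),
            cfg.thermostat == "langevin",
            float(cfg.friction),
        )
        if blow >= 0:
            raise IntegrationBlowupError(blow, float("nan"))
        pH = pot.ph.pH if pot.ph is not None else float("nan")
        return LambdaTrajectory(
            site=site,
            lambdas=frames[:count],
            pH=pH,
            replica_id=replica_id,
            frame_dt=cfg.dt * cfg.stride,
            mean_kinetic_energy=float(mean_ke),
        )

    # multisite
    ns = site.n_states
    if isinstance(potentials, PotentialSet):
        pots = [potentials] * ns
    else:
        pots = list(potentials)
        if len(pots) != ns:
            raise ValueError(f"need {ns} potential sets for a {ns}-state site")
    dlist = [_total_dpot_coeffs(p) for p in pots]
    L = max(len(d) for d in dlist)
    dpots = np.zeros((ns, L))
    for i, d in enumerate(dlist):
        dpots[i, : len(d)] = d
    ph_slopes = np.array(
        [p.ph.slope if p.ph is not None else 0.0 for p in pots], dtype=float
    )
    bias = next((p.bias for p in pots if p.bias is not None), BiasPotentialParams(0.0))
    if x0 is None:
        x_init = np.full(ns, 1.0 / ns)
    else:
        x_init = np.asarray(x0, dtype=float)
    frames, count, blow, mean_ke = _kernels.multisite_leapfrog(
        x_init,
        np.zeros(ns),
        site.lambda_mass,
        cfg.dt,
        int(cfg.n_steps),
        kT,
        cfg.tau_thermostat,
        int(cfg.seed),
        dpots,
        ph_slopes,
        float(bias.barrier_height),
        float(bias.center),
        float(bias.half_width),
        float(bias.wall_bounds[0]),
        float(bias.wall_bounds[1]),
        float(bias.wall_stiffness),
        int(cfg.stride),
    )
    if blow >= 0:
        raise IntegrationBlowupError(blow, float("nan"))
    pH = next((p.ph.pH for p in pots if p.ph is not None), float("nan"))
    return LambdaTrajectory(
        site=site,
        lambdas=frames[:count],
        pH=pH,
        replica_id=replica_id,
        frame_dt=cfg.dt * cfg.stride,
        mean_kinetic_energy=float(mean_ke),
    )


def apply_multisite_constraint(lambda_vec, force_vec):
    """Project a multisite state onto the sum(lambda) = 1 hyperplane.

    Coordinates: subtract the mean excess (sum - 1)/n from each, then fix
    the residual rounding on the first component so the sum is exactly 1.
    Forces: remove the component along (1, ..., 1).
    """
    lam = np.asarray(lambda_vec, dtype=float).copy()
    f = np.asarray(force_vec, dtype=float).copy()
    if lam.size < 2 or f.size != lam.size:
        raise ValueError("need vectors of equal length >= 2")
    lam -= (lam.sum() - 1.0) / lam.size
    lam[0] -= lam.sum() - 1.0
    f -= f.mean()
    return lam, f


@dataclass
class BufferLedger:
    """Per-frame buffer charges compensating the titratable-site charges."""

    n_buffers: int
    charge_range: tuple = (-0.5, 0.5)
    per_buffer_charge: np.ndarray = None  # (n_frames,), e
    total_site_charge: np.ndarray = None  # (n_frames,), e
    out_of_range: np.ndarray = None  # (n_frames,) bool

    def max_neutrality_violation(self) -> float:
        """Largest |total site charge + n_buffers * buffer charge| over frames."""
        return float(
            np.max(np.abs(self.total_site_charge + self.n_buffers * self.per_buffer_charge))
        )

    @property
    def n_flagged(self) -> int:
        return int(np.count_nonzero(self.out_of_range))


def buffer_charges(site_charge_changes, n_buffers: int, charge_range=(-0.5, 0.5)) -> BufferLedger:
    """Distribute the summed site charge change over the buffers each frame.

    ``site_charge_changes`` is (n_frames, n_sites) or (n_frames,) already
    summed, in units of e.  Frames whose per-buffer charge leaves
    ``charge_range`` are flagged but not rejected (the buffer bias is flat).
    """
    if n_buffers < 1:
        raise ValueError("n_buffers must be >= 1")
    q = np.asarray(site_charge_changes, dtype=float)
    total = q.sum(axis=1) if q.ndim == 2 else q
    per_buffer = -total / n_buffers
    lo, hi = charge_range
    flags = (per_buffer < lo) | (per_buffer > hi)
    return BufferLedger(
        n_buffers=n_buffers,
        charge_range=tuple(charge_range),
        per_buffer_charge=per_buffer,
        total_site_charge=total,
        out_of_range=flags,
    )


def recommend_buffer_count(n_sites: int, charge_range=(-0.5, 0.5)) -> int:
    """Worst-case buffer count.

    The total charge of ``n_sites`` titratable sites can swing by
    ``n_sites`` e; centred at its midpoint the buffers must absorb up to
    +/- n_sites/2 e, so the smallest adequate count is
    ceil((n_sites/2) / min(hi, -lo)).  For the optimal range [-0.5, 0.5] e
    this equals n_sites.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    lo, hi = charge_range
    cap = min(hi, -lo)
    if not (hi > lo) or cap <= 0:
        raise ValueError("charge_range must straddle zero")
    return int(math.ceil((n_sites / 2.0) / cap - 1e-12))


def sample_dihedral(
    t: TorsionModel,
    cfg: SimConfig,
    restraint=None,
    diffusion: float = 1.0,
    phi0: float = None,
    inertial: bool = False,
    mass: float = 1.0,
) -> np.ndarray:
    """Langevin sampling of a torsion profile; returns angles in [0, 2*pi).

    ``restraint`` is an optional ``(phi_ref, force_constant)`` pair in
    (rad, kJ/mol/rad^2) applied with the minimum-image angular difference.
    The default integrator is the overdamped Leimkuhler-Matthews scheme
    with diffusion constant ``diffusion`` (rad^2/ps); ``inertial=True``
    switches to an underdamped BAOAB integrator.
    """
    amps, mults, phases = t._cosine_triples()
    if amps.size == 0:
        amps = np.zeros(1)
        mults = np.ones(1)
        phases = np.zeros(1)
    use_r = restraint is not None
    phi_r, k_r = (float(restraint[0]), float(restraint[1])) if use_r else (0.0, 0.0)
    if phi0 is None:
        phi0 = phi_r if use_r else 0.0
    frames, count, blow = _kernels.dihedral_langevin(
        float(phi0),
        cfg.dt,
        int(cfg.n_steps),
        float(diffusion),
        kt(cfg.temperature),
        int(cfg.seed),
        amps,
        mults,
        phases,
        use_r,
        phi_r,
        k_r,
        int(cfg.stride),
        bool(inertial),
        float(mass),
        float(cfg.friction),
    )
    if blow >= 0:
        raise IntegrationBlowupError(blow, float("nan"))
    return frames[:count]


def check_distinct_seeds(seeds) -> None:
    """Raise SeedCollisionError if any two replica seeds coincide."""
    seeds = [int(s) for s in seeds]
    if len(set(seeds)) != len(seeds):
        raise SeedCollisionError(f"replica seeds must be distinct, got {seeds}")
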