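"""Domain types and potential-energy terms acting on titration coordinates.

In lambda-dynamics constant-pH MD every titratable site carries an
auxiliary coordinate ``lambda`` in [0, 1] that interpolates between the
protonated (lambda = 0) and deprotonated (lambda = 1) end states.  The
lambda-particle moves on the sum of four terms:

* the force-field deprotonation free energy of the environment (``V_env``),
* the correction potential ``V_MM(lambda)``, an analytical fit built to
  cancel ``V_env`` (see :mod:`cphkit.ti_fit`),
* the pH potential ``V_pH(lambda) = ln(10) k_B T (pKa - pH) lambda``,
  which tilts the landscape toward the deprotonated state when pH > pKa,
* a biasing potential ``V_bias(lambda)``: a barrier between the end
  states that suppresses unphysical intermediate lambda values, plus
  stiff walls that confine lambda to a finite interval.

Side-chain torsions are modelled with the usual cosine series
``sum_i k_i (1 + cos(n_i phi - delta_i))`` plus optional barrier-lowering
correction terms ``-(eps_i/2)(1 + cos(n_i phi - delta_c,i))``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly

from .constants import KB, LN10
from .errors import InvalidModelError

__all__ = [
    "LambdaSite",
    "CorrectionPotential",
    "PHPotentialParams",
    "BiasPotentialParams",
    "TorsionModel",
    "PotentialSet",
    "eval_vmm",
    "eval_vph",
    "eval_vbias",
    "eval_torsion",
    "vph_slope",
    "ExtrapolationWarning",
]


class ExtrapolationWarning(UserWarning):
    """Raised when a correction potential is evaluated outside its fit domain."""


# --------------------------------------------------------------------------
# domain types


@dataclass
class LambdaSite:
    """One titratable coordinate set.

    ``representation`` is "single" (one scalar lambda, e.g. Asp/Glu/Lys and
    the termini) or "multisite" (one lambda per physical state, e.g. the
    three histidine states, constrained to sum to 1).

    Frames with lambda below ``prot_threshold`` count as protonated and
    above ``deprot_threshold`` as deprotonated; in between they are left
    unclassified.
    """

    name: str
    representation: str = "single"
    n_states: int = 1
    pKa_ref: float = 4.0
    prot_threshold: float = 0.2
    deprot_threshold: float = 0.8
    lambda_mass: float = 5.0  # amu

    def __post_init__(self):
        if self.representation not in ("single", "multisite"):
            raise ValueError(f"unknown representation {self.representation!r}")
        if not (0.0 < self.prot_threshold < self.deprot_threshold < 1.0):
            raise ValueError("need 0 < prot_threshold < deprot_threshold < 1")
        if self.lambda_mass <= 0:
            raise ValueError("lambda_mass must be positive")
        if self.n_states >= 2 and self.representation != "multisite":
            raise ValueError("n_states >= 2 requires the multisite representation")
        if self.representation == "multisite" and self.n_states < 2:
            raise ValueError("multisite representation requires n_states >= 2")


@dataclass
class CorrectionPotential:
    """Fitted polynomial correction potential V_MM(lambda).

    ``dvdl_coeffs`` are the ascending-power coefficients of the order-n
    polynomial fitted to <dV/dlambda>_lambda; ``vmm_coeffs`` are the
    ascending-power coefficients of its minus-antiderivative, so that

        V_MM(lambda) = -integral_0^lambda fit(l') dl',   V_MM(0) = 0.

    The two error metrics quantify the quality of the fit on the grid it
    was built from: mean absolute error in derivative space and in
    integral (free-energy) space.
    """

    dvdl_coeffs: np.ndarray
    vmm_coeffs: np.ndarray
    fit_order: int
    fit_domain: tuple = (-0.1, 1.1)
    mean_abs_error_dvdl: float = float("nan")
    mean_abs_error_integral: float = float("nan")

    def __post_init__(self):
        self.dvdl_coeffs = np.atleast_1d(np.asarray(self.dvdl_coeffs, dtype=float))
        self.vmm_coeffs = np.atleast_1d(np.asarray(self.vmm_coeffs, dtype=float))
        if len(self.vmm_coeffs) != len(self.dvdl_coeffs) + 1:
            raise InvalidModelError(
                "vmm_coeffs must have exactly one more coefficient than dvdl_coeffs"
            )
        if self.vmm_coeffs[0] != 0.0:
            raise InvalidModelError("V_MM(0) must be 0 (constant term of vmm_coeffs)")
        # d/dl vmm == -dvdl, coefficient-wise
        if not np.allclose(npoly.polyder(self.vmm_coeffs), -self.dvdl_coeffs):
            raise InvalidModelError("vmm_coeffs is not minus the antiderivative of dvdl_coeffs")

    @classmethod
    def from_dvdl(
        cls,
        dvdl_coeffs,
        fit_domain=(-0.1, 1.1),
        mean_abs_error_dvdl=float("nan"),
        mean_abs_error_integral=float("nan"),
    ) -> "CorrectionPotential":
        """Build from dvdl coefficients alone; integrates analytically."""
        c = np.atleast_1d(np.asarray(dvdl_coeffs, dtype=float))
        if not np.all(np.isfinite(c)):
            raise InvalidModelError("non-finite dvdl coefficients")
        vmm = -npoly.polyint(c)  # constant of integration 0 -> V_MM(0)=0
        return cls(
            dvdl_coeffs=c,
            vmm_coeffs=vmm,
            fit_order=len(c) - 1,
            fit_domain=tuple(fit_domain),
            mean_abs_error_dvdl=mean_abs_error_dvdl,
            mean_abs_error_integral=mean_abs_error_integral,
        )

    # energies and forces -------------------------------------------------
    def value(self, lam):
        """V_MM(lambda) in kJ/mol."""
        return npoly.polyval(lam, self.vmm_coeffs)

    def dvdl(self, lam):
        """The fitted <dV/dlambda> polynomial."""
        return npoly.polyval(lam, self.dvdl_coeffs)

    def force(self, lam):
        """-dV_MM/dlambda = +fit(lambda)."""
        return npoly.polyval(lam, self.dvdl_coeffs)

    def to_dict(self) -> dict:
        return {
            "dvdl_coeffs": [float(c) for c in self.dvdl_coeffs],
            "vmm_coeffs": [float(c) for c in self.vmm_coeffs],
            "fit_order": int(self.fit_order),
            "fit_domain": [float(self.fit_domain[0]), float(self.fit_domain[1])],
            "mean_abs_error_dvdl": float(self.mean_abs_error_dvdl),
            "mean_abs_error_integral": float(self.mean_abs_error_integral),
            "coefficient_order": "ascending",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrectionPotential":
        return cls(
            dvdl_coeffs=np.asarray(d["dvdl_coeffs"], dtype=float),
            vmm_coeffs=np.asarray(d["vmm_coeffs"], dtype=float),
            fit_order=int(d["fit_order"]),
            fit_domain=tuple(d.get("fit_domain", (-0.1, 1.1))),
            mean_abs_error_dvdl=float(d.get("mean_abs_error_dvdl", float("nan"))),
            mean_abs_error_integral=float(d.get("mean_abs_error_integral", float("nan"))),
        )


@dataclass
class PHPotentialParams:
    """Parameters of the linear pH potential.

    V_pH(lambda) = ln(10) k_B T (pKa - pH) lambda.  Flat when pH = pKa;
    negative slope (favouring lambda = 1, deprotonation) when pH > pKa.
    """

    pH: float
    pKa: float
    temperature: float = 300.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def slope(self) -> float:
        return LN10 * KB * self.temperature * (self.pKa - self.pH)

    def value(self, lam):
        return self.slope * np.asarray(lam, dtype=float)

    def force(self, lam):
        return -self.slope * np.ones_like(np.asarray(lam, dtype=float))


@dataclass
class BiasPotentialParams:
    """Barrier-plus-walls biasing potential for the lambda coordinate.

    The barrier is a smooth compact-support bump

        V(lam) = B * exp(1 - 1/(1 - u^2)),   u = (lam - center) / 0.5,

    which equals exactly ``barrier_height`` at the center and is exactly
    zero at lam = 0 and lam = 1 (and beyond).  Quartic walls of stiffness
    ``wall_stiffness`` rise outside ``wall_bounds`` and confine lambda.
    A flat bias (barrier_height = 0) is used for sampling runs and for
    buffer sites.
    """

    barrier_height: float = 0.0
    center: float = 0.5
    wall_bounds: tuple = (-0.1, 1.1)
    wall_stiffness: float = 10000.0  # kJ/mol per lambda^4, see docs

    #: half-width of the bump support; 0.5 puts the zeros at lam = 0 and 1
    half_width: float = 0.5

    def __post_init__(self):
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be >= 0")
        lo, hi = self.wall_bounds
        if not (lo <= 0.0 and hi >= 1.0):
            raise ValueError("wall_bounds must contain [0, 1]")

    def _bump(self, u):
        out = np.zeros_like(u)
        inside = np.abs(u) < 1.0
        ui = u[inside]
        out[inside] = math.e * np.exp(-1.0 / (1.0 - ui * ui))
        return out

    def value(self, lam):
        lam = np.asarray(lam, dtype=float)
        scalar = lam.ndim == 0
        lam = np.atleast_1d(lam)
        u = (lam - self.center) / self.half_width
        v = self.barrier_height * self._bump(u)
        lo, hi = self.wall_bounds
        below = lam < lo
        above = lam > hi
        v = v + np.where(below, self.wall_stiffness * (lo - lam) ** 4, 0.0)
        v = v + np.where(above, self.wall_stiffness * (lam - hi) ** 4, 0.0)
        return float(v[0]) if scalar else v

    def force(self, lam):
        lam = np.asarray(lam, dtype=float)
        scalar = lam.ndim == 0
        lam = np.atleast_1d(lam)
        u = (lam - self.center) / self.half_width
        f = np.zeros_like(lam)
        inside = np.abs(u) < 1.0
        ui = u[inside]
        bump = math.e * np.exp(-1.0 / (1.0 - ui * ui))
        # dV/du = V * (-2u / (1-u^2)^2);  force = -dV/dlam
        f[inside] = (
            self.barrier_height
            * bump
            * (2.0 * ui / (1.0 - ui * ui) ** 2)
            / self.half_width
        )
        lo, hi = self.wall_bounds
        below = lam < lo
        above = lam > hi
        f = f + np.where(below, 4.0 * self.wall_stiffness * (lo - lam) ** 3, 0.0)
        f = f - np.where(above, 4.0 * self.wall_stiffness * (lam - hi) ** 3, 0.0)
        return float(f[0]) if scalar else f


@dataclass
class TorsionModel:
    """Cosine-series dihedral potential with optional barrier corrections.

    ``base_terms`` is a list of ``(k, n, delta)`` contributing
    ``k (1 + cos(n phi - delta))``; ``correction_terms`` is a list of
    ``(eps, n, delta_c)`` contributing ``-(eps/2)(1 + cos(n phi - delta_c))``,
    which lowers the barriers by about eps when the correction minima are
    aligned with the base maxima (n = 2 for conjugated, n = 3 for
    aliphatic bonds).
    """

    base_terms: list = field(default_factory=list)
    correction_terms: list = field(default_factory=list)

    def __post_init__(self):
        for (k, n, _) in self.base_terms:
            if k < 0:
                raise ValueError("base force constants must be >= 0")
            if int(n) != n or n < 1:
                raise ValueError("multiplicities must be positive integers")
        for (eps, n, _) in self.correction_terms:
            if eps < 0:
                raise ValueError("correction coefficients eps must be >= 0")
            if int(n) != n or n < 1:
                raise ValueError("multiplicities must be positive integers")

    def value(self, phi):
        phi = np.asarray(phi, dtype=float)
        v = np.zeros_like(phi)
        for (k, n, delta) in self.base_terms:
            v = v + k * (1.0 + np.cos(n * phi - delta))
        for (eps, n, delta) in self.correction_terms:
            v = v - 0.5 * eps * (1.0 + np.cos(n * phi - delta))
        return v

    def force(self, phi):
        """-dV/dphi in kJ/mol/rad."""
        phi = np.asarray(phi, dtype=float)
        f = np.zeros_like(phi)
        for (k, n, delta) in self.base_terms:
            f = f + k * n * np.sin(n * phi - delta)
        for (eps, n, delta) in self.correction_terms:
            f = f - 0.5 * eps * n * np.sin(n * phi - delta)
        return f

    # flattened (amplitude, multiplicity, phase) triples where the energy is
    # sum A_i cos(n_i phi - d_i) + const; used by the sampling kernels
    def _cosine_triples(self):
        amps, mults, phases = [], [], []
        for (k, n, delta) in self.base_terms:
            amps.append(float(k))
            mults.append(float(n))
            phases.append(float(delta))
        for (eps, n, delta) in self.correction_terms:
            amps.append(-0.5 * float(eps))
            mults.append(float(n))
            phases.append(float(delta))
        return (
            np.asarray(amps, dtype=float),
            np.asarray(mults, dtype=float),
            np.asarray(phases, dtype=float),
        )

    def to_dict(self) -> dict:
        """Serializable form; angles in degrees at the I/O boundary."""
        return {
            "base_terms": [
                {"k": float(k), "multiplicity": int(n), "phase_deg": math.degrees(d)}
                for (k, n, d) in self.base_terms
            ],
            "correction_terms": [
                {"epsilon": float(e), "multiplicity": int(n), "phase_deg": math.degrees(d)}
                for (e, n, d) in self.correction_terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TorsionModel":
        base = [
            (t["k"], t["multiplicity"], math.radians(t.get("phase_deg", 0.0)))
            for t in d.get("base_terms", [])
        ]
        corr = [
            (t["epsilon"], t["multiplicity"], math.radians(t.get("phase_deg", 0.0)))
            for t in d.get("correction_terms", [])
        ]
        return cls(base_terms=base, correction_terms=corr)


@dataclass
class PotentialSet:
    """The four lambda-potential terms used by the toy dynamics engine.

    ``env`` is the force-field deprotonation free-energy curve of the
    environment, given as ascending polynomial coefficients (kJ/mol) or as
    a tabulated ``(lambda, energy)`` pair which is converted internally.
    Any component may be ``None`` (contributes nothing).
    """

    env: object = None
    correction: CorrectionPotential = None
    ph: PHPotentialParams = None
    bias: BiasPotentialParams = None

    def env_coeffs(self) -> np.ndarray:
        if self.env is None:
            return np.zeros(1)
        if hasattr(self.env, "convert"):  # any numpy polynomial series kind
            return self.env.convert(kind=np.polynomial.Polynomial).coef
        env = self.env
        if (
            isinstance(env, tuple)
            and len(env) == 2
            and np.ndim(env[0]) == 1
            and len(env[0]) > 1
        ):
            x, y = np.asarray(env[0], float), np.asarray(env[1], float)
            deg = min(len(x) - 1, 12)
            return npoly.polyfit(x, y, deg)
        return np.atleast_1d(np.asarray(env, dtype=float))

    def value(self, lam):
        lam = np.asarray(lam, dtype=float)
        v = npoly.polyval(lam, self.env_coeffs())
        if self.correction is not None:
            v = v + self.correction.value(lam)
        if self.ph is not None:
            v = v + self.ph.value(lam)
        if self.bias is not None:
            v = v + self.bias.value(lam)
        return v

    def force(self, lam):
        lam = np.asarray(lam, dtype=float)
        denv = npoly.polyder(self.env_coeffs()) if len(self.env_coeffs()) > 1 else np.zeros(1)
        f = -npoly.polyval(lam, denv)
        if self.correction is not None:
            f = f + self.correction.force(lam)
        if self.ph is not None:
            f = f + self.ph.force(lam)
        if self.bias is not None:
            f = f + self.bias.force(lam)
        return f


# --------------------------------------------------------------------------
# functional wrappers (the operation surface)


def eval_vmm(cp: CorrectionPotential, lam):
    """Evaluate V_MM(lambda); warns when lambda leaves the fit domain."""
    if not (np.all(np.isfinite(cp.dvdl_coeffs)) and np.all(np.isfinite(cp.vmm_coeffs))):
        raise InvalidModelError("correction potential has non-finite coefficients")
    arr = np.asarray(lam, dtype=float)
    lo, hi = cp.fit_domain
    if np.any(arr < lo) or np.any(arr > hi):
        warnings.warn(
            f"evaluating V_MM outside its fit domain [{lo}, {hi}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return cp.value(lam)


def vph_slope(p: PHPotentialParams) -> float:
    """Slope ln(10) k_B T (pKa - pH) of the pH potential, kJ/mol per lambda."""
    return p.slope


def eval_vph(p: PHPotentialParams, lam):
    """V_pH(lambda) = ln(10) k_B T (pKa - pH) lambda."""
    return p.value(lam)


def eval_vbias(b: BiasPotentialParams, lam):
    """Biasing barrier plus confining walls."""
    return b.value(lam)


def eval_torsion(t: TorsionModel, phi):
    """Torsion energy (2*pi-periodic); phi in radians."""
    return t.value(phi)
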