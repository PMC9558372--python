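"""Protonation-state counting, deprotonation fractions and pKa fitting.

A frame of a single-site lambda-trajectory is counted as protonated when
lambda < 0.2 and deprotonated when lambda > 0.8 (strict inequalities);
intermediate frames are physically ambiguous and excluded from both
counts.  The deprotonation fraction is

    S_deprot = N_deprot / (N_prot + N_deprot).

For a three-state multisite residue (e.g. histidine: protonated,
epsilon- and delta-deprotonated) a frame belongs to a state only when
that state's lambda exceeds 0.8, and

    S_deprot = (N_eps + N_delta) / (N_p + N_eps + N_delta).

Replica-averaged fractions as a function of pH are fitted to the
Henderson-Hasselbalch equation S(pH) = 1 / (1 + 10^(pKa - pH)), the pKa
being the single fitting parameter; per-replica fits quantify the spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import least_squares

from .errors import MissingDataError, NonIdentifiableError, UndefinedFractionError
from .simulate import LambdaTrajectory

__all__ = [
    "ProtonationCounts",
    "TitrationCurve",
    "classify_frames",
    "deprot_fraction_single",
    "deprot_fraction_multisite",
    "henderson_hasselbalch",
    "fit_hh",
    "titrate",
]


class ProtonationCounts(NamedTuple):
    n_prot: int
    n_deprot: int
    n_unclassified: int


def classify_frames(traj: LambdaTrajectory) -> ProtonationCounts:
    """Count protonated / deprotonated / unclassified frames of a single site."""
    if traj.is_multisite:
        raise ValueError("classify_frames applies to single-site trajectories")
    lam = traj.lambdas
    if lam.size == 0:
        raise MissingDataError("empty trajectory")
    lo = traj.site.prot_threshold if traj.site is not None else 0.2
    hi = traj.site.deprot_threshold if traj.site is not None else 0.8
    n_prot = int(np.count_nonzero(lam < lo))
    n_deprot = int(np.count_nonzero(lam > hi))
    return ProtonationCounts(n_prot, n_deprot, lam.size - n_prot - n_deprot)


def deprot_fraction_single(counts: ProtonationCounts) -> float:
    """S_deprot = N_deprot / (N_prot + N_deprot)."""
    tot = counts.n_prot + counts.n_deprot
    if tot == 0:
        raise UndefinedFractionError(
            "no classifiable frames (all lambda between the thresholds)"
        )
    return counts.n_deprot / tot


def deprot_fraction_multisite(traj: LambdaTrajectory, threshold: float = 0.8) -> float:
    """Macroscopic deprotonation fraction of a 3-state (His-like) residue.

    State order convention: column 0 is the protonated state, the
    remaining columns are the deprotonated tautomers.  A frame is assigned
    to a state only when that state's lambda exceeds ``threshold``.
    """
    if not traj.is_multisite:
        raise ValueError("deprot_fraction_multisite needs a multisite trajectory")
    lam = traj.lambdas
    if lam.size == 0:
        raise MissingDataError("empty trajectory")
    assigned = lam > threshold
    n_p = int(np.count_nonzero(assigned[:, 0]))
    n_deprot = int(np.count_nonzero(assigned[:, 1:]))
    tot = n_p + n_deprot
    if tot == 0:
        raise UndefinedFractionError("no frames with any state lambda above threshold")
    return n_deprot / tot


def henderson_hasselbalch(pH, pKa):
    """S(pH) = 1 / (1 + 10^(pKa - pH))."""
    return 1.0 / (1.0 + np.power(10.0, pKa - np.asarray(pH, dtype=float)))


def fit_hh(pH_values, fractions) -> tuple:
    """One-parameter nonlinear least-squares fit of the titration curve.

    Returns ``(pKa, residual_std)`` where residual_std is the RMS
    difference between calculated and fitted fractions.  Raises
    :class:`NonIdentifiableError` when every fraction is 0 or every
    fraction is 1 (the pKa lies outside the scanned pH range).
    """
    pH = np.asarray(pH_values, dtype=float)
    s = np.asarray(fractions, dtype=float)
    if pH.size != s.size or pH.size < 1:
        raise ValueError("need equally many pH values and fractions (>= 1)")
    if np.all(s <= 0.0) or np.all(s >= 1.0):
        raise NonIdentifiableError(
            "all fractions saturated: pKa outside the scanned pH range"
        )
    # S = 0.5 at pH = pKa gives a robust starting point
    p0 = float(pH[np.argmin(np.abs(s - 0.5))])
    res = least_squares(
        lambda p: henderson_hasselbalch(pH, p[0]) - s, x0=[p0], method="lm"
    )
    pka = float(res.x[0])
    residual_std = float(np.sqrt(np.mean((henderson_hasselbalch(pH, pka) - s) ** 2)))
    return pka, residual_std


@dataclass
class TitrationCurve:
    """Per-pH, per-replica deprotonation fractions with the fitted pKa."""

    pH_values: np.ndarray
    fractions: np.ndarray  # (n_pH, n_replicas), NaN where undefined
    mean_fractions: np.ndarray
    pKa_fit: float
    residual_std: float
    replica_pKas: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def replica_spread(self) -> float:
        """Standard deviation of the per-replica pKa estimates."""
        ok = self.replica_pKas[np.isfinite(self.replica_pKas)]
        return float(ok.std(ddof=0)) if ok.size else float("nan")

    def to_dict(self) -> dict:
        return {
            "pH_values": self.pH_values.tolist(),
            "mean_fractions": self.mean_fractions.tolist(),
            "pKa": self.pKa_fit,
            "residual_std": self.residual_std,
            "replica_pKas": self.replica_pKas.tolist(),
            "replica_spread": self.replica_spread,
        }


def _fraction_of(traj: LambdaTrajectory) -> float:
    if traj.is_multisite:
        return deprot_fraction_multisite(traj)
    return deprot_fraction_single(classify_frames(traj))


def titrate(replica_trajs: dict) -> TitrationCurve:
    """Build a titration curve from ``{pH: [trajectory, ...]}``.

    Per-replica fractions are averaged at each pH; the
    Henderson-Hasselbalch fit runs on the means, and per-replica fits
    provide the pKa spread.  A pH at which no replica has classifiable
    frames is dropped with a warning.  residual_std is the RMS between
    calculated and fitted fractions over all pH values and replicas.
    """
    if len(replica_trajs) < 2:
        raise ValueError("need at least two pH values")
    pHs = sorted(replica_trajs)
    n_rep = max(len(replica_trajs[p]) for p in pHs)
    frac = np.full((len(pHs), n_rep), np.nan)
    for i, p in enumerate(pHs):
        trajs = replica_trajs[p]
        if not trajs:
            raise ValueError(f"no replicas at pH {p}")
        for j, traj in enumerate(trajs):
            try:
                frac[i, j] = _fraction_of(traj)
            except UndefinedFractionError:
                pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pH rows
        means = np.nanmean(frac, axis=1)
    keep = np.isfinite(means)
    if not np.all(keep):
        dropped = [pHs[i] for i in np.nonzero(~keep)[0]]
        warnings.warn(
            f"dropping pH values with no classifiable frames: {dropped}", stacklevel=2
        )
    pH_arr = np.asarray(pHs, dtype=float)[keep]
    if pH_arr.size < 2:
        raise MissingDataError("fewer than two pH values with classifiable frames")
    pka, _ = fit_hh(pH_arr, means[keep])
    fitted = henderson_hasselbalch(pH_arr, pka)
    resid = frac[keep] - fitted[:, None]
    residual_std = float(np.sqrt(np.nanmean(resid**2)))
    rep_pkas = np.full(n_rep, np.nan)
    for j in range(n_rep):
        col = frac[keep][:, j]
        ok = np.isfinite(col)
        if np.count_nonzero(ok) >= 2:
            try:
                rep_pkas[j], _ = fit_hh(pH_arr[ok], col[ok])
            except NonIdentifiableError:
                pass
    return TitrationCurve(
        pH_values=pH_arr,
        fractions=frac[keep],
        mean_fractions=means[keep],
        pKa_fit=pka,
        residual_std=residual_std,
        replica_pKas=rep_pkas,
    )
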