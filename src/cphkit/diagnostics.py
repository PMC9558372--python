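"""Distribution-comparison and convergence statistics.

Replica convergence is judged with the two-sample Kolmogorov-Smirnov
statistic (KSS), the supremum distance between empirical CDFs, used as a
descriptive similarity measure: replica distributions are considered
consistent when every pairwise KSS is strictly below a threshold
(0.03 by default).  No p-values are computed.

One-sample variants check lambda-distributions for uniformity on [0, 1]
(the hallmark of a well-parametrized site simulated at pH = pKa without a
bias barrier) or against the Boltzmann distribution of an arbitrary
bounded 1-D potential (the validation harness for the toy samplers).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .constants import kt
from .errors import InvalidModelError, MissingDataError

__all__ = [
    "kss",
    "kss_binned",
    "kss_circular",
    "replica_consistency",
    "uniformity",
    "boltzmann_check",
    "ConsistencyReport",
    "UniformityResult",
]


def kss(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic, exact on the pooled points."""
    a = np.sort(np.asarray(sample_a, dtype=float).ravel())
    b = np.sort(np.asarray(sample_b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise MissingDataError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ca = np.searchsorted(a, pooled, side="right")
    cb = np.searchsorted(b, pooled, side="right")
    # integer cross-multiplication keeps the statistic exact (e.g. 1/3)
    num = np.max(np.abs(ca * b.size - cb * a.size))
    return float(num / (a.size * b.size))


def kss_binned(sample_a, sample_b, bin_width: float, lo: float = None, hi: float = None) -> float:
    """KSS computed on binned (histogram) CDFs; for histogram-file workflows."""
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise MissingDataError("both samples must be non-empty")
    if lo is None:
        lo = min(a.min(), b.min())
    if hi is None:
        hi = max(a.max(), b.max())
    edges = np.arange(lo, hi + bin_width, bin_width)
    ca = np.cumsum(np.histogram(a, bins=edges)[0]) / a.size
    cb = np.cumsum(np.histogram(b, bins=edges)[0]) / b.size
    return float(np.max(np.abs(ca - cb)))


def kss_circular(sample_a, sample_b, period: float = 2.0 * np.pi) -> float:
    """KSS for circular data (dihedral angles).

    The angular origin is rotated to the midpoint of the largest gap in the
    pooled sample before comparing ECDFs, so that the statistic does not cut
    through a populated region.  Note the result retains a (documented)
    dependence on this origin choice.
    """
    a = np.mod(np.asarray(sample_a, dtype=float).ravel(), period)
    b = np.mod(np.asarray(sample_b, dtype=float).ravel(), period)
    if a.size == 0 or b.size == 0:
        raise MissingDataError("both samples must be non-empty")
    pooled = np.sort(np.concatenate([a, b]))
    gaps = np.diff(np.concatenate([pooled, [pooled[0] + period]]))
    i = int(np.argmax(gaps))
    origin = pooled[i] + 0.5 * gaps[i]
    return kss(np.mod(a - origin, period), np.mod(b - origin, period))


@dataclass
class ConsistencyReport:
    """Pairwise replica-consistency matrix with a strict threshold."""

    labels: list
    kss_matrix: np.ndarray
    threshold: float = 0.03
    max_kss: float = 0.0
    passed: bool = True

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "kss_matrix": [[float(v) for v in row] for row in self.kss_matrix],
            "threshold": float(self.threshold),
            "max_kss": float(self.max_kss),
            "pass": bool(self.passed),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def matrix_text(self) -> str:
        lines = ["\t" + "\t".join(str(l) for l in self.labels)]
        for lab, row in zip(self.labels, self.kss_matrix):
            lines.append(str(lab) + "\t" + "\t".join(f"{v:.4f}" for v in row))
        lines.append(f"max KSS = {self.max_kss:.4f} (threshold {self.threshold}) "
                     f"-> {'PASS' if self.passed else 'FAIL'}")
        return "\n".join(lines)


def replica_consistency(
    replicas,
    threshold: float = 0.03,
    labels=None,
    circular: bool = False,
    period: float = 2.0 * np.pi,
) -> ConsistencyReport:
    """Full pairwise KSS matrix; passes iff every entry is strictly < threshold."""
    replicas = [np.asarray(r, dtype=float).ravel() for r in replicas]
    if len(replicas) < 2:
        raise ValueError("need at least two replicas")
    n = len(replicas)
    if labels is None:
        labels = list(range(n))
    stat = kss_circular if circular else kss
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = stat(replicas[i], replicas[j], period) if circular else stat(replicas[i], replicas[j])
            mat[i, j] = mat[j, i] = v
    mx = float(mat.max()) if n > 1 else 0.0
    return ConsistencyReport(
        labels=list(labels),
        kss_matrix=mat,
        threshold=threshold,
        max_kss=mx,
        passed=mx < threshold,
    )


@dataclass
class UniformityResult:
    kss: float
    n_inside: int
    fraction_outside: float
    passed: bool
    threshold: float


def uniformity(samples, interval=(0.0, 1.0), threshold: float = 0.02) -> UniformityResult:
    """One-sample KSS of the data inside ``interval`` against the uniform CDF.

    Samples outside the interval (e.g. lambda excursions into the grid
    margins) are excluded; their fraction is reported.
    """
    s = np.asarray(samples, dtype=float).ravel()
    if s.size == 0:
        raise MissingDataError("empty sample")
    lo, hi = interval
    inside = s[(s >= lo) & (s <= hi)]
    if inside.size == 0:
        raise MissingDataError("no samples inside the interval")
    frac_out = 1.0 - inside.size / s.size
    u = np.sort((inside - lo) / (hi - lo))
    n = u.size
    i = np.arange(1, n + 1)
    d = float(np.max(np.maximum(i / n - u, u - (i - 1) / n)))
    return UniformityResult(
        kss=d,
        n_inside=int(n),
        fraction_outside=float(frac_out),
        passed=d < threshold,
        threshold=threshold,
    )


def boltzmann_check(samples, potential, temperature: float = 300.0, grid=None) -> float:
    """One-sample KSS of samples against the Boltzmann CDF of a 1-D potential.

    ``potential`` is a callable V(x) in kJ/mol (or an object with a
    ``value`` method); the analytic CDF is obtained by trapezoid quadrature
    of exp(-V/kT) on a dense grid covering the sample range.
    """
    s = np.sort(np.asarray(samples, dtype=float).ravel())
    if s.size == 0:
        raise MissingDataError("empty sample")
    vfun = potential.value if hasattr(potential, "value") else potential
    if grid is None:
        pad = 0.05 * (s[-1] - s[0] + 1e-12)
        grid = np.linspace(s[0] - pad, s[-1] + pad, 4001)
    v = np.asarray(vfun(grid), dtype=float)
    if not np.all(np.isfinite(v)):
        raise InvalidModelError("potential is not finite on the sample range")
    w = np.exp(-(v - v.min()) / kt(temperature))
    cdf = cumulative_trapezoid(w, grid, initial=0.0)
    cdf /= cdf[-1]
    fs = np.interp(s, grid, cdf)
    n = s.size
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - fs, fs - (i - 1) / n)))
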