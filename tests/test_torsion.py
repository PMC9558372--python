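"""Torsion profiles, barrier corrections, epsilon optimization and WHAM."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from cphkit.constants import kt
from cphkit.errors import AlignmentUndefinedError, DisconnectedHistogramError, SeedCollisionError
from cphkit.model import TorsionModel
from cphkit.simulate import SimConfig, sample_dihedral
from cphkit.torsion import (
    PeriodicProfile,
    ReplicaProtocol,
    UmbrellaWindow,
    _new_minima,
    find_extrema,
    make_correction,
    optimize_epsilon,
    profile_from_model,
    rms_deviation,
    run_umbrella_protocol,
    wham,
)

KT300 = kt(300.0)


class TestProfile:
    def test_range_is_twice_k(self):
        p = profile_from_model(TorsionModel(base_terms=[(5.0, 3, 0.0)]), 360)
        assert p.energies.max() == pytest.approx(10.0, abs=1e-3)
        assert p.energies.min() == 0.0

    def test_empty_model_all_zero(self):
        p = profile_from_model(TorsionModel(), 36)
        assert np.all(p.energies == 0.0)

    def test_matched_correction_reduces_max_by_eps(self):
        t = make_correction(TorsionModel(base_terms=[(8.0, 3, 0.0)]), 4.0, 3)
        p = profile_from_model(t, 360)
        assert p.energies.max() == pytest.approx(12.0, abs=1e-2)


class TestFindExtrema:
    def test_multiplicity_three(self):
        p = profile_from_model(TorsionModel(base_terms=[(5.0, 3, 0.0)]), 360)
        ext = find_extrema(p)
        assert ext.n_minima == 3 and ext.n_maxima == 3

    def test_shallow_shoulder_merged(self):
        angles = np.arange(360) * 2 * np.pi / 360
        # one deep well plus a 0.05 kJ/mol ripple (below the 0.1 merge tol)
        e = 5.0 * (1 + np.cos(angles)) + 0.05 * np.cos(9 * angles)
        ext = find_extrema(PeriodicProfile(angles, e - e.min()))
        assert ext.n_minima == 1 and ext.n_maxima == 1

    def test_flat_profile_flag(self):
        angles = np.arange(36) * 2 * np.pi / 36
        ext = find_extrema(PeriodicProfile(angles, np.zeros(36)))
        assert ext.flat and ext.n_minima == 0


class TestMakeCorrection:
    def test_zero_epsilon_preserves_energy(self):
        t = TorsionModel(base_terms=[(8.0, 3, 0.7)])
        t2 = make_correction(t, 0.0, 3)
        rng = np.random.default_rng(0)
        phi = rng.uniform(0, 2 * np.pi, 1000)
        assert np.allclose(t.value(phi), t2.value(phi))

    def test_barrier_lowered_exactly(self):
        t2 = make_correction(TorsionModel(base_terms=[(8.0, 3, 0.0)]), 4.0, 3)
        p = profile_from_model(t2, 720)
        ext = find_extrema(p)
        assert p.energies.max() == pytest.approx(12.0, abs=5e-3)
        assert ext.n_minima == 3  # count unchanged

    def test_overshoot_creates_new_minima(self):
        base = TorsionModel(base_terms=[(8.0, 3, 0.0)])
        base_ext = find_extrema(profile_from_model(base, 720))
        over = make_correction(base, 2 * 8.0 * 1.5, 3)  # eps = 3k, inverted wells
        over_ext = find_extrema(profile_from_model(over, 720))
        assert _new_minima(base_ext, over_ext, angle_tol=0.26)

    def test_flat_base_alignment_undefined(self):
        with pytest.raises(AlignmentUndefinedError):
            make_correction(TorsionModel(), 1.0, 3)


class TestRmsDeviation:
    def test_identical_and_offset_profiles(self):
        p = profile_from_model(TorsionModel(base_terms=[(5.0, 2, 0.0)]), 360)
        assert rms_deviation(p, p) == 0.0
        shifted = PeriodicProfile(p.angles, p.energies + 7.0)
        assert rms_deviation(p, shifted) == pytest.approx(0.0, abs=1e-12)

    def test_quadrature_oracle(self):
        # a = 0 vs b = -(eps/2)(1+cos phi): min-aligned RMS = eps*sqrt(3/8)
        eps = 3.0
        angles = np.arange(7200) * 2 * np.pi / 7200
        a = PeriodicProfile(angles, np.zeros_like(angles))
        b_e = -(eps / 2) * (1 + np.cos(angles))
        b = PeriodicProfile(angles, b_e)
        assert rms_deviation(a, b) == pytest.approx(eps * math.sqrt(3.0 / 8.0), rel=1e-3)

    def test_grid_mismatch_rejected(self):
        p1 = profile_from_model(TorsionModel(base_terms=[(1.0, 1, 0.0)]), 360)
        p2 = profile_from_model(TorsionModel(base_terms=[(1.0, 1, 0.0)]), 180)
        with pytest.raises(ValueError):
            rms_deviation(p1, p2)


class TestOptimizeEpsilon:
    def test_small_barrier_returns_zero(self):
        t = TorsionModel(base_terms=[(1.0, 3, 0.0)])  # 2 kJ/mol barrier, hops freely
        proto = ReplicaProtocol(
            n_replicas=3, base_cfg=SimConfig(n_steps=500_000, seed=23, stride=50),
            diffusion=3.0,
        )
        res = optimize_epsilon(t, proto, kss_tol=0.05, eps_step=1.0, eps_max=5.0)
        assert res.success and res.epsilon == 0.0
        assert res.audit[0]["pass"]

    def test_identical_seeds_refused(self):
        with pytest.raises(SeedCollisionError):
            ReplicaProtocol(
                n_replicas=2,
                base_cfg=SimConfig(n_steps=1000, seed=1),
                seeds=[5, 5],
            )

    def test_kss_decreases_with_epsilon_on_average(self):
        t = TorsionModel(base_terms=[(20.0, 3, 0.0)])
        means = []
        for eps in (0.0, 16.0, 32.0):
            model = t if eps == 0 else make_correction(t, eps, 3)
            vals = []
            for seed_pair in ((31, 32), (33, 34)):
                samples = [
                    sample_dihedral(
                        model,
                        SimConfig(n_steps=150_000, seed=s, stride=10),
                        diffusion=3.0,
                        phi0=phi0,
                    )
                    for s, phi0 in zip(seed_pair, (np.pi / 3, np.pi))
                ]
                from cphkit.diagnostics import kss_circular

                vals.append(kss_circular(samples[0], samples[1]))
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]


class TestUmbrella:
    def test_default_centers_every_ten_degrees(self):
        t = TorsionModel(base_terms=[(1.0, 1, 0.0)])
        cfg = SimConfig(n_steps=2000, seed=24, dt=0.001, stride=10)
        wins = run_umbrella_protocol(t, cfg=cfg)
        assert len(wins) == 36
        assert np.allclose(
            np.degrees([w.center for w in wins]), np.arange(0, 360, 10)
        )
        assert wins[0].force_constant == 418.4

    def test_four_windows_at_right_angles(self):
        wins = run_umbrella_protocol(
            TorsionModel(base_terms=[(1.0, 1, 0.0)]),
            n_windows=4,
            cfg=SimConfig(n_steps=2000, seed=25, dt=0.001, stride=10),
        )
        assert np.allclose(np.degrees([w.center for w in wins]), [0, 90, 180, 270])

    def test_window_means_near_centers_for_flat_base(self):
        wins = run_umbrella_protocol(
            TorsionModel(),
            n_windows=8,
            cfg=SimConfig(n_steps=20_000, seed=26, dt=0.001, stride=5),
        )
        for w in wins:
            circ_mean = np.angle(np.mean(np.exp(1j * w.samples)))
            d = np.degrees(abs(np.angle(np.exp(1j * (circ_mean - w.center)))))
            assert d < 3.0


def _wham_likelihood_oracle(windows, n_bins, temperature):
    """Independent WHAM route: direct minimization of the log-likelihood."""
    kT = kt(temperature)
    edges = np.linspace(0, 2 * np.pi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.array(
        [np.histogram(np.mod(w.samples, 2 * np.pi), bins=edges)[0] for w in windows]
    )
    counts = hist.sum(axis=0)
    n_k = hist.sum(axis=1)
    bias = np.array(
        [
            0.5 * w.force_constant
            * (np.angle(np.exp(1j * (centers - w.center)))) ** 2
            for w in windows
        ]
    )
    logc = -bias / kT

    def nll(f):
        log_denom = np.logaddexp.reduce(np.log(n_k)[:, None] + f[:, None] + logc, axis=0)
        return np.sum(counts * log_denom) - np.sum(n_k * f)

    res = minimize(nll, np.zeros(len(windows)), method="BFGS")
    f = res.x
    denom = (n_k[:, None] * np.exp(f[:, None] + logc)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, counts / denom, 0.0)
        g = np.where(p > 0, -kT * np.log(np.where(p > 0, p, 1.0)), np.nan)
    return centers, g - np.nanmin(g)


class TestWham:
    def test_single_unbiased_window_is_histogram_inversion(self):
        t = TorsionModel(base_terms=[(2.0, 2, 0.0)])
        s = sample_dihedral(
            t, SimConfig(n_steps=200_000, seed=27, stride=2), diffusion=3.0
        )
        res = wham([UmbrellaWindow(center=0.0, force_constant=0.0, samples=s)], n_bins=36)
        h = np.histogram(s, bins=np.linspace(0, 2 * np.pi, 37))[0]
        direct = -KT300 * np.log(h / h.sum())
        direct -= direct.min()
        assert np.allclose(res.profile.energies, direct, atol=1e-6)

    def test_disjoint_windows_raise(self):
        w1 = UmbrellaWindow(center=0.0, samples=np.full(100, 0.1))
        w2 = UmbrellaWindow(center=np.pi, samples=np.full(100, np.pi))
        with pytest.raises(DisconnectedHistogramError):
            wham([w1, w2], n_bins=36)

    def test_recovers_double_well_profile(self):
        t = TorsionModel(base_terms=[(6.0, 2, 0.0), (2.0, 1, 0.5)])
        cfg = SimConfig(n_steps=30_000, seed=28, dt=0.001, stride=10)
        wins = run_umbrella_protocol(t, cfg=cfg)
        res = wham(wins)
        assert res.converged
        truth = t.value(res.profile.angles)
        truth -= truth.min()
        ok = res.bin_counts >= 100
        assert np.nanmax(np.abs(res.profile.energies[ok] - truth[ok])) < 1.0

    def test_matches_independent_likelihood_minimization(self):
        t = TorsionModel(base_terms=[(4.0, 2, 0.3)])
        cfg = SimConfig(n_steps=15_000, seed=29, dt=0.001, stride=10)
        wins = run_umbrella_protocol(t, n_windows=12, force_constant=60.0, cfg=cfg)
        res = wham(wins, n_bins=36)
        centers, oracle = _wham_likelihood_oracle(wins, 36, 300.0)
        assert np.allclose(centers, res.profile.angles)
        ok = np.isfinite(oracle) & np.isfinite(res.profile.energies)
        assert np.nanmax(np.abs(res.profile.energies[ok] - oracle[ok])) < 0.2
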