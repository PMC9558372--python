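"""Time-stepping kernels for the toy samplers.

Tight scalar loops, jitted with numba when available.  All randomness goes
through the legacy numpy RandomState API seeded inside the kernel, which
numba reproduces bit-for-bit, so trajectories are deterministic functions
of (inputs, seed).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


@njit(cache=False)
def _polyval(coeffs, x):
    # ascending coefficients, Horner from the top
    acc = 0.0
    for i in range(len(coeffs) - 1, -1, -1):
        acc = acc * x + coeffs[i]
    return acc


@njit(cache=False)
def _bias_force(x, height, center, half_width, wall_lo, wall_hi, wall_k):
    f = 0.0
    u = (x - center) / half_width
    if abs(u) < 1.0:
        bump = math.e * math.exp(-1.0 / (1.0 - u * u))
        f += height * bump * (2.0 * u / (1.0 - u * u) ** 2) / half_width
    if x < wall_lo:
        f += 4.0 * wall_k * (wall_lo - x) ** 3
    elif x > wall_hi:
        f -= 4.0 * wall_k * (x - wall_hi) ** 3
    return f


@njit(cache=False)
def lambda_leapfrog(
    x0,
    v0,
    mass,
    dt,
    n_steps,
    kT,
    tau_t,
    seed,
    dpot,  # ascending coeffs of d(V_env + V_MM)/dlambda
    ph_slope,
    bias_height,
    bias_center,
    bias_half_width,
    wall_lo,
    wall_hi,
    wall_k,
    stride,
    use_langevin,
    gamma,
):
    """Leapfrog lambda-dynamics with a v-rescale (or Langevin) thermostat.

    Returns (frames, n_recorded, blowup_step, mean_kinetic_energy).
    blowup_step is -1 on success.
    """
    np.random.seed(seed)
    n_frames = n_steps // stride
    out = np.empty(n_frames)
    x = x0
    v = v0
    c_resc = math.exp(-dt / tau_t)
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(kT / mass * (1.0 - c1 * c1))
    ke_sum = 0.0
    count = 0
    for step in range(n_steps):
        f = -_polyval(dpot, x) - ph_slope + _bias_force(
            x, bias_height, bias_center, bias_half_width, wall_lo, wall_hi, wall_k
        )
        if use_langevin:
            # BAOAB splitting
            v += 0.5 * dt * f / mass
            x += 0.5 * dt * v
            v = c1 * v + c2 * np.random.standard_normal()
            x += 0.5 * dt * v
            f = -_polyval(dpot, x) - ph_slope + _bias_force(
                x, bias_height, bias_center, bias_half_width, wall_lo, wall_hi, wall_k
            )
            v += 0.5 * dt * f / mass
        else:
            v += dt * f / mass
            x += dt * v
            # stochastic velocity rescaling (single degree of freedom)
            kin = 0.5 * mass * v * v
            kbar = 0.5 * kT
            r = np.random.standard_normal()
            if kin > 0.0:
                knew = (
                    math.sqrt(c_resc * kin) + math.sqrt((1.0 - c_resc) * kbar) * r
                ) ** 2
                v *= math.sqrt(knew / kin)
            else:
                v = math.sqrt(2.0 * kbar / mass) * r
        ke_sum += 0.5 * mass * v * v
        if abs(x) > 10.0:
            return out, count, step, ke_sum / (step + 1)
        if (step + 1) % stride == 0:
            out[count] = x
            count += 1
    return out, count, -1, ke_sum / n_steps


@njit(cache=False)
def multisite_leapfrog(
    x0,
    v0,
    mass,
    dt,
    n_steps,
    kT,
    tau_t,
    seed,
    dpots,  # (n_states, L) ascending coeffs per state, zero-padded
    ph_slopes,  # (n_states,)
    bias_height,
    bias_center,
    bias_half_width,
    wall_lo,
    wall_hi,
    wall_k,
    stride,
):
    """Constrained multisite lambda-dynamics (sum over states fixed to 1).

    Forces and velocities are projected off the (1,...,1) direction every
    step and the coordinate sum is renormalized exactly, so the constraint
    holds to machine precision.  Thermostat: v-rescale on n_states - 1
    degrees of freedom.
    """
    np.random.seed(seed)
    ns = x0.shape[0]
    n_frames = n_steps // stride
    out = np.empty((n_frames, ns))
    x = x0.copy()
    v = v0.copy()
    # project initial conditions
    s = 0.0
    for i in range(ns):
        s += x[i]
    for i in range(ns):
        x[i] -= (s - 1.0) / ns
    mv = 0.0
    for i in range(ns):
        mv += v[i]
    for i in range(ns):
        v[i] -= mv / ns
    c_resc = math.exp(-dt / tau_t)
    nf = ns - 1
    f = np.empty(ns)
    count = 0
    blow = -1
    ke_sum = 0.0
    for step in range(n_steps):
        for i in range(ns):
            f[i] = -_polyval(dpots[i], x[i]) - ph_slopes[i] + _bias_force(
                x[i], bias_height, bias_center, bias_half_width, wall_lo, wall_hi, wall_k
            )
        fs = 0.0
        for i in range(ns):
            fs += f[i]
        for i in range(ns):
            f[i] -= fs / ns
        for i in range(ns):
            v[i] += dt * f[i] / mass
        mv = 0.0
        for i in range(ns):
            mv += v[i]
        for i in range(ns):
            v[i] -= mv / ns
        for i in range(ns):
            x[i] += dt * v[i]
        s = 0.0
        for i in range(ns):
            s += x[i]
        for i in range(ns):
            x[i] -= (s - 1.0) / ns
        kin = 0.0
        for i in range(ns):
            kin += 0.5 * mass * v[i] * v[i]
        kbar = 0.5 * nf * kT
        r1 = np.random.standard_normal()
        rsum = r1 * r1
        for i in range(nf - 1):
            ri = np.random.standard_normal()
            rsum += ri * ri
        if kin > 0.0:
            knew = (
                kin * c_resc
                + (kbar / nf) * (1.0 - c_resc) * rsum
                + 2.0 * r1 * math.sqrt(c_resc * (1.0 - c_resc) * kin * kbar / nf)
            )
            if knew < 0.0:
                knew = 0.0
            alpha = math.sqrt(knew / kin)
            for i in range(ns):
                v[i] *= alpha
        ke_sum += kin
        for i in range(ns):
            if abs(x[i]) > 10.0:
                blow = step
                return out, count, blow, ke_sum / (step + 1)
        if (step + 1) % stride == 0:
            for i in range(ns):
                out[count, i] = x[i]
            count += 1
    return out, count, blow, ke_sum / n_steps


@njit(cache=False)
def dihedral_langevin(
    phi0,
    dt,
    n_steps,
    diffusion,
    kT,
    seed,
    amps,
    mults,
    phases,
    use_restraint,
    phi_r,
    k_r,
    stride,
    inertial,
    mass,
    gamma,
):
    """Langevin sampling of a periodic cosine-series torsion profile.

    Overdamped Euler-Maruyama by default (mobility D/kT); optionally an
    inertial BAOAB integrator.  The harmonic restraint uses the
    minimum-image angular difference.  Recorded angles are wrapped to
    [0, 2*pi).  Returns (frames, n_recorded, blowup_step).
    """
    np.random.seed(seed)
    two_pi = 2.0 * math.pi
    n_frames = n_steps // stride
    out = np.empty(n_frames)
    phi = phi0
    v = 0.0
    amp_noise = math.sqrt(2.0 * diffusion * dt)
    mob = diffusion / kT
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(kT / mass * (1.0 - c1 * c1))
    xi_prev = np.random.standard_normal()
    count = 0
    for step in range(n_steps):
        f = 0.0
        for i in range(len(amps)):
            f += amps[i] * mults[i] * math.sin(mults[i] * phi - phases[i])
        if use_restraint:
            d = phi - phi_r
            d -= two_pi * math.floor(d / two_pi + 0.5)  # wrap to (-pi, pi]
            f -= k_r * d
        if inertial:
            v += 0.5 * dt * f / mass
            phi += 0.5 * dt * v
            v = c1 * v + c2 * np.random.standard_normal()
            phi += 0.5 * dt * v
            f2 = 0.0
            for i in range(len(amps)):
                f2 += amps[i] * mults[i] * math.sin(mults[i] * phi - phases[i])
            if use_restraint:
                d = phi - phi_r
                d -= two_pi * math.floor(d / two_pi + 0.5)
                f2 -= k_r * d
            v += 0.5 * dt * f2 / mass
        else:
            # Leimkuhler-Matthews scheme: averaging successive noises gives
            # second-order configurational sampling at overdamped cost
            xi = np.random.standard_normal()
            phi += mob * f * dt + 0.5 * amp_noise * (xi_prev + xi)
            xi_prev = xi
        if abs(phi) > 1.0e6:
            return out, count, step
        if (step + 1) % stride == 0:
            out[count] = phi % two_pi
            count += 1
    return out, count, -1
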