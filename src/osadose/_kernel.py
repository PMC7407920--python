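"""Numba-jitted photon-packet transport kernel.

Transport rules: free paths are sampled from the local interaction
coefficient; every voxel traversal deposits weight x path-length into the
score grid (track-length fluence estimator, unbiased even in non-absorbing
voxels); at an interaction the packet weight is attenuated by the local
albedo (continuous absorption) and the direction is redrawn from the
Henyey-Greenstein phase function; axis-aligned voxel faces between media of
unequal refractive index apply unpolarized Fresnel reflection / Snell
refraction; grid edges are vacuum escape surfaces; low-weight packets play
Russian roulette.

Randomness comes from one splitmix64 counter stream per packet index, so a
run is a pure function of (scene, sources, n_packets, seed) regardless of
scheduling.

All kernel lengths are mm and interaction coefficients mm^-1.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

U64 = np.uint64
_GOLDEN = U64(0x9E3779B97F4A7C15)
_M1 = U64(0xBF58476D1CE4E5B9)
_M2 = U64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53

# packet termination codes
ESCAPED = 0
ROULETTED = 1
FORCED = 2


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> U64(30))) * _M1
    z = (z ^ (z >> U64(27))) * _M2
    return z ^ (z >> U64(31))


@njit(cache=True, inline="always")
def _rand(state):
    """Advance the counter state; return (state, uniform in (0, 1])."""
    state = state + _GOLDEN
    z = _mix64(state)
    u = (np.float64(z >> U64(11)) + 1.0) * _INV53
    return state, u


@njit(cache=True, inline="always")
def _packet_state(seed, packet_id):
    return _mix64(U64(seed) ^ (_GOLDEN * (U64(packet_id) + U64(1))))


@njit(cache=True, inline="always")
def _hg_cos(g, u):
    if g < 1e-6:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, inline="always")
def _scatter(ux, uy, uz, g, u1, u2):
    cost = _hg_cos(g, u1)
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    phi = 2.0 * math.pi * u2
    cosp = math.cos(phi)
    sinp = math.sin(phi)
    if abs(uz) > 0.99999:
        sgn = 1.0 if uz >= 0.0 else -1.0
        nx = sint * cosp
        ny = sgn * sint * sinp
        nz = sgn * cost
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
        ny = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
        nz = -sint * cosp * den + uz * cost
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _fresnel_r(n1, n2, cos_i):
    if n1 == n2:
        return 0.0
    sin_t2 = (n1 / n2) * (n1 / n2) * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def trace_packet(
    labels,
    mu_t,
    albedo,
    g_arr,
    n_arr,
    h,
    px,
    py,
    pz,
    dx,
    dy,
    dz,
    w,
    state,
    roulette_threshold,
    roulette_survival,
    max_interactions,
    score,
):
    """Transport one packet to termination, depositing track length in ``score``.

    Returns (absorbed, escaped, roulette_loss, roulette_gain, forced,
    n_interactions, status, exit_x, exit_y, exit_z, state).
    """
    nx_, ny_, nz_ = labels.shape
    ix = int(px // h)
    iy = int(py // h)
    iz = int(pz // h)
    absorbed = 0.0
    escaped = 0.0
    r_loss = 0.0
    r_gain = 0.0
    forced = 0.0
    n_int = 0
    status = ESCAPED

    state, u = _rand(state)
    tau = -math.log(u)

    while True:
        m = labels[ix, iy, iz]
        mt = mu_t[m]

        if dx > 0.0:
            tbx = ((ix + 1) * h - px) / dx
        elif dx < 0.0:
            tbx = (ix * h - px) / dx
        else:
            tbx = 1e30
        if dy > 0.0:
            tby = ((iy + 1) * h - py) / dy
        elif dy < 0.0:
            tby = (iy * h - py) / dy
        else:
            tby = 1e30
        if dz > 0.0:
            tbz = ((iz + 1) * h - pz) / dz
        elif dz < 0.0:
            tbz = (iz * h - pz) / dz
        else:
            tbz = 1e30

        axis = 0
        tb = tbx
        if tby < tb:
            tb = tby
            axis = 1
        if tbz < tb:
            tb = tbz
            axis = 2
        if tb < 0.0:
            tb = 0.0

        ti = tau / mt if mt > 0.0 else 1e30

        if ti < tb:
            # interaction inside this voxel
            score[ix, iy, iz] += w * ti
            px += dx * ti
            py += dy * ti
            pz += dz * ti
            a = albedo[m]
            absorbed += w * (1.0 - a)
            w *= a
            n_int += 1
            if n_int >= max_interactions:
                forced = w
                status = FORCED
                break
            state, u1 = _rand(state)
            state, u2 = _rand(state)
            dx, dy, dz = _scatter(dx, dy, dz, g_arr[m], u1, u2)
            state, u = _rand(state)
            tau = -math.log(u)
            if w < roulette_threshold:
                state, u = _rand(state)
                if u * roulette_survival <= 1.0:
                    r_gain += w * (roulette_survival - 1.0)
                    w *= roulette_survival
                else:
                    r_loss += w
                    status = ROULETTED
                    break
        else:
            # fly to the voxel face
            score[ix, iy, iz] += w * tb
            if mt > 0.0:
                tau -= mt * tb
                if tau < 0.0:
                    tau = 0.0
            px += dx * tb
            py += dy * tb
            pz += dz * tb
            jx = ix
            jy = iy
            jz = iz
            if axis == 0:
                if dx > 0.0:
                    jx += 1
                    px = jx * h
                else:
                    px = ix * h
                    jx -= 1
            elif axis == 1:
                if dy > 0.0:
                    jy += 1
                    py = jy * h
                else:
                    py = iy * h
                    jy -= 1
            else:
                if dz > 0.0:
                    jz += 1
                    pz = jz * h
                else:
                    pz = iz * h
                    jz -= 1

            if jx < 0 or jx >= nx_ or jy < 0 or jy >= ny_ or jz < 0 or jz >= nz_:
                escaped = w
                status = ESCAPED
                break

            m2 = labels[jx, jy, jz]
            if n_arr[m2] != n_arr[m]:
                n1 = n_arr[m]
                n2 = n_arr[m2]
                if axis == 0:
                    cos_i = abs(dx)
                elif axis == 1:
                    cos_i = abs(dy)
                else:
                    cos_i = abs(dz)
                state, u = _rand(state)
                if u <= _fresnel_r(n1, n2, cos_i):
                    if axis == 0:
                        dx = -dx
                    elif axis == 1:
                        dy = -dy
                    else:
                        dz = -dz
                    # stay in the current voxel
                else:
                    eta = n1 / n2
                    sin_t2 = eta * eta * (1.0 - cos_i * cos_i)
                    cos_t = math.sqrt(max(0.0, 1.0 - sin_t2))
                    if axis == 0:
                        dy *= eta
                        dz *= eta
                        dx = cos_t if dx > 0.0 else -cos_t
                    elif axis == 1:
                        dx *= eta
                        dz *= eta
                        dy = cos_t if dy > 0.0 else -cos_t
                    else:
                        dx *= eta
                        dy *= eta
                        dz = cos_t if dz > 0.0 else -cos_t
                    ix, iy, iz = jx, jy, jz
            else:
                ix, iy, iz = jx, jy, jz

    return absorbed, escaped, r_loss, r_gain, forced, n_int, status, px, py, pz, state


@njit(cache=True)
def run_kernel(
    labels,
    mu_t,
    albedo,
    g_arr,
    n_arr,
    h,
    sources,  # (ns, 6): x0 y0 z0 x1 y1 z1, mm
    n_per_source,  # (ns,) int64
    seed,
    roulette_threshold,
    roulette_survival,
    max_interactions,
    score,
):
    """Launch all packets; returns the energy ledger.

    Ledger components: [launched, absorbed, escaped, roulette_loss,
    roulette_gain, forced, n_forced_packets].
    """
    ledger = np.zeros(7)
    pid = 0
    for s in range(sources.shape[0]):
        ax, ay, az = sources[s, 0], sources[s, 1], sources[s, 2]
        bx, by, bz = sources[s, 3], sources[s, 4], sources[s, 5]
        for _ in range(n_per_source[s]):
            state = _packet_state(seed, pid)
            state, u = _rand(state)
            px = ax + (bx - ax) * u
            py = ay + (by - ay) * u
            pz = az + (bz - az) * u
            state, u1 = _rand(state)
            state, u2 = _rand(state)
            cost = 2.0 * u1 - 1.0
            sint = math.sqrt(max(0.0, 1.0 - cost * cost))
            phi = 2.0 * math.pi * u2
            dx = sint * math.cos(phi)
            dy = sint * math.sin(phi)
            dz = cost

            res = trace_packet(
                labels,
                mu_t,
                albedo,
                g_arr,
                n_arr,
                h,
                px,
                py,
                pz,
                dx,
                dy,
                dz,
                1.0,
                state,
                roulette_threshold,
                roulette_survival,
                max_interactions,
                score,
            )
            ledger[0] += 1.0
            ledger[1] += res[0]
            ledger[2] += res[1]
            ledger[3] += res[2]
            ledger[4] += res[3]
            ledger[5] += res[4]
            if res[6] == FORCED:
                ledger[6] += 1.0
            pid += 1
    return ledger
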