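"""Numba kernel for voxel Monte Carlo photon transport.

Implicit-capture random walk on a labeled cubic-voxel grid: optical depth to
the next interaction is sampled once and consumed across voxels (valid by
the memoryless property), weight ``w * mua/mut`` is deposited at each
interaction, scattering follows Henyey-Greenstein, photons crossing the top
surface are tallied as escaped (with a per-source-assay tag), and photons
crossing lateral/bottom boundaries are terminated as lost.  No Fresnel
events: refractive index is matched everywhere.  Russian roulette below a
weight threshold keeps the walk unbiased; the net weight created/destroyed
by roulette is tallied so the energy ledger closes exactly.

Random numbers come from one splitmix64 stream per photon index, hashed from
the run seed, so results are independent of photon ordering.
"""

import math

import numpy as np
from numba import njit

__all__ = ["transport"]

_G1 = np.uint64(0x9E3779B97F4A7C15)
_G2 = np.uint64(0xD2B74407B1CE6E93)
_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)
_S30 = np.uint64(30)
_S27 = np.uint64(27)
_S31 = np.uint64(31)
_S11 = np.uint64(11)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(inline="always")
def _mix64(z):
    z = (z ^ (z >> _S30)) * _M1
    z = (z ^ (z >> _S27)) * _M2
    return z ^ (z >> _S31)


@njit(inline="always")
def _rand(state):
    """Return (uniform float64 in [0,1), new state)."""
    state = state + _G1
    return float(_mix64(state) >> _S11) * _INV53, state


@njit(cache=True, fastmath=True)
def transport(
    labels,          # (nx, ny, nz) uint8 medium codes
    h,               # voxel edge, mm
    mua, mus, g,     # per-code coefficients, mm^-1 (g dimensionless)
    n_photons,
    seed,            # uint64
    mode,            # 0 = top LED (top-hat + Lambertian), 1 = isotropic volume source
    src_half,        # LED half side, mm (mode 0)
    collimated,      # mode 0 only: 1 = normal incidence instead of Lambertian
    src_cdf,         # (ns,) float64 normalized CDF over source voxels (mode 1)
    src_ix, src_iy, src_iz,  # (ns,) int32 source voxel indices (mode 1)
    absorbed,        # (nx, ny, nz) float64 tally
    surface_escape,  # (nx, ny) float64 top-surface escape tally
    layer_iz,        # int; track-length fluence tally layer (-1 disables)
    layer_fluence,   # (nx, ny) float64
    escape_by_tag,   # (8,) float64 per-source-label top escape
    totals,          # (4,) [escaped_top, escaped_other, roulette_net, absorbed]
    wmin, psurv,     # roulette threshold / survival probability
):
    nx, ny, nz = labels.shape
    lx2 = nx * h / 2.0
    ly2 = ny * h / 2.0
    two_pi = 2.0 * math.pi
    sseed = np.uint64(seed)

    for ip in range(n_photons):
        state = _mix64(sseed ^ (np.uint64(ip) * _G2))

        # --- launch ---------------------------------------------------
        if mode == 0:
            u, state = _rand(state)
            x = (u - 0.5) * 2.0 * src_half
            u, state = _rand(state)
            y = (u - 0.5) * 2.0 * src_half
            z = 0.0
            if collimated == 1:
                ux = 0.0
                uy = 0.0
                uz = 1.0
            else:
                u, state = _rand(state)
                cost = math.sqrt(u)        # Lambertian: p(cos) ~ cos
                u, state = _rand(state)
                phi = two_pi * u
                sint = math.sqrt(1.0 - cost * cost)
                ux = sint * math.cos(phi)
                uy = sint * math.sin(phi)
                uz = cost                   # downward (+z)
            ix = int((x + lx2) / h)
            iy = int((y + ly2) / h)
            iz = 0
            if ix < 0:
                ix = 0
            elif ix >= nx:
                ix = nx - 1
            if iy < 0:
                iy = 0
            elif iy >= ny:
                iy = ny - 1
            tag = 0
        else:
            u, state = _rand(state)
            k = np.searchsorted(src_cdf, u, side="right")
            if k >= src_cdf.shape[0]:
                k = src_cdf.shape[0] - 1
            ix = int(src_ix[k])
            iy = int(src_iy[k])
            iz = int(src_iz[k])
            u, state = _rand(state)
            x = (ix + u) * h - lx2
            u, state = _rand(state)
            y = (iy + u) * h - ly2
            u, state = _rand(state)
            z = (iz + u) * h
            u, state = _rand(state)
            uz = 2.0 * u - 1.0              # isotropic
            u, state = _rand(state)
            phi = two_pi * u
            sint = math.sqrt(max(0.0, 1.0 - uz * uz))
            ux = sint * math.cos(phi)
            uy = sint * math.sin(phi)
            tag = int(labels[ix, iy, iz])

        w = 1.0
        u, state = _rand(state)
        tau = -math.log(1.0 - u)

        # --- random walk ---------------------------------------------
        while True:
            lbl = labels[ix, iy, iz]
            ma = mua[lbl]
            mt = ma + mus[lbl]

            # distances to the three voxel boundary planes
            if ux > 1e-12:
                dbx = ((ix + 1) * h - lx2 - x) / ux
            elif ux < -1e-12:
                dbx = (ix * h - lx2 - x) / ux
            else:
                dbx = 1e30
            if uy > 1e-12:
                dby = ((iy + 1) * h - ly2 - y) / uy
            elif uy < -1e-12:
                dby = (iy * h - ly2 - y) / uy
            else:
                dby = 1e30
            if uz > 1e-12:
                dbz = ((iz + 1) * h - z) / uz
            elif uz < -1e-12:
                dbz = (iz * h - z) / uz
            else:
                dbz = 1e30
            db = dbx
            axis = 0
            if dby < db:
                db = dby
                axis = 1
            if dbz < db:
                db = dbz
                axis = 2
            if db < 0.0:
                db = 0.0

            d_int = tau / mt if mt > 0.0 else 1e30

            if d_int < db:
                # interaction inside the current voxel
                if iz == layer_iz:
                    layer_fluence[ix, iy] += w * d_int
                x += ux * d_int
                y += uy * d_int
                z += uz * d_int
                depo = w * ma / mt
                absorbed[ix, iy, iz] += depo
                totals[3] += depo
                w -= depo
                # Henyey-Greenstein deflection
                u, state = _rand(state)
                gg = g[lbl]
                if gg > 1e-6 or gg < -1e-6:
                    tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * u)
                    cost = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                    if cost > 1.0:
                        cost = 1.0
                    elif cost < -1.0:
                        cost = -1.0
                else:
                    cost = 2.0 * u - 1.0
                u, state = _rand(state)
                phi = two_pi * u
                sint = math.sqrt(max(0.0, 1.0 - cost * cost))
                cosp = math.cos(phi)
                sinp = math.sin(phi)
                if uz > 0.99999 or uz < -0.99999:
                    ux = sint * cosp
                    uy = sint * sinp
                    uz = cost if uz > 0.0 else -cost
                else:
                    den = math.sqrt(1.0 - uz * uz)
                    nux = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                    nuy = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                    nuz = -sint * cosp * den + uz * cost
                    ux = nux
                    uy = nuy
                    uz = nuz
                u, state = _rand(state)
                tau = -math.log(1.0 - u)
                # Russian roulette
                if w < wmin:
                    if w <= 0.0:
                        break
                    u, state = _rand(state)
                    if u < psurv:
                        totals[2] -= w * (1.0 / psurv - 1.0)
                        w /= psurv
                    else:
                        totals[2] += w
                        break
            else:
                # hop to the voxel boundary
                if iz == layer_iz:
                    layer_fluence[ix, iy] += w * db
                x += ux * db
                y += uy * db
                z += uz * db
                tau -= mt * db
                if tau < 0.0:
                    tau = 0.0
                if axis == 0:
                    if ux > 0.0:
                        ix += 1
                        x = ix * h - lx2
                        if ix >= nx:
                            totals[1] += w
                            break
                    else:
                        x = ix * h - lx2
                        ix -= 1
                        if ix < 0:
                            totals[1] += w
                            break
                elif axis == 1:
                    if uy > 0.0:
                        iy += 1
                        y = iy * h - ly2
                        if iy >= ny:
                            totals[1] += w
                            break
                    else:
                        y = iy * h - ly2
                        iy -= 1
                        if iy < 0:
                            totals[1] += w
                            break
                else:
                    if uz > 0.0:
                        iz += 1
                        z = iz * h
                        if iz >= nz:
                            totals[1] += w
                            break
                    else:
                        z = iz * h
                        iz -= 1
                        if iz < 0:
                            totals[0] += w
                            surface_escape[ix, iy] += w
                            escape_by_tag[tag] += w
                            break
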