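"""Numba kernels for voxelized photon transport.

Hop-drop-spin with photon weight: dimensionless steps consumed across voxels
by a 3-D digital differential analyzer, Henyey-Greenstein scattering,
unpolarized Fresnel reflection/refraction at index-mismatched voxel crossings
(normals from the smoothed-index gradient), Russian roulette below a weight
threshold, and escape recording at the outer surface.

The RNG is a per-photon xorshift64* stream seeded by a splitmix64 hash of
(master seed, batch id, photon index), giving reproducible, batch-independent
substreams without shared state.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

U64 = np.uint64
_INV53 = 1.0 / 9007199254740992.0  # 2^-53

# escape-surface codes
SURF_TRANSMISSION = 0
SURF_REFLECTANCE = 1
SURF_LATERAL = 2


@njit(cache=True, inline="always")
def _seed_state(seed, batch, idx):
    h = (
        U64(seed) * U64(0x9E3779B97F4A7C15)
        + U64(batch) * U64(0xBF58476D1CE4E5B9)
        + U64(idx) * U64(0x94D049BB133111EB)
    )
    h ^= h >> U64(30)
    h *= U64(0xBF58476D1CE4E5B9)
    h ^= h >> U64(27)
    h *= U64(0x94D049BB133111EB)
    h ^= h >> U64(31)
    if h == U64(0):
        h = U64(0x9E3779B97F4A7C15)
    return h


@njit(cache=True, inline="always")
def _unif(s):
    """xorshift64*; returns (state, uniform in (0, 1])."""
    s ^= s >> U64(12)
    s ^= s << U64(25)
    s ^= s >> U64(27)
    x = s * U64(0x2545F4914F6CDD1D)
    return s, ((x >> U64(11)) + U64(1)) * _INV53


@njit(cache=True, inline="always")
def hg_cos(g, xi):
    """Henyey-Greenstein deflection cosine from a uniform deviate."""
    if abs(g) < 1e-6:
        return 2.0 * xi - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    ct = (1.0 + g * g - t * t) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True, inline="always")
def fresnel_unpolarized(ci, n1, n2):
    """Unpolarized Fresnel reflectance and transmitted cosine.

    ci is the (positive) cosine of the incidence angle.  Returns (R, ct);
    R = 1 and ct = 0 beyond the critical angle (total internal reflection).
    """
    if n1 == n2:
        return 0.0, ci
    st2 = (n1 / n2) * (n1 / n2) * (1.0 - ci * ci)
    if st2 >= 1.0:
        return 1.0, 0.0
    ct = math.sqrt(1.0 - st2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp), ct


@njit(cache=True, inline="always")
def spin_direction(ux, uy, uz, ct, phi):
    """Rotate a unit vector by polar cosine ct and azimuth phi."""
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz >= 0.0 else -ct
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def hg_cos_sample(g, n, seed):
    """Sample n Henyey-Greenstein deflection cosines (for moment tests)."""
    out = np.empty(n)
    rs = _seed_state(seed, 0, 0)
    for i in range(n):
        rs, xi = _unif(rs)
        out[i] = hg_cos(g, xi)
    return out


@njit(cache=True, inline="always")
def _classify(pz, uz, zc):
    if uz > 0.0 and pz > zc:
        return SURF_REFLECTANCE
    if uz < 0.0 and pz < zc:
        return SURF_TRANSMISSION
    return SURF_LATERAL


@njit(cache=True)
def trace_batch(
    labels, mua, mus, ga, nmed, nsm, h,
    src_kind, sx, sy, sz, sdx, sdy, sdz, sradius,
    n_photons, seed, batch_id,
    w_thresh, p_surv, zc,
    absorbed,
    esc_x, esc_y, esc_z, esc_ux, esc_uy, esc_uz, esc_w, esc_s,
):
    """Trace one batch of photons; accumulate absorption, record escapes.

    Returns (n_escaped, escaped_weight, roulette_net, n_aborted); the exact
    weight ledger is launched = absorbed + escaped + roulette_net.
    """
    nx, ny, nz = labels.shape
    # orthonormal basis perpendicular to the source direction (disk sampling)
    if abs(sdz) < 0.9:
        ax_, ay_, az_ = 0.0, 0.0, 1.0
    else:
        ax_, ay_, az_ = 1.0, 0.0, 0.0
    e1x = sdy * az_ - sdz * ay_
    e1y = sdz * ax_ - sdx * az_
    e1z = sdx * ay_ - sdy * ax_
    e1n = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x /= e1n; e1y /= e1n; e1z /= e1n
    e2x = sdy * e1z - sdz * e1y
    e2y = sdz * e1x - sdx * e1z
    e2z = sdx * e1y - sdy * e1x

    n_esc = 0
    esc_weight = 0.0
    roulette_net = 0.0
    aborted = 0

    for ip in range(n_photons):
        rs = _seed_state(seed, batch_id, ip)
        # --- launch ---
        if src_kind == 0:  # collimated uniform disk
            rs, u1 = _unif(rs)
            rs, u2 = _unif(rs)
            rr = sradius * math.sqrt(u1)
            phi = 2.0 * math.pi * u2
            ca = math.cos(phi); sa = math.sin(phi)
            px = sx + rr * (ca * e1x + sa * e2x)
            py = sy + rr * (ca * e1y + sa * e2y)
            pz = sz + rr * (ca * e1z + sa * e2z)
            ux, uy, uz = sdx, sdy, sdz
        else:  # isotropic point
            rs, u1 = _unif(rs)
            rs, u2 = _unif(rs)
            ct0 = 2.0 * u1 - 1.0
            st0 = math.sqrt(max(0.0, 1.0 - ct0 * ct0))
            phi = 2.0 * math.pi * u2
            ux = st0 * math.cos(phi)
            uy = st0 * math.sin(phi)
            uz = ct0
            px, py, pz = sx, sy, sz

        i = int(px / h)
        j = int(py / h)
        k = int(pz / h)
        if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
            aborted += 1
            roulette_net += 1.0
            continue

        w = 1.0
        rs, xi = _unif(rs)
        s = -math.log(xi)
        nstep = 0
        while True:
            nstep += 1
            if nstep > 4_000_000 or not (
                math.isfinite(px) and math.isfinite(py) and math.isfinite(pz)
            ):
                aborted += 1
                roulette_net += w
                break
            lbl = labels[i, j, k]
            mut = mua[lbl] + mus[lbl]

            # distance to the nearest voxel face along the direction of travel
            if ux > 1e-12:
                tx = ((i + 1) * h - px) / ux
                dxs = 1
            elif ux < -1e-12:
                tx = (i * h - px) / ux
                dxs = -1
            else:
                tx = 1e30
                dxs = 0
            if uy > 1e-12:
                ty = ((j + 1) * h - py) / uy
                dys = 1
            elif uy < -1e-12:
                ty = (j * h - py) / uy
                dys = -1
            else:
                ty = 1e30
                dys = 0
            if uz > 1e-12:
                tz = ((k + 1) * h - pz) / uz
                dzs = 1
            elif uz < -1e-12:
                tz = (k * h - pz) / uz
                dzs = -1
            else:
                tz = 1e30
                dzs = 0
            tmin = tx
            axis = 0
            if ty < tmin:
                tmin = ty
                axis = 1
            if tz < tmin:
                tmin = tz
                axis = 2
            if tmin < 0.0:
                tmin = 0.0

            if mut * tmin <= s:
                # ---- hop to the voxel boundary ----
                px += ux * tmin
                py += uy * tmin
                pz += uz * tmin
                s -= mut * tmin
                ni, nj, nk = i, j, k
                if axis == 0:
                    ni += dxs
                elif axis == 1:
                    nj += dys
                else:
                    nk += dzs
                if ni < 0 or ni >= nx or nj < 0 or nj >= ny or nk < 0 or nk >= nz:
                    # photon leaves the computational grid
                    sc = _classify(pz, uz, zc)
                    esc_x[n_esc] = px; esc_y[n_esc] = py; esc_z[n_esc] = pz
                    esc_ux[n_esc] = ux; esc_uy[n_esc] = uy; esc_uz[n_esc] = uz
                    esc_w[n_esc] = w; esc_s[n_esc] = sc
                    n_esc += 1
                    esc_weight += w
                    break
                nlbl = labels[ni, nj, nk]
                n1 = nmed[lbl]
                n2 = nmed[nlbl]
                if n1 != n2:
                    # interface normal = normalized gradient of the smoothed
                    # index field at the exited voxel, oriented along travel
                    il = i - 1 if i > 0 else 0
                    ih = i + 1 if i < nx - 1 else nx - 1
                    jl = j - 1 if j > 0 else 0
                    jh = j + 1 if j < ny - 1 else ny - 1
                    kl = k - 1 if k > 0 else 0
                    kh = k + 1 if k < nz - 1 else nz - 1
                    gx = (nsm[ih, j, k] - nsm[il, j, k]) / max(ih - il, 1)
                    gy = (nsm[i, jh, k] - nsm[i, jl, k]) / max(jh - jl, 1)
                    gz = (nsm[i, j, kh] - nsm[i, j, kl]) / max(kh - kl, 1)
                    gn = math.sqrt(gx * gx + gy * gy + gz * gz)
                    if gn < 1e-6:
                        gx = gy = gz = 0.0
                        if axis == 0:
                            gx = 1.0 * dxs
                        elif axis == 1:
                            gy = 1.0 * dys
                        else:
                            gz = 1.0 * dzs
                    else:
                        gx /= gn; gy /= gn; gz /= gn
                    ci = ux * gx + uy * gy + uz * gz
                    if ci < 0.0:
                        gx = -gx; gy = -gy; gz = -gz
                        ci = -ci
                    if ci > 1.0:
                        ci = 1.0
                    R, ct = fresnel_unpolarized(ci, n1, n2)
                    rs, xi = _unif(rs)
                    if xi < R:
                        # specular reflection; stay in the current voxel
                        ux -= 2.0 * ci * gx
                        uy -= 2.0 * ci * gy
                        uz -= 2.0 * ci * gz
                        un = math.sqrt(ux * ux + uy * uy + uz * uz)
                        ux /= un; uy /= un; uz /= un
                        # a strongly oblique gradient normal can leave the
                        # mirrored direction still pointing through the
                        # crossed face; flip that component so the photon
                        # leaves the interface (prevents zero-length cycles)
                        if axis == 0:
                            if ux * dxs > 0.0:
                                ux = -ux
                        elif axis == 1:
                            if uy * dys > 0.0:
                                uy = -uy
                        else:
                            if uz * dzs > 0.0:
                                uz = -uz
                    else:
                        eta = n1 / n2
                        ux = eta * ux + (ct - eta * ci) * gx
                        uy = eta * uy + (ct - eta * ci) * gy
                        uz = eta * uz + (ct - eta * ci) * gz
                        un = math.sqrt(ux * ux + uy * uy + uz * uz)
                        ux /= un; uy /= un; uz /= un
                        # mirror-image guard of the reflection case: the
                        # refracted ray must progress into the entered voxel
                        if axis == 0:
                            if ux * dxs < 0.0:
                                ux = -ux
                        elif axis == 1:
                            if uy * dys < 0.0:
                                uy = -uy
                        else:
                            if uz * dzs < 0.0:
                                uz = -uz
                        if nlbl == 0 and lbl != 0:
                            # refracted through the outer surface: escape
                            sc = _classify(pz, uz, zc)
                            esc_x[n_esc] = px; esc_y[n_esc] = py; esc_z[n_esc] = pz
                            esc_ux[n_esc] = ux; esc_uy[n_esc] = uy; esc_uz[n_esc] = uz
                            esc_w[n_esc] = w; esc_s[n_esc] = sc
                            n_esc += 1
                            esc_weight += w
                            break
                        i, j, k = ni, nj, nk
                else:
                    if nlbl == 0 and lbl != 0:
                        # matched-index exit through the outer surface
                        sc = _classify(pz, uz, zc)
                        esc_x[n_esc] = px; esc_y[n_esc] = py; esc_z[n_esc] = pz
                        esc_ux[n_esc] = ux; esc_uy[n_esc] = uy; esc_uz[n_esc] = uz
                        esc_w[n_esc] = w; esc_s[n_esc] = sc
                        n_esc += 1
                        esc_weight += w
                        break
                    i, j, k = ni, nj, nk
            else:
                # ---- interaction inside the voxel ----
                d = s / mut
                px += ux * d
                py += uy * d
                pz += uz * d
                dw = w * mua[lbl] / mut
                absorbed[i, j, k] += dw
                w -= dw
                if mus[lbl] <= 0.0 or w <= 0.0:
                    absorbed[i, j, k] += w  # pure absorber: terminal deposit
                    break
                rs, x1 = _unif(rs)
                ct1 = hg_cos(ga[lbl], x1)
                rs, x2 = _unif(rs)
                ux, uy, uz = spin_direction(ux, uy, uz, ct1, 2.0 * math.pi * x2)
                rs, x3 = _unif(rs)
                s = -math.log(x3)
                if w < w_thresh:
                    rs, x4 = _unif(rs)
                    if x4 < p_surv:
                        roulette_net += w - w / p_surv
                        w = w / p_surv
                    else:
                        roulette_net += w
                        break
    return n_esc, esc_weight, roulette_net, aborted
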