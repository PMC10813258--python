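"""Low-level Monte Carlo photon-packet transport kernels (numba-compiled).

The kernel implements MCML-style weighted photon-packet transport on a
voxelized grid: exponentially sampled optical-depth hops traversed voxel by
voxel (3D DDA), discrete-albedo weight deposition at each interaction,
Henyey-Greenstein scattering, Russian roulette below a weight threshold, and
escape through any grid face with NA-gated fiber detection on the top face.

Randomness is counter-based: every photon owns a splitmix64 stream derived
deterministically from (seed, photon index), so results are independent of
batching and bit-reproducible for a fixed seed.
"""

import math

import numpy as np
from numba import njit

_U = np.uint64


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> _U(30))) * _U(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U(27))) * _U(0x94D049BB133111EB)
    return z ^ (z >> _U(31))


@njit(cache=True, inline="always")
def _stream_init(seed, i):
    # decorrelate photon streams: mix of run seed and photon counter
    return _mix64((_U(seed) + _U(0x9E3779B97F4A7C15)) * _U(0xD1B54A32D192ED03) + _U(i) * _U(0x9E3779B97F4A7C15))


@njit(cache=True, inline="always")
def _next_uniform(state):
    """Advance a splitmix64 state; return (state, deviate) with deviate in (0, 1)."""
    state = state + _U(0x9E3779B97F4A7C15)
    z = _mix64(state)
    # 53-bit mantissa, shifted into the open interval
    return state, (np.float64(z >> _U(11)) + 1.0) * (1.0 / 9007199254740994.0)


@njit(cache=True, inline="always")
def hg_cosine(xi, g):
    """Inverse-CDF sample of the Henyey-Greenstein scattering cosine."""
    if abs(g) < 1e-12:
        return 2.0 * xi - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    c = (1.0 + g * g - t * t) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, inline="always")
def _scatter_direction(ux, uy, uz, ct, phi):
    """Rotate direction (ux,uy,uz) by polar angle acos(ct), azimuth phi."""
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nxd = st * cp
        nyd = st * sp
        nzd = ct if uz > 0.0 else -ct
    else:
        den = math.sqrt(1.0 - uz * uz)
        nxd = st * (ux * uz * cp - uy * sp) / den + ux * ct
        nyd = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nzd = -st * cp * den + uz * ct
    norm = math.sqrt(nxd * nxd + nyd * nyd + nzd * nzd)
    return nxd / norm, nyd / norm, nzd / norm


@njit(cache=True)
def run_transport(
    labels,          # (nx, ny, nz) uint8 voxel material labels
    mua,             # per-label absorption, 1/mm
    mut,             # per-label total attenuation, 1/mm
    g_tab,           # per-label anisotropy
    vs,              # voxel size, mm
    safe,            # (nx, ny, nz) float32: jump radius with guaranteed uniform material
    em_pos, em_ax, em_e1, em_e2, em_r, cos_em_max,
    col_pos, col_ax, col_r, cos_col_max,
    n_rel,           # medium refractive index relative to the outside (1 = matched)
    n_photons, seed,
    wmin, p_roulette, max_events,
    store_mode,      # 0: none, 1: detected only, 2: all photons
    fluence,         # (nx, ny, nz) float64 accumulator of deposited weight
    scratch,         # (max_events + 2, 4) per-photon path scratch
    path_buf,        # (capacity, 4) flat storage of kept paths (x, y, z, w)
    path_off,        # (cap_records + 1,) offsets into path_buf
    rec_info,        # (cap_records, 8): exit pos(3), exit dir(3), weight, detected flag
):
    nx, ny, nz = labels.shape
    max_pts = scratch.shape[0]
    cap_pts = path_buf.shape[0]
    cap_rec = rec_info.shape[0]

    n_det = 0
    n_stored = 0
    pts_used = 0
    pts_needed = 0
    overflow = 0
    dep = 0.0
    esc = 0.0
    detw = 0.0
    lost_roulette = 0.0
    lost_cap = 0.0
    n_capped = 0

    col_r2 = col_r * col_r

    for i in range(n_photons):
        st = _stream_init(seed, i)

        # --- launch: top-hat disc, top-hat divergence cone about the fiber axis
        st, u1 = _next_uniform(st)
        st, u2 = _next_uniform(st)
        rr = em_r * math.sqrt(u1)
        ca = math.cos(2.0 * math.pi * u2)
        sa = math.sin(2.0 * math.pi * u2)
        px = em_pos[0] + rr * (ca * em_e1[0] + sa * em_e2[0])
        py = em_pos[1] + rr * (ca * em_e1[1] + sa * em_e2[1])
        pz = em_pos[2] + rr * (ca * em_e1[2] + sa * em_e2[2])
        # slide the launch point along the fiber axis onto the entry face z=0
        if abs(em_ax[2]) > 1e-12:
            tslide = -pz / em_ax[2]
            px += tslide * em_ax[0]
            py += tslide * em_ax[1]
            pz = 0.0

        st, u3 = _next_uniform(st)
        st, u4 = _next_uniform(st)
        ct0 = 1.0 - u3 * (1.0 - cos_em_max)   # uniform in solid angle
        st0 = math.sqrt(max(0.0, 1.0 - ct0 * ct0))
        cb = math.cos(2.0 * math.pi * u4)
        sb = math.sin(2.0 * math.pi * u4)
        dx = ct0 * em_ax[0] + st0 * (cb * em_e1[0] + sb * em_e2[0])
        dy = ct0 * em_ax[1] + st0 * (cb * em_e1[1] + sb * em_e2[1])
        dz = ct0 * em_ax[2] + st0 * (cb * em_e1[2] + sb * em_e2[2])

        w = 1.0
        n_events = 0
        npts = 0
        scratch[npts, 0] = px
        scratch[npts, 1] = py
        scratch[npts, 2] = pz
        scratch[npts, 3] = w
        npts += 1

        if dz <= 0.0:
            # degenerate: photon not entering the medium; counts as escaped
            esc += w
            continue
        pz = 1e-9  # nudge just inside the grid

        alive = True
        escaped = False
        while alive:
            st, xi = _next_uniform(st)
            s = -math.log(xi)  # dimensionless optical depth to consume
            # --- hop through voxels until the optical depth is spent
            while True:
                ix = int(math.floor(px / vs))
                iy = int(math.floor(py / vs))
                iz = int(math.floor(pz / vs))
                if iz < 0 and n_rel > 1.0 and dz < 0.0:
                    # refractive-index mismatch at the entry face: total
                    # internal reflection / Fresnel reflection (unpolarized)
                    cos_i = -dz
                    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
                    reflect = False
                    if sin_i * n_rel >= 1.0:
                        reflect = True   # beyond the critical angle
                    else:
                        sin_t = sin_i * n_rel
                        cos_t = math.sqrt(1.0 - sin_t * sin_t)
                        rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
                        rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
                        R = 0.5 * (rs * rs + rp * rp)
                        st, ur2 = _next_uniform(st)
                        if ur2 < R:
                            reflect = True
                    if reflect:
                        tb = pz / dz          # overshoot past the face
                        px -= dx * tb
                        py -= dy * tb
                        pz = 1e-9
                        dz = -dz
                        continue
                    # transmit: snap to the face, refract the exit direction
                    tb = pz / dz
                    px -= dx * tb
                    py -= dy * tb
                    pz = -1e-12
                    if sin_i > 1e-12:
                        scale = sin_t / sin_i
                        dx *= scale
                        dy *= scale
                    dz = -cos_t
                    nrm = math.sqrt(dx * dx + dy * dy + dz * dz)
                    dx /= nrm
                    dy /= nrm
                    dz /= nrm
                    escaped = True
                    alive = False
                    break
                if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                    escaped = True
                    alive = False
                    break
                lbl = labels[ix, iy, iz]
                m = mut[lbl]
                # fast path: if the remaining free path fits inside the
                # guaranteed-uniform sphere around this voxel, jump directly
                # to the interaction point without walking voxel boundaries
                if m > 0.0:
                    L = s / m
                    if L < safe[ix, iy, iz]:
                        px += dx * L
                        py += dy * L
                        pz += dz * L
                        ix = int(math.floor(px / vs))
                        iy = int(math.floor(py / vs))
                        iz = int(math.floor(pz / vs))
                        a = mua[lbl] / m
                        dw = w * a
                        fluence[ix, iy, iz] += dw
                        dep += dw
                        w -= dw
                        n_events += 1
                        if npts < max_pts:
                            scratch[npts, 0] = px
                            scratch[npts, 1] = py
                            scratch[npts, 2] = pz
                            scratch[npts, 3] = w
                            npts += 1
                        if n_events >= max_events:
                            n_capped += 1
                            lost_cap += w
                            alive = False
                            break
                        if w < wmin:
                            st, ur = _next_uniform(st)
                            if ur < p_roulette:
                                w /= p_roulette
                                scratch[npts - 1, 3] = w
                            else:
                                lost_roulette += w
                                alive = False
                                break
                        st, xh = _next_uniform(st)
                        ct = hg_cosine(xh, g_tab[lbl])
                        st, up = _next_uniform(st)
                        dx, dy, dz = _scatter_direction(dx, dy, dz, ct, 2.0 * math.pi * up)
                        break
                # distance to the nearest voxel boundary along the direction
                db = 1e30
                if dx > 1e-12:
                    t = ((ix + 1) * vs - px) / dx
                    if t < db:
                        db = t
                elif dx < -1e-12:
                    t = (ix * vs - px) / dx
                    if t < db:
                        db = t
                if dy > 1e-12:
                    t = ((iy + 1) * vs - py) / dy
                    if t < db:
                        db = t
                elif dy < -1e-12:
                    t = (iy * vs - py) / dy
                    if t < db:
                        db = t
                if dz > 1e-12:
                    t = ((iz + 1) * vs - pz) / dz
                    if t < db:
                        db = t
                elif dz < -1e-12:
                    t = (iz * vs - pz) / dz
                    if t < db:
                        db = t
                if db < 0.0:
                    db = 0.0

                if m > 0.0 and m * db >= s:
                    # interaction inside this voxel
                    step = s / m
                    px += dx * step
                    py += dy * step
                    pz += dz * step
                    a = mua[lbl] / m
                    dw = w * a
                    fluence[ix, iy, iz] += dw
                    dep += dw
                    w -= dw
                    n_events += 1
                    if npts < max_pts:
                        scratch[npts, 0] = px
                        scratch[npts, 1] = py
                        scratch[npts, 2] = pz
                        scratch[npts, 3] = w
                        npts += 1
                    if n_events >= max_events:
                        n_capped += 1
                        lost_cap += w
                        alive = False
                        break
                    if w < wmin:
                        st, ur = _next_uniform(st)
                        if ur < p_roulette:
                            w /= p_roulette
                            scratch[npts - 1, 3] = w
                        else:
                            lost_roulette += w
                            alive = False
                            break
                    st, xh = _next_uniform(st)
                    ct = hg_cosine(xh, g_tab[lbl])
                    st, up = _next_uniform(st)
                    dx, dy, dz = _scatter_direction(dx, dy, dz, ct, 2.0 * math.pi * up)
                    break
                else:
                    # traverse to the next voxel (or through a void voxel)
                    adv = db + 1e-9
                    px += dx * adv
                    py += dy * adv
                    pz += dz * adv
                    if m > 0.0:
                        s -= m * db

        if not escaped:
            # died by roulette or event cap; path not a detection candidate
            if store_mode == 2:
                pts_needed += npts
                if n_stored < cap_rec and pts_used + npts <= cap_pts:
                    for k in range(npts):
                        path_buf[pts_used + k, 0] = scratch[k, 0]
                        path_buf[pts_used + k, 1] = scratch[k, 1]
                        path_buf[pts_used + k, 2] = scratch[k, 2]
                        path_buf[pts_used + k, 3] = scratch[k, 3]
                    pts_used += npts
                    rec_info[n_stored, 0] = px
                    rec_info[n_stored, 1] = py
                    rec_info[n_stored, 2] = pz
                    rec_info[n_stored, 3] = dx
                    rec_info[n_stored, 4] = dy
                    rec_info[n_stored, 5] = dz
                    rec_info[n_stored, 6] = w
                    rec_info[n_stored, 7] = 0.0
                    n_stored += 1
                    path_off[n_stored] = pts_used
                else:
                    overflow = 1
            continue

        # --- escape: snap the exit point onto the crossed face
        ex, ey, ez = px, py, pz
        top_exit = False
        if pz < 0.0 and dz < 0.0:
            tback = pz / dz  # > 0: distance overshot past the z=0 plane
            ex = px - dx * tback
            ey = py - dy * tback
            ez = 0.0
            top_exit = True
        if npts < max_pts:
            scratch[npts, 0] = ex
            scratch[npts, 1] = ey
            scratch[npts, 2] = ez
            scratch[npts, 3] = w
            npts += 1

        detected = False
        if top_exit:
            ddx = ex - col_pos[0]
            ddy = ey - col_pos[1]
            ddz = ez - col_pos[2]
            dot = ddx * col_ax[0] + ddy * col_ax[1] + ddz * col_ax[2]
            dperp2 = ddx * ddx + ddy * ddy + ddz * ddz - dot * dot
            cosang = -(dx * col_ax[0] + dy * col_ax[1] + dz * col_ax[2])
            if dperp2 <= col_r2 and cosang >= cos_col_max:
                detected = True

        if detected:
            detw += w
            n_det += 1
        else:
            esc += w

        if store_mode == 2 or (store_mode == 1 and detected):
            pts_needed += npts
            if n_stored < cap_rec and pts_used + npts <= cap_pts:
                for k in range(npts):
                    path_buf[pts_used + k, 0] = scratch[k, 0]
                    path_buf[pts_used + k, 1] = scratch[k, 1]
                    path_buf[pts_used + k, 2] = scratch[k, 2]
                    path_buf[pts_used + k, 3] = scratch[k, 3]
                pts_used += npts
                rec_info[n_stored, 0] = ex
                rec_info[n_stored, 1] = ey
                rec_info[n_stored, 2] = ez
                rec_info[n_stored, 3] = dx
                rec_info[n_stored, 4] = dy
                rec_info[n_stored, 5] = dz
                rec_info[n_stored, 6] = w
                rec_info[n_stored, 7] = 1.0 if detected else 0.0
                n_stored += 1
                path_off[n_stored] = pts_used
            else:
                overflow = 1

    return (n_det, n_stored, pts_used, pts_needed, overflow,
            dep, esc, detw, lost_roulette, lost_cap, n_capped)


@njit(cache=True)
def rasterize_paths(path_buf, path_off, weights_scale, nx, ny, nz, vs, out):
    """Accumulate track-length x packet-weight of each path segment into a 3D grid.

    Exact segment-voxel intersection lengths via a 3D digital differential
    analyzer.  The weight of a segment is the packet weight on entry (column 3
    of the start point).  `weights_scale` multiplies every contribution.
    """
    n_paths = path_off.shape[0] - 1
    for p in range(n_paths):
        for j in range(path_off[p], path_off[p + 1] - 1):
            x0 = path_buf[j, 0]
            y0 = path_buf[j, 1]
            z0 = path_buf[j, 2]
            w = path_buf[j, 3] * weights_scale
            x1 = path_buf[j + 1, 0]
            y1 = path_buf[j + 1, 1]
            z1 = path_buf[j + 1, 2]
            dx = x1 - x0
            dy = y1 - y0
            dz = z1 - z0
            seg_len = math.sqrt(dx * dx + dy * dy + dz * dz)
            if seg_len < 1e-12:
                continue
            ux = dx / seg_len
            uy = dy / seg_len
            uz = dz / seg_len
            t = 0.0
            px, py, pz = x0, y0, z0
            guard = 0
            while t < seg_len - 1e-12:
                ix = int(math.floor(px / vs))
                iy = int(math.floor(py / vs))
                iz = int(math.floor(pz / vs))
                # distance to the next voxel boundary along the segment
                db = 1e30
                if ux > 1e-12:
                    tt = ((ix + 1) * vs - px) / ux
                    if tt < db:
                        db = tt
                elif ux < -1e-12:
                    tt = (ix * vs - px) / ux
                    if tt < db:
                        db = tt
                if uy > 1e-12:
                    tt = ((iy + 1) * vs - py) / uy
                    if tt < db:
                        db = tt
                elif uy < -1e-12:
                    tt = (iy * vs - py) / uy
                    if tt < db:
                        db = tt
                if uz > 1e-12:
                    tt = ((iz + 1) * vs - pz) / uz
                    if tt < db:
                        db = tt
                elif uz < -1e-12:
                    tt = (iz * vs - pz) / uz
                    if tt < db:
                        db = tt
                if db < 1e-12:
                    db = 1e-12
                chunk = db
                if t + chunk > seg_len:
                    chunk = seg_len - t
                if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                    out[ix, iy, iz] += chunk * w
                t += chunk + 1e-12
                px += ux * (chunk + 1e-12)
                py += uy * (chunk + 1e-12)
                pz += uz * (chunk + 1e-12)
                guard += 1
                if guard > 100000:
                    break
    return out
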