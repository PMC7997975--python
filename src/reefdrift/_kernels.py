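"""Compiled inner loops for particle advection.

Everything here operates on plain float/int arrays so numba can compile it;
the public API (``tracking.advect``, ``flowfield.velocity_at``) wraps these.
Velocity sampling matches ``VelocityField.velocity_at`` exactly: bilinear in
lon/lat with land-node weights renormalized, linear in time.

Status codes: 0 = drifting, 1 = settled, 2 = exited.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DEG_TO_M = 6_371_000.0 * np.pi / 180.0
DRIFTING, SETTLED, EXITED = 0, 1, 2


@njit(cache=True)
def point_in_polygon(x, y, xs, ys, i0, i1):
    """Ray-casting point-in-polygon on the packed ring xs/ys[i0:i1]."""
    inside = False
    j = i1 - 1
    for i in range(i0, i1):
        yi = ys[i]
        yj = ys[j]
        if (yi > y) != (yj > y):
            xint = (xs[j] - xs[i]) * (y - yi) / (yj - yi) + xs[i]
            if x < xint:
                inside = not inside
        j = i
    return inside


@njit(cache=True)
def _bracket(ax, val, n):
    """Left index of the interval containing val, clipped to [0, n-2]."""
    i = np.searchsorted(ax, val, side="right") - 1
    if i < 0:
        i = 0
    if i > n - 2:
        i = n - 2
    return i


@njit(cache=True)
def _nearest(ax, val):
    i = np.searchsorted(ax, val)
    if i <= 0:
        return 0
    if i >= ax.shape[0]:
        return ax.shape[0] - 1
    if val - ax[i - 1] <= ax[i] - val:
        return i - 1
    return i


@njit(cache=True)
def sample_uv(x, y, ts, lon, lat, taxis, u, v, mask):
    """Masked bilinear + linear-in-time velocity (m/s). Caller guards bbox."""
    nt = taxis.shape[0]
    if nt == 1:
        k = 0
        k1 = 0
        a = 0.0
    else:
        if ts <= taxis[0]:
            k = 0
        elif ts >= taxis[nt - 1]:
            k = nt - 2
        else:
            k = _bracket(taxis, ts, nt)
        k1 = k + 1
        a = (ts - taxis[k]) / (taxis[k1] - taxis[k])
        if a < 0.0:
            a = 0.0
        elif a > 1.0:
            a = 1.0
    nx = lon.shape[0]
    ny = lat.shape[0]
    i = _bracket(lon, x, nx)
    j = _bracket(lat, y, ny)
    fx = (x - lon[i]) / (lon[i + 1] - lon[i])
    fy = (y - lat[j]) / (lat[j + 1] - lat[j])
    w00 = (1.0 - fx) * (1.0 - fy) * mask[j, i]
    w10 = fx * (1.0 - fy) * mask[j, i + 1]
    w01 = (1.0 - fx) * fy * mask[j + 1, i]
    w11 = fx * fy * mask[j + 1, i + 1]
    s = w00 + w10 + w01 + w11
    if s <= 0.0:
        return 0.0, 0.0
    w00 /= s
    w10 /= s
    w01 /= s
    w11 /= s
    u0 = w00 * u[k, j, i] + w10 * u[k, j, i + 1] + w01 * u[k, j + 1, i] + w11 * u[k, j + 1, i + 1]
    v0 = w00 * v[k, j, i] + w10 * v[k, j, i + 1] + w01 * v[k, j + 1, i] + w11 * v[k, j + 1, i + 1]
    if k1 == k:
        return u0, v0
    u1 = w00 * u[k1, j, i] + w10 * u[k1, j, i + 1] + w01 * u[k1, j + 1, i] + w11 * u[k1, j + 1, i + 1]
    v1 = w00 * v[k1, j, i] + w10 * v[k1, j, i + 1] + w01 * v[k1, j + 1, i] + w11 * v[k1, j + 1, i + 1]
    return (1.0 - a) * u0 + a * u1, (1.0 - a) * v0 + a * v1


@njit(cache=True)
def _deg_vel(x, y, ts, lon, lat, taxis, u, v, mask):
    um, vm = sample_uv(x, y, ts, lon, lat, taxis, u, v, mask)
    return um / (DEG_TO_M * np.cos(np.radians(y))), vm / DEG_TO_M


@njit(cache=True)
def rk4_displacement(x, y, t, dt, lon, lat, taxis, u, v, mask):
    """One classical RK4 step; returns (dx, dy, in_bounds).

    A substep position outside the grid bounding box aborts the step and
    signals domain exit to the caller.
    """
    lon0, lon1 = lon[0], lon[lon.shape[0] - 1]
    lat0, lat1 = lat[0], lat[lat.shape[0] - 1]
    k1x, k1y = _deg_vel(x, y, t, lon, lat, taxis, u, v, mask)
    x2 = x + 0.5 * dt * k1x
    y2 = y + 0.5 * dt * k1y
    if x2 < lon0 or x2 > lon1 or y2 < lat0 or y2 > lat1:
        return 0.0, 0.0, False
    k2x, k2y = _deg_vel(x2, y2, t + 0.5 * dt, lon, lat, taxis, u, v, mask)
    x3 = x + 0.5 * dt * k2x
    y3 = y + 0.5 * dt * k2y
    if x3 < lon0 or x3 > lon1 or y3 < lat0 or y3 > lat1:
        return 0.0, 0.0, False
    k3x, k3y = _deg_vel(x3, y3, t + 0.5 * dt, lon, lat, taxis, u, v, mask)
    x4 = x + dt * k3x
    y4 = y + dt * k3y
    if x4 < lon0 or x4 > lon1 or y4 < lat0 or y4 > lat1:
        return 0.0, 0.0, False
    k4x, k4y = _deg_vel(x4, y4, t + dt, lon, lat, taxis, u, v, mask)
    dx = dt * (k1x + 2.0 * k2x + 2.0 * k3x + k4x) / 6.0
    dy = dt * (k1y + 2.0 * k2y + 2.0 * k3y + k4y) / 6.0
    return dx, dy, True


@njit(cache=True)
def integrate_gridded(x0, y0, t0, n_steps, dt, scheme, lon, lat, taxis, u, v, mask):
    """Open-water single-particle integrator (no land, no settlement).

    scheme: 0 = forward Euler, 1 = RK4.  Used as the cross-check oracle for
    the ensemble tracker.  Returns (x, y, steps_completed); stops early if the
    particle leaves the grid.
    """
    x = x0
    y = y0
    t = t0
    lon0, lon1 = lon[0], lon[lon.shape[0] - 1]
    lat0, lat1 = lat[0], lat[lat.shape[0] - 1]
    for s in range(n_steps):
        if scheme == 0:
            kx, ky = _deg_vel(x, y, t, lon, lat, taxis, u, v, mask)
            dx = dt * kx
            dy = dt * ky
            ok = True
        else:
            dx, dy, ok = rk4_displacement(x, y, t, dt, lon, lat, taxis, u, v, mask)
        if not ok:
            return x, y, s
        xn = x + dx
        yn = y + dy
        if xn < lon0 or xn > lon1 or yn < lat0 or yn > lat1:
            return x, y, s
        x = xn
        y = yn
        t += dt
    return x, y, n_steps


@njit(cache=True)
def _area_at(x, y, lon, lat, cand, pxs, pys, poff):
    """Index of the area polygon containing (x, y), or -1."""
    j = _nearest(lat, y)
    i = _nearest(lon, x)
    c = cand[j, i]
    if c == -1:
        return -1
    if c >= 0:
        if point_in_polygon(x, y, pxs, pys, poff[c], poff[c + 1]):
            return c
        return -1
    # ambiguous cell: test every area
    for a in range(poff.shape[0] - 1):
        if point_in_polygon(x, y, pxs, pys, poff[a], poff[a + 1]):
            return a
    return -1


@njit(cache=True)
def advect_kernel(
    x0, y0, rel_s, natal,
    lon, lat, taxis, u, v, mask,
    cand, pxs, pys, poff,
    dt, n_steps, competency_steps, sample_every, snapshot_mode,
    out_x, out_y, out_t, out_n,
    status, settle_area, settle_t, max_lat,
):
    """Advect all particles through their full lifetime.

    Per particle: RK4 steps of ``dt`` seconds for up to ``n_steps`` steps
    starting at its release instant ``rel_s`` (seconds after the field's first
    time).  A step landing on a land node (nearest-node mask 0) is replaced by
    a coast-parallel slip: the zonal-only, then meridional-only displacement
    component is tried against the mask, else the particle holds position.
    Entering any area polygon after the competency delay settles the particle;
    self-settlement requires having first been outside the natal polygon.
    Leaving the grid bounding box exits the particle.  Positions are recorded
    every ``sample_every`` steps and at termination.

    In snapshot mode settlement is evaluated only once, after the final step.
    """
    n = x0.shape[0]
    nx = lon.shape[0]
    ny = lat.shape[0]
    lon0, lon1 = lon[0], lon[nx - 1]
    lat0, lat1 = lat[0], lat[ny - 1]
    for p in range(n):
        x = x0[p]
        y = y0[p]
        t = rel_s[p]
        nat = natal[p]
        left_natal = False
        out_x[p, 0] = x
        out_y[p, 0] = y
        out_t[p, 0] = t
        ns = 1
        ml = y
        st = DRIFTING
        sa = -1
        stime = np.nan
        terminated = False
        for step in range(n_steps):
            dx, dy, ok = rk4_displacement(x, y, t, dt, lon, lat, taxis, u, v, mask)
            if ok:
                xn = x + dx
                yn = y + dy
                ok = lon0 <= xn <= lon1 and lat0 <= yn <= lat1
            if not ok:
                st = EXITED
                terminated = True
            else:
                jn = _nearest(lat, yn)
                in_ = _nearest(lon, xn)
                if mask[jn, in_] == 0:
                    # beached: coast-parallel slip along the unmasked axis
                    xs_try = x + dx
                    if (lon0 <= xs_try <= lon1
                            and mask[_nearest(lat, y), _nearest(lon, xs_try)] == 1):
                        xn = xs_try
                        yn = y
                    else:
                        ys_try = y + dy
                        if (lat0 <= ys_try <= lat1
                                and mask[_nearest(lat, ys_try), _nearest(lon, x)] == 1):
                            xn = x
                            yn = ys_try
                        else:
                            xn = x
                            yn = y
                x = xn
                y = yn
                t = rel_s[p] + (step + 1) * dt
                area = _area_at(x, y, lon, lat, cand, pxs, pys, poff)
                if not left_natal and area != nat:
                    left_natal = True
                can_settle = area >= 0 and (area != nat or left_natal) \
                    and (step + 1) >= competency_steps
                if can_settle and (not snapshot_mode or step == n_steps - 1):
                    st = SETTLED
                    sa = area
                    stime = t
                    terminated = True
            if terminated or (step + 1) % sample_every == 0 or step == n_steps - 1:
                out_x[p, ns] = x
                out_y[p, ns] = y
                out_t[p, ns] = t
                if y > ml:
                    ml = y
                ns += 1
            if terminated:
                break
        out_n[p] = ns
        status[p] = st
        settle_area[p] = sa
        settle_t[p] = stime
        max_lat[p] = ml
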