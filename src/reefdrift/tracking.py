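"""Particle release and Lagrangian advection.

Implements the tracking protocol: virtual coral-spawn particles are released
at 20:00 on consecutive nights from every source area, advected as passive
surface tracers through a time-varying velocity field with classical RK4 at a
fixed step (default 200 s), and followed for one pelagic larval duration
(default 21 days).  A particle terminates by settling (first entry into any
destination-area polygon after its competency delay, with self-settlement
requiring a prior excursion out of the natal polygon), by leaving the grid
bounding box (exited), or by exhausting the tracking duration (drifting).

Non-destination coastline is non-absorbing: a step that would beach a
particle is replaced by a coast-parallel slip (the tangential displacement
component against the raster coastline), so particles are conserved for the
connectivity census.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import shapely

from . import _kernels
from .domain import Domain
from .flowfield import (DEG_TO_M, ConfigurationError, GeoPosition,
                        VelocityField, _as_seconds)

STATUS_NAMES = {0: "drifting", 1: "settled", 2: "exited"}


@dataclass
class ReleaseSchedule:
    """Nightly release instants plus per-area counts and the seeding RNG seed."""

    instants: list
    per_area_per_night: int = 25
    source_areas: list[str] | None = None  # None = every area in the domain
    seed: int = 0

    def __post_init__(self) -> None:
        self.instants = [np.datetime64(t, "ns") for t in self.instants]
        if len(self.instants) == 0:
            raise ConfigurationError("release schedule needs at least one instant")
        diffs = np.diff(np.asarray(self.instants))
        if len(self.instants) > 1 and not np.all(diffs > np.timedelta64(0, "s")):
            raise ConfigurationError("release instants must be strictly increasing")
        if self.per_area_per_night < 1:
            raise ConfigurationError("per_area_per_night must be >= 1")


@dataclass
class TrackingParams:
    """Numerical parameters of the tracking protocol.

    dt_seconds
        RK4 integration step, seconds (default 200).
    duration_days
        Pelagic larval duration: how long each particle is tracked.
    competency_days
        Minimum drift time before settlement is allowed.
    sample_every
        Output sampling interval as a multiple of dt (default 18 -> hourly
        positions at dt = 200 s).
    settlement_mode
        "continuous": absorb on first destination entry (default);
        "snapshot": evaluate settlement once, at the end of the duration.
    """

    dt_seconds: float = 200.0
    duration_days: float = 21.0
    competency_days: float = 0.0
    sample_every: int = 18
    settlement_mode: str = "continuous"

    def __post_init__(self) -> None:
        if self.dt_seconds <= 0:
            raise ConfigurationError("dt_seconds must be positive")
        if self.sample_every < 1:
            raise ConfigurationError("sample_every must be >= 1 step")
        if self.settlement_mode not in ("continuous", "snapshot"):
            raise ConfigurationError(f"unknown settlement_mode {self.settlement_mode!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_days * 86400.0 / self.dt_seconds))

    @property
    def competency_steps(self) -> int:
        return int(np.ceil(self.competency_days * 86400.0 / self.dt_seconds))


@dataclass
class ParticleBatch:
    """Initial conditions for a set of particles (column arrays)."""

    pid: np.ndarray          # int64
    lon: np.ndarray          # float64, release position
    lat: np.ndarray
    release_time: np.ndarray  # datetime64[ns]
    area_id: np.ndarray      # object (str)
    group: np.ndarray        # int32
    area_index: np.ndarray   # int32, index into domain.areas

    def __len__(self) -> int:
        return int(self.pid.size)


@dataclass
class ParticleTrajectory:
    """One particle's sampled track and terminal bookkeeping."""

    pid: int
    source_area: str
    source_group: int
    release_time: np.datetime64
    times: np.ndarray        # datetime64[ns], sampled instants
    lons: np.ndarray
    lats: np.ndarray
    status: str              # drifting | settled | exited
    settle_area: str | None = None
    settle_group: int | None = None
    settle_time: np.datetime64 | None = None
    max_lat: float = dc_field(default=np.nan)

    def __post_init__(self) -> None:
        if self.status == "settled" and (self.settle_area is None or self.settle_time is None):
            raise ValueError("settled trajectory must carry settlement area and instant")


def seed_particles(schedule: ReleaseSchedule, domain: Domain,
                   field: VelocityField | None = None) -> ParticleBatch:
    """Draw release positions uniformly inside each source-area polygon.

    For every (area, instant) pair, ``per_area_per_night`` positions are
    rejection-sampled from the area's bounding box, accepting points strictly
    inside the polygon, outside land, and (when a field is given) on a water
    node of its grid.  Fully determined by ``schedule.seed``.
    """
    rng = np.random.default_rng(schedule.seed)
    if schedule.source_areas is None:
        areas = list(domain.areas)
    else:
        areas = [domain.area_by_id(a) for a in schedule.source_areas]
    area_index = {a.id: k for k, a in enumerate(domain.areas)}
    land = domain.land_union
    if not land.is_empty:
        shapely.prepare(land)

    pids, lons, lats, rel, aids, grps, aidx = [], [], [], [], [], [], []
    pid = 0
    for area in areas:
        x0, y0, x1, y1 = area.polygon.bounds
        poly = area.polygon
        shapely.prepare(poly)
        npts = schedule.per_area_per_night * len(schedule.instants)
        pts = np.empty((npts, 2))
        got = 0
        for _ in range(10_000):
            if got >= npts:
                break
            m = max(4 * (npts - got), 64)
            cx = rng.uniform(x0, x1, m)
            cy = rng.uniform(y0, y1, m)
            ok = shapely.contains_xy(poly, cx, cy)
            if not land.is_empty:
                ok &= ~shapely.contains_xy(land, cx, cy)
            if field is not None:
                ji = np.abs(field.lat[:, None] - cy[None, :]).argmin(axis=0)
                ii = np.abs(field.lon[:, None] - cx[None, :]).argmin(axis=0)
                ok &= field.mask[ji, ii] == 1
            take = min(int(ok.sum()), npts - got)
            sel = np.flatnonzero(ok)[:take]
            pts[got:got + take, 0] = cx[sel]
            pts[got:got + take, 1] = cy[sel]
            got += take
        if got < npts:
            raise ConfigurationError(
                f"area {area.id}: could not place particles on water inside the polygon")
        k = 0
        for inst in schedule.instants:
            for _ in range(schedule.per_area_per_night):
                pids.append(pid)
                lons.append(pts[k, 0])
                lats.append(pts[k, 1])
                rel.append(inst)
                aids.append(area.id)
                grps.append(area.group)
                aidx.append(area_index[area.id])
                pid += 1
                k += 1
    return ParticleBatch(
        pid=np.asarray(pids, dtype=np.int64),
        lon=np.asarray(lons, dtype=np.float64),
        lat=np.asarray(lats, dtype=np.float64),
        release_time=np.asarray(rel, dtype="datetime64[ns]"),
        area_id=np.asarray(aids, dtype=object),
        group=np.asarray(grps, dtype=np.int32),
        area_index=np.asarray(aidx, dtype=np.int32),
    )


def integration_increment(p, t, dt_seconds: float, field) -> tuple[float, float]:
    """Classical RK4 displacement (dlon, dlat) in degrees for one step.

    Dtype-generic: extended-precision scalars (e.g. ``np.longdouble``)
    propagate through, which oracle-grade integrations use to keep roundoff
    below the scheme's truncation error.
    """
    x, y = p[0], p[1]
    h = dt_seconds
    k1 = field.velocity_deg_per_s((x, y), t)
    t_half = _offset(t, h / 2.0)
    k2 = field.velocity_deg_per_s((x + 0.5 * h * k1[0], y + 0.5 * h * k1[1]), t_half)
    k3 = field.velocity_deg_per_s((x + 0.5 * h * k2[0], y + 0.5 * h * k2[1]), t_half)
    k4 = field.velocity_deg_per_s((x + h * k3[0], y + h * k3[1]), _offset(t, h))
    return (h * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6.0,
            h * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6.0)


def integration_step(p: GeoPosition | tuple[float, float], t, dt_seconds: float,
                     field) -> GeoPosition:
    """One classical RK4 update of (lon, lat) in degrees.

    Works with any object exposing ``velocity_deg_per_s`` (gridded or
    analytic field).  Out-of-coverage substeps propagate the field's
    out-of-bounds error, which the ensemble tracker treats as domain exit.
    """
    dx, dy = integration_increment(p, t, dt_seconds, field)
    return GeoPosition(p[0] + dx, p[1] + dy)


def _offset(t, seconds: float):
    if isinstance(t, (int, float, np.floating, np.integer)):
        return t + seconds
    return np.datetime64(t, "ns") + np.timedelta64(int(round(seconds * 1e9)), "ns")


def integrate_path(p0, t0, duration_seconds: float, dt_seconds: float, field,
                   scheme: str = "rk4", dtype=float) -> np.ndarray:
    """Single-particle open-water integration; returns positions (n+1, 2).

    ``scheme`` is "rk4" or "euler".  Gridded fields dispatch to the compiled
    loop; analytic fields run the pure-Python step (oracle use), carrying
    positions in ``dtype`` (pass ``np.longdouble`` for oracle-grade accuracy)
    with compensated accumulation.
    """
    n = int(round(duration_seconds / dt_seconds))
    if isinstance(field, VelocityField):
        ts = _as_seconds(t0, field.time[0])
        x, y, done = _kernels.integrate_gridded(
            float(p0[0]), float(p0[1]), ts, n, float(dt_seconds),
            0 if scheme == "euler" else 1,
            field.lon, field.lat, field.time_seconds, field.u, field.v, field.mask)
        if done < n:
            raise ConfigurationError("particle left the grid during oracle integration")
        return np.array([[float(p0[0]), float(p0[1])], [x, y]])
    pos = np.empty((n + 1, 2), dtype=dtype)
    x, y = dtype(p0[0]), dtype(p0[1])
    pos[0] = (x, y)
    # Kahan compensation keeps position roundoff below truncation error
    cx, cy = dtype(0.0), dtype(0.0)
    t = t0
    for k in range(n):
        if scheme == "euler":
            vx, vy = field.velocity_deg_per_s((x, y), t)
            dx, dy = dt_seconds * vx, dt_seconds * vy
        else:
            dx, dy = integration_increment((x, y), t, dt_seconds, field)
        ax = dx - cx
        tx = x + ax
        cx = (tx - x) - ax
        x = tx
        ay = dy - cy
        ty = y + ay
        cy = (ty - y) - ay
        y = ty
        t = _offset(t, dt_seconds)
        pos[k + 1] = (x, y)
    return pos


def advect(particles: ParticleBatch, field: VelocityField, domain: Domain,
           params: TrackingParams) -> list[ParticleTrajectory]:
    """Advect a particle batch to termination; returns one trajectory each.

    Raises :class:`ConfigurationError` before integrating if the field's time
    axis does not cover every release instant plus the tracking duration.
    """
    if len(particles) == 0:
        return []
    t0 = field.time[0]
    rel_s = np.array([_as_seconds(t, t0) for t in particles.release_time])
    taxis = field.time_seconds
    need = rel_s.max() + params.duration_days * 86400.0
    if rel_s.min() < taxis[0] - 1e-6 or need > taxis[-1] + 1e-6:
        raise ConfigurationError(
            "field time coverage is shorter than release schedule + tracking duration")

    cand = domain.candidate_raster(field.lon, field.lat)
    pxs, pys, poff = domain.packed_polygons()
    n = len(particles)
    n_steps = params.n_steps
    ns_max = n_steps // params.sample_every + 3
    out_x = np.empty((n, ns_max), dtype=np.float32)
    out_y = np.empty((n, ns_max), dtype=np.float32)
    out_t = np.empty((n, ns_max), dtype=np.float64)
    out_n = np.zeros(n, dtype=np.int32)
    status = np.zeros(n, dtype=np.int8)
    settle_area = np.full(n, -1, dtype=np.int32)
    settle_t = np.full(n, np.nan)
    max_lat = np.full(n, np.nan)

    _kernels.advect_kernel(
        particles.lon, particles.lat, rel_s, particles.area_index,
        field.lon, field.lat, taxis, field.u, field.v, field.mask,
        cand, pxs, pys, poff,
        float(params.dt_seconds), n_steps, params.competency_steps,
        int(params.sample_every), params.settlement_mode == "snapshot",
        out_x, out_y, out_t, out_n, status, settle_area, settle_t, max_lat)

    trajs: list[ParticleTrajectory] = []
    for i in range(n):
        k = int(out_n[i])
        st = STATUS_NAMES[int(status[i])]
        sa = sg = stime = None
        if st == "settled":
            area = domain.areas[int(settle_area[i])]
            sa, sg = area.id, area.group
            stime = t0 + np.timedelta64(int(round(settle_t[i] * 1e9)), "ns")
        times = t0 + (out_t[i, :k] * 1e9).round().astype("timedelta64[ns]")
        trajs.append(ParticleTrajectory(
            pid=int(particles.pid[i]),
            source_area=str(particles.area_id[i]),
            source_group=int(particles.group[i]),
            release_time=particles.release_time[i],
            times=times,
            lons=out_x[i, :k].astype(np.float64),
            lats=out_y[i, :k].astype(np.float64),
            status=st,
            settle_area=sa, settle_group=sg, settle_time=stime,
            max_lat=float(max_lat[i]),
        ))
    return trajs


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def trajectory_table(trajs: list[ParticleTrajectory], thin: int = 1) -> pd.DataFrame:
    """Long-format position table; ``thin`` keeps every thin-th particle."""
    rows = []
    for tr in trajs:
        if thin > 1 and tr.pid % thin != 0:
            continue
        rows.append(pd.DataFrame({
            "particle_id": tr.pid,
            "source_area": tr.source_area,
            "source_group": tr.source_group,
            "time": tr.times,
            "lon": tr.lons,
            "lat": tr.lats,
            "status": tr.status,
        }))
    if not rows:
        return pd.DataFrame(columns=["particle_id", "source_area", "source_group",
                                     "time", "lon", "lat", "status"])
    return pd.concat(rows, ignore_index=True)


def settlement_table(trajs: list[ParticleTrajectory]) -> pd.DataFrame:
    """One row per particle: terminal status, destination and max latitude."""
    return pd.DataFrame({
        "particle_id": [tr.pid for tr in trajs],
        "source_area": [tr.source_area for tr in trajs],
        "source_group": [tr.source_group for tr in trajs],
        "status": [tr.status for tr in trajs],
        "dest_area": [tr.settle_area if tr.settle_area is not None else "" for tr in trajs],
        "dest_group": [tr.settle_group if tr.settle_group is not None else -1 for tr in trajs],
        "settle_time": [np.datetime_as_string(tr.settle_time, unit="s")
                        if tr.settle_time is not None else "" for tr in trajs],
        "max_lat": [tr.max_lat for tr in trajs],
    })


def write_trajectories_csv(trajs, path, thin: int = 1) -> None:
    df = trajectory_table(trajs, thin=thin)
    df["time"] = df["time"].map(lambda t: np.datetime_as_string(np.datetime64(t), unit="s"))
    df.to_csv(path, index=False, float_format="%.6f")


def write_settlement_csv(trajs, path, ldp_flags: np.ndarray | None = None) -> None:
    df = settlement_table(trajs)
    if ldp_flags is not None:
        df["is_ldp"] = np.asarray(ldp_flags).astype(int)
    df.to_csv(path, index=False, float_format="%.6f")


def read_trajectories_csv(traj_path, settlement_path=None) -> list[ParticleTrajectory]:
    """Rebuild trajectories from the long-format CSV (plus settlement CSV).

    Without the settlement table the destination group of settled particles
    is unknown; max latitude is always recomputed from the stored positions.
    """
    df = pd.read_csv(traj_path, parse_dates=["time"])
    settle = None
    if settlement_path is not None:
        settle = pd.read_csv(settlement_path, parse_dates=["settle_time"],
                             keep_default_na=False).set_index("particle_id")
    trajs = []
    for pid, g in df.groupby("particle_id", sort=True):
        g = g.sort_values("time")
        status = str(g["status"].iloc[-1])
        sa = sg = stime = None
        if settle is not None and pid in settle.index:
            row = settle.loc[pid]
            status = str(row["status"])
            if status == "settled":
                sa = str(row["dest_area"])
                sg = int(row["dest_group"])
                stime = np.datetime64(row["settle_time"])
        elif status == "settled":
            sa, sg, stime = "unknown", -1, np.datetime64(g["time"].iloc[-1])
        trajs.append(ParticleTrajectory(
            pid=int(pid),
            source_area=str(g["source_area"].iloc[0]),
            source_group=int(g["source_group"].iloc[0]),
            release_time=np.datetime64(g["time"].iloc[0]),
            times=g["time"].to_numpy(dtype="datetime64[ns]"),
            lons=g["lon"].to_numpy(dtype=np.float64),
            lats=g["lat"].to_numpy(dtype=np.float64),
            status=status,
            settle_area=sa, settle_group=sg, settle_time=stime,
            max_lat=float(g["lat"].max()),
        ))
    return trajs


def schedule_to_yaml(schedule: ReleaseSchedule, path) -> None:
    import yaml
    d = {
        "instants": [str(np.datetime_as_string(t, unit="s")) for t in schedule.instants],
        "per_area_per_night": schedule.per_area_per_night,
        "source_areas": schedule.source_areas,
        "seed": schedule.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def schedule_from_yaml(path) -> ReleaseSchedule:
    import yaml
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return ReleaseSchedule(**d)
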