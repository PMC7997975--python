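"""Idealized velocity fields and domains emulating a boundary-current reef system.

The study system is a coral lagoon sitting just upstream of a strong poleward
western-boundary current (Kuroshio-like).  This module builds desk-scale
stand-ins with the same statistical ingredients so the tracker and the
connectivity analysis are fully testable:

* a steady Gaussian-profile jet along a configurable axis polyline,
* mesoscale eddies with a Rankine (solid-body core) tangential profile that
  drift along the jet axis,
* a spatially uniform rotary tidal oscillation,
* fixture domains, including a ``sekisei_like`` coastline: 145 coastal areas
  in 18 numbered groups (interior groups {3, 10, 14-18}), a Kohama-like
  island flanked by ``west_channel`` and ``east_channel`` gates, and a
  Hatoma-like islet (group 6) off the northern coast of the large western
  island (groups 1-2).

Releases follow coral mass-spawning phenology: nightly discharges at 20:00
starting the first night after the May full moon.  The four historical start
nights (2012-2015) are shipped as configuration rather than computed from an
ephemeris.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field as dc_field, asdict

import numpy as np
import yaml
from shapely.geometry import Point, Polygon, box

from .domain import Area, Domain, Gate
from .flowfield import DEG_TO_M, ConfigurationError, GeoPosition, VelocityField
from .tracking import ReleaseSchedule

#: First release night for each simulated spawning season (first night after
#: the May full moon / spring tide).
RELEASE_START_DATES = {
    2012: dt.date(2012, 5, 7),
    2013: dt.date(2013, 5, 24),
    2014: dt.date(2014, 5, 15),
    2015: dt.date(2015, 5, 3),
}

#: Local clock time of the nightly mass-spawning discharge.
RELEASE_HOUR = dt.time(20, 0)


@dataclass
class JetEddyConfig:
    """Configuration of the analytic jet + eddies + tide velocity field.

    Spatial extent in degrees, times in hours, speeds in m/s, lengths in km.
    The seed fixes every stochastic choice (eddy placement and polarity).
    """

    lon_min: float = 123.3
    lon_max: float = 124.6
    lat_min: float = 24.0
    lat_max: float = 24.85
    grid_spacing: float = 0.01
    t_start: dt.datetime = dc_field(default_factory=lambda: dt.datetime(2012, 5, 6))
    duration_hours: float = 720.0
    output_interval_hours: float = 1.0
    jet_axis: list[tuple[float, float]] = dc_field(
        default_factory=lambda: [(123.3, 24.70), (124.0, 24.78), (124.6, 24.85)])
    jet_peak_speed: float = 1.2
    jet_half_width_km: float = 40.0
    n_eddies: int = 6
    eddy_amplitude: float = 0.35
    eddy_radius_km: float = 40.0
    eddy_drift_speed: float = 0.15
    tidal_amplitude: float = 0.25
    tidal_period_hours: float = 12.42
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ConfigurationError("grid_spacing must be positive")
        if self.jet_peak_speed < 0:
            raise ConfigurationError("jet_peak_speed must be non-negative")
        if self.eddy_radius_km <= 0:
            raise ConfigurationError("eddy_radius_km must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ConfigurationError("domain extent is degenerate (zero cells)")
        if self.output_interval_hours <= 0:
            raise ConfigurationError("output_interval_hours must be positive")
        n = self.duration_hours / self.output_interval_hours
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("output interval must divide the time span")
        if len(self.jet_axis) < 2:
            raise ConfigurationError("jet_axis needs at least two vertices")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["t_start"] = self.t_start.isoformat()
        d["jet_axis"] = [list(p) for p in self.jet_axis]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "JetEddyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["t_start"] = dt.datetime.fromisoformat(d["t_start"])
        d["jet_axis"] = [tuple(p) for p in d["jet_axis"]]
        return cls(**d)


def downstream_config(year: int = 2012, seed: int = 0, **overrides) -> JetEddyConfig:
    """Field preset covering the whole boundary-current downstream region.

    Coarser grid (0.05 deg) over 122-129 E / 23.5-29 N with the jet axis
    running northeastward past the islands, spanning a 14-night release window
    plus the 21-day larval duration.
    """
    start = RELEASE_START_DATES[year]
    cfg = dict(
        lon_min=122.0, lon_max=129.0, lat_min=23.5, lat_max=29.0,
        grid_spacing=0.05,
        t_start=dt.datetime.combine(start, dt.time(0, 0)),
        duration_hours=36 * 24.0,
        jet_axis=[(122.0, 24.2), (123.6, 24.9), (125.2, 25.9),
                  (127.0, 27.2), (129.0, 28.6)],
        jet_half_width_km=60.0,
        seed=seed,
    )
    cfg.update(overrides)
    return JetEddyConfig(**cfg)


def interior_config(year: int = 2012, seed: int = 0, **overrides) -> JetEddyConfig:
    """Field preset for the lagoon close-up: 0.01 deg grid around the islands,
    spanning an 8-night release window plus the 21-day larval duration."""
    start = RELEASE_START_DATES[year]
    cfg = dict(
        t_start=dt.datetime.combine(start, dt.time(0, 0)),
        duration_hours=30 * 24.0,
        seed=seed,
    )
    cfg.update(overrides)
    return JetEddyConfig(**cfg)


# ---------------------------------------------------------------------------
# Field generation
# ---------------------------------------------------------------------------

def _axis_metric(axis, lat_ref: float) -> tuple[np.ndarray, np.ndarray]:
    """Axis vertices in local metric coordinates and cumulative arclength."""
    pts = np.asarray(axis, dtype=np.float64)
    xy = np.column_stack([
        pts[:, 0] * DEG_TO_M * np.cos(np.radians(lat_ref)),
        pts[:, 1] * DEG_TO_M,
    ])
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return xy, np.concatenate([[0.0], np.cumsum(seg)])


def _point_on_axis(xy: np.ndarray, arc: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and unit tangent at arclength s (clamped) along the polyline."""
    s = min(max(s, 0.0), arc[-1])
    k = int(np.searchsorted(arc, s, side="right")) - 1
    k = min(max(k, 0), len(arc) - 2)
    seg = xy[k + 1] - xy[k]
    L = np.linalg.norm(seg)
    tang = seg / L
    return xy[k] + tang * (s - arc[k]), tang


def _dist_tangent_to_axis(px: np.ndarray, py: np.ndarray, xy: np.ndarray):
    """Min distance (m) from points to the polyline and the local unit tangent."""
    n = px.size
    best_d2 = np.full(n, np.inf)
    tx = np.zeros(n)
    ty = np.zeros(n)
    for k in range(len(xy) - 1):
        ax, ay = xy[k]
        bx, by = xy[k + 1]
        vx, vy = bx - ax, by - ay
        L2 = vx * vx + vy * vy
        t = np.clip(((px - ax) * vx + (py - ay) * vy) / L2, 0.0, 1.0)
        dx = px - (ax + t * vx)
        dy = py - (ay + t * vy)
        d2 = dx * dx + dy * dy
        better = d2 < best_d2
        best_d2 = np.where(better, d2, best_d2)
        L = np.sqrt(L2)
        tx = np.where(better, vx / L, tx)
        ty = np.where(better, vy / L, ty)
    return np.sqrt(best_d2), tx, ty


def generate_jet_field(config: JetEddyConfig, land: list[Polygon] | None = None) -> VelocityField:
    """Build the analytic jet + eddies + tide field on the configured grid.

    The jet contributes ``peak * exp(-(d/L)^2)`` along the local axis tangent
    (d = distance to the axis, L = half-width).  Each eddy is a rigid Rankine
    vortex (solid-body core of the configured radius, 1/r tail with a Gaussian
    envelope) whose centre drifts along the jet axis at the drift speed,
    re-entering at the axis start when it runs off the end.  The tide is a
    spatially uniform rotary (clockwise) oscillation.  Identical config and
    seed give a bit-identical field.
    """
    lon = np.arange(config.lon_min, config.lon_max + config.grid_spacing / 2, config.grid_spacing)
    lat = np.arange(config.lat_min, config.lat_max + config.grid_spacing / 2, config.grid_spacing)
    if lon.size < 2 or lat.size < 2:
        raise ConfigurationError("domain extent is degenerate (zero cells)")
    nt = int(round(config.duration_hours / config.output_interval_hours)) + 1
    time = (np.datetime64(config.t_start, "ns")
            + (np.arange(nt) * config.output_interval_hours * 3.6e12).astype("timedelta64[ns]"))

    lat_ref = 0.5 * (config.lat_min + config.lat_max)
    gx, gy = np.meshgrid(lon, lat)
    px = (gx * DEG_TO_M * np.cos(np.radians(lat_ref))).ravel()
    py = (gy * DEG_TO_M).ravel()
    axis_xy, arc = _axis_metric(config.jet_axis, lat_ref)

    d, tx, ty = _dist_tangent_to_axis(px, py, axis_xy)
    hw = config.jet_half_width_km * 1000.0
    speed = config.jet_peak_speed * np.exp(-((d / hw) ** 2))
    u_jet = (speed * tx).reshape(lat.size, lon.size)
    v_jet = (speed * ty).reshape(lat.size, lon.size)

    rng = np.random.default_rng(config.seed)
    eddy_s0 = rng.uniform(0.0, arc[-1], config.n_eddies)
    eddy_sign = rng.choice(np.array([-1.0, 1.0]), config.n_eddies)

    R = config.eddy_radius_km * 1000.0
    u = np.empty((nt, lat.size, lon.size))
    v = np.empty((nt, lat.size, lon.size))
    omega = 2.0 * np.pi / (config.tidal_period_hours * 3600.0)
    for k in range(nt):
        t_s = k * config.output_interval_hours * 3600.0
        uk = u_jet.copy().ravel()
        vk = v_jet.copy().ravel()
        if config.eddy_amplitude > 0.0 and config.n_eddies > 0:
            for e in range(config.n_eddies):
                s = (eddy_s0[e] + config.eddy_drift_speed * t_s) % arc[-1]
                centre, _ = _point_on_axis(axis_xy, arc, s)
                rx = px - centre[0]
                ry = py - centre[1]
                r = np.hypot(rx, ry)
                r = np.maximum(r, 1.0)
                vt = np.where(
                    r < R,
                    config.eddy_amplitude * r / R,
                    config.eddy_amplitude * (R / r) * np.exp(-(((r - R) / (2.5 * R)) ** 2)),
                )
                uk += eddy_sign[e] * vt * (-ry / r)
                vk += eddy_sign[e] * vt * (rx / r)
        if config.tidal_amplitude > 0.0:
            uk += config.tidal_amplitude * np.sin(omega * t_s)
            vk += config.tidal_amplitude * np.cos(omega * t_s)
        u[k] = uk.reshape(lat.size, lon.size)
        v[k] = vk.reshape(lat.size, lon.size)

    if land:
        mask = Domain(land=list(land)).land_mask(lon, lat)
        landed = mask == 0
        u[:, landed] = 0.0
        v[:, landed] = 0.0
    else:
        mask = np.ones((lat.size, lon.size), dtype=np.uint8)
    return VelocityField(lon=lon, lat=lat, time=time, u=u, v=v, mask=mask)


# ---------------------------------------------------------------------------
# Fixture domains
# ---------------------------------------------------------------------------

def _circle(lon: float, lat: float, r: float, n: int = 36) -> Polygon:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([lon + r * np.cos(th), lat + r * np.sin(th)]))


def _ring_areas(group: int, prefix: str, centre, ring_r: float, thetas_deg,
                area_r: float, interior: bool) -> list[Area]:
    out = []
    for k, th in enumerate(thetas_deg):
        a = np.radians(th)
        c = (centre[0] + ring_r * np.cos(a), centre[1] + ring_r * np.sin(a))
        out.append(Area(id=f"{prefix}{k:02d}", group=group,
                        polygon=_circle(c[0], c[1], area_r, n=24), interior=interior))
    return out


def _span(start: float, step: float, n: int) -> np.ndarray:
    return start + step * np.arange(n)


def generate_fixture_domain(kind: str) -> Domain:
    """Built-in test domains: ``sekisei_like``, ``two_island`` or ``channel``.

    ``sekisei_like`` reproduces the study topology with stylized coordinates:
    18 groups over 145 areas, interior groups {3, 10, 14-18}, and the two
    channel gates west and east of the Kohama-like island.  ``two_island`` is
    two coastal areas on facing islands with no gates; ``channel`` is a single
    strait with areas A (west) and B (east) and one gate.
    """
    if kind == "two_island":
        land = [_circle(123.3, 24.5, 0.10), _circle(123.7, 24.5, 0.10)]
        areas = [
            Area("A", 1, _circle(123.42, 24.5, 0.03), False),
            Area("B", 2, _circle(123.58, 24.5, 0.03), False),
        ]
        return Domain(land=land, areas=areas, gates=[])

    if kind == "channel":
        land = [box(123.4, 24.0, 123.6, 24.45), box(123.4, 24.55, 123.6, 25.0)]
        areas = [
            Area("A", 1, _circle(123.2, 24.5, 0.05), False),
            Area("B", 2, _circle(123.8, 24.5, 0.05), False),
        ]
        gates = [Gate("strait", GeoPosition(123.5, 24.45), GeoPosition(123.5, 24.55),
                      "mid-strait crossing line")]
        return Domain(land=land, areas=areas, gates=gates)

    if kind != "sekisei_like":
        raise ValueError(f"unknown fixture kind {kind!r}")

    iri = (123.80, 24.33)   # large western island (Iriomote-like)
    koh = (124.02, 24.40)   # small central island (Kohama-like)
    ish = (124.20, 24.45)   # large eastern island (Ishigaki-like)
    hat = (123.82, 24.53)   # northern islet (Hatoma-like)
    land = [
        _circle(*iri, 0.13, n=48),
        _circle(*koh, 0.030, n=32),
        _circle(*ish, 0.11, n=48),
        _circle(*hat, 0.018, n=24),
    ]

    ar = 0.006  # area radius, deg
    areas: list[Area] = []
    iri_ring = 0.148
    areas += _ring_areas(1, "g01_", iri, iri_ring, _span(56, 7, 10), ar, False)
    areas += _ring_areas(2, "g02_", iri, iri_ring, _span(0, 6, 9), ar, False)
    areas += _ring_areas(3, "g03_", iri, iri_ring, _span(-57, 7, 8), ar, True)
    areas += _ring_areas(4, "g04_", iri, iri_ring, _span(-120, 7, 8), ar, False)
    areas += _ring_areas(5, "g05_", iri, iri_ring, _span(127, 7, 8), ar, False)
    areas += _ring_areas(6, "g06_", hat, 0.036, _span(0, 60, 6), ar, False)
    ish_ring = 0.128
    areas += _ring_areas(7, "g07_", ish, ish_ring, _span(55, 7, 8), ar, False)
    areas += _ring_areas(8, "g08_", ish, ish_ring, _span(-12, 7, 8), ar, False)
    areas += _ring_areas(9, "g09_", ish, ish_ring, _span(-125, 7, 8), ar, False)
    areas += _ring_areas(10, "g10_", ish, ish_ring, _span(175, 7, 8), ar, True)
    areas += _ring_areas(11, "g11_", iri, iri_ring, _span(-177, 7, 8), ar, False)
    areas += _ring_areas(12, "g12_", ish, ish_ring, _span(112, 7, 8), ar, False)
    areas += _ring_areas(13, "g13_", ish, ish_ring, _span(-69, 7, 8), ar, False)
    # lagoon patch reefs sit on tiny synthetic islets so each area is coastal
    patch14 = _ring_areas(14, "g14_", (123.99, 24.30), 0.035, _span(0, 45, 8), ar, True)
    patch15 = _ring_areas(15, "g15_", (124.09, 24.28), 0.035, _span(0, 45, 8), ar, True)
    areas += patch14 + patch15
    areas += _ring_areas(16, "g16_", koh, 0.048, np.linspace(-170, -10, 8), ar, True)
    areas += _ring_areas(17, "g17_", koh, 0.048, np.linspace(25, 155, 8), ar, True)
    barrier = [Area(f"g18_{k:02d}", 18, _circle(x, 24.20, ar, n=24), True)
               for k, x in enumerate(np.linspace(123.95, 124.15, 8))]
    areas += barrier
    for a in patch14 + patch15 + barrier:
        c = a.polygon.centroid
        land.append(_circle(c.x, c.y, 0.004, n=12))

    gates = [
        Gate("west_channel", GeoPosition(123.890, 24.415), GeoPosition(123.995, 24.415),
             "Yonara-like channel west of the Kohama-like island, southward crossing"),
        Gate("east_channel", GeoPosition(124.040, 24.420), GeoPosition(124.096, 24.420),
             "channel east of the Kohama-like island, southward crossing"),
    ]
    return Domain(land=land, areas=areas, gates=gates)


# ---------------------------------------------------------------------------
# Release scheduling
# ---------------------------------------------------------------------------

def generate_release_schedule(first_night: dt.date, nights: int = 8,
                              hour: dt.time = RELEASE_HOUR,
                              per_area_per_night: int = 25,
                              source_areas: list[str] | None = None,
                              seed: int = 0) -> ReleaseSchedule:
    """Nightly release instants: one per night at ``hour`` starting ``first_night``.

    Defaults give the protocol-scale census: 145 areas x 8 nights x 25
    particles/area/night = 29,000 particles on the ``sekisei_like`` fixture.
    """
    if nights < 1:
        raise ConfigurationError("nights must be >= 1")
    instants = [dt.datetime.combine(first_night + dt.timedelta(days=k), hour)
                for k in range(nights)]
    return ReleaseSchedule(instants=instants, per_area_per_night=per_area_per_night,
                           source_areas=source_areas, seed=seed)
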