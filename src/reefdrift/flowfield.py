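"""Gridded time-varying surface velocity fields and space-time interpolation.

A :class:`VelocityField` holds the surface (u, v) current components on a
regular lon/lat grid with a static water mask (1 = water, 0 = land), plus a
strictly increasing time axis.  This is the medium the particle tracker moves
virtual coral spawn through; in production it would be the surface slice of a
regional ocean-model output, here it usually comes from
:mod:`reefdrift.synthetic_ocean`.

Kinematic conventions
---------------------
All positions are geographic degrees.  Velocities are stored in m/s and
converted to degrees/s with the spherical approximation

    dlon/dt = u / (R * pi/180 * cos(lat)),    dlat/dt = v / (R * pi/180)

with Earth radius R = 6 371 000 m.

Interpolation is bilinear in lon/lat and linear in time.  Land nodes
contribute zero velocity and their bilinear weights are renormalized over the
water nodes of the enclosing cell, which prevents spurious onshore velocities
near the coast; if all four nodes are land the interpolated velocity is (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, NamedTuple

import numpy as np
import xarray as xr

EARTH_RADIUS_M = 6_371_000.0
#: metres per degree of latitude (and of longitude at the equator)
DEG_TO_M = EARTH_RADIUS_M * np.pi / 180.0

_U_UNIT_SPELLINGS = {
    "m/s", "m s-1", "m s^-1", "m.s-1", "meter second-1", "meters second-1",
    "meter/second", "meters/second", "metre second-1", "metres second-1",
    "m second-1", "meter per second", "meters per second",
}


class GeoPosition(NamedTuple):
    """A point on the globe in degrees east / degrees north."""

    lon: float
    lat: float


class FieldFormatError(ValueError):
    """Raised when a NetCDF file does not contain a usable velocity field."""


class OutOfBoundsError(ValueError):
    """Query position or time outside the field's coverage."""


class ConfigurationError(ValueError):
    """Invalid configuration for a generator or a tracking run."""


def _as_seconds(t, t0: np.datetime64) -> float:
    """Convert a datetime-like or numeric instant to seconds after ``t0``."""
    if isinstance(t, (int, float, np.floating, np.integer)):
        return float(t)
    return float((np.datetime64(t, "ns") - np.datetime64(t0, "ns")) / np.timedelta64(1, "s"))


@dataclass
class VelocityField:
    """Surface current on a regular lon/lat grid with a static water mask.

    Parameters
    ----------
    lon, lat
        Strictly increasing coordinate axes, degrees.
    time
        Strictly increasing instants (``datetime64``), length ``nt``.
    u, v
        Eastward / northward velocity, m/s, shape ``(nt, nlat, nlon)``.
        Values on land nodes are ignored by the interpolator.
    mask
        Water mask on the grid nodes, shape ``(nlat, nlon)``; 1 = water.
    """

    lon: np.ndarray
    lat: np.ndarray
    time: np.ndarray
    u: np.ndarray
    v: np.ndarray
    mask: np.ndarray = dc_field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=np.float64)
        self.lat = np.asarray(self.lat, dtype=np.float64)
        self.time = np.asarray(self.time, dtype="datetime64[ns]")
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.mask is None:
            self.mask = np.ones((self.lat.size, self.lon.size), dtype=np.uint8)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        for name, ax in (("lon", self.lon), ("lat", self.lat)):
            if ax.ndim != 1 or ax.size < 2 or not np.all(np.diff(ax) > 0):
                raise FieldFormatError(f"coordinate {name} must be 1-D and strictly increasing")
        if self.time.ndim != 1 or self.time.size < 1:
            raise FieldFormatError("time axis must be 1-D and non-empty")
        if self.time.size > 1 and not np.all(np.diff(self.time) > np.timedelta64(0, "s")):
            raise FieldFormatError("time axis must be strictly increasing")
        shape = (self.time.size, self.lat.size, self.lon.size)
        if self.u.shape != shape or self.v.shape != shape:
            raise FieldFormatError(f"u/v must have shape {shape}, got {self.u.shape}/{self.v.shape}")
        if self.mask.shape != (self.lat.size, self.lon.size):
            raise FieldFormatError("mask shape inconsistent with axes")
        water = self.mask.astype(bool)
        if not (np.isfinite(self.u[:, water]).all() and np.isfinite(self.v[:, water]).all()):
            raise FieldFormatError("u/v contain non-finite values on water nodes")

    # -- coverage -----------------------------------------------------------
    @property
    def time_seconds(self) -> np.ndarray:
        """Time axis as float seconds after the first instant."""
        return (self.time - self.time[0]) / np.timedelta64(1, "s")

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of the grid."""
        return float(self.lon[0]), float(self.lat[0]), float(self.lon[-1]), float(self.lat[-1])

    def covers(self, lon: float, lat: float) -> bool:
        return self.lon[0] <= lon <= self.lon[-1] and self.lat[0] <= lat <= self.lat[-1]

    # -- interpolation ------------------------------------------------------
    def velocity_at(self, p: GeoPosition | tuple[float, float], t) -> tuple[float, float]:
        """Interpolated (u, v) in m/s at position ``p`` and instant ``t``.

        Bilinear in lon/lat, linear in time; land-node weights are zeroed and
        renormalized over the water nodes.  Raises
        :class:`OutOfBoundsError` outside spatial or temporal coverage.
        """
        lon, lat = float(p[0]), float(p[1])
        ts = _as_seconds(t, self.time[0])
        taxis = self.time_seconds
        if not self.covers(lon, lat):
            raise OutOfBoundsError(f"position ({lon}, {lat}) outside grid bounding box")
        if ts < taxis[0] - 1e-9 or ts > taxis[-1] + 1e-9:
            raise OutOfBoundsError(f"time {ts} s outside field coverage [0, {taxis[-1]}] s")
        ts = min(max(ts, taxis[0]), taxis[-1])

        k = int(np.searchsorted(taxis, ts, side="right")) - 1
        k = min(max(k, 0), taxis.size - 2) if taxis.size > 1 else 0
        if taxis.size == 1:
            a = 0.0
            k1 = 0
        else:
            a = (ts - taxis[k]) / (taxis[k + 1] - taxis[k])
            k1 = k + 1

        i = int(np.searchsorted(self.lon, lon, side="right")) - 1
        i = min(max(i, 0), self.lon.size - 2)
        j = int(np.searchsorted(self.lat, lat, side="right")) - 1
        j = min(max(j, 0), self.lat.size - 2)
        fx = (lon - self.lon[i]) / (self.lon[i + 1] - self.lon[i])
        fy = (lat - self.lat[j]) / (self.lat[j + 1] - self.lat[j])

        w = np.array([(1 - fx) * (1 - fy), fx * (1 - fy), (1 - fx) * fy, fx * fy])
        jj = np.array([j, j, j + 1, j + 1])
        ii = np.array([i, i + 1, i, i + 1])
        wm = w * self.mask[jj, ii]
        s = wm.sum()
        if s <= 0.0:
            return 0.0, 0.0
        wm = wm / s
        u0 = float((self.u[k, jj, ii] * wm).sum())
        v0 = float((self.v[k, jj, ii] * wm).sum())
        u1 = float((self.u[k1, jj, ii] * wm).sum())
        v1 = float((self.v[k1, jj, ii] * wm).sum())
        return (1 - a) * u0 + a * u1, (1 - a) * v0 + a * v1

    def velocity_deg_per_s(self, p, t) -> tuple[float, float]:
        """Velocity converted to (dlon/dt, dlat/dt) in degrees/s."""
        u, v = self.velocity_at(p, t)
        return (
            u / (DEG_TO_M * np.cos(np.radians(float(p[1])))),
            v / DEG_TO_M,
        )


class AnalyticField:
    """Velocity field defined by a closed-form function of (lon, lat, t).

    Used for integrator oracles where the exact trajectory is known.  The
    callable receives seconds after ``t0`` and returns (u, v) in m/s.
    Spatial/temporal coverage is unbounded.
    """

    def __init__(self, func: Callable[[float, float, float], tuple[float, float]],
                 t0=np.datetime64("2012-01-01", "ns")):
        self.func = func
        self.time = np.asarray([np.datetime64(t0, "ns")])

    def velocity_at(self, p, t) -> tuple[float, float]:
        ts = _as_seconds(t, self.time[0])
        return self.func(float(p[0]), float(p[1]), ts)

    def velocity_deg_per_s(self, p, t) -> tuple[float, float]:
        u, v = self.velocity_at(p, t)
        return u / (DEG_TO_M * np.cos(np.radians(float(p[1])))), v / DEG_TO_M


# ---------------------------------------------------------------------------
# NetCDF I/O (CF conventions, via xarray's scipy backend)
# ---------------------------------------------------------------------------

def write_field(field: VelocityField, path) -> None:
    """Write a field as CF-convention NetCDF (classic format).

    Dimensions (time, lat, lon); variables ``u``, ``v`` in m/s, ``mask``
    (1 = water, 0 = land); time encoded as "hours since" the first instant.
    """
    epoch = np.datetime_as_string(field.time[0].astype("datetime64[s]"))
    ds = xr.Dataset(
        {
            "u": (("time", "lat", "lon"), field.u, {"units": "m s-1", "long_name": "eastward surface velocity"}),
            "v": (("time", "lat", "lon"), field.v, {"units": "m s-1", "long_name": "northward surface velocity"}),
            "mask": (("lat", "lon"), field.mask, {"long_name": "water mask", "flag_values": "0 1",
                                                  "flag_meanings": "land water"}),
        },
        coords={
            "time": ("time", field.time.astype("datetime64[ns]")),
            "lat": ("lat", field.lat, {"units": "degrees_north", "standard_name": "latitude"}),
            "lon": ("lon", field.lon, {"units": "degrees_east", "standard_name": "longitude"}),
        },
        attrs={"Conventions": "CF-1.8"},
    )
    ds.time.encoding.update(units=f"hours since {epoch}", dtype="float64")
    ds.to_netcdf(path, engine="scipy")


def _pick(ds: xr.Dataset, names: tuple[str, ...], what: str) -> str:
    for n in names:
        if n in ds.variables:
            return n
    raise FieldFormatError(f"{what} not found (looked for {'/'.join(names)})")


def read_field(path) -> VelocityField:
    """Read a CF-convention NetCDF velocity field.

    Accepts coordinate spellings {lon, longitude} / {lat, latitude}; requires
    variables ``u`` and ``v`` with a metres-per-second unit string.  Axes are
    sorted ascending; a missing mask means all-water.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    lon_name = _pick(ds, ("lon", "longitude"), "coordinate lon")
    lat_name = _pick(ds, ("lat", "latitude"), "coordinate lat")
    if "time" not in ds.variables:
        raise FieldFormatError("coordinate time not found")
    for var in ("u", "v"):
        if var not in ds.variables:
            raise FieldFormatError(f"variable {var} not found")
        units = str(ds[var].attrs.get("units", "m s-1")).strip().lower()
        if units not in _U_UNIT_SPELLINGS:
            raise FieldFormatError(f"variable {var} has units {units!r}, expected m/s")
    time = ds["time"].values
    if time.ndim != 1 or (time.size > 1 and not np.all(np.diff(time) > np.timedelta64(0, "s"))):
        raise FieldFormatError("time axis is not strictly increasing")
    lon = ds[lon_name].values.astype(np.float64)
    lat = ds[lat_name].values.astype(np.float64)
    u = ds["u"].values.astype(np.float64)
    v = ds["v"].values.astype(np.float64)
    mask = ds["mask"].values.astype(np.uint8) if "mask" in ds.variables else None
    # sort spatial axes ascending if a producer wrote them descending
    if lon.size > 1 and lon[0] > lon[-1]:
        lon = lon[::-1].copy()
        u, v = u[:, :, ::-1].copy(), v[:, :, ::-1].copy()
        mask = mask[:, ::-1].copy() if mask is not None else None
    if lat.size > 1 and lat[0] > lat[-1]:
        lat = lat[::-1].copy()
        u, v = u[:, ::-1, :].copy(), v[:, ::-1, :].copy()
        mask = mask[::-1, :].copy() if mask is not None else None
    return VelocityField(lon=lon, lat=lat, time=time, u=u, v=v, mask=mask)
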