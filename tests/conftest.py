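"""Shared fixtures: small synthetic fields and domains built at test time."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

import reefdrift as rd
from reefdrift.synthetic_ocean import JetEddyConfig, generate_jet_field
from reefdrift.tracking import TrackingParams, advect, seed_particles


def uniform_field(u=0.1, v=0.0, lon=(123.0, 124.0), lat=(24.0, 25.0),
                  spacing=0.1, hours=48.0, mask=None):
    """Spatially/temporally uniform velocity field for interpolation tests."""
    lons = np.arange(lon[0], lon[1] + spacing / 2, spacing)
    lats = np.arange(lat[0], lat[1] + spacing / 2, spacing)
    nt = int(hours // 6) + 1
    time = (np.datetime64("2012-05-06T00:00", "ns")
            + (np.arange(nt) * 6 * 3.6e12).astype("timedelta64[ns]"))
    shape = (nt, lats.size, lons.size)
    return rd.VelocityField(lon=lons, lat=lats, time=time,
                            u=np.full(shape, float(u)), v=np.full(shape, float(v)),
                            mask=mask)


@pytest.fixture(scope="session")
def channel_domain():
    return rd.generate_fixture_domain("channel")


@pytest.fixture(scope="session")
def channel_field(channel_domain):
    """Steady eastward 0.3 m/s flow through the channel fixture, 24 days."""
    cfg = JetEddyConfig(
        lon_min=123.0, lon_max=124.0, lat_min=24.0, lat_max=25.0,
        grid_spacing=0.02, t_start=dt.datetime(2012, 5, 6),
        duration_hours=24 * 24.0, output_interval_hours=6.0,
        jet_axis=[(123.0, 24.5), (124.0, 24.5)], jet_peak_speed=0.3,
        jet_half_width_km=10_000.0, n_eddies=0, eddy_amplitude=0.0,
        tidal_amplitude=0.0, seed=1)
    return generate_jet_field(cfg, land=channel_domain.land)


@pytest.fixture(scope="session")
def channel_run(channel_domain, channel_field):
    """A tracked release on the channel fixture: 2 nights x 50/area."""
    schedule = rd.generate_release_schedule(dt.date(2012, 5, 7), nights=2,
                                            per_area_per_night=50, seed=3)
    particles = seed_particles(schedule, channel_domain, channel_field)
    trajs = advect(particles, channel_field, channel_domain, TrackingParams())
    return particles, trajs
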