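"""Analysis products derived from particle trajectories.

Four products, matching the questions the dispersal study asks:

* **Connectivity matrix** — group-to-group arrival probabilities
  ``P[i][j] = settled(i -> j) / released(i)`` with the per-source loss
  fraction (unsettled + exited), so every row satisfies
  ``sum_j P[i][j] + loss[i] = 1``.
* **Reachability PDF** — gridded probability density of particle presence
  over the larval duration (or of day-PLD positions in snapshot mode),
  normalized so ``sum(density * cell_area) = 1`` with density in deg^-2.
* **Long-distance particles (LDPs)** — particles whose maximum attained
  latitude strictly exceeds a threshold (26.5 deg N by default), the proxy
  for transport into the boundary-current downstream region.
* **Route classification** — the first gate segment a trajectory properly
  crosses, used to split arrivals between the channels west and east of the
  central island.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr

from .domain import Domain, Gate
from .tracking import ParticleTrajectory


@dataclass
class LDPThreshold:
    """Latitude (deg N) above which a particle counts as long-distance."""

    latitude: float = 26.5


@dataclass
class ConnectivityMatrix:
    """Source-group x destination-group arrival probabilities.

    ``P`` is row-indexed by ``source_groups`` (only groups that released at
    least one particle) and column-indexed by ``dest_groups``.
    """

    source_groups: list[int]
    dest_groups: list[int]
    P: np.ndarray
    loss: np.ndarray
    released: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        self.loss = np.asarray(self.loss, dtype=np.float64)
        self.released = np.asarray(self.released, dtype=np.int64)
        if self.P.shape != (len(self.source_groups), len(self.dest_groups)):
            raise ValueError("P shape inconsistent with group lists")
        if np.any(self.released <= 0):
            raise ValueError("included rows must have released > 0")

    def probability(self, source: int, dest: int) -> float:
        return float(self.P[self.source_groups.index(source), self.dest_groups.index(dest)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.P, index=self.source_groups, columns=self.dest_groups)
        df.index.name = "source_group"
        df["released_n"] = self.released
        df["loss"] = self.loss
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.8f")

    @classmethod
    def from_csv(cls, path) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        dest_cols = [c for c in df.columns if c not in ("released_n", "loss")]
        return cls(source_groups=[int(i) for i in df.index],
                   dest_groups=[int(c) for c in dest_cols],
                   P=df[dest_cols].to_numpy(),
                   loss=df["loss"].to_numpy(), released=df["released_n"].to_numpy())


@dataclass
class ReachabilityPDF:
    """Gridded probability density of particle presence, deg^-2."""

    lon_edges: np.ndarray
    lat_edges: np.ndarray
    density: np.ndarray          # (nlat_bins, nlon_bins)
    sample_count: int
    source_filter: list[int] | None = None
    mode: str = "time_integrated"

    @property
    def cell_area(self) -> np.ndarray:
        """Cell areas in deg^2, shape (nlat_bins, nlon_bins)."""
        dlat = np.diff(self.lat_edges)
        dlon = np.diff(self.lon_edges)
        return np.outer(dlat, dlon)

    @property
    def total_mass(self) -> float:
        return float((self.density * self.cell_area).sum())

    def to_dataset(self) -> xr.Dataset:
        lon_c = 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])
        lat_c = 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])
        return xr.Dataset(
            {"density": (("lat", "lon"), self.density, {"units": "degree-2"})},
            coords={"lat": ("lat", lat_c, {"units": "degrees_north"}),
                    "lon": ("lon", lon_c, {"units": "degrees_east"})},
            attrs={"analysis_mode": self.mode, "sample_count": self.sample_count,
                   "source_filter": "all" if self.source_filter is None
                   else ",".join(map(str, self.source_filter))},
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    def to_frame(self) -> pd.DataFrame:
        ds = self.to_dataset()
        df = ds["density"].to_dataframe().reset_index()
        return df[["lon", "lat", "density"]]


# ---------------------------------------------------------------------------
# Connectivity matrix
# ---------------------------------------------------------------------------

def connectivity_matrix(records: pd.DataFrame, domain: Domain) -> ConnectivityMatrix:
    """Aggregate per-particle settlement records into group-level probabilities.

    ``records`` is the settlement table (one row per particle, columns
    ``source_group``, ``status``, ``dest_group``); area-level records are
    summed into their groups before normalization.  Source groups with zero
    released particles are excluded from the rows with a warning.
    """
    groups = domain.groups
    known = set(groups)
    bad = set(records["source_group"].unique()) - known
    if bad:
        raise ValueError(f"records reference unknown source groups {sorted(bad)}")
    dest_known = set(records.loc[records["status"] == "settled", "dest_group"].unique()) - known
    if dest_known:
        raise ValueError(f"records reference unknown destination groups {sorted(dest_known)}")

    released = records.groupby("source_group").size()
    src_groups = [g for g in groups if released.get(g, 0) > 0]
    empty = [g for g in groups if released.get(g, 0) == 0]
    if empty:
        warnings.warn(f"source groups with zero released particles excluded: {empty}")

    P = np.zeros((len(src_groups), len(groups)))
    settled = records[records["status"] == "settled"]
    counts = settled.groupby(["source_group", "dest_group"]).size()
    for (sg, dg), n in counts.items():
        P[src_groups.index(int(sg)), groups.index(int(dg))] = n / released[sg]
    loss = 1.0 - P.sum(axis=1)
    rel = np.array([released[g] for g in src_groups], dtype=np.int64)
    return ConnectivityMatrix(source_groups=src_groups, dest_groups=list(groups),
                              P=P, loss=loss, released=rel)


def rank_external_sources(M: ConnectivityMatrix, interior: set[int],
                          dest: int) -> pd.DataFrame:
    """Exterior source groups ranked by arrival probability into ``dest``.

    Sorted by probability descending, ties broken by ascending group number;
    the top entry is the major exterior source for the destination.
    """
    if dest not in M.dest_groups:
        raise ValueError(f"destination group {dest} not in matrix")
    j = M.dest_groups.index(dest)
    rows = [(g, float(M.P[i, j])) for i, g in enumerate(M.source_groups)
            if g not in interior]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["source_group", "probability"])


# ---------------------------------------------------------------------------
# Reachability PDFs
# ---------------------------------------------------------------------------

def reachability_pdf(trajectories: list[ParticleTrajectory],
                     lon_edges: np.ndarray, lat_edges: np.ndarray,
                     source_filter: list[int] | None = None,
                     mode: str = "time_integrated",
                     pld_days: float = 21.0) -> ReachabilityPDF:
    """Histogram particle presence on an analysis grid and normalize to a PDF.

    ``time_integrated`` bins every sampled position within ``pld_days`` of
    release; ``snapshot_at_PLD`` bins one position per particle (its last
    sample, i.e. the day-PLD position for drifters and the terminal position
    for settled/exited particles).  Positions outside the grid are dropped
    before normalization, so the density integrates to 1 over the grid.
    """
    if mode not in ("time_integrated", "snapshot_at_PLD"):
        raise ValueError(f"unknown mode {mode!r}")
    sel = [tr for tr in trajectories
           if source_filter is None or tr.source_group in source_filter]
    if not sel:
        raise ValueError("no particles match filter")
    xs, ys = [], []
    horizon = np.timedelta64(int(pld_days * 86400 * 1e9), "ns")
    for tr in sel:
        if mode == "time_integrated":
            keep = (tr.times - np.datetime64(tr.release_time, "ns")) <= horizon
            xs.append(tr.lons[keep])
            ys.append(tr.lats[keep])
        else:
            xs.append(tr.lons[-1:])
            ys.append(tr.lats[-1:])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    H, _, _ = np.histogram2d(y, x, bins=[lat_edges, lon_edges])
    n_in = H.sum()
    if n_in == 0:
        raise ValueError("no particle positions fall on the analysis grid")
    area = np.outer(np.diff(lat_edges), np.diff(lon_edges))
    density = H / (n_in * area)
    return ReachabilityPDF(lon_edges=np.asarray(lon_edges), lat_edges=np.asarray(lat_edges),
                           density=density, sample_count=int(n_in),
                           source_filter=source_filter, mode=mode)


# ---------------------------------------------------------------------------
# Long-distance particles
# ---------------------------------------------------------------------------

def classify_ldp(trajectories: list[ParticleTrajectory],
                 threshold: LDPThreshold | float = LDPThreshold()) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag long-distance particles: max latitude strictly above the threshold.

    Returns the per-trajectory boolean flags (trajectory order) and a table
    of per-source-group LDP fractions.
    """
    lat = threshold.latitude if isinstance(threshold, LDPThreshold) else float(threshold)
    flags = np.array([tr.max_lat > lat for tr in trajectories], dtype=bool)
    if trajectories:
        df = pd.DataFrame({
            "source_group": [tr.source_group for tr in trajectories],
            "is_ldp": flags,
        })
        frac = (df.groupby("source_group")["is_ldp"].agg(["mean", "sum", "size"])
                .rename(columns={"mean": "ldp_fraction", "sum": "n_ldp", "size": "n_released"})
                .reset_index())
    else:
        frac = pd.DataFrame(columns=["source_group", "ldp_fraction", "n_ldp", "n_released"])
    return flags, frac


# ---------------------------------------------------------------------------
# Route / gate classification
# ---------------------------------------------------------------------------

def _proper_crossings(lons: np.ndarray, lats: np.ndarray, gate: Gate) -> np.ndarray:
    """Indices of trajectory segments that properly cross the gate segment."""
    x0, y0 = lons[:-1], lats[:-1]
    x1, y1 = lons[1:], lats[1:]
    gx0, gy0 = gate.start
    gx1, gy1 = gate.end

    def orient(ax, ay, bx, by, cx, cy):
        return (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)

    d1 = orient(gx0, gy0, gx1, gy1, x0, y0)
    d2 = orient(gx0, gy0, gx1, gy1, x1, y1)
    d3 = orient(x0, y0, x1, y1, gx0, gy0)
    d4 = orient(x0, y0, x1, y1, gx1, gy1)
    return np.flatnonzero((d1 * d2 < 0) & (d3 * d4 < 0))


def classify_route(trajectory: ParticleTrajectory, gates: list[Gate]) -> str | None:
    """ID of the first gate the trajectory properly crosses, or None.

    Walks the sampled polyline in time order; if one segment crosses several
    gates, the gate hit earliest along that segment wins.
    """
    if trajectory.lons.size < 2:
        return None
    best_seg = None
    best_t = np.inf
    best_gate = None
    for gate in gates:
        idx = _proper_crossings(trajectory.lons, trajectory.lats, gate)
        if idx.size == 0:
            continue
        i = int(idx[0])
        # parametric position of the crossing along trajectory segment i
        x0, y0 = trajectory.lons[i], trajectory.lats[i]
        dxs, dys = trajectory.lons[i + 1] - x0, trajectory.lats[i + 1] - y0
        gx0, gy0 = gate.start
        gdx, gdy = gate.end[0] - gx0, gate.end[1] - gy0
        denom = dxs * gdy - dys * gdx
        tpar = ((gx0 - x0) * gdy - (gy0 - y0) * gdx) / denom if denom != 0 else 0.0
        if best_seg is None or i < best_seg or (i == best_seg and tpar < best_t):
            best_seg, best_t, best_gate = i, tpar, gate.id
    return best_gate


def route_census(trajectories: list[ParticleTrajectory], gates: list[Gate],
                 source_group: int, dest_group: int) -> dict[str, int]:
    """Count settled source->dest trajectories by the first gate crossed.

    Returns ``{gate_id: n, ..., "none": n}``; the counts partition the
    filtered trajectory set.
    """
    counts: dict[str, int] = {g.id: 0 for g in gates}
    counts["none"] = 0
    for tr in trajectories:
        if tr.status != "settled" or tr.source_group != source_group \
                or tr.settle_group != dest_group:
            continue
        gid = classify_route(tr, gates)
        counts[gid if gid is not None else "none"] += 1
    return counts
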