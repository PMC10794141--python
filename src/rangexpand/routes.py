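"""Expansion-route reconstruction from pairwise FST.

"Tracing nearest genetic distances over the landscape" is formalised as
origin-seeded Prim accretion: starting from the origin population, the
unattached population with the smallest FST to any attached population is
repeatedly attached, the edge directed outward.  The result is the
minimum spanning tree of the FST graph rooted at the origin (ties broken
by smaller great-circle distance, then lexicographically), which
reproduces the leave-one-out rewiring behaviour: removing a hub
population re-attaches its children to their next-nearest attached
neighbours.

The gradient surface interpolates the origin-anchored FST profile onto a
hexagonal lattice by inverse-distance weighting and reports the local
spatial gradient magnitude per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DistanceMatrix, SampleManifest
from .exceptions import (
    ConnectivityError,
    DegenerateInputError,
    LookupError_,
)
from .geo import great_circle_km


@dataclass
class RouteGraph:
    """Origin-rooted spanning tree over populations."""

    root: str
    nodes: dict[str, tuple[float, float]]        # population -> (lat, lon)
    edges: list[tuple[str, str, float, float]]   # parent, child, fst, km

    def parent_of(self, population: str) -> str | None:
        for p, c, *_ in self.edges:
            if c == population:
                return p
        return None

    def children_of(self, population: str) -> list[str]:
        return [c for p, c, *_ in self.edges if p == population]

    def total_weight(self) -> float:
        return float(sum(e[2] for e in self.edges))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges,
                            columns=["parent", "child", "fst", "km"])


@dataclass
class GradientSurface:
    """Hexagonal-lattice interpolation of an FST-to-origin profile.

    ``cells`` columns: lat, lon, value (IDW-interpolated FST to origin),
    gradient (km^-1 magnitude; NaN on cells with too few neighbours),
    empty (no population within the IDW cutoff).
    """

    cells: pd.DataFrame
    hex_size_deg: float
    idw_power: float


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------

def origin_fst_profile(fst: DistanceMatrix, origin: str) -> pd.Series:
    """The origin population's row of the FST matrix, origin excluded."""
    if origin not in fst.labels:
        raise LookupError_(f"origin {origin!r} not in FST matrix")
    i = fst.labels.index(origin)
    others = [l for l in fst.labels if l != origin]
    return pd.Series({l: fst.value(origin, l) for l in others},
                     name=f"fst_to_{origin}")


def trace_routes(fst: DistanceMatrix, manifest: SampleManifest,
                 origin: str, exclude: set[str] | None = None) -> RouteGraph:
    """Origin-seeded Prim accretion over the FST graph.

    At each step the unattached population with minimal FST to any
    attached population is attached (edge directed outward); ties are
    broken by smaller great-circle distance between the candidate pair,
    then by lexicographic (parent, child) label order.  NaN FST entries
    are treated as missing edges; if accretion stalls the graph is
    disconnected and an error is raised.
    """
    exclude = set(exclude or ())
    labels = [l for l in fst.labels if l not in exclude]
    if origin not in labels:
        raise LookupError_(f"origin {origin!r} not available for tracing")
    sub = fst.reorder(labels)
    coords = {l: manifest.coords_of(l) for l in labels}
    attached = [origin]
    unattached = set(labels) - {origin}
    edges: list[tuple[str, str, float, float]] = []
    while unattached:
        best = None
        for parent in attached:
            for child in unattached:
                w = sub.value(parent, child)
                if np.isnan(w):
                    continue
                km = great_circle_km(coords[parent], coords[child])
                key = (w, km, parent, child)
                if best is None or key < best:
                    best = key
        if best is None:
            raise ConnectivityError(
                f"populations {sorted(unattached)} unreachable after "
                "NaN pruning")
        w, km, parent, child = best
        edges.append((parent, child, w, km))
        attached.append(child)
        unattached.discard(child)
    return RouteGraph(root=origin, nodes=coords, edges=edges)


def gengrad_surface(fst_profile: pd.Series, manifest: SampleManifest,
                    hex_size: float = 2.0, idw_power: float = 2.0,
                    cutoff_km: float = float("inf")) -> GradientSurface:
    """Inverse-distance-weighted FST surface on a hexagonal lattice.

    Hexagon centres tile the populations' bounding box (padded by one
    cell): rows are spaced ``hex_size * sqrt(3)/2`` degrees of latitude
    apart with alternate rows offset by ``hex_size / 2`` of longitude.
    Each centre's value is the IDW mean (weight ``1/d^idw_power``, great-
    circle km) of the per-population FST-to-origin profile; the gradient
    is the magnitude of a least-squares local plane fitted through the
    neighbouring cells (NaN where fewer than 3 neighbours exist).
    """
    pops = [p for p in fst_profile.index]
    if len(pops) < 4:
        raise DegenerateInputError("need >= 4 populations with coordinates")
    coords = np.array([manifest.coords_of(p) for p in pops])
    vals = fst_profile.to_numpy(dtype=float)

    lat_lo, lat_hi = coords[:, 0].min(), coords[:, 0].max()
    lon_lo, lon_hi = coords[:, 1].min(), coords[:, 1].max()
    row_step = hex_size * np.sqrt(3) / 2
    lats = np.arange(lat_lo - hex_size, lat_hi + hex_size + row_step,
                     row_step)
    rows = []
    for ri, lat in enumerate(lats):
        off = (hex_size / 2) if ri % 2 else 0.0
        lons = np.arange(lon_lo - hex_size + off,
                         lon_hi + hex_size + hex_size, hex_size)
        for lon in lons:
            d = np.array([great_circle_km((lat, lon), (la, lo))
                          for la, lo in coords])
            within = d <= cutoff_km
            if not within.any():
                rows.append((lat, lon, np.nan, True))
                continue
            if (d[within] == 0).any():
                v = float(vals[within][d[within] == 0][0])
            else:
                w = 1.0 / d[within] ** idw_power
                v = float(np.sum(w * vals[within]) / np.sum(w))
            rows.append((lat, lon, v, False))
    cells = pd.DataFrame(rows, columns=["lat", "lon", "value", "empty"])

    # gradient by local plane fit over neighbouring hexagons (km units)
    grad = np.full(len(cells), np.nan)
    pts = cells[["lat", "lon"]].to_numpy()
    mean_lat = np.radians(pts[:, 0].mean())
    km_per_deg_lat = np.pi * 6371.0088 / 180.0
    km_per_deg_lon = km_per_deg_lat * np.cos(mean_lat)
    xy = np.column_stack([pts[:, 1] * km_per_deg_lon,
                          pts[:, 0] * km_per_deg_lat])
    neigh_radius = 1.2 * hex_size * km_per_deg_lat
    values = cells["value"].to_numpy()
    for i in range(len(cells)):
        if cells["empty"].iloc[i]:
            continue
        d2 = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
        nb = np.flatnonzero((d2 > 0) & (d2 <= neigh_radius)
                            & ~cells["empty"].to_numpy())
        if len(nb) < 3:
            continue
        A = np.column_stack([np.ones(len(nb) + 1),
                             xy[np.r_[i, nb], 0] - xy[i, 0],
                             xy[np.r_[i, nb], 1] - xy[i, 1]])
        beta, *_ = np.linalg.lstsq(A, values[np.r_[i, nb]], rcond=None)
        grad[i] = float(np.hypot(beta[1], beta[2]))
    cells["gradient"] = grad
    return GradientSurface(cells=cells, hex_size_deg=hex_size,
                           idw_power=idw_power)
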