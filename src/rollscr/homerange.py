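"""Minimum convex polygon home ranges and sigma <-> area transforms.

The 100% MCP is the convex hull of all of an animal's GPS fixes; its area
(km^2) is the classical home-range estimate.  Under a half-normal detection
model with a roughly circular home range, range area and the SCR spatial
scale are linked by

    area = 18.86 sigma^2      <=>      sigma = sqrt(area / 18.86),

(the 2D normal quantile for ~95% of use: 18.86 = 2 pi chi^2_{2,0.95} / 2
rounded as conventionally used), which lets camera-trap sigma estimates be
confronted with telemetry-derived ranges on a common scale.

Maximum distance moved between camera stations ranks the camera-trapped
individuals by ranging extent, to judge whether collared animals are
representative of the detected sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint

from .errors import ParameterError
from .io import DetectionRecordSet, Track, TrapArray
from .sessions import SessionWindow, make_windows

__all__ = [
    "HomeRange",
    "MovementSummary",
    "HR_SIGMA_FACTOR",
    "mcp_area",
    "rolling_mcp",
    "sigma_from_area",
    "area_from_sigma",
    "max_station_distances",
]

HR_SIGMA_FACTOR = 18.86  # area (km^2) = factor * sigma(km)^2 for circular ranges


@dataclass
class HomeRange:
    """A 100% MCP: convex-hull vertices (metres) and area in km^2."""

    animal: str
    area_km2: float
    vertices: np.ndarray  # (v, 2) metres; empty when degenerate
    n_fixes: int
    window: SessionWindow | None = None
    degenerate: bool = False


def mcp_area(fixes, animal: str = "", window: SessionWindow | None = None) -> HomeRange:
    """Convex hull of planar fixes (metres); area reported in km^2.

    Fewer than three non-collinear fixes give a degenerate zero-area range.
    """
    pts = np.atleast_2d(np.asarray(fixes, dtype=float))
    if pts.size == 0:
        return HomeRange(animal, 0.0, np.empty((0, 2)), 0, window, True)
    if pts.shape[1] != 2:
        raise ParameterError("fixes must be (x, y) pairs")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon":  # point or line: collinear input
        return HomeRange(animal, 0.0, np.empty((0, 2)), len(pts), window, True)
    verts = np.asarray(hull.exterior.coords)[:-1]
    return HomeRange(animal, hull.area / 1e6, verts, len(pts), window, False)


def rolling_mcp(track: Track, L: int = 90, step: int = 1) -> list[HomeRange]:
    """One MCP per rolling L-day window over the track's day span.

    Windows are aligned to the first fix day; a track observed on days
    [d0, d1] yields (d1 - d0 + 1) - L + 1 windows at step 1.  Windows with
    fewer than three usable fixes yield degenerate zero-area entries.
    """
    days = track.days()
    xy = track.xy()
    d0 = int(days.min())
    span = int(days.max()) - d0 + 1
    if span < L:
        raise ParameterError(f"track spans {span} days < window length {L}")
    out = []
    for w in make_windows(span, L, step):
        lo, hi = d0 + w.start_day - 1, d0 + w.end_day - 1
        sel = (days >= lo) & (days <= hi)
        out.append(
            mcp_area(xy[sel], animal=track.animal, window=SessionWindow(lo, hi))
        )
    return out


def sigma_from_area(area_km2: float) -> float:
    """Sigma (km) equivalent to a circular home range of ``area_km2``."""
    if area_km2 < 0:
        raise ParameterError("area must be >= 0")
    return math.sqrt(area_km2 / HR_SIGMA_FACTOR)


def area_from_sigma(sigma_km: float) -> float:
    """Circular home-range area (km^2) implied by sigma (km)."""
    if sigma_km < 0:
        raise ParameterError("sigma must be >= 0")
    return HR_SIGMA_FACTOR * sigma_km**2


@dataclass
class MovementSummary:
    """Maximum between-station distance for one individual, with its rank."""

    individual: str
    max_distance_km: float
    rank: int  # 1 = largest; ties share the smaller rank


def max_station_distances(
    records: DetectionRecordSet,
    traps: TrapArray,
    sex_filter: str = "male",
) -> list[MovementSummary]:
    """Rank individuals by the largest distance between their detectors.

    Individuals detected at a single station carry no movement information
    and are excluded.  Distances are between detector coordinates, in km.
    """
    stations: dict[str, set[str]] = {}
    for r in records.records:
        if sex_filter == "all" or r.sex == sex_filter:
            stations.setdefault(r.individual, set()).add(r.detector)
    coords = traps.coords()
    dists = {}
    for ind, dets in stations.items():
        if len(dets) < 2:
            continue
        pts = coords[[traps.index(d) for d in sorted(dets)]]
        diff = pts[:, None, :] - pts[None, :, :]
        dists[ind] = float(np.sqrt((diff**2).sum(axis=2)).max()) / 1000.0
    ordered = sorted(dists.items(), key=lambda kv: (-kv[1], kv[0]))
    out, prev_d, prev_rank = [], None, 0
    for pos, (ind, d) in enumerate(ordered, start=1):
        rank = prev_rank if d == prev_d else pos
        out.append(MovementSummary(ind, d, rank))
        prev_d, prev_rank = d, rank
    return out
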