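"""Trait polarity from worldwide modern-population frequency clines.

Under a serial-founder history out of sub-Saharan Africa, ancestral
dental trait frequencies decay and derived frequencies rise with
distance along the expansion routes.  The sign of the correlation
between a trait's presence frequency across modern populations and
their waypoint-routed great-circle distance from a sub-Saharan African
origin therefore identifies the ancestral state: a negative correlation
means presence is ancestral, a positive one means absence is ancestral.
An optional outgroup (e.g. pooled Pleistocene African early *Homo*
fossils) is appended as a single data point at distance zero to root the
states.  Only traits whose correlation is significant at ``alpha`` are
retained downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "EARTH_RADIUS_KM",
    "WaypointRoute",
    "PolarityResult",
    "haversine",
    "waypoint_distance",
    "load_waypoint_config",
    "population_distances",
    "estimate_polarity",
    "filter_polarized_traits",
]

EARTH_RADIUS_KM = 6371.0

LatLon = tuple[float, float]


def _check_coord(point: LatLon) -> None:
    lat, lon = point
    if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 360.0):
        raise ValueError(f"coordinate out of range: {point}")


def haversine(a: LatLon, b: LatLon, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    _check_coord(a)
    _check_coord(b)
    la1, lo1 = map(math.radians, a)
    la2, lo2 = map(math.radians, b)
    s = (
        math.sin((la2 - la1) / 2.0) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2.0) ** 2
    )
    return 2.0 * radius_km * math.asin(min(1.0, math.sqrt(s)))


@dataclass(frozen=True)
class WaypointRoute:
    """An ordered chain of migration waypoints from an origin point.

    The routed distance to a population is the sum of great-circle legs
    origin -> w1 -> ... -> wk -> population; an empty waypoint list
    degenerates to the plain geodesic.
    """

    origin: LatLon
    waypoints: tuple[LatLon, ...] = ()

    def distance_to(self, point: LatLon, radius_km: float = EARTH_RADIUS_KM) -> float:
        chain = (self.origin, *self.waypoints, point)
        return sum(
            haversine(p, q, radius_km) for p, q in zip(chain, chain[1:])
        )


def waypoint_distance(
    origin: LatLon,
    population: LatLon,
    waypoints: Sequence[LatLon] = (),
    radius_km: float = EARTH_RADIUS_KM,
) -> float:
    """Waypoint-routed distance origin -> waypoints -> population, in km."""
    return WaypointRoute(origin, tuple(waypoints)).distance_to(population, radius_km)


def load_waypoint_config(path=None) -> dict:
    """Load a waypoint configuration (YAML); ``None`` loads the packaged
    editable default.

    Returns ``{"origin": (lat, lon), "routes": {path_name: WaypointRoute}}``.
    """
    if path is None:
        text = resources.files("dentabc.data").joinpath("waypoints.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    origin = (raw["origin"]["latitude"], raw["origin"]["longitude"])
    points = {
        name: (w["latitude"], w["longitude"]) for name, w in raw["waypoints"].items()
    }
    routes = {
        name: WaypointRoute(origin, tuple(points[w] for w in chain))
        for name, chain in raw["paths"].items()
    }
    return {"origin": origin, "routes": routes}


def population_distances(
    populations: pd.DataFrame,
    config: dict,
    path_column: str = "path",
) -> pd.Series:
    """Routed distance (km) for each population row.

    ``populations`` needs latitude, longitude and a path column naming a
    route in the config; an unknown path raises.
    """
    routes = config["routes"]
    out = {}
    for pid, row in populations.iterrows():
        path = row[path_column]
        if path not in routes:
            raise KeyError(f"population {pid!r}: no configured path {path!r}")
        out[pid] = routes[path].distance_to((row["latitude"], row["longitude"]))
    return pd.Series(out, name="distance_km")


@dataclass(frozen=True)
class PolarityResult:
    trait_id: str
    r: float
    p_value: float
    ancestral_state: str  # "absence" | "presence" | "inestimable"
    n: int
    significant: bool


def estimate_polarity(
    frequencies: pd.DataFrame,
    distances: Mapping[str, float] | pd.Series,
    alpha: float = 0.05,
    outgroup: pd.Series | None = None,
    method: str = "pearson",
) -> list[PolarityResult]:
    """Correlate each trait's presence frequency with routed distance.

    ``frequencies`` is populations x traits (values in [0, 1], NaN where
    a trait is unscored); ``distances`` gives each population's routed
    distance from the origin.  ``outgroup``, if given, is a per-trait
    frequency series appended as one pooled data point at distance 0.
    A positive correlation marks absence as ancestral, a negative one
    presence; traits observed in fewer than three populations are
    flagged inestimable.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    distances = pd.Series(distances)
    results = []
    for trait in frequencies.columns:
        f = frequencies[trait]
        d = distances.reindex(f.index)
        keep = f.notna() & d.notna()
        x = list(d[keep])
        y = list(f[keep])
        if outgroup is not None and trait in outgroup.index and pd.notna(outgroup[trait]):
            x.append(0.0)
            y.append(float(outgroup[trait]))
        n = len(x)
        if n < 3 or len(set(y)) < 2 or len(set(x)) < 2:
            results.append(
                PolarityResult(trait, math.nan, math.nan, "inestimable", n, False)
            )
            continue
        r, p = corr(x, y)
        r, p = float(r), float(p)
        state = "presence" if r < 0 else "absence"
        results.append(PolarityResult(trait, r, p, state, n, bool(p < alpha)))
    return results


def filter_polarized_traits(
    results: Sequence[PolarityResult], alpha: float = 0.05
) -> list[str]:
    """Trait ids whose polarity estimate is significant at ``alpha``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return [
        r.trait_id
        for r in results
        if r.ancestral_state != "inestimable" and r.p_value < alpha
    ]


def results_to_frame(results: Sequence[PolarityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trait": [r.trait_id for r in results],
            "r": [r.r for r in results],
            "p": [r.p_value for r in results],
            "ancestral_state": [r.ancestral_state for r in results],
            "n": [r.n for r in results],
            "retained": [r.significant for r in results],
        }
    )
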