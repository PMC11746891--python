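"""Zone-based serve-accuracy scoring from 2D bounce coordinates.

Coordinates live in a side-local court frame: the origin is the "T" of the
correct (diagonally opposite) service box — the intersection of the service
line and the centre service line — with x pointing toward the net along the
centre service line and y toward the singles sideline of that box. In this
frame the deuce and ad boxes coincide, so one zone layout serves both sides;
side-specific layouts remain possible because every scoring call carries the
side.

A bounce scores 0 if it misses the correct service box; inside the box it
receives the point value (9, 6, 3 or 1) of the region containing it, and 1
if no configured region covers it. Lines count as in (tennis rules), and a
point on a shared region boundary belongs to the higher-valued region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from shapely.geometry import Point, Polygon, box as shapely_box
from shapely.prepared import prep

__all__ = [
    "SCORE_VALUES",
    "ZoneConfig",
    "ScoredRegion",
    "BouncePoint",
    "load_zone_config",
    "default_zone_config",
    "in_service_box",
    "score_bounce",
    "sample_bounce_for_score",
]

#: Closed point scale: region values plus the 0 awarded outside the box.
SCORE_VALUES = (0, 1, 3, 6, 9)
_REGION_VALUES = (1, 3, 6, 9)

SERVE_TYPES = ("first", "second")
TARGETS = ("T", "body", "wide")
SIDES = ("deuce", "ad")

_OVERLAP_TOL_M2 = 1e-9


@dataclass(frozen=True)
class BouncePoint:
    """Ball bounce location in the side-local court frame (metres)."""

    x_m: float
    y_m: float
    side: str = "deuce"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_m) and np.isfinite(self.y_m)):
            raise ValueError("bounce coordinates must be finite")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}; expected one of {SIDES}")


@dataclass(frozen=True)
class ScoredRegion:
    region_id: str
    points_value: int
    polygon: Polygon


class ZoneConfig:
    """Validated target-zone geometry for every (serve type, target) context."""

    def __init__(self, box_depth_m: float, box_width_m: float,
                 zones: Mapping[tuple[str, str], list[ScoredRegion]],
                 source: str = "<dict>") -> None:
        self.box_depth_m = float(box_depth_m)
        self.box_width_m = float(box_width_m)
        self.zones = dict(zones)
        self.source = source
        self.service_box = shapely_box(0.0, 0.0, self.box_depth_m, self.box_width_m)
        self._validate()
        self._prepared = {key: [(r, prep(r.polygon)) for r in regions]
                          for key, regions in self.zones.items()}

    def _validate(self) -> None:
        if self.box_depth_m <= 0 or self.box_width_m <= 0:
            raise ValueError("service-box dimensions must be positive")
        for st in SERVE_TYPES:
            for tg in TARGETS:
                if (st, tg) not in self.zones:
                    raise ValueError(f"zone config lacks context ({st}, {tg})")
        for (st, tg), regions in self.zones.items():
            if st not in SERVE_TYPES or tg not in TARGETS:
                raise ValueError(f"unknown scoring context ({st!r}, {tg!r})")
            for r in regions:
                if r.points_value not in _REGION_VALUES:
                    raise ValueError(
                        f"region {r.region_id!r}: point value {r.points_value} not in "
                        f"{_REGION_VALUES} (the point scale is closed)")
                if not r.polygon.is_valid or r.polygon.is_empty:
                    raise ValueError(f"region {r.region_id!r}: invalid or empty polygon")
                if not self.service_box.covers(r.polygon):
                    raise ValueError(
                        f"region {r.region_id!r} extends outside the service box")
            for i, a in enumerate(regions):
                for b in regions[i + 1:]:
                    if a.polygon.intersection(b.polygon).area > _OVERLAP_TOL_M2:
                        raise ValueError(
                            f"overlapping regions in context ({st}, {tg}): "
                            f"{a.region_id!r} and {b.region_id!r}")

    def regions(self, serve_type: str, target: str) -> list[ScoredRegion]:
        try:
            return self.zones[(serve_type, target)]
        except KeyError:
            raise ValueError(
                f"unknown scoring context ({serve_type!r}, {target!r})") from None

    def mirrored(self) -> "ZoneConfig":
        """Config reflected across the centre service line (y -> width - y)."""
        zones = {}
        for key, regions in self.zones.items():
            zones[key] = [ScoredRegion(
                r.region_id, r.points_value,
                Polygon([(x, self.box_width_m - y) for x, y in r.polygon.exterior.coords]))
                for r in regions]
        return ZoneConfig(self.box_depth_m, self.box_width_m, zones,
                          source=f"mirror({self.source})")

    def to_dict(self) -> dict:
        ctx: dict[str, dict] = {st: {} for st in SERVE_TYPES}
        for (st, tg), regions in self.zones.items():
            ctx[st][tg] = [{"id": r.region_id, "points": r.points_value,
                            "polygon": [list(xy) for xy in r.polygon.exterior.coords[:-1]]}
                           for r in regions]
        return {"frame": {"origin": "T of the receiving service box",
                          "x_axis": "toward the net along the centre service line",
                          "y_axis": "toward the singles sideline"},
                "service_box": {"depth_m": self.box_depth_m, "width_m": self.box_width_m},
                "zones": ctx}


def _parse_regions(items: Iterable[Mapping], context: str) -> list[ScoredRegion]:
    regions = []
    for item in items:
        for k in ("id", "points", "polygon"):
            if k not in item:
                raise ValueError(f"region in context {context} lacks key {k!r}")
        poly = Polygon([tuple(map(float, xy)) for xy in item["polygon"]])
        regions.append(ScoredRegion(str(item["id"]), int(item["points"]), poly))
    return regions


def load_zone_config(document: Mapping | str | Path) -> ZoneConfig:
    """Load and validate a zone configuration from a JSON file or dict."""
    if isinstance(document, (str, Path)):
        source = str(document)
        with open(document) as fh:
            document = json.load(fh)
    else:
        source = "<dict>"
    if "service_box" not in document or "zones" not in document:
        raise ValueError("zone config must define 'service_box' and 'zones'")
    sb = document["service_box"]
    zones: dict[tuple[str, str], list[ScoredRegion]] = {}
    for st, targets in document["zones"].items():
        for tg, items in targets.items():
            zones[(st, tg)] = _parse_regions(items, f"({st}, {tg})")
    return ZoneConfig(sb["depth_m"], sb["width_m"], zones, source=source)


def default_zone_config() -> ZoneConfig:
    """The packaged default geometry.

    SYNTHETIC layout: plausible rectangular 9/6/3 regions near each aiming
    target with second-serve regions shifted toward the net for net
    clearance. It is a stand-in for coach-defined target areas, which are
    not standardised; real analyses should supply their own geometry.
    """
    ref = resources.files("servechain").joinpath("data/default_zones.json")
    with resources.as_file(ref) as path:
        return load_zone_config(path)


def in_service_box(p: BouncePoint, config: ZoneConfig) -> bool:
    """True iff the bounce lies in the correct service box, lines included."""
    return bool(0.0 <= p.x_m <= config.box_depth_m and 0.0 <= p.y_m <= config.box_width_m)


def score_bounce(p: BouncePoint, serve_type: str, target: str,
                 config: ZoneConfig) -> int:
    """Accuracy points for one bounce: 0 out of the box, else the zone value.

    Regions are checked in descending point order so shared boundaries
    resolve to the higher value; uncovered in-box area scores 1.
    """
    regions = config.regions(serve_type, target)  # validates the context
    if not in_service_box(p, config):
        return 0
    pt = Point(p.x_m, p.y_m)
    best = 1
    for region, prepared in sorted(config._prepared[(serve_type, target)],
                                   key=lambda rp: -rp[0].points_value):
        if prepared.intersects(pt) and region.polygon.covers(pt):
            return region.points_value
    return best


def sample_bounce_for_score(score: int, serve_type: str, target: str,
                            config: ZoneConfig, rng: np.random.Generator,
                            side: str = "deuce",
                            max_tries: int = 10_000) -> BouncePoint:
    """Draw a bounce location that scores exactly ``score``.

    For 0 the point is placed beyond the service line (a long serve); for
    positive values a uniform in-box point is rejection-sampled until the
    scoring function returns the requested value.
    """
    if score not in SCORE_VALUES:
        raise ValueError(f"score {score} not in {SCORE_VALUES}")
    if score == 0:
        return BouncePoint(float(rng.uniform(-1.5, -0.05)),
                           float(rng.uniform(0.0, config.box_width_m)), side)
    for _ in range(max_tries):
        p = BouncePoint(float(rng.uniform(0.0, config.box_depth_m)),
                        float(rng.uniform(0.0, config.box_width_m)), side)
        if score_bounce(p, serve_type, target, config) == score:
            return p
    raise RuntimeError(
        f"could not sample a bounce scoring {score} in context ({serve_type}, {target}); "
        "is the corresponding region vanishingly small?")
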