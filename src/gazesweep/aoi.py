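"""Areas of interest: the 12-segment room-wall layout and target regions.

The searched room is modelled as a closed wall loop unwrapped onto a
plane: azimuth runs from -180 deg (left of the door) to +180 deg (right
of the door), elevation spans the vertical extent of the walls.  The 12
ordered wall segments tile this band; segment 1 is the first area on the
left just inside the door and segment 12 the last area on the right, by
the door.  Target regions (where threats can appear) are smaller
polygons overlaid on the segments.

Role tags mark the segments relevant to the trained search order:
``near_corner`` (the corners next to the door, segments 1 and 12 by
default) and ``back_wall`` (the wall opposite the door, segments 6 and 7
by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from shapely.geometry import Point, Polygon, box

__all__ = ["AOI", "AOILayout", "default_room_layout"]


@dataclass(frozen=True)
class AOI:
    aoi_id: object
    polygon: Polygon
    role: str = "segment"  # "segment" or "target"


@dataclass
class AOILayout:
    """Ordered wall segments plus target regions, with role tags.

    near_corner / back_wall reference segment ids; entry_point is the
    gaze direction of the doorway at room entry (degrees).
    """

    aois: list
    near_corner: tuple = ()
    back_wall: tuple = ()
    entry_point: tuple = (180.0, 0.0)

    def __post_init__(self):
        ids = [a.aoi_id for a in self.aois]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate AOI ids")
        known = set(ids)
        for tag, members in (("near_corner", self.near_corner), ("back_wall", self.back_wall)):
            for m in members:
                if m not in known:
                    raise ValueError(f"{tag} tag references unknown AOI id {m!r}")

    @property
    def segments(self) -> list:
        return [a for a in self.aois if a.role == "segment"]

    @property
    def targets(self) -> list:
        return [a for a in self.aois if a.role == "target"]

    @property
    def segment_ids(self) -> list:
        return [a.aoi_id for a in self.segments]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def locate(self, az: float, el: float, targets_first: bool = False) -> Optional[object]:
        """Return the id of the AOI containing the point, or None.

        AOIs are tested in listed (id) order so a point on a shared
        boundary is assigned to the lower-numbered AOI.  With
        ``targets_first`` target polygons take precedence over the wall
        segments they overlap.
        """
        p = Point(az, el)
        pools = (self.targets, self.segments) if targets_first else (self.aois,)
        for pool in pools:
            for a in pool:
                if a.polygon.covers(p):
                    return a.aoi_id
        return None

    def in_target(self, az: float, el: float) -> bool:
        p = Point(az, el)
        return any(a.polygon.covers(p) for a in self.targets)

    def role_of(self, aoi_id) -> Optional[str]:
        if aoi_id in self.near_corner:
            return "near_corner"
        if aoi_id in self.back_wall:
            return "back_wall"
        return None

    # --- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "aois": [
                {
                    "id": a.aoi_id,
                    "role": a.role,
                    "polygon": [list(xy) for xy in a.polygon.exterior.coords[:-1]],
                }
                for a in self.aois
            ],
            "near_corner": list(self.near_corner),
            "back_wall": list(self.back_wall),
            "entry_point": list(self.entry_point),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AOILayout":
        aois = [
            AOI(a["id"], Polygon(a["polygon"]), a.get("role", "segment"))
            for a in d["aois"]
        ]
        return cls(
            aois=aois,
            near_corner=tuple(d.get("near_corner", ())),
            back_wall=tuple(d.get("back_wall", ())),
            entry_point=tuple(d.get("entry_point", (180.0, 0.0))),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AOILayout":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_room_layout(
    n_segments: int = 12,
    elevation_span: tuple = (-15.0, 15.0),
    n_targets: int = 2,
) -> AOILayout:
    """Build the canonical unwrapped room layout.

    ``n_segments`` equal-width wall segments tile azimuth [-180, 180];
    targets are person-sized rectangles centred in segments spread over
    the room interior (by default segments 4 and 9).
    """
    if n_segments < 2:
        raise ValueError("layout needs at least 2 segments")
    lo, hi = elevation_span
    width = 360.0 / n_segments
    aois = []
    for i in range(n_segments):
        x0 = -180.0 + i * width
        aois.append(AOI(i + 1, box(x0, lo, x0 + width, hi), role="segment"))
    # target regions: centred horizontally in their host segment,
    # roughly torso-sized in angular terms at room-clearance distances
    target_hosts = [int(round((k + 1) * n_segments / (n_targets + 1))) for k in range(n_targets)]
    for k, host in enumerate(target_hosts):
        cx = -180.0 + (host - 0.5) * width
        aois.append(AOI(f"target_{k + 1}", box(cx - 4.0, lo * 0.5, cx + 4.0, hi * 0.5), role="target"))
    near = (1, n_segments)
    back = (n_segments // 2, n_segments // 2 + 1)
    return AOILayout(aois=aois, near_corner=near, back_wall=back, entry_point=(180.0, 0.0))
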