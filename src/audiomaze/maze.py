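"""Maze geometry: rooms, wall segments, and proximity queries.

A maze is a set of wall segments inside a rectangular room (the study room
is 8 x 9 m).  Corridor-style mazes are generated from axis-aligned
centerline polylines offset to both sides; a designated exit segment caps
the far end of the corridor.  All coordinates are metres, origin at a room
corner, x rightward, y upward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString

Segment = tuple[tuple[float, float], tuple[float, float]]

#: Default corridor width (m); comfortably above the 0.8 m passability floor.
CORRIDOR_WIDTH = 1.2


class UnknownShapeError(KeyError):
    """Requested maze shape is not in the built-in catalogue."""


@dataclass
class MazeSpec:
    """Wall layout of one maze inside a rectangular room.

    Parameters
    ----------
    room_width, room_height : float
        Room extent in metres.
    walls : list of segments
        Each segment is a pair of (x, y) endpoints.
    shape_id : str
        Catalogue label or user-supplied name.
    start_position : (float, float)
        Agent start point, inside the corridor mouth.
    start_heading : float
        Initial heading in radians (0 = +x, counter-clockwise positive).
    exit_segment : segment or None
        Crossing this segment ends a trial.
    """

    room_width: float = 8.0
    room_height: float = 9.0
    walls: list[Segment] = field(default_factory=list)
    shape_id: str = "custom"
    start_position: tuple[float, float] = (4.0, 1.0)
    start_heading: float = np.pi / 2
    exit_segment: Segment | None = None

    def __post_init__(self) -> None:
        for seg in self.walls:
            for (x, y) in seg:
                if not (0.0 <= x <= self.room_width and 0.0 <= y <= self.room_height):
                    raise ValueError(
                        f"wall endpoint ({x}, {y}) outside room "
                        f"[0, {self.room_width}] x [0, {self.room_height}]"
                    )
        # vectorized wall arrays for the per-step hot path
        if self.walls:
            self._A = np.asarray([s[0] for s in self.walls], dtype=float)
            self._B = np.asarray([s[1] for s in self.walls], dtype=float)
            self._AB = self._B - self._A
            self._len2 = np.maximum((self._AB**2).sum(axis=1), 1e-300)
        else:
            self._A = np.zeros((0, 2))
            self._B = np.zeros((0, 2))
            self._AB = np.zeros((0, 2))
            self._len2 = np.zeros(0)

    # -- queries ----------------------------------------------------------

    def wall_distances(self, points) -> np.ndarray:
        """Minimum point-to-wall distance for one point or an (k, 2) array."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if len(self._A) == 0:
            return np.full(len(pts), np.inf)
        ap = pts[:, None, :] - self._A[None, :, :]  # (k, n, 2)
        t = np.clip((ap * self._AB[None]).sum(-1) / self._len2[None], 0.0, 1.0)
        closest = self._A[None] + t[..., None] * self._AB[None]
        return np.hypot(*(pts[:, None, :] - closest).transpose(2, 0, 1)).min(axis=1)

    def wall_distance(self, point) -> float:
        """Minimum distance from ``point`` to any wall segment (inf if no walls)."""
        return float(self.wall_distances(point)[0])

    def nearest_wall(self, point) -> tuple[float, np.ndarray]:
        """Distance to the closest wall and the unit direction toward it."""
        p = np.asarray(point, dtype=float)
        if len(self._A) == 0:
            return float("inf"), np.zeros(2)
        ap = p[None, :] - self._A
        t = np.clip((ap * self._AB).sum(-1) / self._len2, 0.0, 1.0)
        closest = self._A + t[:, None] * self._AB
        d = np.hypot(*(p[None, :] - closest).T)
        i = int(np.argmin(d))
        if d[i] == 0:
            return 0.0, np.zeros(2)
        return float(d[i]), (closest[i] - p) / d[i]

    def first_wall_hit(self, p0, direction, max_dist: float) -> float:
        """Distance along ``direction`` from p0 to the first wall, capped at max_dist.

        Returns ``max_dist`` when no wall lies within reach.  Walls exactly
        parallel to the ray are ignored (grazing contact has measure zero
        and is handled by the proximity queries).
        """
        p0 = np.asarray(p0, dtype=float)
        d = np.asarray(direction, dtype=float)
        n = np.hypot(*d)
        if n == 0 or len(self._A) == 0:
            return float(max_dist)
        u = d / n
        w = self._A - p0[None, :]
        denom = u[0] * self._AB[:, 1] - u[1] * self._AB[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (w[:, 0] * self._AB[:, 1] - w[:, 1] * self._AB[:, 0]) / denom
            t = (u[0] * w[:, 1] - u[1] * w[:, 0]) / -denom
        hit = (np.abs(denom) > 1e-12) & (t >= 0.0) & (t <= 1.0) & (s >= 0.0) & (s <= max_dist)
        return float(s[hit].min()) if hit.any() else float(max_dist)

    def crosses_wall(self, p0, p1) -> bool:
        """True if the segment p0->p1 intersects any wall segment."""
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        d = float(np.hypot(*(p1 - p0)))
        if d == 0:
            return bool(self.wall_distance(p0) == 0.0)
        return self.first_wall_hit(p0, p1 - p0, d) < d

    def crossed_exit(self, p0, p1) -> bool:
        if self.exit_segment is None:
            return False
        return LineString([tuple(p0), tuple(p1)]).intersects(LineString(self.exit_segment))

    # -- (de)serialization ------------------------------------------------

    def to_json(self) -> str:
        obj = {
            "shape_id": self.shape_id,
            "room": [self.room_width, self.room_height],
            "walls": [[list(a), list(b)] for a, b in self.walls],
            "start": [*self.start_position, self.start_heading],
            "exit": (
                [list(self.exit_segment[0]), list(self.exit_segment[1])]
                if self.exit_segment is not None
                else None
            ),
        }
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MazeSpec":
        obj = json.loads(text)
        exit_seg = obj.get("exit")
        return cls(
            room_width=obj["room"][0],
            room_height=obj["room"][1],
            walls=[(tuple(a), tuple(b)) for a, b in obj["walls"]],
            shape_id=obj["shape_id"],
            start_position=tuple(obj["start"][:2]),
            start_heading=obj["start"][2],
            exit_segment=(tuple(map(tuple, exit_seg)) if exit_seg else None),
        )


def wall_touch_query(
    point, maze: MazeSpec, threshold: float = 0.05
) -> tuple[bool, float]:
    """Is ``point`` within ``threshold`` of a wall?  Returns (flag, min distance)."""
    d = maze.wall_distance(tuple(point))
    return (d <= threshold, d)


# ---------------------------------------------------------------------------
# corridor construction from axis-aligned centerlines


def _offset_polyline(points: np.ndarray, half_width: float, side: int) -> np.ndarray:
    """Offset an axis-aligned polyline by half_width to one side (miter corners)."""
    pts = np.asarray(points, dtype=float)
    segs = np.diff(pts, axis=0)
    lens = np.hypot(segs[:, 0], segs[:, 1])
    units = segs / lens[:, None]
    # left normal of each segment, flipped for side=-1 (right)
    normals = np.stack([-units[:, 1], units[:, 0]], axis=1) * side
    out = [pts[0] + normals[0] * half_width]
    for i in range(1, len(pts) - 1):
        # right-angle miter: sum of adjacent normals lands on the corner offset
        miter = normals[i - 1] + normals[i]
        out.append(pts[i] + miter * half_width)
    out.append(pts[-1] + normals[-1] * half_width)
    return np.asarray(out)


def _corridor_maze(
    shape_id: str,
    centerline: list[tuple[float, float]],
    room: tuple[float, float],
    width: float = CORRIDOR_WIDTH,
) -> MazeSpec:
    pts = np.asarray(centerline, dtype=float)
    half = width / 2.0
    left = _offset_polyline(pts, half, +1)
    right = _offset_polyline(pts, half, -1)
    walls: list[Segment] = []
    for poly in (left, right):
        for a, b in zip(poly[:-1], poly[1:]):
            walls.append((tuple(a), tuple(b)))
    # cap the entrance so the agent cannot back out of the corridor
    walls.append((tuple(left[0]), tuple(right[0])))
    exit_seg: Segment = (tuple(left[-1]), tuple(right[-1]))
    u0 = pts[1] - pts[0]
    heading = float(np.arctan2(u0[1], u0[0]))
    start = pts[0] + u0 / np.hypot(*u0) * 0.5
    return MazeSpec(
        room_width=room[0],
        room_height=room[1],
        walls=walls,
        shape_id=shape_id,
        start_position=(float(start[0]), float(start[1])),
        start_heading=heading,
        exit_segment=exit_seg,
    )


_CATALOGUE = {
    "straight": [(4.0, 0.5), (4.0, 8.5)],
    "L": [(1.5, 0.5), (1.5, 7.5), (7.0, 7.5)],
    "Z": [(1.5, 0.5), (1.5, 4.5), (6.5, 4.5), (6.5, 8.5)],
    "U": [(1.5, 0.5), (1.5, 8.0), (6.5, 8.0), (6.5, 0.5)],
}


def build_maze(
    shape_id: str,
    room: tuple[float, float] = (8.0, 9.0),
    walls: list[Segment] | None = None,
    width: float = CORRIDOR_WIDTH,
) -> MazeSpec:
    """Build a maze from the corridor catalogue or a user wall list.

    Catalogue ids: ``straight``, ``L``, ``Z``, ``U`` — corridor mazes whose
    centerlines bend 0, 1, 2 and 2 times respectively, all at least 0.8 m
    wide.  A user wall list bypasses the catalogue (shape_id is kept as a
    label); walls must lie within the room.
    """
    if walls is not None:
        return MazeSpec(
            room_width=room[0], room_height=room[1], walls=walls, shape_id=shape_id
        )
    if shape_id not in _CATALOGUE:
        raise UnknownShapeError(
            f"unknown maze shape {shape_id!r}; catalogue: {sorted(_CATALOGUE)}"
        )
    if width < 0.8:
        raise ValueError("corridor width must be at least 0.8 m")
    return _corridor_maze(shape_id, _CATALOGUE[shape_id], room, width)
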