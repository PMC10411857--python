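"""Boundary partitioning and spot-to-boundary distance measurement.

The drawn leader-cell outline is split at four user-clicked anchor points
into the nuclear, side1, invasive and side2 segments (clockwise starting at
the nuclear side).  Each in-outline spot then receives its nearest Euclidean
distance to each segment.  Distances are computed in the x-y plane: the
outline is drawn on one slice and applied through the whole stack, so the
boundary is a vertical prism wall and the 3D distance to it equals the
planar one.  "Clockwise" is defined by the shoelace sign of the (x, y)
vertex sequence (negative signed area).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Point

from .errors import (
    AnchorOrderError,
    DegenerateSegmentError,
    DuplicateAnchorError,
    PolygonOutsideImageError,
)
from .spot_detection import Spot
from .stack_io import ChannelStack, RoiPolygon

SEGMENT_ROLES = ("nuclear", "side1", "invasive", "side2")


@dataclass
class BoundaryPartition:
    """The cell outline partitioned into the four named segments.

    ``polygon`` is clockwise-normalised; ``anchors`` are four vertex indices
    in strictly clockwise cyclic order starting at the nuclear side;
    ``segments`` maps each role to its ``(k, 2)`` polyline.  The segments
    tile the closed outline exactly once, sharing only the anchor vertices.
    """

    polygon: RoiPolygon
    anchors: tuple[int, int, int, int]
    segments: dict[str, np.ndarray]

    def to_json(self, path: str | Path) -> Path:
        """Serialise the partition for provenance."""
        payload = {
            "vertices": self.polygon.vertices.tolist(),
            "anchors": list(self.anchors),
            "segments": {k: v.tolist() for k, v in self.segments.items()},
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "BoundaryPartition":
        d = json.loads(Path(path).read_text())
        return cls(polygon=RoiPolygon(np.asarray(d["vertices"], dtype=float)),
                   anchors=tuple(d["anchors"]),
                   segments={k: np.asarray(v, dtype=float)
                             for k, v in d["segments"].items()})


@dataclass
class SpotDistanceRecord:
    """One spot with its nearest distance to each boundary segment."""

    spot: Spot
    d_nuclear: float
    d_side1: float
    d_invasive: float
    d_side2: float
    image_id: int = 0

    def distance(self, role: str) -> float:
        return {"nuclear": self.d_nuclear, "side1": self.d_side1,
                "invasive": self.d_invasive, "side2": self.d_side2}[role]


def orient_clockwise(polygon: RoiPolygon) -> RoiPolygon:
    """Return the polygon with clockwise vertex order (negative shoelace)."""
    if polygon.signed_area() > 0:
        return RoiPolygon(polygon.vertices[::-1].copy())
    return polygon


def snap_anchors(polygon: RoiPolygon,
                 clicks: Sequence[Sequence[float]]) -> BoundaryPartition:
    """Snap four boundary clicks to outline vertices and build the partition.

    Clicks need not land exactly on the outline: each snaps to the nearest
    polygon vertex.  They must be given clockwise, the first two bracketing
    the nuclear side; otherwise an :class:`AnchorOrderError` asks the user to
    re-click.  Either polygon orientation is accepted (normalised internally).
    """
    clicks = np.asarray(clicks, dtype=float)
    if clicks.shape != (4, 2):
        raise AnchorOrderError(
            f"need exactly 4 (x, y) click points, got shape {clicks.shape}")
    poly = orient_clockwise(polygon)
    verts = poly.vertices
    n = len(verts)
    idx = []
    for c in clicks:
        d2 = np.sum((verts - c) ** 2, axis=1)
        idx.append(int(np.argmin(d2)))
    if len(set(idx)) != 4:
        raise DuplicateAnchorError(
            f"two clicks snapped to the same outline vertex (indices {idx}); "
            "re-click further apart")
    a0 = idx[0]
    rel = [(i - a0) % n for i in idx]
    if not (0 == rel[0] < rel[1] < rel[2] < rel[3]):
        raise AnchorOrderError(
            "anchor clicks are not in clockwise order around the outline; "
            "re-click going clockwise starting from the nuclear side")

    segments: dict[str, np.ndarray] = {}
    for role, (start, stop) in zip(SEGMENT_ROLES,
                                   [(idx[0], idx[1]), (idx[1], idx[2]),
                                    (idx[2], idx[3]), (idx[3], idx[0])]):
        if start <= stop:
            seg = verts[start:stop + 1]
        else:
            seg = np.vstack([verts[start:], verts[:stop + 1]])
        segments[role] = seg.astype(float)
    return BoundaryPartition(polygon=poly, anchors=tuple(idx),
                             segments=segments)


def point_in_polygon(p: Sequence[float], polygon: RoiPolygon) -> bool:
    """Even-odd containment; points exactly on the outline count as inside."""
    return bool(shapely.covers(polygon.shapely(), Point(float(p[0]),
                                                        float(p[1]))))


def distance_to_segment(p: Sequence[float], segment: np.ndarray) -> float:
    """Nearest Euclidean distance from a point to a polyline, in the plane.

    Minimum over the segment's edges of the point-to-edge distance
    (perpendicular foot when it falls within the edge, else the nearer
    endpoint).
    """
    seg = np.asarray(segment, dtype=float)
    if len(seg) < 2:
        raise DegenerateSegmentError("segment needs >= 2 vertices")
    line = LineString(seg)
    if line.length == 0:
        raise DegenerateSegmentError("segment has zero length")
    return float(line.distance(Point(float(p[0]), float(p[1]))))


def measure_all_spots(spots: Sequence[Spot], partition: BoundaryPartition,
                      image_id: int = 0) -> list[SpotDistanceRecord]:
    """Attach the four segment distances to every in-outline spot.

    Spots whose (x, y) falls outside the outline are dropped (all z planes
    are retained: the outline applies through the whole stack).  Order
    follows the input spot order.
    """
    if not spots:
        return []
    pts = shapely.points(np.array([[s.x, s.y] for s in spots]))
    inside = shapely.covers(partition.polygon.shapely(), pts)
    dists = {role: shapely.distance(pts, LineString(seg))
             for role, seg in partition.segments.items()}
    records = []
    for i, (spot, ok) in enumerate(zip(spots, inside)):
        if not ok:
            continue
        records.append(SpotDistanceRecord(
            spot=spot,
            d_nuclear=float(dists["nuclear"][i]),
            d_side1=float(dists["side1"][i]),
            d_invasive=float(dists["invasive"][i]),
            d_side2=float(dists["side2"][i]),
            image_id=image_id))
    return records


def polygon_mask(polygon: RoiPolygon, shape_yx: tuple[int, int]) -> np.ndarray:
    """Rasterise the outline: True where the pixel center is inside/on it."""
    ny, nx = shape_yx
    yy, xx = np.mgrid[0:ny, 0:nx]
    pts = shapely.points(np.column_stack([xx.ravel(), yy.ravel()]).astype(float))
    inside = shapely.covers(polygon.shapely(), pts)
    return inside.reshape(ny, nx)


def apply_front_mask(stack: ChannelStack, polygon: RoiPolygon) -> ChannelStack:
    """Zero all signal outside the drawn front outline, across z and channels.

    Replicates the manual Fiji clearing step and provides the detection mask
    implicitly (the returned stack is zero outside the outline).
    """
    xs, ys = polygon.vertices[:, 0], polygon.vertices[:, 1]
    _, _, ny, nx = stack.voxels.shape
    if xs.max() < 0 or ys.max() < 0 or xs.min() > nx - 1 or ys.min() > ny - 1:
        raise PolygonOutsideImageError(
            "the outline lies entirely outside the image frame")
    mask2d = polygon_mask(polygon, (ny, nx))
    voxels = stack.voxels * mask2d[np.newaxis, np.newaxis, :, :]
    return ChannelStack(voxels=voxels, channel_map=dict(stack.channel_map),
                        voxel_size=stack.voxel_size)
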