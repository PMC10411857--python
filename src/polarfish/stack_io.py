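"""Image and table I/O for the polarity pipeline.

Reads multi-channel confocal z-stacks (TIFF), cell-outline polygons (ImageJ
``.roi`` or 2-column CSV) and writes the three per-image spot tables
("Spot Distances", "Spots1", "Spots2") in the fixed tab-delimited layout the
downstream analysis consumes.

The in-memory axis convention is always ``(channel, z, y, x)``; readers
normalise whatever axis order the file uses.  Channel roles follow the
acquisition order nuclear / cellmask / rna1 / rna2 by default but can be
remapped.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import (
    AmbiguousAxesError,
    ChannelCountError,
    MissingFileError,
    PolygonFormatError,
    SchemaError,
    SelfIntersectingPolygonError,
    TooFewVerticesError,
)

CHANNEL_ROLES = ("nuclear", "cellmask", "rna1", "rna2")

#: Acquisition-order default: DAPI, CellMask, then the two RNA channels.
DEFAULT_CHANNEL_MAP: dict[str, int] = {
    "nuclear": 0,
    "cellmask": 1,
    "rna1": 2,
    "rna2": 3,
}

#: Physical voxel extent (x, y, z) in micrometers; the recommended sampling
#: is about half the PSF width, i.e. ~0.1 x 0.1 x 0.3 um.
DEFAULT_VOXEL_SIZE: tuple[float, float, float] = (0.1, 0.1, 0.3)

#: Fixed header of the "Spot Distances" table.
SPOT_DISTANCE_COLUMNS = (
    "x", "y", "z", "d_nuclear", "d_side1", "d_invasive", "d_side2", "type",
)
SPOT_COLUMNS = ("x", "y", "z", "intensity")
POOLED_COLUMNS = SPOT_DISTANCE_COLUMNS + ("image",)


@dataclass
class ChannelStack:
    """A 4-channel 3D image with voxel-size metadata.

    ``voxels`` is indexed ``(channel, z, y, x)``; ``channel_map`` assigns the
    four roles (nuclear, cellmask, rna1, rna2) to channel indices;
    ``voxel_size`` is the physical extent of one voxel in (x, y, z)
    micrometers.
    """

    voxels: np.ndarray
    channel_map: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ChannelCountError(
                f"expected a (channel, z, y, x) array, got ndim={self.voxels.ndim}")
        if set(self.channel_map) != set(CHANNEL_ROLES):
            raise ChannelCountError(
                f"channel_map must cover exactly {CHANNEL_ROLES}, "
                f"got {sorted(self.channel_map)}")
        idx = sorted(self.channel_map.values())
        if len(set(idx)) != 4:
            raise ChannelCountError("channel_map indices must be distinct")
        if self.voxels.shape[0] < 4:
            raise ChannelCountError(
                f"need >= 4 channels, file has {self.voxels.shape[0]}")
        if max(idx) >= self.voxels.shape[0]:
            raise ChannelCountError(
                f"channel index {max(idx)} out of range for "
                f"{self.voxels.shape[0]} channels")
        if any(s < 1 for s in self.voxels.shape[1:]):
            raise ChannelCountError("all spatial dimensions must be >= 1")
        if np.issubdtype(self.voxels.dtype, np.floating):
            if not np.all(np.isfinite(self.voxels)):
                raise ValueError("intensities must be finite")
            if self.voxels.min() < 0:
                raise ValueError("intensities must be non-negative")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive floats, got {vs}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def channel(self, role: str) -> np.ndarray:
        """Return the 3D ``(z, y, x)`` volume for a channel role."""
        return self.voxels[self.channel_map[role]]


@dataclass
class RoiPolygon:
    """A closed cell-outline polygon in pixel coordinates.

    Vertices are ordered ``(x, y)`` pairs; the outline is implicitly closed
    (the first vertex is not repeated).  Simple-polygon validity is enforced
    at construction.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise PolygonFormatError(
                f"vertices must be an (n, 2) array, got shape {v.shape}")
        if len(v) >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]  # tolerate explicitly closed input
        if len(v) < 3:
            raise TooFewVerticesError(
                f"a polygon needs >= 3 vertices, got {len(v)}")
        dup = np.all(v == np.roll(v, -1, axis=0), axis=1)
        if dup.any():
            raise SelfIntersectingPolygonError(
                f"consecutive duplicate vertex at index {int(np.argmax(dup))}")
        if not _ShapelyPolygon(v).is_valid:
            raise SelfIntersectingPolygonError(
                "cell outline is self-intersecting")
        self.vertices = v

    def __len__(self) -> int:
        return len(self.vertices)

    def signed_area(self) -> float:
        """Shoelace signed area; negative means clockwise (y-up convention)."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def _normalize_axes(data: np.ndarray, axes: str,
                    axis_order: str | None) -> np.ndarray:
    """Reorder an on-disk array to (C, Z, Y, X)."""
    axes = (axis_order or axes or "").upper().replace("S", "C")
    if axis_order is None and any(a not in "CZYX" for a in axes):
        raise AmbiguousAxesError(
            f"cannot interpret TIFF axes {axes!r}; pass axis_order explicitly")
    if len(axes) != data.ndim or sorted(axes) != sorted(set(axes)):
        raise AmbiguousAxesError(
            f"axes {axes!r} do not describe a {data.ndim}-D array")
    if "C" not in axes or "Y" not in axes or "X" not in axes:
        raise AmbiguousAxesError(f"axes {axes!r} lack C/Y/X")
    if "Z" not in axes:
        data = data[np.newaxis]
        axes = "Z" + axes
    order = [axes.index(a) for a in "CZYX"]
    return np.transpose(data, order)


def _voxel_size_from_tiff(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Pull (x, y, z) voxel size in um from ImageJ/resolution metadata."""
    z = None
    if tf.imagej_metadata:
        z = tf.imagej_metadata.get("spacing")
    page = tf.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        x = xres[1] / xres[0]
        y = yres[1] / yres[0]
    except (KeyError, ZeroDivisionError):
        return None
    if z is None:
        return None
    return (float(x), float(y), float(z))


def read_stack(path: str | Path,
               channel_map: Mapping[str, int] | None = None,
               voxel_size: Sequence[float] | None = None,
               axis_order: str | None = None) -> ChannelStack:
    """Read a multi-channel z-stack TIFF into a :class:`ChannelStack`.

    Axes are normalised to ``(channel, z, y, x)`` from whatever order the
    file declares (``CZYX``, ``ZCYX``, ``ZYXC`` ...).  ``axis_order``
    overrides undeclared or ambiguous axis metadata.  ``voxel_size`` falls
    back to file metadata, then to the 0.1 x 0.1 x 0.3 um default.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such image file: {path}")
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        voxels = _normalize_axes(data, series.axes, axis_order)
        meta_vs = _voxel_size_from_tiff(tf)
    if voxels.shape[0] < 4:
        raise ChannelCountError(
            f"{path.name}: need >= 4 channels, found {voxels.shape[0]}")
    vs = tuple(voxel_size) if voxel_size is not None else (meta_vs or DEFAULT_VOXEL_SIZE)
    cm = dict(channel_map) if channel_map is not None else dict(DEFAULT_CHANNEL_MAP)
    return ChannelStack(voxels=voxels, channel_map=cm, voxel_size=vs)


def write_stack(stack: ChannelStack, path: str | Path) -> Path:
    """Write a ChannelStack as a CZYX TIFF with voxel-size metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    x, y, z = stack.voxel_size
    tifffile.imwrite(
        path, stack.voxels,
        photometric="minisblack",
        metadata={"axes": "CZYX", "spacing": z, "unit": "um"},
        resolution=(1.0 / x, 1.0 / y),
    )
    return path


# ---------------------------------------------------------------------------
# Cell-outline polygons (ImageJ .roi and CSV)
# ---------------------------------------------------------------------------

_ROI_POLYGON, _ROI_FREEHAND = 0, 7
_ROI_SUBPIXEL = 128  # options bit


def _read_imagej_roi(raw: bytes) -> np.ndarray:
    if raw[:4] != b"Iout":
        raise PolygonFormatError("not an ImageJ .roi file (bad magic)")
    roi_type = raw[6]
    if roi_type not in (_ROI_POLYGON, _ROI_FREEHAND):
        raise PolygonFormatError(
            f"unsupported ROI type {roi_type}; only POLYGON/FREEHAND outlines "
            "are accepted")
    top, left, _bottom, _right = struct.unpack(">4h", raw[8:16])
    n = struct.unpack(">h", raw[16:18])[0]
    options = struct.unpack(">h", raw[50:52])[0]
    if options & _ROI_SUBPIXEL and len(raw) >= 64 + 4 * n + 8 * n:
        off = 64 + 4 * n
        xs = np.frombuffer(raw, ">f4", n, off).astype(float)
        ys = np.frombuffer(raw, ">f4", n, off + 4 * n).astype(float)
    else:
        xs = np.frombuffer(raw, ">i2", n, 64).astype(float) + left
        ys = np.frombuffer(raw, ">i2", n, 64 + 2 * n).astype(float) + top
    return np.column_stack([xs, ys])


def write_polygon_roi(polygon: RoiPolygon, path: str | Path) -> Path:
    """Write an outline as an ImageJ POLYGON ``.roi`` file.

    Integer pixel coordinates are stored in the classic int16 block; if any
    vertex is non-integral the sub-pixel float block is written as well, so
    the round-trip is exact in both cases.
    """
    v = polygon.vertices
    n = len(v)
    left, top = int(np.floor(v[:, 0].min())), int(np.floor(v[:, 1].min()))
    right, bottom = int(np.ceil(v[:, 0].max())), int(np.ceil(v[:, 1].max()))
    subpixel = not np.allclose(v, np.round(v))
    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 228)          # version
    header[6] = _ROI_POLYGON
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    if subpixel:
        struct.pack_into(">h", header, 50, _ROI_SUBPIXEL)
    xi = (np.round(v[:, 0]).astype(int) - left).astype(">i2")
    yi = (np.round(v[:, 1]).astype(int) - top).astype(">i2")
    payload = xi.tobytes() + yi.tobytes()
    if subpixel:
        payload += v[:, 0].astype(">f4").tobytes() + v[:, 1].astype(">f4").tobytes()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_bytes(bytes(header) + payload)
    return path


def _read_polygon_csv(path: Path) -> np.ndarray:
    rows: list[tuple[float, float]] = []
    for i, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = [p for p in line.replace(",", " ").split() if p]
        if len(parts) < 2:
            raise PolygonFormatError(
                f"{path.name} line {i + 1}: expected two columns (x, y)")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if i == 0:
                continue  # header line
            raise PolygonFormatError(
                f"{path.name} line {i + 1}: non-numeric coordinate {parts!r}")
    return np.asarray(rows, dtype=float).reshape(-1, 2)


def read_polygon(path: str | Path) -> RoiPolygon:
    """Load a cell outline from an ImageJ ``.roi`` file or a 2-column CSV."""
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such outline file: {path}")
    if path.suffix.lower() == ".roi":
        verts = _read_imagej_roi(path.read_bytes())
    elif path.suffix.lower() in (".csv", ".txt"):
        verts = _read_polygon_csv(path)
    else:
        raise PolygonFormatError(
            f"unknown outline format {path.suffix!r}; use .roi or .csv")
    return RoiPolygon(verts)


def write_polygon_csv(polygon: RoiPolygon, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["x,y"] + [f"{x:.6g},{y:.6g}" for x, y in polygon.vertices]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Spot tables
# ---------------------------------------------------------------------------

def _distance_frame(records: Iterable, scale_xy: float, scale_z: float
                    ) -> pd.DataFrame:
    rows = [{
        "x": r.spot.x * scale_xy, "y": r.spot.y * scale_xy,
        "z": r.spot.z * scale_z,
        "d_nuclear": r.d_nuclear * scale_xy, "d_side1": r.d_side1 * scale_xy,
        "d_invasive": r.d_invasive * scale_xy, "d_side2": r.d_side2 * scale_xy,
        "type": r.spot.type,
    } for r in records]
    return pd.DataFrame(rows, columns=list(SPOT_DISTANCE_COLUMNS))


def write_spot_tables(records: Sequence, spots1: Sequence, spots2: Sequence,
                      out_dir: str | Path, units: str = "px",
                      voxel_size: Sequence[float] | None = None,
                      ) -> tuple[Path, Path, Path]:
    """Write "Spot Distances", "Spots1" and "Spots2" tab-delimited tables.

    ``records`` are :class:`~polarfish.cell_geometry.SpotDistanceRecord` in
    detection order; ``spots1``/``spots2`` list the per-type detected spots
    with intensities.  ``units`` is ``"px"`` (default) or ``"um"``; the
    micrometer conversion uses ``voxel_size`` (x, y, z).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if units == "px":
        sxy = sz = 1.0
    elif units == "um":
        vs = tuple(voxel_size) if voxel_size is not None else DEFAULT_VOXEL_SIZE
        sxy, sz = vs[0], vs[2]
    else:
        raise ValueError(f"units must be 'px' or 'um', got {units!r}")

    dist_path = out_dir / "Spot Distances.txt"
    # %.17g guarantees a lossless float round trip through the text table
    _distance_frame(records, sxy, sz).to_csv(dist_path, sep="\t", index=False,
                                             float_format="%.17g")

    paths = [dist_path]
    for name, spots in (("Spots1.txt", spots1), ("Spots2.txt", spots2)):
        df = pd.DataFrame(
            [{"x": s.x * sxy, "y": s.y * sxy, "z": s.z * sz,
              "intensity": s.intensity} for s in spots],
            columns=list(SPOT_COLUMNS))
        p = out_dir / name
        df.to_csv(p, sep="\t", index=False, float_format="%.17g")
        paths.append(p)
    return tuple(paths)


def read_spot_distances(path: str | Path) -> pd.DataFrame:
    """Re-parse a "Spot Distances" table."""
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such table: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in SPOT_DISTANCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    return df


def read_pooled_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate the pooled per-spot CSV (comma-delimited).

    The pooled file carries one row per spot across all analysed images, with
    an ``image`` column identifying the source cell.  Schema violations are
    reported with 1-based data row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such pooled file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in POOLED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing}; "
            f"expected {list(POOLED_COLUMNS)}")
    bad_type = df.index[~df["type"].isin([1, 2])]
    if len(bad_type):
        raise SchemaError(
            f"{path.name}: 'type' must be 1 or 2; bad rows "
            f"{[int(i) + 1 for i in bad_type[:10]]}")
    dcols = ["d_nuclear", "d_side1", "d_invasive", "d_side2"]
    bad = df.index[(df[dcols] < 0).any(axis=1) | df[dcols].isna().any(axis=1)]
    if len(bad):
        raise SchemaError(
            f"{path.name}: negative or missing distances in rows "
            f"{[int(i) + 1 for i in bad[:10]]}")
    return df
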