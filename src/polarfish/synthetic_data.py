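"""Ground-truthed synthetic leader-cell scenes.

Generates 4-channel anisotropic-voxel z-stacks that emulate the acquisition
conventions of the real experiment — nuclear stain, whole-cell stain and two
smFISH channels whose spots are PSF-blurred Gaussians over Poisson + read
noise — together with the exact planted spot coordinates, the cell-outline
polygon and the four anchor clicks.  The cell mask is a stadium capsule
(elongated body, two identical semicircular caps): front-back symmetric, so
uniform spot placement has mean normalized distance exactly 0.5 in
expectation.

Spot positions follow a truncated-exponential law along the front-back axis
whose rate is set from a polarity bias in [0, 1] (0 = uniform, 1 = strongly
invasive-biased), which makes the expected polarity index of every scene
computable independently of the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy.optimize import brentq

from .cell_geometry import (
    SEGMENT_ROLES,
    SpotDistanceRecord,
    measure_all_spots,
    snap_anchors,
)
from .spot_detection import Spot
from .stack_io import (
    DEFAULT_CHANNEL_MAP,
    DEFAULT_VOXEL_SIZE,
    ChannelStack,
    RoiPolygon,
    write_polygon_csv,
    write_stack,
)

#: PSF widths in voxels (~half the optical PSF at 0.1 x 0.1 x 0.3 um voxels).
PSF_SIGMA_XY = 1.3
PSF_SIGMA_Z = 1.5

#: Default camera/noise model: (poisson_gain, gaussian_read_sigma, background).
DEFAULT_NOISE_MODEL = (1.0, 2.0, 100.0)

#: Keep planted spots this far (px) inside the mask edge.
EDGE_MARGIN = 2.0

#: polarity bias 1.0 maps to a target axial mean of 0.05 (strongly invasive).
_BIAS_SPAN = 0.45


@dataclass
class SyntheticScene:
    """One simulated leader-cell front with known ground truth."""

    stack: ChannelStack | None
    true_spots: list[Spot]
    polygon: RoiPolygon
    anchors: np.ndarray          # the 4 click points, clockwise from nuclear
    polarity_bias: tuple[float, float]
    noise_model: tuple[float, float, float]
    seed: int

    def partition(self):
        return snap_anchors(self.polygon, self.anchors)


# ---------------------------------------------------------------------------
# Placement law
# ---------------------------------------------------------------------------

def _truncexp_mean(lam: float) -> float:
    """Mean of the exponential law truncated to [0, 1] with rate lam."""
    if abs(lam) < 1e-9:
        return 0.5
    return 1.0 / lam - 1.0 / np.expm1(lam)


def rate_for_mean(target_mean: float) -> float:
    """Rate of the truncated exponential on [0, 1] with the given mean."""
    if not 0.0 < target_mean < 1.0:
        raise ValueError("target mean must be in (0, 1)")
    if abs(target_mean - 0.5) < 1e-12:
        return 0.0
    return brentq(lambda lam: _truncexp_mean(lam) - target_mean,
                  -500.0, 500.0, xtol=1e-10)


def _sample_truncexp(rng: np.random.Generator, lam: float, n: int) -> np.ndarray:
    q = rng.random(n)
    if abs(lam) < 1e-9:
        return q
    return -np.log1p(-q * (-np.expm1(-lam))) / lam


def bias_to_mean(beta: float) -> float:
    """Target axial mean normalized distance for a polarity bias in [0, 1]."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("polarity bias must be in [0, 1]")
    return 0.5 - _BIAS_SPAN * beta


# ---------------------------------------------------------------------------
# Capsule geometry
# ---------------------------------------------------------------------------

def capsule_polygon(shape_yx: tuple[int, int], margin: float = 6.0,
                    n_arc: int = 24) -> tuple[RoiPolygon, np.ndarray]:
    """Stadium-capsule outline filling the frame, plus the 4 anchor clicks.

    The long axis runs along x with the invasive cap at high x and the
    nuclear cap at low x.  Returns the polygon (clockwise in the shoelace
    sense) and the four anchor clicks ordered nuclear-start, nuclear-end,
    invasive-start, invasive-end — i.e. clockwise starting at the nuclear
    side, at the four cap/side junction vertices.
    """
    ny, nx = shape_yx
    cy = (ny - 1) / 2.0
    # cap radius limited by the frame height and by keeping the straight
    # section at least as long as the two caps together
    r = min((ny - 1) / 2.0 - margin, ((nx - 1) - 2 * margin) / 4.0)
    if r < 4:
        raise ValueError(f"frame {shape_yx} too small for a capsule")
    cx_rear = margin + r
    cx_front = (nx - 1) - margin - r

    # clockwise traversal: rear-bottom junction -> rear apex -> rear-top ->
    # top side -> front-top -> front apex -> front-bottom -> bottom side
    th_rear = np.linspace(-np.pi / 2, -3 * np.pi / 2, n_arc + 1)
    rear = np.column_stack([cx_rear + r * np.cos(th_rear),
                            cy + r * np.sin(th_rear)])
    th_front = np.linspace(np.pi / 2, -np.pi / 2, n_arc + 1)
    front = np.column_stack([cx_front + r * np.cos(th_front),
                             cy + r * np.sin(th_front)])
    verts = np.vstack([rear, front])  # junction vertices shared implicitly
    poly = RoiPolygon(verts)
    clicks = np.array([
        [cx_rear, cy - r],   # nuclear segment start (rear-bottom junction)
        [cx_rear, cy + r],   # nuclear end / side1 start
        [cx_front, cy + r],  # invasive start
        [cx_front, cy - r],  # invasive end / side2 start
    ])
    return poly, clicks


def _capsule_halfwidth(x: np.ndarray, cx_rear: float, cx_front: float,
                       r: float) -> np.ndarray:
    h = np.full_like(np.asarray(x, dtype=float), r)
    left = x < cx_rear
    right = x > cx_front
    h[left] = np.sqrt(np.maximum(r ** 2 - (cx_rear - x[left]) ** 2, 0.0))
    h[right] = np.sqrt(np.maximum(r ** 2 - (x[right] - cx_front) ** 2, 0.0))
    return h


def _capsule_params(polygon: RoiPolygon) -> tuple[float, float, float, float]:
    """Recover (cx_rear, cx_front, cy, r) from a capsule outline."""
    v = polygon.vertices
    cy = float(v[:, 1].mean())
    r = float((v[:, 1].max() - v[:, 1].min()) / 2.0)
    return (float(v[:, 0].min()) + r, float(v[:, 0].max()) - r, cy, r)


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

def _place_spots(rng: np.random.Generator, polygon: RoiPolygon,
                 nz: int, n: int, beta: float, spot_type: int,
                 min_spacing: float = 0.0) -> list[Spot]:
    cx_rear, cx_front, cy, r = _capsule_params(polygon)
    x_front = cx_front + r - EDGE_MARGIN
    x_rear = cx_rear - r + EDGE_MARGIN
    lam = rate_for_mean(bias_to_mean(beta))
    zlo, zhi = min(2.0, (nz - 1) / 2), max(nz - 3.0, (nz - 1) / 2)

    def draw(k: int) -> np.ndarray:
        u = _sample_truncexp(rng, lam, k)
        x = x_front - u * (x_front - x_rear)
        h = np.maximum(
            _capsule_halfwidth(x, cx_rear, cx_front, r) - EDGE_MARGIN, 0.0)
        y = cy + (2 * rng.random(k) - 1) * h
        z = zlo + rng.random(k) * (zhi - zlo)
        return np.column_stack([x, y, z])

    if min_spacing <= 0:
        pos = draw(n)
    else:
        accepted: list[np.ndarray] = []
        attempts = 0
        while len(accepted) < n:
            attempts += 1
            if attempts > 200 * max(n, 1):
                raise ValueError(
                    f"could not place {n} spots with spacing "
                    f">= {min_spacing} in this mask")
            cand = draw(1)[0]
            if all(np.max(np.abs(cand - a)) >= min_spacing
                   for a in accepted):
                accepted.append(cand)
        pos = np.asarray(accepted)
    return [Spot(x=float(p[0]), y=float(p[1]), z=float(p[2]), intensity=1.0,
                 type=spot_type) for p in pos]


def _render_gaussian_spots(volume: np.ndarray, spots: Sequence[Spot],
                           amplitude: float) -> None:
    """Add anisotropic Gaussian PSFs at sub-voxel spot positions, in place."""
    nz, ny, nx = volume.shape
    wz = int(np.ceil(4 * PSF_SIGMA_Z))
    wxy = int(np.ceil(4 * PSF_SIGMA_XY))
    for s in spots:
        z0, y0, x0 = s.z, s.y, s.x
        zi = np.arange(max(0, int(z0) - wz), min(nz, int(z0) + wz + 1))
        yi = np.arange(max(0, int(y0) - wxy), min(ny, int(y0) + wxy + 1))
        xi = np.arange(max(0, int(x0) - wxy), min(nx, int(x0) + wxy + 1))
        gz = np.exp(-0.5 * ((zi - z0) / PSF_SIGMA_Z) ** 2)
        gy = np.exp(-0.5 * ((yi - y0) / PSF_SIGMA_XY) ** 2)
        gx = np.exp(-0.5 * ((xi - x0) / PSF_SIGMA_XY) ** 2)
        volume[np.ix_(zi, yi, xi)] += amplitude * (
            gz[:, None, None] * gy[None, :, None] * gx[None, None, :])


def scene_mask(polygon: RoiPolygon, shape: tuple[int, int, int]) -> np.ndarray:
    """3D cell mask: outline interior replicated over all z planes."""
    nz, ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    path = MplPath(polygon.vertices)
    inside = path.contains_points(
        np.column_stack([xx.ravel(), yy.ravel()]), radius=1e-9)
    return np.broadcast_to(inside.reshape(ny, nx), (nz, ny, nx)).copy()


def make_scene(shape: tuple[int, int, int] = (16, 72, 192),
               n_spots: tuple[int, int] = (150, 150),
               polarity_bias: tuple[float, float] = (0.6, 0.0),
               snr: float = 10.0,
               seed: int = 0,
               noise_model: tuple[float, float, float] = DEFAULT_NOISE_MODEL,
               min_spacing: float = 0.0,
               render: bool = True) -> SyntheticScene:
    """Build one ground-truthed leader-cell scene.

    ``shape`` is (z, y, x) with z >= 8 and y, x >= 64; ``n_spots`` gives the
    planted counts per RNA type; ``polarity_bias`` the per-type bias toward
    the invasive pole (0 = uniform); ``snr`` the spot peak amplitude over
    the background noise scale; ``min_spacing`` enforces a per-axis minimum
    spacing between planted spots of the same type (error when the mask is
    too small for it).  ``render=False`` skips voxel rendering and returns
    the geometry and ground-truth spots only.
    """
    nz, ny, nx = shape
    if nz < 8 or ny < 64 or nx < 64:
        raise ValueError(f"minimum scene shape is (8, 64, 64), got {shape}")
    if any(n < 0 for n in n_spots):
        raise ValueError("spot counts must be non-negative")
    rng = np.random.default_rng(seed)
    polygon, clicks = capsule_polygon((ny, nx))
    spots1 = _place_spots(rng, polygon, nz, n_spots[0], polarity_bias[0], 1,
                          min_spacing)
    spots2 = _place_spots(rng, polygon, nz, n_spots[1], polarity_bias[1], 2,
                          min_spacing)
    true_spots = spots1 + spots2

    stack = None
    if render:
        gain, read_sigma, background = noise_model
        sigma_floor = np.sqrt(background / gain + read_sigma ** 2)
        amplitude = snr * sigma_floor

        signal = np.zeros((4,) + shape, dtype=float)
        cx_rear, cx_front, cy, r = _capsule_params(polygon)
        zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float)
        # nuclear channel: soft ellipsoid at the rear cap
        nuc = 4.0 * background * np.exp(
            -0.5 * (((xx - cx_rear) / (0.8 * r)) ** 2
                    + ((yy - cy) / (0.8 * r)) ** 2
                    + ((zz - (nz - 1) / 2) / (0.6 * nz)) ** 2))
        signal[0] = nuc
        # cellmask channel: smooth fill of the capsule
        h = _capsule_halfwidth(xx[0], cx_rear, cx_front, r)
        soft = 1.0 / (1.0 + np.exp((np.abs(yy[0] - cy) - h) / 1.5))
        signal[1] = 3.0 * background * soft
        _render_gaussian_spots(signal[2], spots1, amplitude)
        _render_gaussian_spots(signal[3], spots2, amplitude)

        expected = background + signal
        counts = rng.poisson(expected * gain) / gain \
            + rng.normal(0.0, read_sigma, size=expected.shape)
        stack = ChannelStack(voxels=np.maximum(counts, 0.0),
                             channel_map=dict(DEFAULT_CHANNEL_MAP),
                             voxel_size=DEFAULT_VOXEL_SIZE)

    return SyntheticScene(stack=stack, true_spots=true_spots, polygon=polygon,
                          anchors=clicks, polarity_bias=tuple(polarity_bias),
                          noise_model=tuple(noise_model), seed=int(seed))


# ---------------------------------------------------------------------------
# Independent distance oracle
# ---------------------------------------------------------------------------

def _dense_segment_points(segment: np.ndarray, n_samples: int) -> np.ndarray:
    """Evenly arclength-spaced points along a polyline."""
    seg = np.asarray(segment, dtype=float)
    d = np.sqrt(np.sum(np.diff(seg, axis=0) ** 2, axis=1))
    s = np.concatenate([[0.0], np.cumsum(d)])
    t = np.linspace(0.0, s[-1], n_samples)
    x = np.interp(t, s, seg[:, 0])
    y = np.interp(t, s, seg[:, 1])
    return np.column_stack([x, y])


def brute_force_distance(p: Sequence[float], segment: np.ndarray,
                         n_samples: int = 10_000) -> float:
    """Min distance to a dense sampling of the polyline (oracle path)."""
    pts = _dense_segment_points(segment, n_samples)
    return float(np.sqrt(np.min(np.sum((pts - np.asarray(p, dtype=float)) ** 2,
                                       axis=1))))


def _oracle_segments(polygon: RoiPolygon,
                     clicks: np.ndarray) -> dict[str, np.ndarray]:
    """Re-derive the four boundary segments without cell_geometry.

    Orientation and snapping are recomputed from scratch (shoelace sign,
    nearest-vertex snap) so the oracle shares no code with the measured
    path.
    """
    v = np.asarray(polygon.vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 > 0:
        v = v[::-1]
    n = len(v)
    idx = [int(np.argmin(np.sum((v - c) ** 2, axis=1))) for c in clicks]
    segments = {}
    bounds = [(idx[0], idx[1]), (idx[1], idx[2]), (idx[2], idx[3]),
              (idx[3], idx[0])]
    for role, (a, b) in zip(SEGMENT_ROLES, bounds):
        if a <= b:
            segments[role] = v[a:b + 1]
        else:
            segments[role] = np.vstack([v[a:], v[:b + 1]])
    return segments


def true_distance_table(scene: SyntheticScene,
                        image_id: int = 0,
                        n_samples: int = 10_000) -> list[SpotDistanceRecord]:
    """Exact distances of the planted spots via dense boundary sampling.

    Independent of :mod:`polarfish.cell_geometry`: segments are re-derived
    with plain numpy and distances taken as the minimum over ``n_samples``
    arclength-uniform boundary points per segment.
    """
    segments = _oracle_segments(scene.polygon, scene.anchors)
    dense = {role: _dense_segment_points(seg, n_samples)
             for role, seg in segments.items()}
    records = []
    for spot in scene.true_spots:
        p = np.array([spot.x, spot.y])
        d = {role: float(np.sqrt(np.min(np.sum((pts - p) ** 2, axis=1))))
             for role, pts in dense.items()}
        records.append(SpotDistanceRecord(
            spot=spot, d_nuclear=d["nuclear"], d_side1=d["side1"],
            d_invasive=d["invasive"], d_side2=d["side2"], image_id=image_id))
    return records


def expected_polarity_index(polygon: RoiPolygon, clicks: np.ndarray,
                            beta: float, n_axial: int = 400,
                            n_lateral: int = 15,
                            n_samples: int = 4_000) -> float:
    """Expected M under the placement law, by deterministic quadrature.

    Integrates the oracle nuclear/invasive distances over the truncated-
    exponential axial density and the uniform lateral density, then forms
    E[Id] / (E[Id] + E[Nd]) — the large-n limit of the pipeline's M.
    """
    segments = _oracle_segments(polygon, clicks)
    dense_n = _dense_segment_points(segments["nuclear"], n_samples)
    dense_i = _dense_segment_points(segments["invasive"], n_samples)
    cx_rear, cx_front, cy, r = _capsule_params(polygon)
    x_front = cx_front + r - EDGE_MARGIN
    x_rear = cx_rear - r + EDGE_MARGIN
    lam = rate_for_mean(bias_to_mean(beta))

    u = (np.arange(n_axial) + 0.5) / n_axial
    if abs(lam) < 1e-9:
        wu = np.full(n_axial, 1.0 / n_axial)
    else:
        wu = lam * np.exp(-lam * u) / (-np.expm1(-lam)) / n_axial
        wu /= wu.sum()
    xs = x_front - u * (x_front - x_rear)
    hs = np.maximum(_capsule_halfwidth(xs, cx_rear, cx_front, r)
                    - EDGE_MARGIN, 0.0)
    t = (np.arange(n_lateral) + 0.5) / n_lateral * 2 - 1

    e_id = e_nd = 0.0
    for xi, hi, wi in zip(xs, hs, wu):
        ys = cy + t * hi
        pts = np.column_stack([np.full_like(ys, xi), ys])
        d_i = np.sqrt(((dense_i[None, :, :] - pts[:, None, :]) ** 2
                       ).sum(-1)).min(1)
        d_n = np.sqrt(((dense_n[None, :, :] - pts[:, None, :]) ** 2
                       ).sum(-1)).min(1)
        e_id += wi * d_i.mean()
        e_nd += wi * d_n.mean()
    return float(e_id / (e_id + e_nd))


# ---------------------------------------------------------------------------
# Multi-image studies
# ---------------------------------------------------------------------------

def _study_biases(effect: float) -> tuple[float, float]:
    """Per-type polarity biases giving target M1 = 0.5 - effect, M2 = 0.5."""
    if not -_BIAS_SPAN <= effect <= _BIAS_SPAN:
        raise ValueError(f"|effect| must be <= {_BIAS_SPAN}")
    return effect / _BIAS_SPAN, 0.0


def simulate_study_distances(n_images: int, effect: float, seed: int,
                             n_spots: tuple[int, int] = (40, 40),
                             shape: tuple[int, int, int] = (12, 64, 160)
                             ) -> pd.DataFrame:
    """Pooled ground-truth distance table for a multi-image study.

    Geometry-only fast path: spots are planted per the placement law and
    measured against the drawn boundary; no voxel data is rendered.  Image
    frames are jittered in length per image so cells differ in scale.
    """
    if n_images < 2:
        raise ValueError("a study needs >= 2 images")
    beta1, beta2 = _study_biases(effect)
    rng = np.random.default_rng(seed)
    frames = []
    for image_id in range(1, n_images + 1):
        nz, ny, nx = shape
        nx_i = int(nx * rng.uniform(0.85, 1.25))
        scene = make_scene(shape=(nz, ny, nx_i), n_spots=n_spots,
                           polarity_bias=(beta1, beta2),
                           seed=int(rng.integers(2 ** 31)), render=False)
        records = measure_all_spots(scene.true_spots, scene.partition(),
                                    image_id=image_id)
        frames.append(pd.DataFrame([{
            "x": r.spot.x, "y": r.spot.y, "z": r.spot.z,
            "d_nuclear": r.d_nuclear, "d_side1": r.d_side1,
            "d_invasive": r.d_invasive, "d_side2": r.d_side2,
            "type": r.spot.type, "image": image_id} for r in records]))
    return pd.concat(frames, ignore_index=True)


def make_study(n_images: int, effect: float, seed: int,
               out_dir: str | Path,
               n_spots: tuple[int, int] = (40, 40),
               shape: tuple[int, int, int] = (12, 64, 160),
               snr: float = 10.0,
               render_stacks: bool = True) -> dict:
    """Write a ready-to-run multi-image study to ``out_dir``.

    Produces per-image stack TIFFs (optional), outline CSVs and anchor-click
    CSVs, a pooled ground-truth distance CSV, and a parameters JSON.  The
    planted per-type polarity targets are M1 = 0.5 - effect and M2 = 0.5.
    ``n_images = 2`` runs but downstream tests will warn about low n.
    """
    if n_images < 2:
        raise ValueError("a study needs >= 2 images")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    beta1, beta2 = _study_biases(effect)
    rng = np.random.default_rng(seed)
    pooled_frames = []
    image_files = []
    for image_id in range(1, n_images + 1):
        nz, ny, nx = shape
        nx_i = int(nx * rng.uniform(0.85, 1.25))
        scene = make_scene(shape=(nz, ny, nx_i), n_spots=n_spots,
                           polarity_bias=(beta1, beta2), snr=snr,
                           seed=int(rng.integers(2 ** 31)),
                           render=render_stacks)
        entry = {"image": image_id}
        if render_stacks:
            stack_path = out_dir / f"image_{image_id:02d}.tif"
            write_stack(scene.stack, stack_path)
            entry["stack"] = str(stack_path)
        poly_path = out_dir / f"image_{image_id:02d}_outline.csv"
        write_polygon_csv(scene.polygon, poly_path)
        anchors_path = out_dir / f"image_{image_id:02d}_anchors.csv"
        anchors_path.write_text(
            "x,y\n" + "\n".join(f"{x:.3f},{y:.3f}" for x, y in scene.anchors)
            + "\n")
        entry.update(outline=str(poly_path), anchors=str(anchors_path))
        image_files.append(entry)
        records = measure_all_spots(scene.true_spots, scene.partition(),
                                    image_id=image_id)
        pooled_frames.append(pd.DataFrame([{
            "x": r.spot.x, "y": r.spot.y, "z": r.spot.z,
            "d_nuclear": r.d_nuclear, "d_side1": r.d_side1,
            "d_invasive": r.d_invasive, "d_side2": r.d_side2,
            "type": r.spot.type, "image": image_id} for r in records]))
    pooled = pd.concat(pooled_frames, ignore_index=True)
    pooled_path = out_dir / "ground_truth_pooled.csv"
    pooled.to_csv(pooled_path, index=False)
    params = {"n_images": n_images, "effect": effect, "seed": seed,
              "n_spots": list(n_spots), "shape": list(shape), "snr": snr,
              "target_M": [0.5 - effect, 0.5],
              "polarity_bias": [beta1, beta2]}
    (out_dir / "study_params.json").write_text(json.dumps(params, indent=1))
    return {"out_dir": out_dir, "pooled_csv": pooled_path,
            "images": image_files, "params": params, "pooled": pooled}
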