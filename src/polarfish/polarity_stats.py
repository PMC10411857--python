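"""Normalization and statistical comparison of spot distances.

For each image the per-cell normalization scale is the total length

    L = (1/n) * sum_i (Nd_i + Id_i)

over all n spots of both RNA types, where Nd_i and Id_i are a spot's
nearest distances to the nuclear and invasive boundary segments.  Each RNA
type then gets a mean normalized distance

    M = (1/n_type) * sum_i Id_i / L

so M = 0 means the type sits on the invasive edge and M = 1 near the
nuclear edge.  Comparisons across cells use one (M_rna1, M_rna2) pair per
image — never the pooled per-spot values — so heavily expressing cells do
not dominate, and the two types are compared with a Wilcoxon matched-pairs
signed-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cell_geometry import SpotDistanceRecord
from .errors import (
    DuplicateImageIdError,
    EmptyRecordsError,
    InsufficientPairsError,
)

#: KDE evaluation grid for per-image M values.
KDE_GRID = np.linspace(-0.2, 1.2, 512)

#: Histogram bins for per-spot normalized distances.
HISTOGRAM_BINS = 20


@dataclass
class ImageSummary:
    """Per-image spot counts, normalization length and polarity indices.

    ``M_rna1``/``M_rna2`` are NaN when that type has no spots in the image
    (undefined, never coerced to 0).
    """

    image_id: int
    n1: int
    n2: int
    L: float
    M_rna1: float
    M_rna2: float


def total_length(records: Sequence[SpotDistanceRecord]) -> float:
    """Per-cell normalization scale L: mean of (Nd_i + Id_i), types pooled."""
    if not records:
        raise EmptyRecordsError("total_length needs >= 1 spot record")
    return float(np.mean([r.d_nuclear + r.d_invasive for r in records]))


def mean_normalized_distance(records: Sequence[SpotDistanceRecord],
                             L: float) -> float:
    """Mean normalized invasive distance M of one RNA type: mean(Id_i / L)."""
    if not records:
        raise EmptyRecordsError(
            "mean_normalized_distance needs >= 1 record of the type")
    if not L > 0:
        raise ValueError(f"normalization length must be positive, got {L}")
    m = float(np.mean([r.d_invasive for r in records]) / L)
    if not 0.0 <= m <= 1.0:
        warnings.warn(
            f"M = {m:.3f} outside [0, 1]; irregular cell geometry can "
            "legitimately produce this", stacklevel=2)
    return m


def summarize_image(image_id: int,
                    records: Sequence[SpotDistanceRecord]) -> ImageSummary:
    """Compute n per type, L and M per type for one image."""
    if not records:
        raise EmptyRecordsError(f"image {image_id} has no spot records")
    by_type = {t: [r for r in records if r.spot.type == t] for t in (1, 2)}
    L = total_length(records)
    ms = {}
    for t in (1, 2):
        ms[t] = (mean_normalized_distance(by_type[t], L)
                 if by_type[t] else float("nan"))
    return ImageSummary(image_id=int(image_id), n1=len(by_type[1]),
                        n2=len(by_type[2]), L=L,
                        M_rna1=ms[1], M_rna2=ms[2])


def pool_images(per_image_tables: Iterable[tuple[int, Sequence[SpotDistanceRecord]]]
                ) -> pd.DataFrame:
    """Pool per-image record lists into one long table with an image column."""
    frames = []
    seen: set[int] = set()
    for image_id, records in per_image_tables:
        image_id = int(image_id)
        if image_id in seen:
            raise DuplicateImageIdError(f"duplicate image id {image_id}")
        seen.add(image_id)
        frames.append(pd.DataFrame([{
            "x": r.spot.x, "y": r.spot.y, "z": r.spot.z,
            "d_nuclear": r.d_nuclear, "d_side1": r.d_side1,
            "d_invasive": r.d_invasive, "d_side2": r.d_side2,
            "type": r.spot.type, "image": image_id,
        } for r in records]))
    if not frames:
        raise EmptyRecordsError("no images to pool")
    cols = ["x", "y", "z", "d_nuclear", "d_side1", "d_invasive", "d_side2",
            "type", "image"]
    return pd.concat(frames, ignore_index=True)[cols] if any(
        len(f) for f in frames) else pd.DataFrame(columns=cols)


def summaries_from_pooled(pooled: pd.DataFrame) -> list[ImageSummary]:
    """Per-image summaries straight from a pooled long-format table."""
    out = []
    for image_id, g in pooled.groupby("image", sort=True):
        L = float((g["d_nuclear"] + g["d_invasive"]).mean())
        ms = {}
        for t in (1, 2):
            gt = g[g["type"] == t]
            ms[t] = float(gt["d_invasive"].mean() / L) if len(gt) else float("nan")
        out.append(ImageSummary(image_id=int(image_id),
                                n1=int((g["type"] == 1).sum()),
                                n2=int((g["type"] == 2).sum()),
                                L=L, M_rna1=ms[1], M_rna2=ms[2]))
    return out


# ---------------------------------------------------------------------------
# Wilcoxon matched-pairs signed-rank test
# ---------------------------------------------------------------------------

def _exact_signed_rank_sf(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact sign-flip distribution of W+ for given |difference| midranks.

    Doubling the midranks makes them integers (ties give .5 ranks), so the
    distribution is built by dynamic programming over achievable doubled
    rank sums.  Returns (support of 2*W+, counts).
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[:counts.size - r].copy()
    return np.arange(total + 1), counts


def wilcoxon_matched_pairs(m1: Sequence[float], m2: Sequence[float]
                           ) -> tuple[float, float]:
    """Two-sided Wilcoxon matched-pairs signed-rank test on paired M values.

    Pairs with a NaN member (type absent in that image) are dropped, as are
    zero differences (classic Wilcoxon convention); tied |differences| get
    midranks.  The null distribution is exact (full sign-flip enumeration
    via rank-sum counts) for n <= 25 usable pairs, and a normal
    approximation with continuity and tie correction above.  Returns
    ``(statistic, p_value)`` where the statistic is min(W+, W-).
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape:
        raise InsufficientPairsError(
            f"paired samples differ in length: {m1.shape} vs {m2.shape}")
    keep = ~(np.isnan(m1) | np.isnan(m2))
    d = m1[keep] - m2[keep]
    d = d[d != 0]
    n = d.size
    if n < 2:
        raise InsufficientPairsError(
            f"need >= 2 usable non-zero pairs, got {n} "
            "(identical or missing M values)")
    ranks = sps.rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)
    total = ranks.sum()

    if n <= 25:
        support2, counts = _exact_signed_rank_sf(ranks)
        probs = counts / counts.sum()
        w2 = int(round(2 * w_plus))
        p_le = probs[support2 <= w2].sum()
        p_ge = probs[support2 >= w2].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mu = total / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 \
            - np.sum(tie_counts ** 3 - tie_counts) / 48.0
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return statistic, float(p)


# ---------------------------------------------------------------------------
# Density estimates and histograms
# ---------------------------------------------------------------------------

def kde_of_m_values(m_values: Sequence[float],
                    grid: np.ndarray = KDE_GRID
                    ) -> tuple[np.ndarray, np.ndarray, float] | None:
    """Gaussian KDE (Silverman bandwidth) of per-image M values on a grid.

    Returns ``(grid, density, bandwidth)`` or None (with a warning) when
    fewer than two distinct finite values exist, where a KDE is degenerate.
    """
    vals = np.asarray(m_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(np.unique(vals)) < 2:
        warnings.warn(
            "KDE skipped: fewer than two distinct M values", stacklevel=2)
        return None
    grid = np.asarray(grid)
    kde = sps.gaussian_kde(vals, bw_method="silverman")
    bandwidth = float(kde.factor * vals.std(ddof=1))
    # floor the bandwidth at one grid step so near-identical values still
    # produce a density resolvable on (and normalized over) the grid
    floor = float(grid[1] - grid[0])
    if bandwidth < floor:
        bandwidth = floor
        kde = sps.gaussian_kde(vals, bw_method=floor / vals.std(ddof=1))
    return grid, kde(grid), bandwidth


def spot_histogram(normalized_distances: Sequence[float],
                   bins: int = HISTOGRAM_BINS
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-spot Id_i / L on [0, 1].

    Values outside [0, 1] (possible in irregular cells) are left out of
    range rather than clipped into the edge bins.
    """
    vals = np.asarray(normalized_distances, dtype=float)
    counts, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    return counts, edges
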