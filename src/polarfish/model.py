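"""Model/Results interface over the polarity comparison.

`PolarityModel` wraps a pooled per-spot distance table (one row per spot,
with an image column); `fit()` computes the per-image summaries, the paired
Wilcoxon test and the density estimates, returning a `PolarityResults`
object with a text `summary()`, plotting methods and file export.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib
import numpy as np
import pandas as pd

from . import polarity_stats as ps
from .cell_geometry import SpotDistanceRecord
from .errors import InsufficientPairsError
from .stack_io import read_pooled_csv


class PolarityModel:
    """Front-back polarity comparison of two RNA species across images.

    Parameters
    ----------
    data
        Pooled long-format table with columns x, y, z, d_nuclear, d_side1,
        d_invasive, d_side2, type (1/2) and image.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in ("d_nuclear", "d_invasive", "type", "image")
                   if c not in data.columns]
        if missing:
            raise ps.EmptyRecordsError(
                f"pooled table missing columns {missing}")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PolarityModel":
        """Build the model from a pooled .csv file (validated)."""
        return cls(read_pooled_csv(path))

    @classmethod
    def from_records(cls, per_image: Sequence[tuple[int, Sequence[SpotDistanceRecord]]]
                     ) -> "PolarityModel":
        """Build the model from per-image lists of SpotDistanceRecord."""
        return cls(ps.pool_images(per_image))

    def fit(self, bins: int = ps.HISTOGRAM_BINS,
            kde_grid: np.ndarray = ps.KDE_GRID) -> "PolarityResults":
        """Run the normalization and the paired comparison."""
        summaries = ps.summaries_from_pooled(self.data)
        per_image = pd.DataFrame([vars(s) for s in summaries])
        m1 = per_image["M_rna1"].to_numpy()
        m2 = per_image["M_rna2"].to_numpy()
        statistic = pvalue = float("nan")
        test_note = ""
        try:
            statistic, pvalue = ps.wilcoxon_matched_pairs(m1, m2)
        except InsufficientPairsError as exc:
            test_note = str(exc)
            warnings.warn(f"paired test skipped: {exc}", stacklevel=2)

        kde = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kde["rna1"] = ps.kde_of_m_values(m1, kde_grid)
            kde["rna2"] = ps.kde_of_m_values(m2, kde_grid)

        # per-spot normalized distances, per type, using each image's L
        Ls = per_image.set_index("image_id")["L"]
        norm = self.data["d_invasive"] / self.data["image"].map(Ls)
        hists = {
            "rna1": ps.spot_histogram(norm[self.data["type"] == 1], bins),
            "rna2": ps.spot_histogram(norm[self.data["type"] == 2], bins),
        }
        return PolarityResults(
            model=self, per_image=per_image, statistic=statistic,
            pvalue=pvalue, test_note=test_note, kde=kde, histograms=hists,
            normalized_distances=pd.DataFrame(
                {"normalized": norm, "type": self.data["type"],
                 "image": self.data["image"]}))


@dataclass
class PolarityResults:
    """Fitted polarity comparison: per-image indices, test, densities."""

    model: PolarityModel
    per_image: pd.DataFrame
    statistic: float
    pvalue: float
    test_note: str
    kde: dict
    histograms: dict
    normalized_distances: pd.DataFrame = field(repr=False)

    @property
    def n_images(self) -> int:
        return len(self.per_image)

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = ["Front-back RNA polarity comparison",
                 "=" * 50]
        cols = ["image_id", "n1", "n2", "L", "M_rna1", "M_rna2"]
        lines.append(self.per_image[cols].to_string(
            index=False, float_format=lambda v: f"{v:.4f}"))
        lines.append("-" * 50)
        m1 = np.nanmean(self.per_image["M_rna1"])
        m2 = np.nanmean(self.per_image["M_rna2"])
        lines.append(f"images: {self.n_images}   "
                     f"mean M_rna1: {m1:.4f}   mean M_rna2: {m2:.4f}")
        if np.isnan(self.pvalue):
            lines.append(f"Wilcoxon matched-pairs test: skipped "
                         f"({self.test_note})")
        else:
            lines.append(f"Wilcoxon matched-pairs signed-rank: "
                         f"W = {self.statistic:.1f}, "
                         f"two-sided p = {self.pvalue:.4g}")
        lines.append("(M near 0: biased toward the invasive edge; "
                     "near 1: toward the nucleus)")
        return "\n".join(lines)

    # -- plots ---------------------------------------------------------------

    def plot_density(self, path: str | Path | None = None):
        """KDE of the per-image M values for both RNA types."""
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 4))
        for role, color in (("rna1", "tab:red"), ("rna2", "tab:blue")):
            if self.kde.get(role) is not None:
                grid, dens, bw = self.kde[role]
                ax.plot(grid, dens, color=color, label=f"{role} (bw={bw:.3f})")
        ax.set_xlabel("mean normalized distance M")
        ax.set_ylabel("probability density")
        if not np.isnan(self.pvalue):
            ax.set_title(f"Wilcoxon p = {self.pvalue:.3g}")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path)
            plt.close(fig)
        return fig

    def plot_histograms(self, path: str | Path | None = None):
        """Per-spot normalized-distance histograms for both RNA types."""
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharey=True)
        for ax, role, color in zip(axes, ("rna1", "rna2"),
                                   ("tab:red", "tab:blue")):
            counts, edges = self.histograms[role]
            ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
                   color=color, alpha=0.7)
            ax.set_xlabel("normalized distance Id/L")
            ax.set_title(role)
        axes[0].set_ylabel("spots")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path)
            plt.close(fig)
        return fig

    # -- export --------------------------------------------------------------

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Write summary CSV, stats JSON and the KDE/histogram TIFF plots."""
        matplotlib.use("Agg", force=False)
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["summary"] = out_dir / "image_summaries.csv"
        self.per_image.to_csv(paths["summary"], index=False)
        stats = {
            "n_images": self.n_images,
            "wilcoxon_statistic": None if np.isnan(self.statistic)
            else self.statistic,
            "p_value": None if np.isnan(self.pvalue) else self.pvalue,
            "test_note": self.test_note,
            "mean_M_rna1": float(np.nanmean(self.per_image["M_rna1"])),
            "mean_M_rna2": float(np.nanmean(self.per_image["M_rna2"])),
            "kde_bandwidths": {k: (v[2] if v is not None else None)
                               for k, v in self.kde.items()},
        }
        paths["stats"] = out_dir / "stats.json"
        paths["stats"].write_text(json.dumps(stats, indent=1))
        paths["kde_plot"] = out_dir / "density.tif"
        self.plot_density(paths["kde_plot"])
        paths["histogram_plot"] = out_dir / "histograms.tif"
        self.plot_histograms(paths["histogram_plot"])
        return paths
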