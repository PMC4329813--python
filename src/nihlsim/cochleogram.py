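"""Percentage cytocochleograms: assembly, regions, losses, plotting.

A cytocochleogram plots hair-cell density (IHC and OHC separately, per
1000 µm² of stereociliary fringe) against percent distance from the
cochlear apex in 5% sectors, with a tonotopic frequency axis attached
through the place–frequency map.  Sectors are grouped into the three
standard regions (apical 5–25%, middle 30–55%, basal 60–80%).

The estimation step is exposed statsmodels-style:
``CochleogramModel(hair_cell_map, design).fit()`` returns a
:class:`CochleogramResults` carrying per-sector estimates, their
coefficients of error, region summaries and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cochlea import CELL_CLASSES, HairCellMap, render_sector_substrate
from .placemap import PlaceFrequencyMap
from .stereology import SamplingDesign, estimate_sector

__all__ = [
    "REGIONS",
    "sector_bins",
    "Cochleogram",
    "region_means",
    "percent_loss",
    "CochleogramModel",
    "CochleogramResults",
]

#: the three standard cochlear regions, by sector label (basal edge, %)
REGIONS = {
    "apical": tuple(range(5, 30, 5)),
    "middle": tuple(range(30, 60, 5)),
    "basal": tuple(range(60, 85, 5)),
}


def sector_bins(coverage_percent: float) -> np.ndarray:
    """Labels of the half-open 5% sectors ``(k-5, k]`` from the apex.

    Coverage is the dissected percent of the cochlea (70–85 in real
    preparations; 100 for an idealized full cochlea).  Non-multiples of
    5 are rounded down with a warning.
    """
    if not (70 <= coverage_percent <= 85 or coverage_percent == 100):
        raise ValueError("coverage must lie in [70, 85] (or be 100)")
    if coverage_percent % 5 != 0:
        warnings.warn(
            f"coverage {coverage_percent}% is not a multiple of 5; rounding down",
            stacklevel=2,
        )
    n = int(coverage_percent // 5)
    return np.arange(1, n + 1) * 5


@dataclass
class Cochleogram:
    """Per-sector densities and CEs for both cell classes.

    ``data`` columns: sector, cell_class, sum_q, sum_a_um2,
    n_a_per_1000um2, ce, freq_khz.
    """

    data: pd.DataFrame
    coverage_percent: float
    place_map: PlaceFrequencyMap = field(default_factory=PlaceFrequencyMap)

    def __post_init__(self):
        labels = np.sort(self.data["sector"].unique())
        if len(labels) and (labels[0] != 5 or np.any(np.diff(labels) != 5)):
            raise ValueError("sector labels must be 5, 10, ... in steps of 5")
        if len(labels) and labels[-1] > self.coverage_percent:
            raise ValueError("sector labels exceed the stated coverage")
        if "freq_khz" not in self.data.columns:
            self.data = self.data.assign(
                freq_khz=self.place_map.percent_to_frequency(
                    self.data["sector"].to_numpy(dtype=float))
            )

    @property
    def sectors(self) -> np.ndarray:
        return np.sort(self.data["sector"].unique())

    def class_table(self, cell_class: str) -> pd.DataFrame:
        out = self.data[self.data["cell_class"] == cell_class]
        return out.sort_values("sector").reset_index(drop=True)

    def mean_density(self, cell_class: str) -> float:
        return float(self.class_table(cell_class)["n_a_per_1000um2"].mean())

    def mean_ce(self, cell_class: str) -> float:
        """Mean per-sector CE, ignoring sectors with undefined (NaN) CE."""
        return float(np.nanmean(self.class_table(cell_class)["ce"]))

    def to_csv(self, path: str | Path) -> None:
        cols = ["sector", "cell_class", "sum_q", "sum_a_um2",
                "n_a_per_1000um2", "ce", "freq_khz"]
        self.data[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 place_map: PlaceFrequencyMap | None = None) -> "Cochleogram":
        df = pd.read_csv(path)
        return cls(df, coverage_percent=float(df["sector"].max()),
                   place_map=place_map or PlaceFrequencyMap())

    def plot(self, ax=None, control: "Cochleogram | None" = None):
        """Density vs percent distance per class, with a frequency top axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for cell_class, marker in (("OHC", "o"), ("IHC", "s")):
            t = self.class_table(cell_class)
            ax.errorbar(t["sector"], t["n_a_per_1000um2"],
                        yerr=t["n_a_per_1000um2"] * t["ce"],
                        marker=marker, capsize=2, label=cell_class)
            if control is not None:
                tc = control.class_table(cell_class)
                ax.plot(tc["sector"], tc["n_a_per_1000um2"], ls="--", alpha=0.5,
                        label=f"{cell_class} control")
        ax.set_xlabel("distance from apex (%)")
        ax.set_ylabel("bundles / 1000 µm²")
        ax.legend(frameon=False)
        top = ax.secondary_xaxis(
            "top",
            functions=(self.place_map.percent_to_frequency,
                       self.place_map.frequency_to_percent))
        top.set_xlabel("frequency (kHz)")
        return ax


def _require_full_sectors(c: Cochleogram, labels=None):
    labels = np.asarray(labels if labels is not None else np.arange(5, 85, 5))
    missing = sorted(int(x) for x in set(labels) - set(c.sectors))
    if missing:
        raise ValueError(f"cochleogram is missing sectors: {missing}")


def region_means(c: Cochleogram) -> pd.DataFrame:
    """Mean density and pooled CE per class for the three standard regions.

    The pooled CE is the root-mean-square of sector CEs weighted by each
    sector's ΣQ (sectors with undefined CE are excluded from the pool).
    """
    _require_full_sectors(c)
    rows = []
    for region, labels in REGIONS.items():
        for cell_class in CELL_CLASSES:
            t = c.class_table(cell_class)
            t = t[t["sector"].isin(labels)]
            ok = np.isfinite(t["ce"]) & (t["sum_q"] > 0)
            pooled = (
                float(np.sqrt(np.average(t.loc[ok, "ce"] ** 2,
                                         weights=t.loc[ok, "sum_q"])))
                if ok.any() else float("nan")
            )
            rows.append({
                "region": region,
                "cell_class": cell_class,
                "n_sectors": len(labels),
                "mean_n_a": float(t["n_a_per_1000um2"].mean()),
                "pooled_ce": pooled,
            })
    return pd.DataFrame(rows)


def percent_loss(c: Cochleogram, control: Cochleogram) -> pd.DataFrame:
    """Per-sector percent density loss relative to a control cochleogram.

    ``100·(1 − n_a/n_a_control)`` clipped to [0, 100]; sectors whose
    control density is zero are flagged (``control_zero``) with NaN loss.
    """
    if not np.array_equal(c.sectors, control.sectors):
        raise ValueError("sector sets differ between cochleogram and control")
    merged = c.data.merge(
        control.data, on=["sector", "cell_class"], suffixes=("", "_control"))
    zero = merged["n_a_per_1000um2_control"] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        loss = 100.0 * (1.0 - merged["n_a_per_1000um2"]
                        / merged["n_a_per_1000um2_control"])
    out = merged[["sector", "cell_class"]].copy()
    out["percent_loss"] = np.clip(loss, 0.0, 100.0).where(~zero)
    out["control_zero"] = zero
    return out


class CochleogramModel:
    """Stereological cytocochleogram estimation for one hair-cell map.

    Parameters
    ----------
    hc_map : HairCellMap
        The (control or lesioned) flattened-mount map to sample.
    design : SamplingDesign, optional
        Frame geometry and placement; defaults to 5 frames of 25×25 µm.
    place_map : PlaceFrequencyMap, optional
        Tonotopic map for the frequency axis.

    ``fit(seed)`` samples every 5% sector and returns
    :class:`CochleogramResults`.
    """

    def __init__(self, hc_map: HairCellMap, design: SamplingDesign | None = None,
                 place_map: PlaceFrequencyMap | None = None):
        self.hc_map = hc_map
        self.design = design or SamplingDesign()
        self.place_map = place_map or PlaceFrequencyMap()

    def fit(self, seed: int | None = None) -> "CochleogramResults":
        design = self.design
        rng = np.random.default_rng(design.seed if seed is None else seed)
        rows = []
        for label in sector_bins(self.hc_map.params.coverage_percent):
            substrate = render_sector_substrate(self.hc_map, label)
            for est in estimate_sector(substrate, design, rng=rng):
                rows.append({
                    "sector": float(label),
                    "cell_class": est.cell_class,
                    "sum_q": est.sum_q,
                    "sum_a_um2": est.sum_a_um2,
                    "n_a_per_1000um2": est.n_a_per_1000um2,
                    "ce": est.ce,
                })
        cochleogram = Cochleogram(
            pd.DataFrame(rows),
            coverage_percent=self.hc_map.params.coverage_percent,
            place_map=self.place_map,
        )
        return CochleogramResults(self, cochleogram)


class CochleogramResults:
    """Fitted cytocochleogram: per-sector estimates plus summaries."""

    def __init__(self, model: CochleogramModel, cochleogram: Cochleogram):
        self.model = model
        self.cochleogram = cochleogram

    @property
    def data(self) -> pd.DataFrame:
        return self.cochleogram.data

    def mean_density(self, cell_class: str) -> float:
        return self.cochleogram.mean_density(cell_class)

    def mean_ce(self, cell_class: str) -> float:
        return self.cochleogram.mean_ce(cell_class)

    def region_means(self) -> pd.DataFrame:
        return region_means(self.cochleogram)

    def percent_loss(self, control: "CochleogramResults | Cochleogram") -> pd.DataFrame:
        other = control.cochleogram if isinstance(control, CochleogramResults) else control
        return percent_loss(self.cochleogram, other)

    def plot(self, ax=None, control=None):
        other = control.cochleogram if isinstance(control, CochleogramResults) else control
        return self.cochleogram.plot(ax=ax, control=other)

    def summary(self) -> str:
        d = self.model.design
        lines = [
            "Cytocochleogram (unbiased-frame stereology)",
            "=" * 60,
            f"coverage: {self.cochleogram.coverage_percent:.0f}% of BM from apex; "
            f"{len(self.cochleogram.sectors)} sectors of 5%",
            f"design: {d.frames_per_sector} frames of "
            f"{d.frame_width_um:.0f}x{d.frame_height_um:.0f} um per sector, "
            f"{d.lateral_placement}",
            "",
        ]
        for cell_class in CELL_CLASSES:
            lines.append(
                f"{cell_class}: mean N_A = {self.mean_density(cell_class):6.2f} "
                f"/1000 um2, mean CE = {self.mean_ce(cell_class):.3f}"
            )
        lines.append("")
        lines.append(self.data.to_string(index=False,
                                         float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)
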