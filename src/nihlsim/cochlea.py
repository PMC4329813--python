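"""Synthetic flattened-mount cochleae and a tonotopic lesion model.

The generator emulates the whole-mount preparation used for
cytocochleograms: the organ of Corti is flattened so hair bundles lie
in a narrow "stereociliary fringe" band — one IHC row and three OHC
rows — along a percent-distance axis from the apex.  Only the apical
~80% (the dissectable portion) is populated.

Bundles are placed by independent homogeneous Poisson processes per
row; this makes frame counts near-Poisson, which is what gives the
sampling procedure its empirical coefficient of error.  A lesion model
then removes bundles with a probability that depends on the exposure
band and level:

    p_loss = clip( peak_loss(level) * [ focal + basal + gradient ], 0, 1 )

* ``focal``   — Gaussian (in octaves) at the exposure band's
  geometric-centre place: damage within the cochlear region that codes
  the stimulus.
* ``basal``   — broad Gaussian anchored at the band's upper edge
  shifted basally (default 1 octave, the classic half-to-two-octave
  basal displacement of noise damage).
* ``gradient``— extra loss accruing linearly beyond 55% distance,
  the intrinsic vulnerability of the basal turn.

IHC loss is the OHC loss scaled by ``ihc_factor`` (< 1: OHCs are the
more vulnerable class).  All constants are calibration values, not
measured biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .placemap import PlaceFrequencyMap, octave_distance
from .stimulus import StimulusSpec

__all__ = [
    "CELL_CLASSES",
    "ROW_LABELS",
    "CochleaParams",
    "LesionModel",
    "HairCellMap",
    "SamplingSubstrate",
    "build_control_map",
    "survival_probability",
    "apply_lesion",
    "render_sector_substrate",
]

ROW_LABELS = ("IHC", "OHC1", "OHC2", "OHC3")
CELL_CLASSES = ("IHC", "OHC")

# lateral row centres as fractions of the fringe width (IHC row apart,
# three OHC rows packed toward the outer edge, as in the flattened mount)
_ROW_OFFSET_FRAC = {"IHC": 5 / 28, "OHC1": 16 / 28, "OHC2": 20 / 28, "OHC3": 24 / 28}


@dataclass(frozen=True)
class CochleaParams:
    """Geometry and bundle intensities of the synthetic control cochlea.

    Defaults give fringe-area densities of ≈ 11.9 OHC and ≈ 4.5 IHC
    bundles per 1000 µm², matching a healthy mouse organ of Corti.
    """

    bm_length_mm: float = 5.13
    coverage_percent: float = 80.0
    fringe_width_um: float = 28.0
    ohc_rows: int = 3
    ohc_intensity: float = 1 / 9.0  # bundles per µm, per OHC row
    ihc_intensity: float = 1 / 8.0  # bundles per µm

    def __post_init__(self):
        if not 70 <= self.coverage_percent <= 85:
            raise ValueError("coverage_percent must lie in [70, 85]")
        if self.bm_length_mm <= 0 or self.fringe_width_um <= 0:
            raise ValueError("lengths must be positive")
        if self.ohc_intensity <= 0 or self.ihc_intensity <= 0:
            raise ValueError("intensities must be positive")
        if self.ohc_rows != 3:
            raise ValueError("the organ of Corti model has exactly 3 OHC rows")

    @property
    def um_per_percent(self) -> float:
        return self.bm_length_mm * 1000.0 / 100.0

    def expected_density(self, cell_class: str) -> float:
        """Closed-form expected bundles per 1000 µm² of fringe area."""
        if cell_class == "OHC":
            return self.ohc_rows * self.ohc_intensity / self.fringe_width_um * 1000
        if cell_class == "IHC":
            return self.ihc_intensity / self.fringe_width_um * 1000
        raise ValueError(f"unknown cell class {cell_class!r}")


@dataclass(frozen=True)
class LesionModel:
    """Level- and band-dependent hair-bundle loss model (calibration constants).

    Parameters
    ----------
    peak_loss_by_level : mapping level (dB SPL) -> peak loss fraction.
        Linearly interpolated through (0, 0); clamped above the top level.
    basal_shift_octaves : basal displacement of the broad damage component
        relative to the band's upper edge (valid 0.5–2).
    spread_octaves : σ of the broad basal Gaussian.
    focal_spread_octaves : σ of the narrow focal Gaussian at the band centre.
    basal_gradient_per_percent : extra loss per % distance beyond 55%.
    ihc_factor : multiplier on loss probability for IHCs (≤ 1).
    """

    peak_loss_by_level: tuple = ((105.0, 0.55), (120.0, 0.98))
    basal_shift_octaves: float = 1.0
    spread_octaves: float = 1.2
    focal_spread_octaves: float = 0.2
    basal_gradient_per_percent: float = 0.006
    ihc_factor: float = 0.6

    def __post_init__(self):
        if not 0.5 <= self.basal_shift_octaves <= 2.0:
            raise ValueError("basal_shift_octaves must lie in [0.5, 2]")
        if not 0 <= self.ihc_factor <= 1:
            raise ValueError("ihc_factor must lie in [0, 1]")
        for _, p in self.peak_loss_by_level:
            if not 0 <= p <= 1:
                raise ValueError("peak losses must lie in [0, 1]")

    def peak_loss(self, level: float) -> float:
        pts = sorted(self.peak_loss_by_level)
        levels = [0.0] + [l for l, _ in pts]
        losses = [0.0] + [p for _, p in pts]
        return float(np.interp(level, levels, losses))


@dataclass
class HairCellMap:
    """Hair bundles of one flattened cochlea.

    ``cells`` columns: position_percent (from apex), row (IHC/OHC1..3),
    lateral_um (within the fringe), present (bool).
    """

    cells: pd.DataFrame
    params: CochleaParams
    lesioned: bool = False

    @property
    def n_present(self) -> int:
        return int(self.cells["present"].sum())

    def class_of(self) -> pd.Series:
        """IHC/OHC class label per cell."""
        return self.cells["row"].map(lambda r: "IHC" if r == "IHC" else "OHC")

    def true_density(self, cell_class: str) -> float:
        """Realized present-bundle density over the fringe area, per 1000 µm²."""
        sel = (self.class_of() == cell_class) & self.cells["present"]
        area = (self.params.coverage_percent * self.params.um_per_percent
                * self.params.fringe_width_um)
        return float(sel.sum()) / area * 1000.0

    def to_csv(self, path: str | Path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, params: CochleaParams,
                 lesioned: bool = False) -> "HairCellMap":
        df = pd.read_csv(path)
        df["present"] = df["present"].astype(bool)
        return cls(df, params, lesioned)


@dataclass
class SamplingSubstrate:
    """One sector's fringe rectangle with its present bundles, in µm."""

    sector_label: float
    length_um: float
    fringe_width_um: float
    points: np.ndarray        # (n, 2) local µm coordinates (x along, y lateral)
    classes: np.ndarray       # (n,) "IHC"/"OHC"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.classes = np.asarray(self.classes, dtype=object)
        if self.points.shape[0] != self.classes.shape[0]:
            raise ValueError("points and classes must align")
        if self.points.size and (
            np.any(self.points[:, 0] < 0) or np.any(self.points[:, 0] > self.length_um)
            or np.any(self.points[:, 1] < 0)
            or np.any(self.points[:, 1] > self.fringe_width_um)
        ):
            raise ValueError("bundle points must lie inside the fringe rectangle")


def build_control_map(params: CochleaParams, seed: int) -> HairCellMap:
    """Draw a healthy cochlea: Poisson rows of present bundles.

    Longitudinal positions are independent homogeneous Poisson processes
    per row over the dissected coverage; each row sits at its fixed
    lateral offset in the fringe.
    """
    rng = np.random.default_rng(seed)
    length_um = params.coverage_percent * params.um_per_percent
    frames = []
    for row in ROW_LABELS:
        lam = params.ihc_intensity if row == "IHC" else params.ohc_intensity
        n = rng.poisson(lam * length_um)
        pos = np.sort(rng.uniform(0.0, params.coverage_percent, n))
        frames.append(pd.DataFrame({
            "position_percent": pos,
            "row": row,
            "lateral_um": _ROW_OFFSET_FRAC[row] * params.fringe_width_um,
            "present": True,
        }))
    cells = pd.concat(frames, ignore_index=True)
    return HairCellMap(cells, params, lesioned=False)


def _loss_probability(position_percent, is_ihc, spec: StimulusSpec,
                      model: LesionModel, place_map: PlaceFrequencyMap):
    pos = np.asarray(position_percent, dtype=float)
    cf = place_map.percent_to_frequency(np.clip(pos, 0, 100))
    f_center = np.sqrt(spec.f_low * spec.f_high)
    f_anchor = spec.f_high * 2 ** model.basal_shift_octaves
    d_focal = octave_distance(cf, f_center)
    d_basal = octave_distance(cf, f_anchor)
    bracket = (
        np.exp(-d_focal**2 / (2 * model.focal_spread_octaves**2))
        + np.exp(-d_basal**2 / (2 * model.spread_octaves**2))
        + model.basal_gradient_per_percent * np.maximum(0.0, pos - 55.0)
    )
    p = np.clip(model.peak_loss(spec.level) * bracket, 0.0, 1.0)
    return np.where(np.asarray(is_ihc, dtype=bool), model.ihc_factor * p, p)


def survival_probability(position_percent, row, spec: StimulusSpec,
                         model: LesionModel,
                         place_map: PlaceFrequencyMap | None = None):
    """Probability that a bundle survives the exposure.

    Accepts scalars or arrays; ``row`` is any of IHC/OHC1/OHC2/OHC3
    (or the class labels IHC/OHC).
    """
    place_map = place_map or PlaceFrequencyMap()
    is_ihc = np.asarray(row, dtype=object) == "IHC"
    p = _loss_probability(position_percent, is_ihc, spec, model, place_map)
    out = 1.0 - p
    return float(out) if np.isscalar(position_percent) else out


def apply_lesion(hc_map: HairCellMap, spec: StimulusSpec, model: LesionModel,
                 seed: int, place_map: PlaceFrequencyMap | None = None) -> HairCellMap:
    """Thin the map: each bundle independently survives with its survival probability.

    Maps can be lesioned exactly once (one exposure per animal).
    """
    if hc_map.lesioned:
        raise ValueError("map already lesioned; one exposure per map")
    place_map = place_map or PlaceFrequencyMap()
    rng = np.random.default_rng(seed)
    cells = hc_map.cells.copy()
    surv = survival_probability(cells["position_percent"].to_numpy(),
                                cells["row"].to_numpy(), spec, model, place_map)
    cells["present"] = rng.uniform(size=len(cells)) < surv
    return HairCellMap(cells, hc_map.params, lesioned=True)


def render_sector_substrate(hc_map: HairCellMap, sector_label: float,
                            params: CochleaParams | None = None) -> SamplingSubstrate:
    """Convert one 5% sector's present bundles to local µm coordinates.

    Sectors are half-open intervals ``(label-5, label]`` in percent
    distance from the apex, labelled by their basal edge.
    """
    params = params or hc_map.params
    if not 5 <= sector_label <= params.coverage_percent:
        raise ValueError(
            f"sector {sector_label} outside dissected coverage "
            f"(5..{params.coverage_percent})"
        )
    lo, hi = sector_label - 5.0, sector_label
    cells = hc_map.cells
    sel = (cells["position_percent"] > lo) & (cells["position_percent"] <= hi) \
        & cells["present"]
    sub = cells.loc[sel]
    x = (sub["position_percent"].to_numpy() - lo) * params.um_per_percent
    y = sub["lateral_um"].to_numpy()
    classes = np.where(sub["row"].to_numpy() == "IHC", "IHC", "OHC")
    return SamplingSubstrate(
        sector_label=float(sector_label),
        length_um=5.0 * params.um_per_percent,
        fringe_width_um=params.fringe_width_um,
        points=np.column_stack([x, y]) if len(sub) else np.empty((0, 2)),
        classes=classes,
    )
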