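"""Unbiased-frame sampling, density estimation and the Cochran CE.

Hair-bundle densities are estimated per 5% sector with 2-D unbiased
counting frames placed by systematic-uniform-random sampling along the
sector and uniformly across the stereociliary fringe.  Each frame
counts bundles under the Gundersen edge rule (inclusion on top/right,
exclusion on bottom/left), the reference area is estimated by corner
point-counting (area-per-point = frame area / 4), and the density is
the ratio estimator

    N_A = ΣQ · 1000 / Σa      [bundles per 1000 µm²]

whose precision is the Cochran ratio-estimator coefficient of error

    CE² = Σq²/(Σq)² + Σa²/(Σa)² − 2·Σqa/(Σq·Σa).

Lateral frame placement is uniform over the fringe width with periodic
wrap (a toroidal edge correction): every lateral position is then
sampled with equal probability, which makes the ratio estimator exactly
unbiased for the fringe-area density while keeping the per-frame
reference area constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .cochlea import CELL_CLASSES, SamplingSubstrate

__all__ = [
    "UndefinedDensityError",
    "SamplingDesign",
    "CountingFrame",
    "SectorEstimate",
    "place_frames",
    "count_frame",
    "sampled_area",
    "density",
    "coefficient_of_error",
    "estimate_sector",
]

LATERAL_UNIFORM_WRAP = "fringe_uniform_wrap"
LATERAL_MIDLINE_JITTER = "fringe_midline_jitter"


class UndefinedDensityError(ZeroDivisionError):
    """Raised when a density is requested with zero sampled reference area."""


@dataclass(frozen=True)
class SamplingDesign:
    """Frame geometry and placement strategy for one sector.

    ``ce_bessel_correction`` toggles an n/(n−1) factor on the CE (off by
    default); ``lateral_placement`` selects toroidal-uniform (default,
    unbiased) or midline-jitter placement.
    """

    frame_width_um: float = 25.0
    frame_height_um: float = 25.0
    frames_per_sector: int = 5
    lateral_placement: str = LATERAL_UNIFORM_WRAP
    ce_bessel_correction: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.frame_width_um <= 0 or self.frame_height_um <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.frames_per_sector < 2:
            raise ValueError("frames_per_sector must be >= 2 (CE needs >= 2 samples)")
        if self.lateral_placement not in (LATERAL_UNIFORM_WRAP, LATERAL_MIDLINE_JITTER):
            raise ValueError(f"unknown lateral placement {self.lateral_placement!r}")

    @property
    def frame_area_um2(self) -> float:
        return self.frame_width_um * self.frame_height_um


@dataclass
class CountingFrame:
    """One placed unbiased frame with its per-class counts.

    ``y0`` may wrap laterally (``wrap_width`` set): the frame occupies
    ``[y0, y0+height) mod wrap_width``.
    """

    x0: float
    y0: float
    width: float
    height: float
    wrap_width: float | None = None
    counts: dict = field(default_factory=dict)
    corner_hits: int = 0


def place_frames(substrate: SamplingSubstrate, design: SamplingDesign,
                 rng: np.random.Generator | None = None) -> list[CountingFrame]:
    """Systematic-uniform-random frames along the sector, toroidal laterally.

    One frame per equal longitudinal subinterval (random common start,
    fixed period), so frames never overlap; requires the sector to be at
    least ``frames_per_sector * frame_width`` long.
    """
    n, w, h = design.frames_per_sector, design.frame_width_um, design.frame_height_um
    L, W = substrate.length_um, substrate.fringe_width_um
    if L < n * w:
        raise ValueError(
            f"sector of {L:.1f} µm cannot hold {n} non-overlapping frames "
            f"of {w:.1f} µm; reduce frames_per_sector or frame_width"
        )
    if rng is None:
        rng = np.random.default_rng([design.seed, int(round(substrate.sector_label * 10))])
    period = L / n
    u = rng.uniform(0.0, period - w)
    frames = []
    for k in range(n):
        if design.lateral_placement == LATERAL_UNIFORM_WRAP:
            y0, wrap = rng.uniform(0.0, W), W
        else:
            if h > W:
                raise ValueError("frame taller than fringe under midline jitter")
            jitter = (W - h) / 2.0
            y0, wrap = W / 2.0 - h / 2.0 + rng.uniform(-jitter, jitter), None
        frames.append(CountingFrame(x0=u + k * period, y0=y0, width=w, height=h,
                                    wrap_width=wrap))
    return frames


def count_frame(frame: CountingFrame, substrate: SamplingSubstrate) -> CountingFrame:
    """Count bundles in a frame under the unbiased edge rule; set corner hits.

    A bundle is counted if strictly inside the frame or on the inclusion
    edges (top, right) and not on the exclusion edges (bottom, left):
    with local offsets dx = x − x0 and dy = y − y0 (lateral offset taken
    modulo the fringe width for wrapped frames), the bundle counts iff
    0 < dx ≤ width and 0 < dy ≤ height.  ``corner_hits`` is the number
    of the 4 frame corners inside the fringe rectangle.
    """
    pts, cls = substrate.points, substrate.classes
    if pts.size:
        dx = pts[:, 0] - frame.x0
        dy = pts[:, 1] - frame.y0
        if frame.wrap_width is not None:
            dy = dy % frame.wrap_width
        inside = (dx > 0) & (dx <= frame.width) & (dy > 0) & (dy <= frame.height)
    else:
        inside = np.zeros(0, dtype=bool)
    frame.counts = {c: int(np.sum(inside & (cls == c))) for c in CELL_CLASSES}

    L, W = substrate.length_um, substrate.fringe_width_um
    hits = 0
    for cx in (frame.x0, frame.x0 + frame.width):
        for cy in (frame.y0, frame.y0 + frame.height):
            if frame.wrap_width is not None:
                cy = cy % frame.wrap_width
            if 0 <= cx <= L and 0 <= cy <= W:
                hits += 1
    frame.corner_hits = hits
    return frame


def _frame_areas(frames: Sequence[CountingFrame]) -> np.ndarray:
    return np.array([f.corner_hits * f.width * f.height / 4.0 for f in frames])


def sampled_area(frames: Sequence[CountingFrame]) -> float:
    """Corner point-count estimate of the sampled reference area (µm²)."""
    if not frames:
        raise ValueError("need at least one frame")
    return float(_frame_areas(frames).sum())


def density(sum_q: float, sum_a: float) -> float:
    """N_A = ΣQ·1000/Σa, bundles per 1000 µm²."""
    if sum_a <= 0:
        raise UndefinedDensityError(
            "density undefined: zero sampled reference area"
        )
    return 1000.0 * sum_q / sum_a


def coefficient_of_error(q: Iterable[float], a: Iterable[float],
                         bessel: bool = False) -> float:
    """Cochran ratio-estimator CE of ΣQ/Σa across frames.

    Returns NaN (flagged undefined) when ΣQ or Σa is zero.  The
    quadratic form is floored at zero before the square root to guard
    against rounding; ``bessel`` applies an n/(n−1) factor.
    """
    q = np.asarray(list(q), dtype=float)
    a = np.asarray(list(a), dtype=float)
    if q.size != a.size or q.size < 2:
        raise ValueError("need matched per-frame q and a with >= 2 frames")
    sq, sa = q.sum(), a.sum()
    if sq == 0 or sa == 0:
        return float("nan")
    ce2 = (q @ q) / sq**2 + (a @ a) / sa**2 - 2.0 * (q @ a) / (sq * sa)
    if bessel:
        n = q.size
        ce2 *= n / (n - 1)
    return float(np.sqrt(max(ce2, 0.0)))


@dataclass(frozen=True)
class SectorEstimate:
    """Density estimate and its CE for one sector and one cell class."""

    sector_label: float
    cell_class: str
    sum_q: int
    sum_a_um2: float
    n_a_per_1000um2: float
    ce: float
    n_frames: int


def estimate_sector(substrate: SamplingSubstrate, design: SamplingDesign,
                    rng: np.random.Generator | None = None) -> list[SectorEstimate]:
    """Run the full per-sector procedure for both cell classes.

    The same frames (hence the same Σa) serve IHC and OHC; the CE is
    computed per class.  A class with ΣQ = 0 gets density 0 and CE NaN.
    """
    frames = place_frames(substrate, design, rng=rng)
    for f in frames:
        count_frame(f, substrate)
    areas = _frame_areas(frames)
    sum_a = float(areas.sum())
    out = []
    for c in CELL_CLASSES:
        q = np.array([f.counts[c] for f in frames], dtype=float)
        n_a = density(q.sum(), sum_a) if sum_a > 0 else float("nan")
        ce = coefficient_of_error(q, areas, bessel=design.ce_bessel_correction)
        out.append(SectorEstimate(
            sector_label=substrate.sector_label, cell_class=c,
            sum_q=int(q.sum()), sum_a_um2=sum_a,
            n_a_per_1000um2=n_a, ce=ce, n_frames=len(frames),
        ))
    return out
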