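"""ABR/DPOAE cohort simulation, threshold detection and audiograms.

Hearing function in the NIHL model is followed longitudinally: auditory
brainstem responses (ABR) to click and tone-burst stimuli presented in
descending 5 dB steps, and distortion-product otoacoustic emissions
(DPOAE) at 2f1−f2 for primary pairs derived from a central frequency
(f1 = 0.909·F, f2 = 1.09·F, so f2/f1 ≈ 1.2).

The cohort simulator draws each subject's true threshold from a
calibrated group × timepoint × stimulus distribution, renders a level
series (zero response below threshold, saturating growth above it,
optional additive noise), and detects the threshold as the lowest grid
level whose response exceeds ``criterion_k`` times the noise floor with
every higher level also responding.  Detected thresholds therefore land
on the grid ceiling of the true threshold.  Threshold shift (TS) is
post minus baseline.

The default calibration emulates four exposure groups (unexposed
control; violet swept-sine 2–20 kHz at 105 and 120 dB SPL; 9–13 kHz at
105 dB SPL) over days 0/2/14/28: controls stay flat, the 120 dB group
worsens by day 14, the 9–13 kHz group recovers partially and keeps an
audiogram notch at 8–10 kHz.  Treatment arms (saline/P17/P144) share
the exposed distribution — a null treatment effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ABR_GRID",
    "DPOAE_GRID",
    "TONE_FREQS_KHZ",
    "DPOAE_CENTER_FREQS_KHZ",
    "GROUPS",
    "ThresholdResult",
    "CohortDesign",
    "dpoae_primaries",
    "simulate_level_series",
    "detect_threshold",
    "threshold_shift",
    "default_design",
    "simulate_cohort",
    "audiogram_table",
    "threshold_shift_table",
    "structure_function_correlation",
]

#: presentation grids, dB SPL, presented in descending order
ABR_GRID = np.arange(90, 5, -5)
DPOAE_GRID = np.arange(80, 25, -5)

TONE_FREQS_KHZ = (4.0, 8.0, 10.0, 16.0, 20.0, 28.0, 40.0)
DPOAE_CENTER_FREQS_KHZ = (8.0, 10.0, 14.0, 18.0, 22.0)

EXPOSED = ("vs105_2_20", "vs120_2_20", "vs105_9_13")
TREATMENTS = ("saline", "p17", "p144")
GROUPS = ("control",) + EXPOSED + TREATMENTS

OK, ABOVE_CEILING, AT_FLOOR = "ok", "above_ceiling", "at_floor"


def dpoae_primaries(F: float) -> tuple[float, float, float]:
    """Primary tones and distortion product for a central frequency (kHz).

    f1 = 0.909·F, f2 = 1.09·F (f2/f1 ≈ 1.2), f_dp = 2·f1 − f2.
    """
    if F <= 0:
        raise ValueError("central frequency must be positive")
    f1, f2 = 0.909 * F, 1.09 * F
    return f1, f2, 2 * f1 - f2


@dataclass(frozen=True)
class ThresholdResult:
    """A detected threshold in dB SPL with its grid-edge flag."""

    value: float
    flag: str = OK

    @property
    def ok(self) -> bool:
        return self.flag == OK


def simulate_level_series(true_threshold: float, grid: np.ndarray,
                          noise_sd: float = 0.0,
                          rng: np.random.Generator | int | None = None,
                          saturation: float = 1.0,
                          growth_db: float = 10.0) -> np.ndarray:
    """Response amplitude at each grid level (arbitrary units).

    Zero mean below the true threshold (noise-floor draws), saturating
    exponential growth above it, additive Gaussian noise everywhere.
    """
    rng = np.random.default_rng(rng)
    grid = np.asarray(grid, dtype=float)
    above = grid > true_threshold
    amp = np.where(
        above, saturation * (1 - np.exp(-(grid - true_threshold) / growth_db)), 0.0)
    if noise_sd > 0:
        amp = amp + rng.normal(0.0, noise_sd, size=grid.shape)
    return amp


def detect_threshold(grid: np.ndarray, amplitudes: np.ndarray,
                     noise_floor: float = 0.0,
                     criterion_k: float = 2.0) -> ThresholdResult:
    """Lowest level responding above criterion with all higher levels responding.

    The criterion is ``criterion_k × noise_floor`` (strictly exceeded).
    No response anywhere → flagged ``above_ceiling`` and recorded as
    ceiling + step; a response at the lowest presented level → flagged
    ``at_floor``.
    """
    grid = np.asarray(grid, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if grid.size < 3 or grid.size != amplitudes.size:
        raise ValueError("need a grid of >= 3 levels matching the amplitudes")
    order = np.argsort(grid)[::-1]  # descending presentation
    levels, amps = grid[order], amplitudes[order]
    step = float(np.abs(np.diff(levels)).min())
    responding = amps > criterion_k * noise_floor
    if not responding.any():
        return ThresholdResult(levels[0] + step, ABOVE_CEILING)
    # run of responses starting at the highest level
    run_end = np.argmin(responding) if not responding.all() else len(levels)
    if run_end == 0:
        return ThresholdResult(levels[0] + step, ABOVE_CEILING)
    detected = levels[run_end - 1]
    if run_end == len(levels):
        return ThresholdResult(float(detected), AT_FLOOR)
    return ThresholdResult(float(detected), OK)


def threshold_shift(baseline: ThresholdResult | float,
                    post: ThresholdResult | float) -> ThresholdResult:
    """TS = post − baseline (dB); grid-edge flags propagate."""
    b = baseline if isinstance(baseline, ThresholdResult) else ThresholdResult(baseline)
    p = post if isinstance(post, ThresholdResult) else ThresholdResult(post)
    flag = OK if (b.ok and p.ok) else (p.flag if not p.ok else b.flag)
    return ThresholdResult(p.value - b.value, flag)


# --------------------------------------------------------------------------
# cohort calibration

def _abr_calibration() -> dict:
    """(group, timepoint_days, stimulus) -> (true mean dB SPL, sd)."""
    base_sd, post_sd = 4.0, 5.0
    stimuli = ("click",) + TONE_FREQS_KHZ
    table: dict = {}
    for stim in stimuli:
        for t in (0, 2, 14, 28):
            table[("control", t, stim)] = (15.0, base_sd)
        table[("vs105_2_20", 0, stim)] = (15.0, base_sd)
        table[("vs120_2_20", 0, stim)] = (15.0, base_sd)
        table[("vs105_9_13", 0, stim)] = (15.0, base_sd)

    def tones(group, t, by_freq):
        for f, m in zip(TONE_FREQS_KHZ, by_freq):
            table[(group, t, f)] = (float(m), post_sd)

    # 105 VS 2-20: ~50 dB click TS at day 2, slow partial recovery
    table[("vs105_2_20", 2, "click")] = (67.0, post_sd)
    table[("vs105_2_20", 14, "click")] = (62.0, post_sd)
    table[("vs105_2_20", 28, "click")] = (58.0, post_sd)
    tones("vs105_2_20", 2, (60, 63, 64, 65, 66, 67, 68))
    tones("vs105_2_20", 14, (55, 58, 59, 60, 61, 62, 63))
    tones("vs105_2_20", 28, (51, 54, 55, 56, 57, 58, 59))
    # 120 VS 2-20: worsens by day 14, permanent
    table[("vs120_2_20", 2, "click")] = (72.0, post_sd)
    table[("vs120_2_20", 14, "click")] = (80.0, post_sd)
    table[("vs120_2_20", 28, "click")] = (82.0, post_sd)
    tones("vs120_2_20", 2, (62, 68, 70, 72, 74, 76, 78))
    tones("vs120_2_20", 14, (70, 76, 78, 80, 82, 84, 85))
    tones("vs120_2_20", 28, (70, 77, 79, 81, 83, 85, 85))
    # 105 VS 9-13: early notch at 8-10 kHz, partial quick recovery
    table[("vs105_9_13", 2, "click")] = (67.0, post_sd)
    table[("vs105_9_13", 14, "click")] = (60.0, post_sd)
    table[("vs105_9_13", 28, "click")] = (55.0, post_sd)
    tones("vs105_9_13", 2, (50, 72, 75, 65, 62, 64, 66))
    tones("vs105_9_13", 14, (40, 58, 62, 50, 48, 50, 52))
    tones("vs105_9_13", 28, (23, 50, 55, 40, 43, 45, 47))
    # treatment arms share the 105 VS 2-20 exposed distribution (null effect)
    for arm in TREATMENTS:
        for (group, t, stim), v in list(table.items()):
            if group == "vs105_2_20":
                table[(arm, t, stim)] = v
    return table


def _dpoae_calibration() -> dict:
    table: dict = {}
    for g in GROUPS:
        for F in DPOAE_CENTER_FREQS_KHZ:
            for t in (0, 2, 14, 28):
                exposed = g != "control" and t > 0
                table[(g, t, F)] = (68.0, 5.0) if exposed else (35.0, 4.0)
    return table


@dataclass(frozen=True)
class CohortDesign:
    """Group sizes and true-threshold calibration for a simulated cohort."""

    group_sizes: dict = field(default_factory=lambda: {
        "control": 12, "vs105_2_20": 12, "vs120_2_20": 8, "vs105_9_13": 12,
        "saline": 6, "p17": 6, "p144": 6,
    })
    timepoints: tuple = (0, 2, 14, 28)
    abr_table: dict = field(default_factory=_abr_calibration)
    dpoae_table: dict = field(default_factory=_dpoae_calibration)
    noise_sd: float = 0.0
    criterion_k: float = 2.0
    subject_sd: float = 3.0  # within-subject susceptibility, shared across days
    seed: int = 0

    def __post_init__(self):
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        for (_, _, _), (m, sd) in {**self.abr_table, **self.dpoae_table}.items():
            if sd <= 0:
                raise ValueError("threshold sds must be positive")


def default_design(seed: int = 0, **overrides) -> CohortDesign:
    return replace(CohortDesign(), seed=seed, **overrides)


def _simulate_records(design: CohortDesign, table: dict, grid: np.ndarray,
                      modality: str, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group, n in sorted(design.group_sizes.items()):
        stimuli = sorted({s for (g, _, s) in table if g == group}, key=str)
        for subj in range(n):
            sid = f"{group}_{subj:02d}"
            # per-animal susceptibility: thresholds are paired within subject,
            # so a shared offset correlates timepoints; the residual sd keeps
            # the marginal (mean, sd) calibration intact
            offset = rng.normal(0.0, design.subject_sd)
            for t in design.timepoints:
                for stim in stimuli:
                    if (group, t, stim) not in table:
                        continue
                    mean, sd = table[(group, t, stim)]
                    resid = np.sqrt(max(sd**2 - design.subject_sd**2, 0.25))
                    true_thr = mean + offset + rng.normal(0.0, resid)
                    amps = simulate_level_series(
                        true_thr, grid, noise_sd=design.noise_sd, rng=rng)
                    det = detect_threshold(grid, amps,
                                           noise_floor=design.noise_sd,
                                           criterion_k=design.criterion_k)
                    rows.append({
                        "subject": sid, "group": group, "timepoint_days": t,
                        "modality": modality, "stimulus": str(stim),
                        "freq_khz": float(stim) if stim != "click" else np.nan,
                        "true_threshold_db": true_thr,
                        "threshold_db": det.value, "flag": det.flag,
                    })
    return pd.DataFrame(rows)


def simulate_cohort(design: CohortDesign) -> pd.DataFrame:
    """Simulate the full ABR + DPOAE cohort; returns one long-format table.

    Fully determined by ``design.seed``: identical designs give
    identical tables.
    """
    root = np.random.SeedSequence(design.seed)
    abr_rng, dp_rng = (np.random.default_rng(s) for s in root.spawn(2))
    abr = _simulate_records(design, design.abr_table, ABR_GRID, "abr", abr_rng)
    dpoae = _simulate_records(design, design.dpoae_table, DPOAE_GRID, "dpoae", dp_rng)
    return pd.concat([abr, dpoae], ignore_index=True)


def audiogram_table(records: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM detected threshold by group × timepoint × stimulus.

    Grid-edge-flagged records are excluded from the mean and reported in
    ``n_flagged``; a cell with a single record carries SEM = NaN.
    """
    if records.empty:
        raise ValueError("no records to aggregate")
    keys = ["modality", "group", "timepoint_days", "stimulus"]
    ok = records[records["flag"] == OK]
    agg = ok.groupby(keys)["threshold_db"].agg(
        mean="mean", sem=lambda v: stats.sem(v) if len(v) > 1 else np.nan,
        n="count").reset_index()
    flagged = (records[records["flag"] != OK].groupby(keys).size()
               .rename("n_flagged").reset_index())
    out = agg.merge(flagged, on=keys, how="left")
    out["n_flagged"] = out["n_flagged"].fillna(0).astype(int)
    return out


def threshold_shift_table(records: pd.DataFrame, baseline_day: int = 0) -> pd.DataFrame:
    """Per-subject paired TS (post − baseline) for every later timepoint."""
    ok = records[records["flag"] == OK]
    base = ok[ok["timepoint_days"] == baseline_day]
    post = ok[ok["timepoint_days"] != baseline_day]
    keys = ["subject", "group", "modality", "stimulus", "freq_khz"]
    merged = post.merge(base[keys + ["threshold_db"]], on=keys,
                        suffixes=("", "_baseline"))
    merged["ts_db"] = merged["threshold_db"] - merged["threshold_db_baseline"]
    return merged[keys + ["timepoint_days", "ts_db"]]


def structure_function_correlation(ts_by_freq: pd.DataFrame,
                                   loss_table: pd.DataFrame,
                                   place_map=None,
                                   coverage_percent: float = 80.0) -> dict:
    """Rank-correlate tone-frequency TS with OHC loss at the mapped sectors.

    ``ts_by_freq`` needs columns freq_khz and ts_db (e.g. group-mean TS
    at day 28); ``loss_table`` is a :func:`~nihlsim.cochleogram.percent_loss`
    table.  Each tone frequency is assigned the 5% sector containing its
    cochlear place (frequencies apical of the map's range go to the
    apical-most sector).  Returns the paired table plus Spearman rho.
    """
    from .placemap import PlaceFrequencyMap

    place_map = place_map or PlaceFrequencyMap()
    ohc = loss_table[loss_table["cell_class"] == "OHC"]
    pairs = []
    for _, row in ts_by_freq.iterrows():
        f = float(row["freq_khz"])
        pos = place_map.frequency_to_percent(
            float(np.clip(f, place_map.f_min, place_map.f_max)))
        sector = float(np.clip(5 * np.ceil(pos / 5), 5, coverage_percent))
        match = ohc[ohc["sector"] == sector]
        if match.empty or not np.isfinite(match["percent_loss"].iloc[0]):
            continue
        pairs.append({"freq_khz": f, "sector": sector,
                      "ts_db": float(row["ts_db"]),
                      "ohc_percent_loss": float(match["percent_loss"].iloc[0])})
    paired = pd.DataFrame(pairs)
    if len(paired) < 3:
        raise ValueError("fewer than 3 overlapping frequency/sector pairs")
    rho, p = stats.spearmanr(paired["ts_db"], paired["ohc_percent_loss"])
    return {"pairs": paired, "spearman_rho": float(rho),
            "p_value": float(p), "n": int(len(paired))}
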