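"""End-to-end pipeline: expose → evaluate hearing → dissect → count → plot.

``run_pipeline`` drives every stage from one :class:`RunConfig` and a
single master seed: stimulus synthesis + verification, synthetic
cochleae per exposure group, lesioning, stereological estimation,
cytocochleograms and percent-loss tables, the ABR/DPOAE cohort with
audiogram summaries, and the structure–function correlation for the
narrow-band group.  Outputs are plain CSV/JSON/WAV files plus a
manifest recording the derived stage seeds, so reruns with the same
config are byte-identical and any stage can be regenerated in
isolation.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .audiology import (CohortDesign, audiogram_table, simulate_cohort,
                        structure_function_correlation, threshold_shift_table)
from .cochlea import (CochleaParams, LesionModel, apply_lesion,
                      build_control_map)
from .cochleogram import CochleogramModel, percent_loss
from .placemap import PlaceFrequencyMap
from .stereology import SamplingDesign
from .stimulus import StimulusSpec, synthesize, verify_waveform

__all__ = ["RunConfig", "run_pipeline", "EXPOSURE_SPECS"]

log = logging.getLogger("nihlsim.pipeline")

#: the four experimental groups' stimuli (exposure level dB SPL, band kHz)
EXPOSURE_SPECS = {
    "vs105_2_20": StimulusSpec("violet_sweep", 2, 20, 105, 1800, 10),
    "vs120_2_20": StimulusSpec("violet_sweep", 2, 20, 120, 1800, 10),
    "vs105_9_13": StimulusSpec("violet_sweep", 9, 13, 105, 1800, 10),
}


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; round-trips losslessly via YAML."""

    master_seed: int = 0
    cochlea: CochleaParams = field(default_factory=CochleaParams)
    lesion: LesionModel = field(default_factory=LesionModel)
    design: SamplingDesign = field(default_factory=SamplingDesign)
    cohort: CohortDesign = field(default_factory=CohortDesign)
    place_map: PlaceFrequencyMap = field(default_factory=PlaceFrequencyMap)
    maps_per_group: int = 4
    render_duration_s: float = 2.0  # WAV excerpt length written to disk

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["abr_table"] = {
            "|".join(map(str, k)): list(v) for k, v in self.cohort.abr_table.items()}
        d["cohort"]["dpoae_table"] = {
            "|".join(map(str, k)): list(v) for k, v in self.cohort.dpoae_table.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, payload, name):
            try:
                return klass(**payload)
            except (TypeError, ValueError) as err:
                raise ValueError(f"invalid config field {name!r}: {err}") from err

        d = dict(d)
        parsed = {}
        for name, klass in (("cochlea", CochleaParams), ("lesion", LesionModel),
                            ("design", SamplingDesign), ("place_map", PlaceFrequencyMap)):
            if name in d:
                payload = dict(d.pop(name))
                if name == "lesion" and "peak_loss_by_level" in payload:
                    payload["peak_loss_by_level"] = tuple(
                        tuple(p) for p in payload["peak_loss_by_level"])
                parsed[name] = build(klass, payload, name)
        if "cohort" in d:
            payload = dict(d.pop("cohort"))
            for key in ("abr_table", "dpoae_table"):
                if key in payload and payload[key] and \
                        isinstance(next(iter(payload[key])), str):
                    decoded = {}
                    for flat, v in payload[key].items():
                        g, t, s = flat.split("|")
                        stim = s if s == "click" else float(s)
                        decoded[(g, int(t), stim)] = tuple(v)
                    payload[key] = decoded
            if "timepoints" in payload:
                payload["timepoints"] = tuple(payload["timepoints"])
            parsed["cohort"] = build(CohortDesign, payload, "cohort")
        return build(cls, {**d, **parsed}, "run")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage 31-bit seed derived from the master seed."""
    digest = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([master, digest])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage; write outputs under ``outdir``; return the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__,
                      "master_seed": config.master_seed,
                      "stage_seeds": {}, "outputs": [], "errors": {}}

    def record(path: Path):
        manifest["outputs"].append(str(path.relative_to(out)))

    # --- stimuli ---------------------------------------------------------
    for name, spec in EXPOSURE_SPECS.items():
        seed = _stage_seed(config.master_seed, f"stimulus/{name}")
        manifest["stage_seeds"][f"stimulus/{name}"] = seed
        excerpt = replace(spec, total_duration=config.render_duration_s,
                          sweep_duration=min(spec.sweep_duration,
                                             config.render_duration_s))
        wave = synthesize(excerpt, seed=seed)
        wav_path = out / f"stimulus_{name}.wav"
        wave.to_wav(wav_path)
        record(wav_path)
        report = verify_waveform(wave, excerpt)
        report["full_spec"] = json.loads(spec.to_json())
        rep_path = out / f"stimulus_{name}_report.json"
        rep_path.write_text(json.dumps(report, indent=2))
        record(rep_path)
        log.info("stimulus %s: seed=%s rms=%.3g Pa", name, seed, wave.rms)

    # --- cochleae + cochleograms ----------------------------------------
    results: dict[str, list] = {}
    for group in ("control",) + tuple(EXPOSURE_SPECS):
        fits = []
        for i in range(config.maps_per_group):
            seed = _stage_seed(config.master_seed, f"cochlea/{group}/{i}")
            manifest["stage_seeds"][f"cochlea/{group}/{i}"] = seed
            hc_map = build_control_map(config.cochlea, seed=seed)
            if group != "control":
                hc_map = apply_lesion(hc_map, EXPOSURE_SPECS[group], config.lesion,
                                      seed=seed + 1, place_map=config.place_map)
            map_path = out / f"map_{group}_{i}.csv"
            hc_map.to_csv(map_path)
            record(map_path)
            fit = CochleogramModel(hc_map, config.design, config.place_map).fit(
                seed=seed + 2)
            fits.append(fit)
        results[group] = fits
        mean = (pd.concat([f.data for f in fits])
                .groupby(["sector", "cell_class"], as_index=False)
                .agg({"sum_q": "sum", "sum_a_um2": "sum",
                      "n_a_per_1000um2": "mean", "ce": "mean",
                      "freq_khz": "first"}))
        coch_path = out / f"cochleogram_{group}.csv"
        mean.to_csv(coch_path, index=False)
        record(coch_path)
        log.info("cochleogram %s: n_maps=%d mean OHC N_A=%.2f", group,
                 len(fits), mean.loc[mean.cell_class == "OHC", "n_a_per_1000um2"].mean())

    control_mean = pd.read_csv(out / "cochleogram_control.csv")
    from .cochleogram import Cochleogram
    control_c = Cochleogram(control_mean, config.cochlea.coverage_percent,
                            config.place_map)
    losses = {}
    for group in EXPOSURE_SPECS:
        g = Cochleogram(pd.read_csv(out / f"cochleogram_{group}.csv"),
                        config.cochlea.coverage_percent, config.place_map)
        loss = percent_loss(g, control_c)
        losses[group] = loss
        loss_path = out / f"percent_loss_{group}.csv"
        loss.to_csv(loss_path, index=False)
        record(loss_path)

    # --- cohort ----------------------------------------------------------
    cohort_seed = _stage_seed(config.master_seed, "cohort")
    manifest["stage_seeds"]["cohort"] = cohort_seed
    records = simulate_cohort(replace(config.cohort, seed=cohort_seed))
    rec_path = out / "cohort_records.csv"
    records.to_csv(rec_path, index=False)
    record(rec_path)
    audiogram = audiogram_table(records)
    aud_path = out / "audiogram_summary.csv"
    audiogram.to_csv(aud_path, index=False)
    record(aud_path)

    # --- structure-function correlation (narrow-band group, day 28) ------
    ts = threshold_shift_table(records)
    ts_928 = (ts[(ts["group"] == "vs105_9_13") & (ts["timepoint_days"] == 28)
                 & (ts["modality"] == "abr") & ts["freq_khz"].notna()]
              .groupby("freq_khz", as_index=False)["ts_db"].mean())
    corr = structure_function_correlation(
        ts_928, losses["vs105_9_13"], config.place_map,
        coverage_percent=config.cochlea.coverage_percent)
    corr_path = out / "structure_function.json"
    corr_path.write_text(json.dumps(
        {k: (v.to_dict(orient="records") if isinstance(v, pd.DataFrame) else v)
         for k, v in corr.items()}, indent=2))
    record(corr_path)
    log.info("structure-function rho=%.3f (n=%d)", corr["spearman_rho"], corr["n"])

    config.to_yaml(out / "config.yaml")
    record(out / "config.yaml")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
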