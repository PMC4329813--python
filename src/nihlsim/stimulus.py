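"""Violet and violet swept-sine (VS) noise synthesis and verification.

Exposure stimuli for the mouse NIHL model are "violet" sounds: their
amplitude spectrum rises linearly with frequency (+6.02 dB/octave in
power), compensating the high-frequency roll-off of an exposure chamber
and biasing energy toward the upper half of the mouse audiogram.  Two
kinds are provided:

* ``violet_noise`` — Gaussian white noise reshaped in the frequency
  domain so that amplitude gain is proportional to frequency inside the
  exposure band, with raised-cosine band edges.
* ``violet_sweep`` — a repeated linear sweep (chirp) whose instantaneous
  frequency rises linearly across the band and whose envelope is
  proportional to the instantaneous frequency.

Levels are set by RMS scaling against a reference pressure (SPL on the
digital waveform; no transducer or room model).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

__all__ = [
    "StimulusSpec",
    "Waveform",
    "synth_violet_noise",
    "synth_violet_sweep",
    "synthesize",
    "instantaneous_frequency",
    "estimate_psd_slope",
    "band_power_fraction",
    "sweep_ridge_linearity",
    "scale_to_level",
    "verify_waveform",
    "P_REF",
]

#: reference pressure for SPL, Pa
P_REF = 20e-6

VIOLET_NOISE = "violet_noise"
VIOLET_SWEEP = "violet_sweep"


@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of an exposure stimulus.

    Parameters
    ----------
    kind : {"violet_noise", "violet_sweep"}
    f_low, f_high : float
        Band edges in kHz; for the sweep, the start and end frequency.
    level : float
        Target sound pressure level in dB SPL (set by RMS scaling).
    total_duration : float
        Total stimulus duration in seconds.
    sweep_duration : float or None
        Duration of one sweep in seconds (sweep kind only); the sweep is
        repeated back-to-back until ``total_duration``.
    sample_rate : float
        Sampling rate in Hz; must exceed twice the upper band edge.
    """

    kind: str
    f_low: float = 2.0
    f_high: float = 20.0
    level: float = 105.0
    total_duration: float = 30 * 60.0
    sweep_duration: float | None = None
    sample_rate: float = 96_000.0

    def __post_init__(self):
        if self.kind not in (VIOLET_NOISE, VIOLET_SWEEP):
            raise ValueError(f"unknown stimulus kind: {self.kind!r}")
        if not 0 < self.f_low < self.f_high:
            raise ValueError("need 0 < f_low < f_high (kHz)")
        if self.sample_rate <= 2 * self.f_high * 1000:
            raise ValueError(
                f"sample_rate {self.sample_rate} Hz violates Nyquist for "
                f"f_high={self.f_high} kHz"
            )
        if self.total_duration <= 0:
            raise ValueError("total_duration must be positive")
        if self.kind == VIOLET_SWEEP:
            if self.sweep_duration is None or self.sweep_duration <= 0:
                raise ValueError("violet_sweep needs sweep_duration > 0")
            if self.total_duration < self.sweep_duration:
                raise ValueError("total_duration must be >= sweep_duration")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "StimulusSpec":
        return cls(**json.loads(text))

    def with_level(self, level: float) -> "StimulusSpec":
        return replace(self, level=level)


@dataclass
class Waveform:
    """A sampled pressure waveform (arbitrary units before SPL scaling)."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def to_wav(self, path: str | Path, normalize: bool = True) -> None:
        """Write float32 WAV; peak-normalized to 0.95 unless disabled."""
        x = self.samples.astype(np.float32)
        if normalize and np.max(np.abs(x)) > 0:
            x = 0.95 * x / np.max(np.abs(x))
        wavfile.write(str(path), int(self.sample_rate), x)

    @classmethod
    def from_wav(cls, path: str | Path) -> "Waveform":
        fs, x = wavfile.read(str(path))
        x = np.asarray(x, dtype=np.float64)
        if x.dtype.kind == "i":  # pragma: no cover - ints already cast above
            x = x / np.iinfo(x.dtype).max
        return cls(x, float(fs))


def _violet_band_gain(freqs_hz: np.ndarray, f_low_hz: float, f_high_hz: float,
                      taper_frac: float = 0.05) -> np.ndarray:
    """Amplitude gain ∝ f inside the band, raised-cosine tapered edges.

    The taper width is ``taper_frac`` of the band width on each side,
    applied inside the nominal band so that out-of-band energy is
    strongly attenuated without ringing.
    """
    bw = f_high_hz - f_low_hz
    tw = taper_frac * bw
    gain = np.where(
        (freqs_hz >= f_low_hz) & (freqs_hz <= f_high_hz), freqs_hz, 0.0
    ).astype(float)
    lo_edge = (freqs_hz >= f_low_hz) & (freqs_hz < f_low_hz + tw)
    hi_edge = (freqs_hz > f_high_hz - tw) & (freqs_hz <= f_high_hz)
    gain[lo_edge] *= 0.5 * (1 - np.cos(np.pi * (freqs_hz[lo_edge] - f_low_hz) / tw))
    gain[hi_edge] *= 0.5 * (1 - np.cos(np.pi * (f_high_hz - freqs_hz[hi_edge]) / tw))
    return gain


def synth_violet_noise(spec: StimulusSpec, seed: int) -> Waveform:
    """Synthesize band-limited violet noise from seeded white noise.

    White Gaussian noise is transformed to the frequency domain, its
    amplitude multiplied by frequency inside ``[f_low, f_high]`` (zero
    outside, raised-cosine edges), and transformed back.  Identical
    seeds give bit-identical output.
    """
    if spec.kind != VIOLET_NOISE:
        raise ValueError("spec.kind must be 'violet_noise'")
    rng = np.random.default_rng(seed)
    n = int(round(spec.total_duration * spec.sample_rate))
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sample_rate)
    spectrum *= _violet_band_gain(freqs, spec.f_low * 1000, spec.f_high * 1000)
    x = np.fft.irfft(spectrum, n=n)
    x /= np.sqrt(np.mean(x**2))  # unit RMS before SPL scaling
    return Waveform(x, spec.sample_rate)


def instantaneous_frequency(spec: StimulusSpec, t: float | np.ndarray) -> np.ndarray:
    """Instantaneous frequency (kHz) of the repeated linear sweep at time t (s)."""
    if spec.kind != VIOLET_SWEEP:
        raise ValueError("spec.kind must be 'violet_sweep'")
    tt = np.asarray(t, dtype=float) % spec.sweep_duration
    # the sweep endpoint t == T maps to f_high, not back to f_low
    tt = np.where((np.asarray(t, dtype=float) != 0) & (tt == 0), spec.sweep_duration, tt)
    return spec.f_low + (spec.f_high - spec.f_low) * tt / spec.sweep_duration


def synth_violet_sweep(spec: StimulusSpec) -> Waveform:
    """Synthesize the repeated linear sweep with frequency-proportional envelope.

    Instantaneous frequency rises linearly from ``f_low`` to ``f_high``
    over ``sweep_duration``; the envelope is proportional to the
    instantaneous frequency (the linear-with-frequency gain); the sweep
    repeats back-to-back, truncating the last repeat at
    ``total_duration``.  Deterministic (no randomness).
    """
    if spec.kind != VIOLET_SWEEP:
        raise ValueError("spec.kind must be 'violet_sweep'")
    fs = spec.sample_rate
    t1 = np.arange(int(round(spec.sweep_duration * fs))) / fs
    f0, f1 = spec.f_low * 1000, spec.f_high * 1000
    T = spec.sweep_duration
    phase = 2 * np.pi * (f0 * t1 + (f1 - f0) * t1**2 / (2 * T))
    envelope = (f0 + (f1 - f0) * t1 / T) / f1
    one = envelope * np.sin(phase)
    n_total = int(round(spec.total_duration * fs))
    reps = int(np.ceil(n_total / one.size))
    x = np.tile(one, reps)[:n_total]
    x = x / np.sqrt(np.mean(x**2))
    return Waveform(x, fs)


def synthesize(spec: StimulusSpec, seed: int = 0) -> Waveform:
    """Synthesize either stimulus kind and scale it to ``spec.level`` dB SPL."""
    if spec.kind == VIOLET_NOISE:
        w = synth_violet_noise(spec, seed)
    else:
        w = synth_violet_sweep(spec)
    return scale_to_level(w, spec.level)


def scale_to_level(w: Waveform, level: float, p_ref: float = P_REF) -> Waveform:
    """Scale a waveform so its RMS equals ``p_ref * 10**(level/20)`` (Pa).

    Pure scalar multiplication; idempotent for a fixed level.
    """
    rms = w.rms
    if rms == 0:
        raise ValueError("cannot scale a zero-RMS waveform")
    target = p_ref * 10 ** (level / 20.0)
    return Waveform(w.samples * (target / rms), w.sample_rate)


def _welch_psd(w: Waveform, nperseg: int = 4096):
    nperseg = min(nperseg, w.samples.size)
    return sps.welch(w.samples, fs=w.sample_rate, nperseg=nperseg)


def estimate_psd_slope(w: Waveform, band: tuple[float, float]) -> float:
    """Fit the averaged power spectrum over ``band`` (kHz); return dB/octave.

    A least-squares line is fitted to 10·log10(PSD) against log2(f)
    over the requested band.  Violet shaping gives ≈ +6.02 dB/octave.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError("band must satisfy 0 < low < high (kHz)")
    if hi * 1000 > w.sample_rate / 2:
        raise ValueError("band exceeds Nyquist")
    if w.duration < 1.0:
        raise ValueError("waveform too short for PSD averaging (need >= 1 s)")
    f, pxx = _welch_psd(w)
    sel = (f >= lo * 1000) & (f <= hi * 1000) & (pxx > 0)
    if sel.sum() < 8:
        raise ValueError("band too narrow for the PSD resolution")
    octaves = np.log2(f[sel])
    db = 10 * np.log10(pxx[sel])
    slope = np.polyfit(octaves, db, 1)[0]
    return float(slope)


def band_power_fraction(w: Waveform, f_low: float, f_high: float,
                        margin: float = 0.1) -> float:
    """Fraction of total power inside ``[f_low*(1-margin), f_high*(1+margin)]`` (kHz)."""
    f, pxx = _welch_psd(w)
    total = np.trapezoid(pxx, f)
    sel = (f >= f_low * 1000 * (1 - margin)) & (f <= f_high * 1000 * (1 + margin))
    return float(np.trapezoid(pxx[sel], f[sel]) / total)


def sweep_ridge_linearity(w: Waveform, sweep_duration: float,
                          nperseg: int = 1024) -> dict:
    """Track the spectrogram ridge over one sweep; return fit diagnostics.

    Returns a dict with ``r2`` of a line fit to ridge frequency vs time,
    plus the fitted start/end frequencies (kHz) of the sweep.
    """
    n = int(round(sweep_duration * w.sample_rate))
    f, t, sxx = sps.spectrogram(w.samples[:n], fs=w.sample_rate,
                                nperseg=nperseg, noverlap=nperseg // 2)
    ridge = f[np.argmax(sxx, axis=0)]
    # discard edge frames where the window truncates the sweep
    keep = slice(1, -1)
    coef = np.polyfit(t[keep], ridge[keep], 1)
    pred = np.polyval(coef, t[keep])
    resid = ridge[keep] - pred
    ss_tot = np.sum((ridge[keep] - ridge[keep].mean()) ** 2)
    r2 = 1 - np.sum(resid**2) / ss_tot
    return {
        "r2": float(r2),
        "f_start_khz": float(np.polyval(coef, 0.0) / 1000),
        "f_end_khz": float(np.polyval(coef, sweep_duration) / 1000),
        "slope_khz_per_s": float(coef[0] / 1000),
    }


def verify_waveform(w: Waveform, spec: StimulusSpec) -> dict:
    """Report PSD slope, band containment and (for sweeps) ridge linearity."""
    bw = spec.f_high - spec.f_low
    interior = (spec.f_low + 0.15 * bw, spec.f_high - 0.15 * bw)
    report = {
        "kind": spec.kind,
        "rms_pa": w.rms,
        "level_db_spl": 20 * np.log10(w.rms / P_REF) if w.rms > 0 else None,
        "band_power_fraction": band_power_fraction(w, spec.f_low, spec.f_high),
    }
    if spec.kind == VIOLET_NOISE:
        report["psd_slope_db_per_octave"] = estimate_psd_slope(w, interior)
    else:
        report["ridge"] = sweep_ridge_linearity(w, spec.sweep_duration)
    return report
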