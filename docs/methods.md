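# Methods

This note documents the models behind `nihlsim`, their assumptions and
calibration constants, the numerical choices, and what the synthetic
data do and do not establish.

## Exposure stimuli

Violet noise is synthesized by shaping seeded white Gaussian noise in
the frequency domain: the amplitude spectrum is multiplied by f inside
the exposure band and zeroed outside, with raised-cosine tapers of
width 5% of the bandwidth at each edge. The taper is a stand-in for an
unspecified analogue high-pass chain; it realizes the
linear-with-frequency gain exactly while avoiding ringing. The violet
swept-sine is a repeated linear chirp: instantaneous frequency
f(t) = f_low + (f_high − f_low)·t/T over one sweep of T = 10 s, with
the envelope proportional to f(t), tiled to the total exposure
duration (1800 s, i.e. 180 complete repeats) and truncated.

Sound pressure level is defined on the digital waveform:
RMS = p_ref·10^(level/20) with p_ref = 20 µPa. No transducer, room or
chamber transfer function is modelled; a waveform at "105 dB SPL" is a
calibrated pressure signal, not a prediction of in-ear level.

Verification utilities estimate the PSD slope (Welch periodogram,
least-squares fit of 10·log10 PSD against log2 f; violet shaping gives
+6.02 dB/octave) and track the spectrogram ridge of a sweep (R² of a
line fit; > 0.999 for the default parameters). Slope fits should use a
band interior to the tapers (e.g. 3–17 kHz for a 2–20 kHz stimulus).

Default sample rate: 96 kHz (covers 20 kHz content with margin).

## Synthetic cochlea

The generator emulates a flattened whole-mount preparation, not
cochlear geometry. One IHC row and three OHC rows lie at fixed lateral
offsets inside a 28 µm stereociliary fringe; longitudinal bundle
positions are independent homogeneous Poisson processes per row
(IHC 1/8 µm⁻¹; OHC 1/9 µm⁻¹ per row) along the apical 80% of a 5.13 mm
basilar membrane (the dissectable portion; the basal 20% — the 50–80
kHz "hook" — is never populated). Closed-form fringe-area densities:
OHC 3/(9·28)·1000 ≈ 11.9, IHC 1/(8·28)·1000 ≈ 4.5 bundles/1000 µm².

Poisson placement (rather than a jittered lattice) is deliberate: it
gives frame counts near-Poisson dispersion, which is what makes the
empirical coefficient of error of the sampling design realistic; a
lattice would be underdispersed.

### Lesion model

Each bundle independently survives exposure with probability 1 − p,

    p = clip( peak(level) · [ exp(−Δc²/2σ_f²) + exp(−Δb²/2σ_b²)
                              + g·max(0, d − 55) ], 0, 1 )

with Δc the octave distance from the bundle's characteristic frequency
to the exposure band's geometric centre, Δb the octave distance to the
band's upper edge shifted one octave basally, and d the percent
distance from the apex. IHC loss is the OHC loss times 0.6.

Defaults (calibration constants, not measured biology):

| parameter | default | role |
|---|---|---|
| peak(105) / peak(120) | 0.55 / 0.98 | level dependence (linear through 0) |
| σ_f (focal spread) | 0.2 octaves | focal damage at the band's own place |
| σ_b (basal spread) | 1.2 octaves | broad damage displaced toward the base |
| basal shift | 1.0 octave (valid 0.5–2) | classic basal displacement of noise damage |
| g (basal gradient) | 0.006 /% beyond 55% | intrinsic basal-turn vulnerability |
| IHC factor | 0.6 | OHCs are the more vulnerable class |

The two-component form is a design choice: a single basally shifted
Gaussian cannot simultaneously produce a focal lesion at the place of
a narrow 9–13 kHz band (sectors 25–30%) and the near-total basal OHC
loss of a 120 dB SPL wide-band exposure; the narrow focal term plus
the broad shifted term reproduces both, along with ~0.6 mean OHC
survival after the 105 dB 2–20 kHz exposure. The constants were fixed
once by closed-form analysis of the survival field; they are exposed
in `LesionModel` for sensitivity studies. One lesion per map: maps are
flagged after exposure and cannot be re-lesioned.

## Stereology

Sectors are half-open 5% intervals (k−5, k] of percent distance,
labelled by their basal edge k ∈ {5, …, 80}; each is rendered as a
local fringe rectangle (256.5 µm × 28 µm at the defaults).

Frames (default five 25×25 µm frames per sector) are placed by
systematic uniform random sampling along the sector (one frame per
equal subinterval, shared random start), which guarantees
non-overlap; the sector must be at least n·frame_width long, otherwise
placement is rejected. Laterally, frame origins are uniform on the
fringe width with periodic wrap (a toroidal edge correction): every
lateral position is sampled with equal probability, making the ratio
estimator exactly unbiased for the fringe-area density while keeping
the per-frame reference area constant. Under this design all four
frame corners always lie in the fringe; the corner point-count
machinery (area-per-point = frame area/4) matters for frames supplied
directly, e.g. from digitized data, and is unit-tested on
partial-overlap geometry.

Counting uses the Gundersen unbiased rule: a bundle counts if strictly
inside the frame or on the top/right inclusion edges, never on the
bottom/left exclusion edges. Densities with zero sampled area raise an
explicit error (never a silent 0 or infinity); a class with zero
counts in a sector gets density 0 and CE flagged NaN.

The CE uses the quadratic ratio-estimator form without the n/(n−1)
factor; the Bessel-style correction and the lateral-placement variant
(spec-literal midline jitter) are both exposed as `SamplingDesign`
toggles. Note the sample CE statistic is biased low at small n
(roughly √((n−1)/n) plus a Jensen term): with five frames of ~7.4
expected OHC bundles each, the expected reported CE is ≈ 0.15–0.16 on
controls and ≈ 0.20 after the default 105 dB wide-band lesion —
matching the ~0.17/~0.21 working precision of the design. The
asymptotic 1/√(n·m) behaviour holds cleanly only for n ≳ 25 frames,
which is where the scaling tests run.

## Place–frequency map

f(kHz) = 10^((A − (100 − d))/B), A = 156.5, B = 82.5, d = percent
distance from the apex. The inverse is exact (round-trip to 1e-9).
Alternative published mouse maps can be used by constructing
`PlaceFrequencyMap` with other constants. Tone frequencies apical of
the map's range (e.g. a 4 kHz probe; the apex codes ≈ 4.8 kHz) are
clamped to the apical-most sector when paired with cochleogram data.

## Audiology

The response model behind threshold detection is deliberately minimal:
amplitude 0 below the true threshold, saturating exponential growth
(τ = 10 dB, saturation 1) above it, optional additive Gaussian noise.
Detection takes the lowest grid level whose amplitude strictly exceeds
criterion_k (default 2.0) times the noise floor with all higher levels
also responding; "no response anywhere" is flagged and recorded as
ceiling + step, a response at the lowest level is flagged "at floor".
Noise-free, the detected threshold is the grid ceiling of the true
threshold, so detected cohort means sit ~2.5 dB above the true means.
The ABR grid runs 90→10 dB SPL in 5 dB steps (extended below the
nominal 20 dB presentation floor so that ~15 dB baselines are
representable); DPOAE uses 80→30 dB SPL.

Cohort calibration: true thresholds are drawn per subject ×
timepoint × stimulus from Normal distributions whose means encode the
group trajectories — controls flat at 15 dB SPL; both 105 dB groups
shifted ~52 dB at day 2 with partial recovery (faster for the
narrow-band group); the 120 dB group worsening by day 14; an audiogram
notch at 8–10 kHz for the 9–13 kHz band; DPOAE thresholds elevated
uniformly in all exposed groups. Baseline sd 4 dB, post-exposure sd
5 dB. A per-subject susceptibility offset (σ = 3 dB, shared across
timepoints; residual sd reduced accordingly so the marginals are
unchanged) makes repeated measurements paired within animal, as in a
longitudinal design. Treatment arms (saline/P17/P144) reuse the
exposed distribution — an explicit null treatment effect. All values
live in plain tables in `CohortDesign` and can be replaced wholesale.

Structure–function correlation pairs group-mean tone threshold shifts
with OHC percent loss at each tone's containing sector and reports
Spearman's ρ; with the default calibration and lesion model the
narrow-band group yields ρ ≈ 0.5–0.8.

## Problem sizes and determinism

Default analyses are sized for interactive use: 16 sectors × 5 frames
per cochlea, 3–10 cochleae per condition for density/CE summaries,
n = 12 subjects per cohort group. Estimator-validation runs use 100
cochleae with 50 small (5×5 µm) frames per sector, chosen so the
Monte-Carlo error (<1.5%) is well inside the 5% recovery tolerance.
Every stochastic stage takes a seed or Generator; the pipeline derives
per-stage seeds from one master seed (recorded in the manifest), and
reruns are byte-identical.

## What the synthetic data do not show

The generator reproduces the statistical structure the estimators care
about (Poisson bundle placement, row geometry, tonotopic loss
gradients, threshold-grid censoring) but none of the messiness of real
preparations: dissection tears, variable fringe width, curved sector
boundaries, phalloidin staining artefacts, partially damaged bundles,
ABR wave-morphology scoring ambiguity, or inter-laboratory calibration
offsets. Passing tests therefore validate the estimators and the
pipeline logic under the stated model — they do not certify accuracy
on real micrographs, and the lesion-model constants are pattern
calibrations, not biological measurements. ABR peak latencies and
amplitudes, recruitment, and inferential statistics (repeated-measures
ANOVA and post hoc tests) are out of scope.
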