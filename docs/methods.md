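# Methods

This note records the models implemented in `cranioppg`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic data
do and do not establish about real recordings.

## Signal model

Reflected green-light intensity at pixel *p* and time *t* is modeled as

    I(t, p) = B(p) · V(t) · [1 + a(p) · g(t) · c(φ(t))] + n(t, p)

with `B` the baseline image (10-bit counts), `V(t) ≤ 1` the slow
blood-volume intensity factor, `a(p)` the fractional pulsatility
(artery ≫ vein ≥ parenchyma), `g(t) ≥ 1` the stimulation gain on the pulse
amplitude, `c(φ)` a fixed cardiac pulse shape over the cycle phase `φ`
defined by R-peaks, and `n` additive Gaussian sensor noise. Frames are
rendered, warped by the lateral tissue motion (bilinear), noise-corrupted
and clipped to the 10-bit range (clipped pixels are counted and logged).

**Cardiac template.** `c(φ)` is an asymmetric C¹ raised-cosine pulse (rise
over 30% of the cycle, slow decay), normalized to max − min = 1 and
zero-mean over the cycle. Zero mean makes two identities exact: the
temporal mean over whole cycles returns `B·V`, and the injected fractional
pulse amplitude is `a(p)·g(t)` — the ground truth that APC recovery is
judged against. Any plausible arterial shape would do; only smoothness
matters (harmonics near the frame rate alias into the cycle mean).

**Slow kinetics.** During the stimulation epoch the response rises as
`1 − exp(−t/τ_on)` (τ_on = 4 s for the pulse gain, 8 s for the volume
factor) and relaxes mono-exponentially afterwards with τ_relax = 12 s.
With the default magnitudes this puts the 2-SD return of the normalized
traces 40–90 s after stimulation onset, the range the adaptive integral is
designed for. ABP and HR dip with a fast shared time constant (3 s),
essentially confined to the stimulation epoch, so they recover much sooner
than the optical parameters.

**Defaults** (chosen once as physiologically plausible magnitudes; the
study they emulate reports kinetics and geometry but no effect amplitudes):

| parameter | default | meaning |
|---|---|---|
| heart_rate_bpm | 413 | rat heart rate; R-R ≈ 145 ms |
| hr_variability | 0.03 | fractional R-R jitter |
| artery / vein / background pulsatility | 0.02 / 0.005 / 0.002 | fractional AC/DC |
| stim_apc_gain | 1.5 | pulse amplitude ×1.5 at the response peak |
| stim_volume_drop | 0.10 | 10% intensity drop → ~10% OIS peak |
| abp_dip_frac / hr_dip_frac | 0.10 / 0.07 | transient dips during stimulation |
| motion_amplitude_px | 1.5 | peak lateral offset (drift + tremor) |
| noise_sd_counts | 1.0 | additive sensor noise on the 10-bit scale |

Geometry defaults to a desk-scale field (188 × 120 px at 50 fps, 60 s
trials) for tests and examples; the full 752 × 480 px @ 100 fps, 120 s
configuration is available through `TrialProtocol`/`make_tissue` arguments.
The trial traces used by the experiment-level pipeline are sampled at
10 Hz.

**Motion.** The global offset trajectory is the sum of a slow drift
(random walk low-passed at ~0.3 Hz) and a band-limited fast tremor
(Gaussian noise low-passed at a few Hz, 35% of the peak amplitude),
anchored at zero on the first frame, which is also the motion-compensation
reference. The split matters: drift lives in the PPG DC band and is
largely harmless to APC, whereas tremor reaches the cardiac band and is
precisely what segment-wise compensation can and should remove. Pure
slow-drift motion would make compensation unfalsifiable (nothing left to
improve) and pure white jitter would be uncompensatable at any frame rate;
the default sits in between, as tissue tremor of breathing animals does.

**Two forward paths.** The video path renders full frame stacks and is
used wherever pixels matter (APC/OIS extraction, motion). The trace path
emits the per-trial big-ROI APC/OIS/ABP/HR time courses directly from the
same kinetics and is used for experiment-scale simulation (384 trials per
cohort, hundreds of cohorts for calibration), where rendering videos would
be pointless: the group statistics consume trial traces only. Trial- and
animal-level variability enter as multiplicative lognormal factors
(fractional SDs 0.10 and 0.15).

**Pharmacology (phenomenological).** The stimulation gain excess at
infusion step *s* is multiplied by `drift^s · drug(s)`: a time-drift of
1.25 per step in every group (the sensitization the saline controls show)
opposed by cumulative drug multipliers — sumatriptan (0.8, 0.6, 0.4),
valproate (0.85, 0.70, 0.55), saline (1, 1, 1). OIS responses get milder
drug multipliers and no drift. These produce the qualitative group
divergence (saline rising, drugs restrained) without claiming quantitative
pharmacokinetics.

## Motion compensation

The frame is tiled into 16 × 16-px segments (edge segments smaller when
dimensions are not multiples). Per segment and frame, the offset *d*
against the fixed reference frame (frame 0) solves the least-squares
gradient-constraint system with per-segment gain and offset nuisance
terms:

    Σ ( ∇I_ref · d + α·I_ref + β + (I_i − I_ref) )² → min .

The nuisance terms are essential on photoplethysmographic data: pulse and
blood-volume signals change a segment's brightness without displacing its
pattern, and a plain gradient solve books that change as motion — the
subsequent "compensation" then subtracts the pulse itself (in testing this
changed artery APC by ~40% on motion-free data and made compensated maps
*worse* than uncompensated ones). Algebraically the nuisance elimination
reduces to centering the reference gradients per segment and
orthogonalizing them against the centered reference image, so the 2 × 2
solve is kept. Residual pulse leakage (segments whose pulsatility pattern
is not proportional to the local reference image) is removed by
decorrelating each segment's offset time series from the field-mean
cardiac waveform (moving-average residual with the median R-R window);
this step is skipped on stacks shorter than four cardiac windows and for
unfiltered two-frame pairs.

Numerics: reference gradients are central differences (one-sided at
borders); segments whose reduced normal matrix has condition number
> 10³, smallest eigenvalue < 10⁻⁶ × the segment's mean squared gradient,
or |d| above the configured maximum (8 px) are flagged and pass through
with d = 0. Offsets are estimated independently per frame against the
fixed reference — never chained — so errors do not accumulate. The
correction is additive, `Î = I + ∇I_ref · d` (for a content shift *d* the
motion component of the signal is −∇I_ref·d), keeping the pipeline linear
in intensity; output frames are float and re-quantized only on export.
The single-step linearization is accurate to ±0.15 px for ~1 px offsets on
smooth texture and degrades gently toward the 8 px cap; no pyramid is
used because expected offsets are small.

## PPG extraction

R-peaks come either from the recording (externally provided peaks always
take precedence) or from the ECG detector: 5–35 Hz band-pass, squared
derivative, 20 ms energy smoothing, adaptive threshold, 100 ms refractory
period. The refractory default is set below the ~145 ms rat R-R interval
on purpose; a conventional 200 ms (human) refractory would halve the
detected rate. R-R gaps > 1.8 × median are flagged as missed beats.

The DC of each 3×3-px ROI is a centered moving average whose window is the
median R-R interval rounded to an odd frame count — one cardiac period, so
the pulse averages out of DC by construction; AC is the residual and the
waveform is AC/DC. Each R-R segment is resampled to 50 phase points by
linear interpolation and 10 consecutive cycles are averaged; APC is
(max − min) × 100%. APC time series use the 10-cycle window sliding by one
cycle, stamped at the window center; maps tile the frame with
non-overlapping 3×3 ROIs anchored at (0,0), masking remainder rows/columns
and ROIs with non-positive DC.

Known bias: at 50 fps (≈7.3 frames per cycle) the one-cycle moving average
leaks ~4% of the pulse amplitude into DC and linear phase interpolation
flattens the peak by a few percent more, so recovered APC sits ~8%
below the injected value uniformly across amplitudes — within the 10%
recovery band and halved at the full 100 fps rate. The bias cancels in
all ratio- and contrast-based quantities (normalized traces, integrals,
group statistics).

## OIS and quality control

`OIS_i = (I_0 − I_i)/I_0 × 100%` per pixel, with `I_0` the first
pre-stimulation frame and pixels with `I_0 ≤ 1` count masked. OIS is
computed on the motion-compensated, DC-filtered sequence (heartbeat
modulation of OIS is noise here); raw-frame OIS sits behind a flag. Big-ROI
time courses average per-pixel OIS over 27×27-px windows. The contact gate
takes the peak of the big-ROI mean during stimulation minus the
pre-stimulation mean and passes at ≥ 7%: a peak (not a phase mean) because
the gate must detect any effective contact. Whether the original
acquisition gated on a specific ROI or the whole field is not documented;
the big-ROI mean is used here.

## Response metrics

Big ROIs are selected automatically (the original work picked them by
hand): candidate 27×27-px windows anchored on the 3-px tile grid are
scored by mean APC on the map from the 10th second of stimulation, chosen
greedily without overlap (ties resolve in row-major order), and the two
windows nearest the electrode midpoint are flagged representative (ties
toward higher APC). Trial APC/OIS traces average the two representative
ROIs.

Normalization divides by the mean over the first 20 s and multiplies by
100, so the pre-stimulation mean is exactly 100% (machine precision); the
pre-stimulation SD on the normalized scale defines the 2-SD return band.
Because OIS is already a relative quantity with pre-stimulation mean ≈ 0,
its trial trace is expressed as 100 + OIS(%) before normalization — the
pre-stimulation level is then ~100% and the integral of (value − 100%)
equals the integral of OIS.

Integrals are trapezoidal on the native sampling grid with interpolated
window ends; the fixed window is [20, 35] s (gaps > 2 sample intervals
inside it are an error). The adaptive integral ends at the first time
≥ 35 s at which the trace stays inside 100% ± 2 SD for a sustained hold
window (1 s) — the hold prevents noise-triggered early stops, which a bare
first-crossing rule suffers from; if the trace never returns, the trial
end is used and flagged. Baseline normalization divides each animal's
integrals by its three-baseline-trial mean; a non-positive baseline
excludes the animal for APC/OIS, while the dip parameters (ABP, HR), whose
integrals are negative by construction, only require a non-degenerate
baseline (the ratio of same-signed integrals keeps its meaning).

## Statistics

All inference is nonparametric, two-sided, α = 0.05. The
Kolmogorov–Smirnov screen (against a normal with the sample's own mean and
SD) is recorded but never switches the path. Wilcoxon signed-rank uses the
exact null distribution for n ≤ 25 without ties/zeros and the normal
approximation otherwise; all-zero differences yield a degenerate p = 1
record. Friedman runs on complete blocks (animals missing a stage are
dropped and logged) over the per-animal stage value = mean of the three
trials at that stage. Kruskal–Wallis compares groups per stage. When an
omnibus test is significant, post-hocs are pairwise signed-rank
(within-subject) or Mann–Whitney (between-group) with Bonferroni
adjustment over all pairs, `p_adj = min(1, m·p)`; the underlying pairwise
statistic is a reporting choice (Dunn's test would be an alternative) and
is named in the report records.

## What the synthetic data establish — and what they do not

Passing tests show that the pipeline recovers *injected* quantities:
pulse amplitudes to within ~10% under the stated noise, motion offsets to
~0.05 px RMS, volume drops as OIS, calibrated type-I error, and the
saline/drug divergence at the configured effect sizes. The generator does
not emulate spatially heterogeneous (per-quadrant) motion by default,
pulse-shape changes with vascular tone, illumination drift, breathing
artifacts in the optical path, or realistic ECG morphology (only
detectable R-peaks); absolute effect magnitudes are configuration, not
measurements. Conclusions about real recordings are therefore limited to
the correctness of the computations, not to expected effect sizes.

## Reduced problem sizes

Tests and the acceptance script run at the desk-scale geometry
(188 × 120 px, 50 fps, 60 s video trials; 10 Hz trial traces), 200
replicate cohorts for null calibration and 20 for the divergence pattern —
sizes chosen so the whole suite completes in minutes while keeping every
statistical check adequately powered.
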