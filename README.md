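# cranioppg

Imaging photoplethysmography (iPPG) and optical intrinsic signal (OIS)
analysis of cranial-window video, for quantifying stimulation-evoked changes
of meningeal blood flow in small-animal migraine models — plus a synthetic
data generator with known ground truth so the entire chain is testable
without animal recordings.

## The problem and the method

A camera images the rat cortex through a closed cranial window under green
(530 nm) illumination at 100 fps while dural trigeminal afferents are
stimulated electrically (20 s pre-stimulation, 15 s stimulation, 85 s
relaxation per 120 s trial) and an ECG is recorded at 1 kHz. Reflected
intensity carries two hemodynamic signals:

* **APC — amplitude of the pulsatile component.** Per small 3×3-px ROI
  (≈65 µm), the frame-mean intensity is split into a slowly varying DC and a
  cardiac-synchronous AC; the waveform of interest is AC/DC. Cycles are
  delimited by ECG R-peaks, resampled to a common phase axis, and 10
  consecutive cycles are averaged into a mean pulse. APC = (max − min) of
  that mean pulse, in percent. Arteries show much higher APC than veins,
  and electrical stimulation raises APC field-wide.
* **OIS — optical intrinsic signal.** Per pixel,
  `OIS_i = (I_0 − I_i) / I_0 × 100%` with `I_0` the first pre-stimulation
  frame; at green wavelengths OIS grows with cerebral blood volume. A trial
  is accepted only when the big-ROI OIS rises by ≥ 7% during stimulation
  (electrode-contact quality gate).

Before either signal is extracted, tissue motion is compensated: the frame
is tiled into 16×16-px segments and, per segment and frame, the lateral
offset against the first frame is estimated by the least-squares gradient
(optical-flow) method; the motion-related intensity component
`∇I_ref · d` is then subtracted.

Responses are quantified per trial on six 27×27-px (≈0.6 mm) big ROIs
placed at APC maxima (the two electrode-adjacent ones are representative):
each parameter trace (APC, OIS, ABP, HR) is normalized to its
pre-stimulation mean (= 100%), then integrated over the stimulation window
(20–35 s) and adaptively until the trace re-enters the pre-stimulation
± 2 SD band. Integrals are normalized per animal to its three baseline
trials. Group-level inference is nonparametric: Wilcoxon signed-rank
(pre vs during stimulation), Friedman (baseline and three cumulative
infusion steps, within group), Kruskal–Wallis (saline / sumatriptan /
valproate, per stage), all two-sided at α = 0.05 with Bonferroni-corrected
post-hoc pairwise comparisons; descriptives are median + IQR.

The synthetic generator renders all of this forward: vessel maps with
class-specific pulsatility, a zero-mean asymmetric cardiac pulse template
phase-locked to generated R-peaks (≈413 bpm), exponential-onset /
exponential-relaxation stimulation kinetics (2-SD return 40–90 s after
onset), transient ABP/HR dips, drift + tremor tissue motion, sensor noise,
and a three-group infusion design (saline sensitization vs drug
attenuation) — every injected quantity is recorded as ground truth.

## A worked example

```bash
python examples/trial_response.py
```

prints, for one simulated 120 s trial with the default response magnitudes:

```
trial: 120 s, stimulation 20-35 s
 APC: pre-stim mean  100.0%  integral[20-35 s]    556.5 %*s  adaptive   1112.4 %*s (ends  68.0 s)
 OIS: pre-stim mean  100.0%  integral[20-35 s]     82.4 %*s  adaptive    179.0 %*s (ends  68.7 s)
 ABP: pre-stim mean  100.0%  integral[20-35 s]   -118.9 %*s  adaptive   -144.3 %*s (ends  40.0 s)
  HR: pre-stim mean  100.0%  integral[20-35 s]    -84.3 %*s  adaptive   -102.7 %*s (ends  41.2 s)
QC: OIS rise during stimulation 9.4% (threshold 7%) -> good contact
```

Every trace is anchored at a 100% pre-stimulation level; APC and OIS rise
with stimulation and relax over tens of seconds (the adaptive integration
ends when the trace re-enters the 2 SD band, here ≈48 s after stimulation
onset), while arterial pressure and heart rate dip briefly — hence their
negative integrals — and recover much faster.

The other examples cover the APC map and artery/vein contrast
(`simulate_and_map.py`), motion compensation against injected ground truth
(`motion_compensation.py`), and the full three-group experiment with the
Friedman/Kruskal–Wallis report (`experiment_stats.py`).

## Layout

```
src/cranioppg/
  synth/       tissue, cardiac/hemodynamic kinetics, ECG, video and trace
               forward models, experiment schedules
  motion.py    16x16-px segment grid, gradient offset estimation, additive
               motion compensation
  ppg.py       R-peak detection, AC/DC waveforms, mean pulses, APC maps
  ois.py       OIS maps/time courses and the 7% contact gate
  response.py  big-ROI selection, normalization, integral metrics
  stats.py     Wilcoxon / Friedman / Kruskal-Wallis / Bonferroni report
  pipeline.py  single-trial video chain and cohort-level chains
  io.py        TIFF+JSON video, CSV trace/R-peak, JSON schedule round-trips
```
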