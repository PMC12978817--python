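# Methods

This note documents the models, parameter choices and numerical
conventions behind `tscs_calib`, and what the synthetic benchmark does
and does not establish about real recordings.

## Signal model of the synthetic generator

Each trial is a 5-s multi-channel trace (default 2 kHz sampling, 14 leg
muscles) composed of:

* **Baseline noise** — zero-mean white Gaussian noise, default SD 5 µV.
  Real surface EMG noise is colored and can contain movement artifacts
  and power-line residue; the detection criteria only ever use the noise
  SD, so white noise is the minimal model that exercises them. The 50 Hz
  notch in the preprocessing chain is still exercised by dedicated
  filter tests.
* **Stimulation artifact** — two 1-ms rectangular biphasic transients
  (default 2000 µV peak-to-peak) separated by the 50 ms interpulse
  interval, with onset drawn uniformly in [0.8, 1.25] s per trial
  (shared by all muscles, as the stimulus is common-mode). The
  rectangular doublet makes the double-differentiation produce sharp,
  well-defined peaks. Sampling rates below 2 kHz cannot represent the
  1-ms biphasic pulse and are rejected.
* **Evoked responses** — a single biphasic sine lobe of 10 ms duration
  whose peak-to-peak follows a sigmoid recruitment function
  `gain · saturation / (1 + exp(−slope·(I − threshold)))` (defaults:
  threshold 30 mA, slope 0.8 /mA, saturation 1000 µV), at a fixed
  15 ms latency after each pulse. The second (conditioned) response is
  scaled by the suppression ratio (default 0.15, i.e. 85 % paired-pulse
  suppression, the PRM-reflex signature). The sigmoid is a modelling
  convention — the analysis relies only on monotone recruitment, stable
  latency and strong suppression, not on the exact shape. Real reflexes
  have muscle-specific latencies, multiphasic morphology and
  trial-to-trial amplitude variability that the generator omits;
  passing the synthetic benchmark therefore validates the *logic* of
  the pipeline, not its performance on physiological waveforms.

**Selectivity profile.** Gains per (electrode, muscle) encode the
expected rostrocaudal gradient (rostral rows: proximal 1.0 / distal
0.3; middle: 1.0 / 0.7; caudal: 0.3 / 1.0) and, for bilateral montages,
an ipsilateral factor (contralateral leg × 0.4). Every electrode has at
least one unit gain. These values were chosen once to give clearly
ordered but overlapping recruitment, comparable to the qualitative
gradients reported for multi-electrode lumbar stimulation.

**Ground-truth amplitudes.** The generator reports response amplitudes
on the *measurement* scale: the injected peak-to-peak multiplied by the
fixed attenuation of the preprocessing chain on the 10-ms lobe (≈ 0.88
at 2 kHz, computed once per sampling rate by filtering a unit lobe).
Ground truth is thus the ideal noise-free measurement, so recovery
errors quantify noise and detection effects rather than a known,
deterministic filter gain. A reflex is labelled present when this
measurable amplitude exceeds the 50 µV criterion.

## Detection pipeline

* **Ordering.** Artifact detection operates on the Laplacian of the
  median-removed *raw* trace; band-pass filtering happens afterwards,
  for amplitude measurement only. Running the narrow notch filter first
  would smear the artifact into long low-amplitude ringing and create
  spurious early candidates near the threshold.
* **Criteria.** Candidates are local maxima of |Δ| above 3·SD of the
  differentiated resting-period noise (resting window 2.5–5 s); the
  second-peak check searches ±1 ms around the nominal 50-ms offset; the
  comparability ratio uses peak-to-peak amplitudes in 2-ms windows on
  the differentiated signal for both peaks. With a zero noise SD
  (noiseless traces) the threshold becomes a strictly positive epsilon.
  The scan is padded a few samples past the search window so a pulse at
  the window edge keeps its neighbours; accepted candidates must lie
  inside the window.
* **Synchronization.** Detections are clustered; the trial t₀ is the
  earliest member of the largest cluster agreeing within 2 samples.
  The stimulus is common-mode across muscles, so genuine detections
  coincide while 3-SD noise crossings are isolated; a plain minimum
  over muscles would let a single early false candidate corrupt the
  whole trial. When no two detections agree the earliest detection is
  used, and with no detections at all the trial is unsynchronized and
  contributes no reflexes.
* **Artifact removal.** Before the reflex search, 1 ms before to 3 ms
  after each pulse is blanked (set to zero); otherwise the artifact
  tail would be the largest "peak" in the (t₀, t₀+40 ms] window.
* **Reflex measurement.** The peak search uses |x| (polarity-free),
  earliest peak on exact magnitude ties. The amp2 window is anchored to
  t_max, not to the second stimulus. Windows truncated by the trace end
  raise a warning and are computed on the available samples. The noise
  SD used for the amplitude criteria is measured on the filtered trace
  (post-filter SD).

## Recruitment and selectivity

Absent responses (reflex in < 2 of 3 repetitions) are carried forward
from the last valid response; leading absences are zero. Normalization
is per muscle over all electrodes and amplitudes of the configuration;
AUC is trapezoidal over current; REC divides by the maximum AUC over
all (muscle, electrode) pairs of the configuration (a per-muscle
denominator is available via `normalize_responses` composition for
sensitivity analyses). The amplitude-resolved SI used by the SDA
applies the group-SI formula to normalized responses at a single
current — an AUC-based SI could not discriminate between amplitudes.

## Selection algorithms

* The muscle-group partition is disjoint (proximal/distal per
  configuration, quadrants for bilateral); composite targets (whole
  leg) must be unions of cells. Non-target groups are the cells
  disjoint from the target.
* The selective amplitude range counts a group as activated at I when
  ≥ 50 % of its muscles show a reflex at I, pooling each muscle's
  reflexes over electrodes (the logged session data); a per-electrode
  variant is available (`selective_range(..., electrode=...)`). With no
  non-target groups (global-activation targets) the full range is
  selective, which is how the conventional maximal-activation selection
  is implemented.
* RBA criteria 1–2 count target muscles responding at *any* amplitude
  of the range; I is the lowest amplitude achieving the maximal
  simultaneous count, I′ the first amplitude with any target reflex.
  Exact ties after criterion 4 are reported as tie sets, never broken
  silently; the first electrode in layout order is the nominal choice.
* SDA amplitude ties prefer the lower current (comfort/energy), mirroring
  RBA criterion 4.
* NRD codes electrodes ordinally within the configuration (E1→1 … E3→3;
  L1→1 … R3→6) by default; the coding is user-configurable and NRD is
  coding-dependent by construction. Non-selective cases are excluded
  with a warning, or penalized with the maximal coded deviation via
  `nonselective="max"`. The condition partition is user-supplied
  (default: a single condition).

## Protocol arithmetic and statistics

Schedules ramp from 10 mA below the visual threshold in 5 mA steps,
then 15 amplitudes in 2 mA steps from the first detected reflex, capped
at reflex threshold + 30 mA or the tolerated maximum (the cap follows
the detected reflex threshold when one is supplied). Step counts use a
ceiling for partial spans. Durations are exactly multiplicative; the
2-s interstimulus variant is a parameter, not a separate code path.
Group statistics always take the nonparametric route (Kruskal–Wallis,
pairwise Wilcoxon signed-rank, Benjamini–Hochberg at α = 0.05); the
Kolmogorov–Smirnov normality check is advisory. Constant inputs
degrade gracefully to H = 0, p = 1 with a warning.

## Problem sizes and determinism

The test suite and acceptance script run noisy sessions of 216 trials
(3 electrodes × 24 amplitudes × 3 repetitions, ~3 000 muscle traces),
noiseless sessions of 45–72 trials, 100 random summaries for the
brute-force selection oracle and 1000 random REC tables for the SI
properties — sizes chosen so the full pipeline is exercised end to end
while a complete run stays in the tens of seconds. All randomness is
seeded (hypothesis runs derandomized); identical seeds reproduce
sessions bit for bit.

## Known limitations

* The sigmoid recruitment model and fixed latency are conventions; no
  claim is made about physiological dose–response shapes.
* White Gaussian noise understates real-world artifacts (motion, ECG,
  mains residue); classification accuracy on real EMG will be lower.
* NRD depends on the ordinal electrode coding (a property of the
  definition itself).
* The detector's false-candidate behaviour is tied to the 3-SD
  threshold; heavy-tailed noise would require a more conservative
  threshold or cluster size.
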