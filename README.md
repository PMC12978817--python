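# tscs-calib

Automated calibration tools for **multi-electrode transcutaneous spinal
cord stimulation (tSCS)**: detection of posterior root-muscle (PRM)
reflexes from EMG, recruitment and selectivity quantification, and
automatic selection of the electrode position and stimulation amplitude
that most selectively recruit a target muscle group.

tSCS excites dorsal-root afferents through the skin; the evoked EMG
response (PRM reflex) shows strong paired-pulse suppression, which
separates it from direct motor activation. Calibrating a multi-electrode
montage by hand — palpating landmarks, moving electrodes, re-testing
thresholds — is slow and subjective. This package implements the offline
counterpart of an automated protocol: it consumes per-trial EMG
organized by electrode × stimulation amplitude × repetition (or
generates ground-truthed synthetic sessions with the same structure) and
outputs where and how strongly to stimulate.

The package is aimed at neural-engineering researchers who work with
evoked-response calibration data; the primary interface is the Python
API (see `examples/`), with a thin `tscs-calib` CLI for shell use.

## Method

For each 5-s trial and muscle *i*, the stimulation artifact is localized
on the double-differentiated raw EMG, `Δ_i(t) = 4·(x[t+1] − 2x[t] +
x[t−1])`: a candidate peak t̃* is accepted when `|Δ(t̃*)| > 3·SD_Δ`, a
second suprathreshold peak sits one interpulse interval (50 ms) later,
and the two peaks have comparable 2-ms peak-to-peak amplitudes
(`1 − min/max < 0.8`). The earliest consistent detection across muscles
synchronizes the trial (t₀).

On the filtered trace (median removal, 48–53 Hz notch, 300 Hz low-pass,
zero-phase), the reflex peak t_max is the largest suprathreshold peak in
(t₀, t₀+40 ms]; `amp1` and `amp2` are peak-to-peak amplitudes over
[t_max−8, t_max+15] ms and [t_max+42, t_max+65] ms. A PRM reflex
requires suppression `1 − amp2/amp1 > 0.70`, `amp1 > 50 µV` and
`amp1 > 3·SD` of the resting noise. Responses seen in ≥ 2 of 3
repetitions are averaged into muscle activity `MA`.

Recruitment curves (MA vs current, carry-forward for isolated dropouts)
are normalized per muscle across the configuration; their trapezoidal
area (AUC) normalized over all (muscle, electrode) pairs gives
`REC ∈ [0, 1]`, and the group selectivity index is

    SI_T = mean(REC, target muscles) − mean(REC, non-target muscles) ∈ [−1, 1].

Two selection algorithms operate on these tables. The **ranking-based
approach (RBA)** restricts attention to the amplitude range where fewer
than half of the non-target muscle groups are activated, then ranks
electrodes by binary criteria: ≥ 50 % of target muscles responding, the
most target muscles responding, the smallest gap between the maximal-
response amplitude I and the first-response amplitude I′, and finally
the lowest I. The **selectivity-driven approach (SDA)** requires ≥ 50 %
target activation and ≥ 5 % mean target recruitment, then maximizes the
amplitude-resolved SI_T. Their divergence over a set of cases is
summarized by the **normalized relative deviation**
`NRD = Σᵢ Nᵢ·Δ̄ᵢ / Σᵢ Nᵢ` with `Δ = |code(E_RBA) − code(E_SDA)| / code(E_SDA)`.

## Worked example

```bash
python examples/simulate_and_detect.py
```

```
session: 162 trials, 2268 muscle traces
artifact onset error (samples): max 0
reflex classification accuracy: 99.78%
amp1 recovery relative error:   median 0.59%
```

Every trial of a noisy synthetic midline session was synchronized to the
exact injected pulse sample, 99.8 % of muscle traces were classified
(reflex present/absent) in agreement with the generator's labels, and
the measured first-response amplitudes track the injected ones to well
under a percent (median). `examples/recruitment_selectivity.py` prints
the REC/SI tables (distal-group selectivity peaking at the most caudal
electrode), `examples/electrode_selection.py` contrasts RBA and SDA
choices and their NRD, and `examples/protocol_planning.py` prints the
amplitude schedule and the calibration durations (11.25 min midline /
22.5 min bilateral at a 5-s interval; 4.5 / 9 min at 2 s).

The same steps are available from the shell:

```bash
tscs-calib simulate --configuration midline --seed 3 --out session/
tscs-calib calibrate session/ --algorithm both --out results/
tscs-calib plan --visual-threshold 30 --max-tolerated 80 --first-reflex 30
```

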