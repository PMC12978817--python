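"""EMG preprocessing, noise estimation and stimulation-artifact detection.

The artifact detector synchronizes each 5-s trial to the double-pulse
stimulus: the raw (median-removed) EMG is double-differentiated with a
discrete Laplacian, which turns the narrow biphasic stimulation transients
into sharp peaks, and candidate peaks are accepted when

1. the peak exceeds 3 SD of the differentiated resting-period noise,
2. a second suprathreshold peak sits one interpulse interval later, and
3. the two peaks have comparable peak-to-peak amplitudes
   (1 - min/max < 0.8, measured in 2 ms windows around each peak).

The earliest candidate passing all three criteria gives the trial's
synchronization sample t0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import signal

__all__ = [
    "NoiseEstimate",
    "ArtifactDetection",
    "preprocess_trace",
    "laplacian_transform",
    "estimate_noise",
    "detect_artifact",
    "synchronize_trial",
    "blank_artifacts",
]

RESTING_WINDOW_S = (2.5, 5.0)
_EPS_UV = 1e-9  # strictly positive threshold stand-in when the noise SD is 0


@dataclass(frozen=True)
class NoiseEstimate:
    """Resting-period noise levels of one trace.

    ``sd_raw_uV`` is the SD of the trace handed to :func:`estimate_noise`
    over the resting window; ``sd_laplacian_uV`` the SD of its discrete
    Laplacian over the same window.
    """

    sd_raw_uV: float
    sd_laplacian_uV: float


@dataclass(frozen=True)
class ArtifactDetection:
    detected: bool
    t0_sample: int | None
    second_peak_sample: int | None
    criteria_passed: tuple[bool, bool, bool]


def preprocess_trace(x: np.ndarray, fs: float) -> np.ndarray:
    """Median removal, 48-53 Hz notch and 300 Hz low-pass (zero-phase).

    The notch is a second-order Butterworth band-stop against power-line
    interference; the low-pass a first-order Butterworth. Both are applied
    forward-backward so reflex latencies are not shifted.
    """
    if fs <= 600:
        raise ValueError(f"sampling rate {fs} Hz too low for a 300 Hz low-pass")
    x = np.asarray(x, dtype=float)
    y = x - np.median(x)
    sos_notch = signal.butter(2, [48.0, 53.0], btype="bandstop", fs=fs, output="sos")
    sos_lp = signal.butter(1, 300.0, btype="lowpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos_notch, y)
    y = signal.sosfiltfilt(sos_lp, y)
    return y


def laplacian_transform(x: np.ndarray) -> np.ndarray:
    """Scaled discrete Laplacian ``4 * (x[n+1] - 2 x[n] + x[n-1])``.

    Endpoints are set to zero (the artifact search window never touches
    them).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("trace too short for the Laplacian stencil (need >= 3)")
    out = np.zeros_like(x)
    out[1:-1] = 4.0 * (x[2:] - 2.0 * x[1:-1] + x[:-2])
    return out


def estimate_noise(
    x: np.ndarray,
    fs: float,
    resting_window_s: tuple[float, float] = RESTING_WINDOW_S,
) -> NoiseEstimate:
    """Noise SDs over the resting period (no stimulus after 2.5 s)."""
    x = np.asarray(x, dtype=float)
    i0 = int(round(resting_window_s[0] * fs))
    i1 = int(round(resting_window_s[1] * fs))
    if i0 < 0 or i1 > x.size or i1 - i0 < 3:
        raise ValueError(
            f"resting window {resting_window_s} s outside trace of {x.size} samples"
        )
    seg = x[i0:i1]
    return NoiseEstimate(
        sd_raw_uV=float(np.std(seg)),
        sd_laplacian_uV=float(np.std(laplacian_transform(seg))),
    )


def _p2p_around(x: np.ndarray, center: int, half_width: int) -> float:
    lo = max(center - half_width, 0)
    hi = min(center + half_width + 1, x.size)
    seg = x[lo:hi]
    return float(seg.max() - seg.min())


def detect_artifact(
    trace_delta: np.ndarray,
    noise: NoiseEstimate,
    fs: float,
    interpulse_interval_ms: float = 50.0,
    search_window_s: tuple[float, float] = (0.8, 1.25),
    peak_tolerance_ms: float = 1.0,
    p2p_window_ms: float = 2.0,
) -> ArtifactDetection:
    """Locate the first stimulation pulse on the differentiated trace.

    Candidate peaks of ``|trace_delta|`` inside the search window are
    scanned in increasing time; the second peak is searched within
    ``peak_tolerance_ms`` of the nominal interpulse offset. Returns the
    earliest candidate passing all three criteria; ``detected=False`` (not
    an error) when none does.
    """
    delta = np.asarray(trace_delta, dtype=float)
    thr = 3.0 * noise.sd_laplacian_uV
    if thr <= 0.0:
        thr = _EPS_UV
    i0 = int(round(search_window_s[0] * fs))
    i1 = int(round(search_window_s[1] * fs))
    if i0 < 0 or i1 > delta.size or i1 <= i0:
        raise ValueError("search window outside trace")

    offset = int(round(interpulse_interval_ms * 1e-3 * fs))
    tol = int(round(peak_tolerance_ms * 1e-3 * fs))
    half_p2p = max(int(round(p2p_window_ms * 1e-3 * fs / 2)), 1)
    a = np.abs(delta)

    # pad the scanned slice so peaks at the window edge keep their
    # neighbours; candidates themselves must lie within the window
    pad = max(tol, 3)
    lo_scan = max(i0 - pad, 0)
    hi_scan = min(i1 + 1 + pad, a.size)
    peaks, _ = signal.find_peaks(a[lo_scan:hi_scan], height=thr)
    last_flags = (False, False, False)
    for p in peaks:
        t = lo_scan + int(p)
        if t < i0 or t > i1:
            continue
        lo = t + offset - tol
        hi = min(t + offset + tol + 1, delta.size)
        if lo >= delta.size:
            last_flags = (True, False, False)
            continue
        seg = a[lo:hi]
        t2 = lo + int(np.argmax(seg))
        c2 = bool(a[t2] > thr)
        if not c2:
            last_flags = (True, False, False)
            continue
        p2p1 = _p2p_around(delta, t, half_p2p)
        p2p2 = _p2p_around(delta, t2, half_p2p)
        ratio = 1.0 - min(p2p1, p2p2) / max(p2p1, p2p2)
        c3 = bool(ratio < 0.8)
        last_flags = (True, True, c3)
        if c3:
            return ArtifactDetection(True, t, t2, (True, True, True))
    return ArtifactDetection(False, None, None, last_flags)


def synchronize_trial(
    detections: Mapping[str, ArtifactDetection],
    tolerance_samples: int = 2,
) -> int | None:
    """Trial synchronization sample from per-muscle artifact detections.

    The stimulation transient is common-mode: every recording muscle sees
    the same pulse, so genuine detections agree to within a sample or two
    while a noise-triggered candidate is isolated. The earliest t0 of the
    largest cluster of mutually consistent detections (consecutive gaps
    <= ``tolerance_samples``) is returned; when no two detections agree,
    the earliest detection overall. ``None`` when no muscle detected the
    artifact -- the trial is then unsynchronized and downstream reflex
    classification treats every muscle as non-responding.
    """
    t0s = sorted(d.t0_sample for d in detections.values() if d.detected)
    if not t0s:
        return None
    clusters: list[list[int]] = [[t0s[0]]]
    for t in t0s[1:]:
        if t - clusters[-1][-1] <= tolerance_samples:
            clusters[-1].append(t)
        else:
            clusters.append([t])
    best = max(clusters, key=len)
    if len(best) == 1:
        return int(t0s[0])
    return int(best[0])


def blank_artifacts(
    x: np.ndarray,
    fs: float,
    t0_sample: int,
    interpulse_interval_ms: float = 50.0,
    pre_ms: float = 1.0,
    post_ms: float = 3.0,
) -> np.ndarray:
    """Zero short windows around both stimulation pulses.

    Removes the stimulation transients (and the local ringing the filters
    leave behind) so that the reflex peak search in (t0, t0+40 ms] cannot
    land on the artifact itself.
    """
    y = np.asarray(x, dtype=float).copy()
    offset = int(round(interpulse_interval_ms * 1e-3 * fs))
    pre = int(round(pre_ms * 1e-3 * fs))
    post = int(round(post_ms * 1e-3 * fs))
    for start in (t0_sample, t0_sample + offset):
        lo = max(start - pre, 0)
        hi = min(start + post + 1, y.size)
        y[lo:hi] = 0.0
    return y
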