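"""Paired-pulse reflex (PRM / MEP) classification and repetition pooling.

A posterior root-muscle reflex is recognized by three properties of the
synchronized, filtered trace: a suprathreshold peak within 40 ms of the
first pulse, a first-response peak-to-peak amplitude above 50 uV and above
3 SD of the resting noise, and strong (> 70%) suppression of the second
(conditioned) response relative to the first -- the paired-pulse signature
that separates reflex responses from direct motor activation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .preprocess import NoiseEstimate, _EPS_UV

__all__ = ["ReflexResult", "MuscleActivity", "find_mep", "classify_reflex", "aggregate_ma"]

#: reflex-classification thresholds
MIN_AMP1_UV = 50.0
MIN_SUPPRESSION = 0.70

#: measurement windows relative to the first-response peak tmax (ms)
AMP1_WINDOW_MS = (-8.0, 15.0)
AMP2_WINDOW_MS = (42.0, 65.0)
PEAK_SEARCH_MS = 40.0


@dataclass(frozen=True)
class ReflexResult:
    """Per-trial paired-pulse evaluation for one muscle."""

    tmax_sample: int | None
    amp1_uV: float
    amp2_uV: float
    suppression: float
    detected: bool


@dataclass(frozen=True)
class MuscleActivity:
    """Repetition-pooled response MA for one (electrode, amplitude, muscle).

    ``MA_uV`` is the mean first-response peak-to-peak amplitude over the
    repetitions in which a reflex was detected; the value is only ``valid``
    when at least ``min_detected`` (default 2 of 3) repetitions responded.
    """

    MA_uV: float
    n_detected: int
    valid: bool


def _window_p2p(x: np.ndarray, fs: float, center: int, window_ms: tuple[float, float]) -> float:
    lo = center + int(round(window_ms[0] * 1e-3 * fs))
    hi = center + int(round(window_ms[1] * 1e-3 * fs)) + 1
    if hi > x.size:
        warnings.warn("response window truncated at trace end", stacklevel=3)
        hi = x.size
    lo = max(lo, 0)
    if hi - lo < 2:
        return 0.0
    seg = x[lo:hi]
    return float(seg.max() - seg.min())


def find_mep(
    x: np.ndarray,
    fs: float,
    t0_sample: int,
    noise: NoiseEstimate,
) -> ReflexResult:
    """Evaluate the paired-pulse response of a synchronized, filtered trace.

    Peaks of ``|x|`` exceeding 3 SD of the resting noise are searched in
    (t0, t0 + 40 ms]; the largest-magnitude one (earliest on ties) gives
    tmax. ``amp1`` is the peak-to-peak amplitude over
    [tmax - 8 ms, tmax + 15 ms], ``amp2`` over [tmax + 42 ms, tmax + 65 ms],
    and the suppression level is ``1 - amp2/amp1``. The stimulation
    transients must have been blanked beforehand (see
    :func:`tscs_calib.preprocess.blank_artifacts`).
    """
    x = np.asarray(x, dtype=float)
    thr = 3.0 * noise.sd_raw_uV
    if thr <= 0.0:
        thr = _EPS_UV
    lo = t0_sample + 1
    hi = min(t0_sample + int(round(PEAK_SEARCH_MS * 1e-3 * fs)) + 1, x.size)
    if lo >= hi:
        return ReflexResult(None, 0.0, 0.0, 0.0, False)
    a = np.abs(x[lo:hi])
    peaks, _ = signal.find_peaks(a, height=thr)
    if peaks.size == 0:
        return ReflexResult(None, 0.0, 0.0, 0.0, False)
    tmax = lo + int(peaks[np.argmax(a[peaks])])  # argmax returns first on ties
    amp1 = _window_p2p(x, fs, tmax, AMP1_WINDOW_MS)
    amp2 = _window_p2p(x, fs, tmax, AMP2_WINDOW_MS)
    suppression = 1.0 - amp2 / amp1 if amp1 > 0 else 0.0
    result = ReflexResult(tmax, amp1, amp2, suppression, False)
    return ReflexResult(tmax, amp1, amp2, suppression, classify_reflex(result, noise))


def classify_reflex(result: ReflexResult, noise: NoiseEstimate) -> bool:
    """True iff suppression > 70%, amp1 > 50 uV and amp1 > 3 SD of noise."""
    return (
        result.suppression > MIN_SUPPRESSION
        and result.amp1_uV > MIN_AMP1_UV
        and result.amp1_uV > 3.0 * noise.sd_raw_uV
    )


def aggregate_ma(
    results: Sequence[ReflexResult],
    min_detected: int = 2,
) -> MuscleActivity:
    """Pool repetitions into a muscle-activity value MA.

    The mean first-response amplitude over detected repetitions; valid only
    when the reflex appeared in at least ``min_detected`` repetitions.
    """
    if not results:
        raise ValueError("no repetition results to aggregate")
    amps = [r.amp1_uV for r in results if r.detected]
    n = len(amps)
    ma = float(np.mean(amps)) if n else float("nan")
    return MuscleActivity(MA_uV=ma, n_detected=n, valid=n >= min_detected)
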