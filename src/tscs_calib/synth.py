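"""Ground-truthed synthetic tSCS calibration sessions.

Emulates the statistical structure the detection and selection stages
assume: baseline Gaussian noise, a biphasic double-pulse stimulation
artifact (1 ms pulses, 50 ms interpulse interval) at a jittered onset,
and amplitude-dependent evoked responses whose peak-to-peak amplitude
follows a sigmoid recruitment function

    p2p(I) = gain * saturation / (1 + exp(-slope * (I - threshold)))

with electrode- and muscle-specific gains encoding rostrocaudal and
ipsilateral recruitment gradients, and a strongly suppressed second
(conditioned) response characteristic of posterior root-muscle reflexes.

The sigmoid is a modelling convention: the analysis pipeline only relies
on monotone recruitment, fixed response latency and paired-pulse
suppression, not on the exact shape.

Ground-truth response amplitudes are reported on the *measurement* scale:
the injected waveform's peak-to-peak after the standard preprocessing
filters (a fixed, known gain per sampling rate), so that comparisons with
pipeline output isolate noise and detection error from filter attenuation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .layouts import ELECTRODE_SIDE, ROSTROCAUDAL_RANK, SynthSessionConfig
from .preprocess import preprocess_trace
from .reflex import MIN_AMP1_UV

__all__ = [
    "RecruitmentParams",
    "SelectivityProfile",
    "Session",
    "sigmoid_response",
    "synth_trial",
    "synth_session",
    "measurement_attenuation",
]


@dataclass(frozen=True)
class RecruitmentParams:
    """Sigmoid recruitment parameters of one muscle.

    threshold_mA: current at the half-maximum response;
    slope_per_mA: sigmoid steepness;
    saturation_uV: asymptotic peak-to-peak response;
    suppression_ratio: amp2/amp1 of the conditioned response, in [0, 1]
    (PRM reflexes show strong paired-pulse suppression, i.e. small ratios).
    """

    threshold_mA: float = 30.0
    slope_per_mA: float = 0.8
    saturation_uV: float = 1000.0
    suppression_ratio: float = 0.15

    def __post_init__(self) -> None:
        if self.saturation_uV <= 0:
            raise ValueError("saturation_uV must be > 0")
        if self.slope_per_mA <= 0:
            raise ValueError("slope_per_mA must be > 0")
        if not 0.0 <= self.suppression_ratio <= 1.0:
            raise ValueError("suppression_ratio must lie in [0, 1]")


# rostrocaudal gain gradient: rank 1 = rostral favours proximal muscles,
# rank 3 = caudal favours distal muscles
_PROXIMAL_GAIN_BY_RANK = {1: 1.0, 2: 1.0, 3: 0.3}
_DISTAL_GAIN_BY_RANK = {1: 0.3, 2: 0.7, 3: 1.0}
_CONTRALATERAL_GAIN = 0.4


@dataclass(frozen=True)
class SelectivityProfile:
    """Multiplicative saturation gains per (electrode, muscle), in [0, 1]."""

    gains: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for electrode, per_muscle in self.gains.items():
            vals = list(per_muscle.values())
            if any(g < 0.0 or g > 1.0 for g in vals):
                raise ValueError(f"gains of {electrode} outside [0, 1]")
            if not vals or not math.isclose(max(vals), 1.0):
                raise ValueError(f"electrode {electrode} needs at least one gain of 1")

    def gain(self, electrode: str, muscle: str) -> float:
        return self.gains[electrode][muscle]

    @classmethod
    def default(cls, config: SynthSessionConfig) -> "SelectivityProfile":
        """Rostrocaudal (proximal vs distal) and ipsilateral gradient.

        Rostral electrodes predominantly drive proximal muscles, caudal
        electrodes distal ones; lateral electrodes drive the ipsilateral
        leg at full gain and the contralateral leg attenuated.
        """
        gains: dict[str, dict[str, float]] = {}
        for electrode in config.electrodes:
            rank = ROSTROCAUDAL_RANK[electrode]
            side = ELECTRODE_SIDE[electrode]
            per_muscle: dict[str, float] = {}
            for muscle in config.muscles:
                name, leg = muscle.rsplit("_", 1)
                rc = (
                    _DISTAL_GAIN_BY_RANK[rank]
                    if name in ("GASTRO", "TA", "SOL")
                    else _PROXIMAL_GAIN_BY_RANK[rank]
                )
                lateral = 1.0 if side in ("M", leg) else _CONTRALATERAL_GAIN
                per_muscle[muscle] = rc * lateral
            gains[electrode] = per_muscle
        return cls(gains)


@dataclass
class Session:
    """All traces of one synthetic calibration session.

    ``trials`` maps (electrode, amplitude_mA, repetition) to a DataFrame
    with one column per muscle (uV) and one row per sample.
    """

    config: SynthSessionConfig
    trials: dict[tuple[str, float, int], pd.DataFrame]

    def trial(self, electrode: str, amplitude_mA: float, repetition: int) -> pd.DataFrame:
        return self.trials[(electrode, float(amplitude_mA), repetition)]


def sigmoid_response(amplitude_mA: float, params: RecruitmentParams, gain: float = 1.0) -> float:
    """Raw (pre-filter) evoked peak-to-peak amplitude at a given current."""
    if amplitude_mA < 0:
        raise ValueError("amplitude_mA must be >= 0")
    z = -params.slope_per_mA * (amplitude_mA - params.threshold_mA)
    return gain * params.saturation_uV / (1.0 + math.exp(z))


def _evoked_lobe(p2p_uV: float, fs: float, duration_ms: float) -> np.ndarray:
    """Single biphasic sine-like lobe with the requested peak-to-peak."""
    n = max(int(round(duration_ms * 1e-3 * fs)), 4)
    t = np.arange(n) / n
    return 0.5 * p2p_uV * np.sin(2.0 * np.pi * t)


def _artifact_pulse(p2p_uV: float, fs: float) -> np.ndarray:
    """1 ms rectangular biphasic stimulation transient."""
    n_half = int(round(0.5e-3 * fs))
    if n_half < 1:
        raise ValueError("sampling rate too low to place a 1 ms pulse")
    return np.concatenate(
        [np.full(n_half, 0.5 * p2p_uV), np.full(n_half, -0.5 * p2p_uV)]
    )


def _add(trace: np.ndarray, wave: np.ndarray, start: int) -> None:
    trace[start : start + wave.size] += wave[: max(trace.size - start, 0)]


@lru_cache(maxsize=8)
def measurement_attenuation(fs: float, duration_ms: float) -> float:
    """Peak-to-peak gain of the preprocessing chain on the evoked lobe.

    The zero-phase notch and low-pass filters attenuate the ~100 Hz lobe
    slightly; this fixed factor converts raw injected amplitudes to the
    amplitudes an ideal noise-free measurement reports.
    """
    pad = int(round(fs))
    lobe = _evoked_lobe(1.0, fs, duration_ms)
    x = np.zeros(3 * pad)
    _add(x, lobe, pad)
    y = preprocess_trace(x, fs)
    tmax = pad - lobe.size + int(np.argmax(np.abs(y[pad - lobe.size : pad + 2 * lobe.size])))
    lo = tmax + int(round(-8e-3 * fs))
    hi = tmax + int(round(15e-3 * fs)) + 1
    return float(y[lo:hi].max() - y[lo:hi].min())


def synth_trial(
    config: SynthSessionConfig,
    electrode: str,
    amplitude_mA: float,
    repetition: int,
    params: RecruitmentParams | dict[str, RecruitmentParams],
    profile: SelectivityProfile,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One 5-s trial: per-muscle traces plus its ground-truth slice.

    Each trace is baseline noise + the double-pulse artifact + (where the
    recruitment sigmoid is non-zero) two evoked lobes, the second scaled
    by the suppression ratio and delayed by the interpulse interval. The
    resting period after 2.5 s contains noise only.
    """
    if electrode not in config.electrodes:
        raise ValueError(f"unknown electrode {electrode!r}")
    fs = config.sampling_rate_Hz
    n = config.n_samples
    lo = int(math.ceil(config.artifact_window_s[0] * fs))
    hi = int(math.floor(config.artifact_window_s[1] * fs))
    onset = int(rng.integers(lo, hi + 1))
    ipi = int(round(config.interpulse_interval_ms * 1e-3 * fs))
    latency = int(round(config.response_latency_ms * 1e-3 * fs))
    kappa = measurement_attenuation(fs, config.response_duration_ms)

    pulse = _artifact_pulse(config.artifact_p2p_uV, fs)
    traces: dict[str, np.ndarray] = {}
    gt_rows = []
    for muscle in config.muscles:
        p = params[muscle] if isinstance(params, dict) else params
        gain = profile.gain(electrode, muscle)
        raw_amp1 = sigmoid_response(amplitude_mA, p, gain)
        raw_amp2 = p.suppression_ratio * raw_amp1

        x = (
            rng.normal(0.0, config.noise_sd_uV, n)
            if config.noise_sd_uV > 0
            else np.zeros(n)
        )
        _add(x, pulse, onset)
        _add(x, pulse, onset + ipi)
        if raw_amp1 > 0:
            _add(x, _evoked_lobe(raw_amp1, fs, config.response_duration_ms), onset + latency)
            _add(x, _evoked_lobe(raw_amp2, fs, config.response_duration_ms), onset + ipi + latency)
        traces[muscle] = x
        true_amp1 = kappa * raw_amp1
        gt_rows.append(
            {
                "electrode": electrode,
                "amplitude_mA": float(amplitude_mA),
                "repetition": repetition,
                "muscle": muscle,
                "artifact_onset_sample": onset,
                "reflex_present": bool(true_amp1 > MIN_AMP1_UV),
                "true_amp1_uV": true_amp1,
                "true_amp2_uV": kappa * raw_amp2,
            }
        )
    return pd.DataFrame(traces), pd.DataFrame(gt_rows)


def synth_session(
    config: SynthSessionConfig,
    params: RecruitmentParams | dict[str, RecruitmentParams] | None = None,
    profile: SelectivityProfile | None = None,
) -> tuple[Session, pd.DataFrame]:
    """Full session: every electrode x amplitude x repetition trial.

    Deterministic given ``config.seed``; the ground-truth table has one
    row per (electrode, amplitude, repetition, muscle).
    """
    if params is None:
        params = RecruitmentParams()
    if profile is None:
        profile = SelectivityProfile.default(config)
    rng = np.random.default_rng(config.seed)
    trials: dict[tuple[str, float, int], pd.DataFrame] = {}
    gt_parts = []
    for electrode in config.electrodes:
        for amplitude in config.amplitudes_mA:
            for rep in range(1, config.n_repetitions + 1):
                df, gt = synth_trial(config, electrode, amplitude, rep, params, profile, rng)
                trials[(electrode, float(amplitude), rep)] = df
                gt_parts.append(gt)
    ground_truth = pd.concat(gt_parts, ignore_index=True)
    return Session(config=config, trials=trials), ground_truth
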