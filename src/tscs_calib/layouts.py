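"""Electrode layouts, muscle sets and session configuration.

Two spinal electrode configurations are supported, mirroring common
multi-electrode tSCS montages over the T10-L1 vertebral levels:

* ``midline`` -- three electrodes E1 (most rostral), E2, E3 (most caudal)
  aligned on the spinal midline;
* ``bilateral`` -- six electrodes, three per side of the midline
  (L1-L3 left, R1-R3 right; index 1 rostral, 3 caudal).

EMG is recorded from seven muscles per leg: four proximal (rectus femoris
RF, semitendinosus ST, vastus lateralis VL, vastus medialis VM) and three
distal (gastrocnemius GASTRO, tibialis anterior TA, soleus SOL). Muscle
labels carry a ``_L``/``_R`` leg suffix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PROXIMAL_MUSCLES = ("RF", "ST", "VL", "VM")
DISTAL_MUSCLES = ("GASTRO", "TA", "SOL")
LEG_MUSCLES = PROXIMAL_MUSCLES + DISTAL_MUSCLES

MIDLINE_ELECTRODES = ("E1", "E2", "E3")
BILATERAL_ELECTRODES = ("L1", "L2", "L3", "R1", "R2", "R3")

#: rostrocaudal rank (1 = most rostral, 3 = most caudal) of each electrode
ROSTROCAUDAL_RANK = {
    "E1": 1, "E2": 2, "E3": 3,
    "L1": 1, "L2": 2, "L3": 3,
    "R1": 1, "R2": 2, "R3": 3,
}

#: side of each electrode: "L", "R", or "M" (midline)
ELECTRODE_SIDE = {
    "E1": "M", "E2": "M", "E3": "M",
    "L1": "L", "L2": "L", "L3": "L",
    "R1": "R", "R2": "R", "R3": "R",
}


def default_muscles() -> list[str]:
    """All 14 muscle labels, left leg first, proximal before distal."""
    return [f"{m}_{leg}" for leg in ("L", "R") for m in LEG_MUSCLES]


def default_groups(configuration: str) -> dict[str, list[str]]:
    """Disjoint muscle-group partition used for selectivity analyses.

    ``midline`` partitions muscles into proximal/distal (both legs pooled);
    ``bilateral`` into the four leg x proximal/distal quadrants. Composite
    targets (e.g. the whole left leg) are unions of these cells.
    """
    if configuration == "midline":
        return {
            "proximal": [f"{m}_{leg}" for leg in ("L", "R") for m in PROXIMAL_MUSCLES],
            "distal": [f"{m}_{leg}" for leg in ("L", "R") for m in DISTAL_MUSCLES],
        }
    if configuration == "bilateral":
        return {
            "left_proximal": [f"{m}_L" for m in PROXIMAL_MUSCLES],
            "left_distal": [f"{m}_L" for m in DISTAL_MUSCLES],
            "right_proximal": [f"{m}_R" for m in PROXIMAL_MUSCLES],
            "right_distal": [f"{m}_R" for m in DISTAL_MUSCLES],
        }
    raise ValueError(f"unknown configuration: {configuration!r}")


def composite_targets(configuration: str) -> dict[str, list[str]]:
    """Named target groups, including unions of partition cells."""
    groups = dict(default_groups(configuration))
    if configuration == "bilateral":
        groups["left"] = groups["left_proximal"] + groups["left_distal"]
        groups["right"] = groups["right_proximal"] + groups["right_distal"]
    return groups


@dataclass
class SynthSessionConfig:
    """Configuration of one synthetic calibration session.

    Defaults follow the acquisition protocol the analysis stages assume:
    5-s trial windows, a charge-balanced double pulse with a 50 ms
    interpulse interval delivered somewhere in [0.8, 1.25] s, three
    repetitions per amplitude, and 2 kHz sampling.
    """

    configuration: str = "midline"
    electrodes: tuple[str, ...] | None = None
    muscles: tuple[str, ...] | None = None
    amplitudes_mA: tuple[float, ...] = tuple(float(a) for a in range(20, 62, 5))
    n_repetitions: int = 3
    sampling_rate_Hz: float = 2000.0
    trial_length_s: float = 5.0
    artifact_window_s: tuple[float, float] = (0.8, 1.25)
    noise_sd_uV: float = 5.0
    artifact_p2p_uV: float = 2000.0
    interpulse_interval_ms: float = 50.0
    response_latency_ms: float = 15.0
    response_duration_ms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.electrodes is None:
            self.electrodes = (
                MIDLINE_ELECTRODES
                if self.configuration == "midline"
                else BILATERAL_ELECTRODES
            )
        self.electrodes = tuple(self.electrodes)
        if self.muscles is None:
            self.muscles = tuple(default_muscles())
        self.muscles = tuple(self.muscles)
        self.amplitudes_mA = tuple(float(a) for a in self.amplitudes_mA)
        self.validate()

    def validate(self) -> None:
        if self.configuration not in ("midline", "bilateral"):
            raise ValueError(f"unknown configuration: {self.configuration!r}")
        if len(set(self.electrodes)) != len(self.electrodes):
            raise ValueError("duplicate electrode labels")
        if len(set(self.muscles)) != len(self.muscles):
            raise ValueError("duplicate muscle labels")
        amps = self.amplitudes_mA
        if any(b <= a for a, b in zip(amps, amps[1:])):
            raise ValueError("amplitudes_mA must be strictly increasing")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.trial_length_s < self.artifact_window_s[1]:
            raise ValueError("trial_length_s must cover the artifact window")
        # the 1 ms pulse needs at least one sample per phase
        if self.sampling_rate_Hz * 1e-3 < 2:
            raise ValueError(
                "sampling rate too low to place a 1 ms biphasic pulse "
                f"({self.sampling_rate_Hz} Hz < 2000 Hz)"
            )
        if self.noise_sd_uV < 0 or self.artifact_p2p_uV <= 0:
            raise ValueError("noise_sd_uV must be >= 0 and artifact_p2p_uV > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_length_s * self.sampling_rate_Hz))

    @property
    def groups(self) -> dict[str, list[str]]:
        return default_groups(self.configuration)
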