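"""Stimulation amplitude schedules, protocol timing and group statistics.

The calibration protocol ramps the current from 10 mA below the visually
identified reflex threshold in 5 mA steps; once the first reflex is
detected online, fifteen further amplitudes follow in 2 mA steps, capped
at 30 mA above the reflex threshold or the maximum tolerated intensity.
Protocol duration is purely multiplicative: electrodes x amplitudes x
repetitions x interstimulus interval.

Group-level selectivity statistics follow the standard nonparametric
route: Kolmogorov-Smirnov normality check (advisory), Kruskal-Wallis
omnibus test across electrodes, pairwise Wilcoxon signed-rank tests and
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AmplitudeSchedule",
    "ProtocolTiming",
    "StatsReport",
    "build_schedule",
    "protocol_duration",
    "steps_for_range",
    "group_stats",
]


@dataclass(frozen=True)
class AmplitudeSchedule:
    """Realized amplitude schedule for one electrode configuration."""

    start_mA: float
    cap_mA: float
    coarse_step_mA: float
    fine_step_mA: float
    n_fine: int
    amplitudes_mA: tuple[float, ...]
    coarse_only: bool
    n_repetitions: int = 3
    interstimulus_interval_s: float = 5.0


@dataclass(frozen=True)
class ProtocolTiming:
    n_electrodes: int
    n_amplitudes: int
    n_repetitions: int
    interstimulus_interval_s: float
    total_s: float
    total_min: float


def build_schedule(
    visual_threshold_mA: float,
    max_tolerated_mA: float,
    first_reflex_mA: float | None = None,
    coarse_step_mA: float = 5.0,
    fine_step_mA: float = 2.0,
    n_fine: int = 15,
    headroom_mA: float = 30.0,
    start_offset_mA: float = 10.0,
    n_repetitions: int = 3,
    interstimulus_interval_s: float = 5.0,
) -> AmplitudeSchedule:
    """Amplitude schedule around a reflex threshold.

    Coarse 5 mA steps start 10 mA below the visual threshold and run until
    the first online-detected reflex (``first_reflex_mA``); ``n_fine``
    amplitudes in 2 mA steps follow, truncated at
    min(reflex threshold + 30 mA, maximum tolerated current). With no
    detected reflex the coarse ramp runs to the cap and the schedule is
    flagged ``coarse_only``.
    """
    if max_tolerated_mA < visual_threshold_mA - start_offset_mA:
        raise ValueError("max tolerated current below the schedule start")
    start = visual_threshold_mA - start_offset_mA
    reflex_ref = first_reflex_mA if first_reflex_mA is not None else visual_threshold_mA
    cap = min(reflex_ref + headroom_mA, max_tolerated_mA)
    if cap < start:
        raise ValueError("empty schedule: cap below start amplitude")

    amps: list[float] = []
    a = start
    coarse_end = first_reflex_mA if first_reflex_mA is not None else cap
    while a <= min(coarse_end, cap) + 1e-9:
        amps.append(round(a, 6))
        a += coarse_step_mA
    coarse_only = first_reflex_mA is None
    if not coarse_only:
        for k in range(1, n_fine + 1):
            f = first_reflex_mA + k * fine_step_mA
            if f > cap + 1e-9:
                break
            amps.append(round(f, 6))
    return AmplitudeSchedule(
        start_mA=start,
        cap_mA=cap,
        coarse_step_mA=coarse_step_mA,
        fine_step_mA=fine_step_mA,
        n_fine=n_fine,
        amplitudes_mA=tuple(amps),
        coarse_only=coarse_only,
        n_repetitions=n_repetitions,
        interstimulus_interval_s=interstimulus_interval_s,
    )


def protocol_duration(
    n_electrodes: int,
    n_amplitudes: int,
    n_repetitions: int,
    interstimulus_interval_s: float = 5.0,
) -> ProtocolTiming:
    """Total calibration time: one double pulse per interval, exhaustively."""
    if min(n_electrodes, n_amplitudes, n_repetitions) < 1:
        raise ValueError("all counts must be >= 1")
    if interstimulus_interval_s <= 0:
        raise ValueError("interval must be positive")
    total_s = n_electrodes * n_amplitudes * n_repetitions * interstimulus_interval_s
    return ProtocolTiming(
        n_electrodes=n_electrodes,
        n_amplitudes=n_amplitudes,
        n_repetitions=n_repetitions,
        interstimulus_interval_s=interstimulus_interval_s,
        total_s=float(total_s),
        total_min=float(total_s) / 60.0,
    )


def steps_for_range(span_mA: float, increment_mA: float) -> int:
    """Number of equal increments covering an amplitude span (ceiling)."""
    if span_mA < 0 or increment_mA <= 0:
        raise ValueError("span must be >= 0 and increment > 0")
    return math.ceil(round(span_mA / increment_mA, 9))


@dataclass
class StatsReport:
    """Nonparametric comparison of SI values across electrodes."""

    normality: dict[str, tuple[float, float]]
    kruskal_H: float
    kruskal_p: float
    pairwise: pd.DataFrame
    alpha: float
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = bool(np.isfinite(self.kruskal_p) and self.kruskal_p < self.alpha)


def group_stats(si_table: pd.DataFrame, alpha: float = 0.05) -> StatsReport:
    """Compare one target group's SI across electrodes (subjects paired).

    ``si_table``: rows = subjects, columns = electrodes, values = SI_T.
    Runs a KS normality check per electrode (advisory; the nonparametric
    path is always taken), a Kruskal-Wallis omnibus test, and pairwise
    Wilcoxon signed-rank tests with Benjamini-Hochberg correction.
    """
    if si_table.shape[1] < 2 or si_table.shape[0] < 2:
        raise ValueError("need >= 2 electrodes and >= 2 subjects")
    normality: dict[str, tuple[float, float]] = {}
    for col in si_table.columns:
        x = si_table[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            warnings.warn(f"constant SI values for electrode {col}; degenerate test")
            normality[str(col)] = (float("nan"), float("nan"))
        else:
            stat, p = sps.kstest((x - x.mean()) / sd, "norm")
            normality[str(col)] = (float(stat), float(p))

    groups = [si_table[c].to_numpy(dtype=float) for c in si_table.columns]
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):  # all values identical: H is undefined
        warnings.warn("identical SI values across all electrodes; degenerate test")
        h, p_kw = 0.0, 1.0
    else:
        h, p_kw = sps.kruskal(*groups)

    rows = []
    for c1, c2 in combinations(si_table.columns, 2):
        d = si_table[c1].to_numpy(dtype=float) - si_table[c2].to_numpy(dtype=float)
        if np.allclose(d, 0):
            warnings.warn(f"identical paired SI for {c1} vs {c2}; degenerate test")
            p = 1.0
        else:
            _, p = sps.wilcoxon(d)
        rows.append({"electrode_1": c1, "electrode_2": c2, "p_raw": float(p)})
    pairwise = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(pairwise["p_raw"], alpha=alpha, method="fdr_bh")
    pairwise["p_adj"] = p_adj
    pairwise["significant"] = reject
    return StatsReport(
        normality=normality,
        kruskal_H=float(h),
        kruskal_p=float(p_kw),
        pairwise=pairwise,
        alpha=alpha,
    )
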