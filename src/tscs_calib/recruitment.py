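"""Recruitment curves, AUC/REC metrics and selectivity indices.

A recruitment curve is the pooled response amplitude of one muscle under
one electrode as a function of stimulation current. Responses are
normalized per muscle to the largest response that muscle showed on any
electrode of the configuration; the area under the normalized curve (AUC)
summarizes cumulative recruitment, and its normalization over all
(muscle, electrode) pairs yields REC in [0, 1].

The selectivity index compares target to non-target recruitment:

    SI_m = REC_m - mean_{n != m} REC_n                (single muscle)
    SI_T = mean_{m in T} REC_m - mean_{n not in T} REC_n   (muscle group)

Both lie in [-1, 1]; for a two-group partition SI of the complement is the
exact negative. An amplitude-resolved variant applies the group formula to
the normalized responses at a single current, which is what the
selectivity-driven electrode selection maximizes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "build_curve",
    "normalize_responses",
    "compute_auc",
    "compute_rec",
    "si_muscle",
    "si_group",
    "si_group_at_amplitude",
]


def build_curve(
    ma_values: Sequence[float],
    carry_forward: bool = True,
) -> np.ndarray:
    """Fill absences in an amplitude-ordered response series.

    ``ma_values`` holds one pooled response per amplitude with ``NaN`` (or
    ``None``) marking amplitudes without a valid reflex. Absences that
    follow a valid value are replaced by the last valid value (limiting
    false negatives at currents where a response was already established);
    leading absences become 0.
    """
    vals = np.array(
        [np.nan if v is None else float(v) for v in ma_values], dtype=float
    )
    if not carry_forward:
        return np.nan_to_num(vals, nan=0.0)
    out = np.empty_like(vals)
    last = 0.0
    for i, v in enumerate(vals):
        if np.isfinite(v):
            last = v
        out[i] = last
    return out


def normalize_responses(curves: pd.DataFrame) -> pd.DataFrame:
    """Normalize one muscle's curves by its maximum over all electrodes.

    ``curves``: rows = amplitudes, columns = electrodes, values = pooled
    responses (uV) of a single muscle. The muscle's largest response across
    the whole configuration maps to 1. An all-zero muscle stays all-zero.
    """
    peak = float(np.nanmax(curves.to_numpy())) if curves.size else 0.0
    if peak <= 0:
        return curves * 0.0
    return curves / peak


def compute_auc(normalized: Sequence[float], amplitudes_mA: Sequence[float]) -> float:
    """Trapezoidal area under a normalized recruitment curve (mA units)."""
    y = np.asarray(normalized, dtype=float)
    x = np.asarray(amplitudes_mA, dtype=float)
    if x.size < 2 or y.size != x.size:
        raise ValueError("need >= 2 amplitudes and matching curve length")
    return float(np.trapezoid(y, x))


def compute_rec(aucs: pd.DataFrame) -> pd.DataFrame:
    """Normalize AUCs by the configuration-wide maximum.

    ``aucs``: rows = muscles, columns = electrodes. The largest AUC over
    all (muscle, electrode) pairs maps to REC = 1; all-zero input stays 0.
    """
    peak = float(np.nanmax(aucs.to_numpy())) if aucs.size else 0.0
    if peak <= 0:
        return aucs * 0.0
    return aucs / peak


def si_muscle(rec_values: Sequence[float], m: int) -> float:
    """Selectivity of muscle ``m`` against the mean of all others."""
    rec = np.asarray(rec_values, dtype=float)
    if rec.size < 2:
        raise ValueError("need at least two muscles")
    others = np.delete(rec, m)
    return float(rec[m] - others.mean())


def si_group(
    rec_values: Sequence[float],
    target: Sequence[int] | np.ndarray,
) -> float:
    """Group selectivity: mean target REC minus mean non-target REC.

    ``target`` is either an index array or a boolean mask over muscles.
    Both the target set and its complement must be non-empty.
    """
    rec = np.asarray(rec_values, dtype=float)
    mask = np.zeros(rec.size, dtype=bool)
    mask[np.asarray(target)] = True
    if not mask.any() or mask.all():
        raise ValueError("target set and its complement must both be non-empty")
    return float(rec[mask].mean() - rec[~mask].mean())


def si_group_at_amplitude(
    normalized_at_I: Sequence[float],
    target: Sequence[int] | np.ndarray,
) -> float:
    """Group selectivity from normalized responses at a single current."""
    return si_group(normalized_at_I, target)
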