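"""End-to-end session analysis: from raw traces to selection-ready tables.

For every trial the raw traces are median-removed and double-
differentiated to locate the stimulation artifact (per muscle), the trial
is synchronized to the earliest detection, and the filtered, artifact-
blanked traces are evaluated for paired-pulse reflexes. Repetitions are
pooled into muscle-activity values, recruitment curves are built with
carry-forward, normalized per muscle across electrodes, and summarized as
AUC/REC and group selectivity indices. The resulting
:class:`~tscs_calib.selection.SessionSummary` feeds the RBA/SDA selection
algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocess as pp
from . import recruitment as rc
from .layouts import SynthSessionConfig, default_groups
from .reflex import ReflexResult, aggregate_ma, find_mep
from .selection import SessionSummary
from .synth import Session

__all__ = ["SessionAnalysis", "analyze_trial", "analyze_session", "build_summary"]


@dataclass
class SessionAnalysis:
    """All per-session analysis tables.

    detections: per (electrode, amplitude, repetition, muscle) artifact and
        reflex outcome; activity: repetition-pooled MA values; curves: tidy
        recruitment curves (raw and normalized, after carry-forward);
        rec: REC values (muscle x electrode); si: group SI_T per electrode;
        summary: algorithm-ready flags and normalized responses.
    """

    detections: pd.DataFrame
    activity: pd.DataFrame
    curves: pd.DataFrame
    rec: pd.DataFrame
    si: pd.DataFrame
    summary: SessionSummary


def analyze_trial(
    traces: pd.DataFrame,
    fs: float,
    interpulse_interval_ms: float = 50.0,
    search_window_s: tuple[float, float] = (0.8, 1.25),
) -> tuple[int | None, dict[str, pp.ArtifactDetection], dict[str, ReflexResult]]:
    """Synchronize one trial and evaluate the reflex of every muscle.

    Artifact detection runs on the Laplacian of the median-removed raw
    trace; reflex evaluation on the filtered trace with both stimulation
    transients blanked. An unsynchronized trial (no artifact on any
    muscle) yields non-detected results throughout.
    """
    detections: dict[str, pp.ArtifactDetection] = {}
    raw_centered: dict[str, np.ndarray] = {}
    for muscle in traces.columns:
        x = traces[muscle].to_numpy(dtype=float)
        x = x - np.median(x)
        raw_centered[muscle] = x
        noise_delta = pp.estimate_noise(x, fs)
        detections[muscle] = pp.detect_artifact(
            pp.laplacian_transform(x),
            noise_delta,
            fs,
            interpulse_interval_ms=interpulse_interval_ms,
            search_window_s=search_window_s,
        )
    t0 = pp.synchronize_trial(detections)

    results: dict[str, ReflexResult] = {}
    for muscle in traces.columns:
        if t0 is None:
            results[muscle] = ReflexResult(None, 0.0, 0.0, 0.0, False)
            continue
        filtered = pp.preprocess_trace(raw_centered[muscle], fs)
        blanked = pp.blank_artifacts(
            filtered, fs, t0, interpulse_interval_ms=interpulse_interval_ms
        )
        noise = pp.estimate_noise(blanked, fs)
        results[muscle] = find_mep(blanked, fs, t0, noise)
    return t0, detections, results


def analyze_session(
    session: Session,
    min_detected: int = 2,
    groups: dict[str, list[str]] | None = None,
) -> SessionAnalysis:
    """Run the full detection/recruitment pipeline on a session."""
    config = session.config
    fs = config.sampling_rate_Hz
    det_rows = []
    rep_results: dict[tuple[str, float, str], list[ReflexResult]] = {}
    for (electrode, amplitude, rep), traces in session.trials.items():
        t0, detections, results = analyze_trial(
            traces, fs, interpulse_interval_ms=config.interpulse_interval_ms,
            search_window_s=config.artifact_window_s,
        )
        for muscle in traces.columns:
            d = detections[muscle]
            r = results[muscle]
            det_rows.append(
                {
                    "electrode": electrode,
                    "amplitude_mA": amplitude,
                    "repetition": rep,
                    "muscle": muscle,
                    "artifact_detected": d.detected,
                    "t0_sample": d.t0_sample,
                    "trial_t0_sample": t0,
                    "reflex_detected": r.detected,
                    "amp1_uV": r.amp1_uV,
                    "amp2_uV": r.amp2_uV,
                    "suppression": r.suppression,
                }
            )
            rep_results.setdefault((electrode, amplitude, muscle), []).append(r)
    detections_df = pd.DataFrame(det_rows)

    act_rows = []
    for (electrode, amplitude, muscle), results_list in rep_results.items():
        ma = aggregate_ma(results_list, min_detected=min_detected)
        act_rows.append(
            {
                "electrode": electrode,
                "amplitude_mA": amplitude,
                "muscle": muscle,
                "MA_uV": ma.MA_uV,
                "n_detected": ma.n_detected,
                "valid": ma.valid,
            }
        )
    activity = pd.DataFrame(act_rows)

    if groups is None:
        groups = default_groups(config.configuration)
    curves, rec, si, summary = build_summary(
        activity,
        electrodes=list(config.electrodes),
        amplitudes_mA=list(config.amplitudes_mA),
        muscles=list(config.muscles),
        groups=groups,
    )
    return SessionAnalysis(
        detections=detections_df,
        activity=activity,
        curves=curves,
        rec=rec,
        si=si,
        summary=summary,
    )


def build_summary(
    activity: pd.DataFrame,
    electrodes: list[str],
    amplitudes_mA: list[float],
    muscles: list[str],
    groups: dict[str, list[str]],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SessionSummary]:
    """Recruitment curves, REC, SI tables and the selection summary.

    ``activity`` must hold one row per (electrode, amplitude, muscle) with
    ``MA_uV`` and ``valid``. Invalid entries are treated as absent, filled
    by carry-forward, and all responses are normalized per muscle over the
    whole configuration.
    """
    amps = np.asarray(amplitudes_mA, dtype=float)
    n_e, n_a, n_m = len(electrodes), amps.size, len(muscles)
    ma = np.full((n_e, n_a, n_m), np.nan)
    reflex = np.zeros((n_e, n_a, n_m), dtype=bool)
    e_idx = {e: i for i, e in enumerate(electrodes)}
    a_idx = {a: i for i, a in enumerate(amps)}
    m_idx = {m: i for i, m in enumerate(muscles)}
    for row in activity.itertuples():
        e, a, m = e_idx[row.electrode], a_idx[float(row.amplitude_mA)], m_idx[row.muscle]
        reflex[e, a, m] = bool(row.valid)
        if row.valid:
            ma[e, a, m] = row.MA_uV

    filled = np.empty_like(ma)
    for e in range(n_e):
        for m in range(n_m):
            filled[e, :, m] = rc.build_curve(ma[e, :, m])

    normalized = np.empty_like(filled)
    curve_rows = []
    auc = pd.DataFrame(0.0, index=muscles, columns=electrodes)
    for m, muscle in enumerate(muscles):
        per_muscle = pd.DataFrame(filled[:, :, m].T, index=amps, columns=electrodes)
        norm = rc.normalize_responses(per_muscle)
        for e, electrode in enumerate(electrodes):
            normalized[e, :, m] = norm[electrode].to_numpy()
            auc.loc[muscle, electrode] = rc.compute_auc(normalized[e, :, m], amps)
            for a, amp in enumerate(amps):
                curve_rows.append(
                    {
                        "muscle": muscle,
                        "electrode": electrode,
                        "amplitude_mA": float(amp),
                        "response_uV": filled[e, a, m],
                        "normalized": normalized[e, a, m],
                    }
                )
    curves = pd.DataFrame(curve_rows)
    rec = rc.compute_rec(auc)

    summary = SessionSummary(
        electrodes=electrodes,
        amplitudes_mA=amps,
        muscles=muscles,
        groups=groups,
        reflex=reflex,
        response=normalized,
    )
    si_rows = []
    for group in groups:
        idx = summary.target_indices(group)
        for electrode in electrodes:
            si_rows.append(
                {
                    "group": group,
                    "electrode": electrode,
                    "SI_T": rc.si_group(rec[electrode].to_numpy(), idx),
                }
            )
    si = pd.DataFrame(si_rows)
    return curves, rec, si, summary
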