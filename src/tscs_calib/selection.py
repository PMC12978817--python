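"""Electrode/amplitude selection: ranking-based (RBA), selectivity-driven
(SDA), conventional maximal-activation selection, and the normalized
relative deviation (NRD) between two sets of selections.

Both algorithms consume a :class:`SessionSummary`: per (electrode,
amplitude, muscle) reflex flags and normalized responses, plus a disjoint
muscle-group partition. RBA applies a hierarchy of binary criteria inside
a "selective" amplitude range (where fewer than half of the non-target
groups are activated); SDA maximizes the amplitude-resolved group
selectivity index subject to minimum activation and recruitment criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .recruitment import si_group_at_amplitude

__all__ = [
    "SessionSummary",
    "SelectionOutcome",
    "NRDResult",
    "selective_range",
    "rba_select",
    "sda_select",
    "conventional_select",
    "compute_nrd",
    "default_electrode_coding",
]


@dataclass
class SessionSummary:
    """Logged calibration data in algorithm-ready form.

    ``reflex[e, a, m]`` flags a detected reflex for electrode index ``e``,
    amplitude index ``a``, muscle index ``m``; ``response`` holds the
    matching normalized responses. ``groups`` is the disjoint muscle-group
    partition used to define non-target activation.
    """

    electrodes: list[str]
    amplitudes_mA: np.ndarray
    muscles: list[str]
    groups: dict[str, list[str]]
    reflex: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes_mA = np.asarray(self.amplitudes_mA, dtype=float)
        self.reflex = np.asarray(self.reflex, dtype=bool)
        self.response = np.asarray(self.response, dtype=float)
        shape = (len(self.electrodes), self.amplitudes_mA.size, len(self.muscles))
        if self.reflex.shape != shape or self.response.shape != shape:
            raise ValueError(f"reflex/response arrays must have shape {shape}")
        seen: set[str] = set()
        for name, members in self.groups.items():
            bad = set(members) - set(self.muscles)
            if bad:
                raise ValueError(f"group {name!r} references unknown muscles {bad}")
            if seen & set(members):
                raise ValueError("muscle groups must be disjoint")
            seen |= set(members)

    def muscle_indices(self, muscles: Sequence[str]) -> np.ndarray:
        index = {m: i for i, m in enumerate(self.muscles)}
        return np.array([index[m] for m in muscles], dtype=int)

    def target_indices(self, target: str | Sequence[str]) -> np.ndarray:
        """Resolve a target (group name or explicit muscle list) to indices."""
        if isinstance(target, str):
            if target not in self.groups:
                raise KeyError(f"unknown target group {target!r}")
            return self.muscle_indices(self.groups[target])
        return self.muscle_indices(list(target))


@dataclass
class SelectionOutcome:
    """Result of one selection run, with a per-electrode audit trail.

    ``electrodes`` lists every tied winner (never silently broken);
    ``electrode`` is the first of them in layout order. ``I_mA`` is the
    amplitude of maximal target response for the winner, ``Iprime_mA`` the
    first amplitude with any target reflex.
    """

    algorithm: str
    target_group: str | tuple[str, ...]
    selective: bool
    electrode: str | None = None
    electrodes: tuple[str, ...] = ()
    Istim_mA: float | None = None
    I_mA: float | None = None
    Iprime_mA: float | None = None
    score: float | None = None
    audit: list[dict] = field(default_factory=list)


@dataclass
class NRDResult:
    """Weighted relative deviation between two selection sets (Eqs. 7-9 style).

    ``per_condition`` maps each condition to (N cases, mean relative
    difference); ``nrd`` is the case-count-weighted mean.
    """

    per_condition: dict[str, tuple[int, float]]
    nrd: float
    n_excluded: int = 0


def _non_target_groups(summary: SessionSummary, target_idx: np.ndarray) -> list[np.ndarray]:
    """Partition cells disjoint from the target; error on partial overlap."""
    target = set(int(i) for i in target_idx)
    out = []
    for name, members in summary.groups.items():
        idx = summary.muscle_indices(members)
        overlap = target & set(int(i) for i in idx)
        if not overlap:
            out.append(idx)
        elif len(overlap) != len(idx):
            raise ValueError(
                f"target partially overlaps group {name!r}; targets must be "
                "unions of partition cells"
            )
    return out


def selective_range(
    summary: SessionSummary,
    target: str | Sequence[str],
    electrode: str | None = None,
) -> np.ndarray:
    """Amplitude indices where fewer than half the non-target groups activate.

    A group counts as activated at amplitude I when at least 50% of its
    muscles show a reflex at I. By default a muscle's reflex at I is pooled
    over electrodes (any electrode); pass ``electrode`` to restrict the
    range to one electrode's own recruitment. With no non-target groups
    (global-activation targets) the full range is selective.
    """
    target_idx = summary.target_indices(target)
    nt_groups = _non_target_groups(summary, target_idx)
    n_amp = summary.amplitudes_mA.size
    if not nt_groups:
        return np.arange(n_amp)
    if electrode is None:
        reflex_am = summary.reflex.any(axis=0)  # (amplitude, muscle)
    else:
        reflex_am = summary.reflex[summary.electrodes.index(electrode)]
    keep = []
    for a in range(n_amp):
        n_active = sum(
            reflex_am[a, idx].sum() >= 0.5 * idx.size for idx in nt_groups
        )
        if n_active < len(nt_groups) / 2.0:
            keep.append(a)
    return np.array(keep, dtype=int)


def _electrode_stats(
    summary: SessionSummary, e: int, amp_idx: np.ndarray, target_idx: np.ndarray
) -> dict:
    """Per-electrode RBA quantities within the selective range.

    ``ever_count`` is the number of target muscles responding at any
    amplitude of the range (criteria 1-2); ``I_mA`` the lowest amplitude
    achieving the maximal simultaneous target count, ``Iprime_mA`` the
    first amplitude with any target reflex.
    """
    reflex = summary.reflex[e][np.ix_(amp_idx, target_idx)]  # (range, target)
    counts = reflex.sum(axis=1)
    ever_count = int(reflex.any(axis=0).sum())
    stats = {
        "electrode": summary.electrodes[e],
        "ever_count": ever_count,
        "I_mA": None,
        "Iprime_mA": None,
    }
    if ever_count > 0:
        amps = summary.amplitudes_mA[amp_idx]
        stats["I_mA"] = float(amps[int(np.argmax(counts == counts.max()))])
        stats["Iprime_mA"] = float(amps[int(np.argmax(counts > 0))])
    return stats


def rba_select(summary: SessionSummary, target: str | Sequence[str]) -> SelectionOutcome:
    """Ranking-based selection by hierarchical binary criteria.

    Within the selective amplitude range: (1) keep electrodes where at
    least 50% of target muscles respond at some amplitude of the range;
    (2) keep those maximizing the responding-target count; (3) break ties
    by minimal I - I' (amplitude of maximal response minus first-response
    amplitude); (4) then by lowest I. Remaining ties are reported as a tie
    set. No target reflex in the selective range means non-selective.
    """
    target_idx = summary.target_indices(target)
    label = target if isinstance(target, str) else tuple(target)
    amp_idx = selective_range(summary, target)
    out = SelectionOutcome(algorithm="RBA", target_group=label, selective=False)
    if amp_idx.size == 0:
        return out
    stats = [
        _electrode_stats(summary, e, amp_idx, target_idx)
        for e in range(len(summary.electrodes))
    ]
    out.audit = stats
    need = 0.5 * target_idx.size
    survivors = [s for s in stats if s["ever_count"] >= need and s["ever_count"] > 0]
    if not survivors:
        return out
    best_count = max(s["ever_count"] for s in survivors)
    survivors = [s for s in survivors if s["ever_count"] == best_count]
    best_delta = min(s["I_mA"] - s["Iprime_mA"] for s in survivors)
    survivors = [s for s in survivors if s["I_mA"] - s["Iprime_mA"] == best_delta]
    best_I = min(s["I_mA"] for s in survivors)
    survivors = [s for s in survivors if s["I_mA"] == best_I]
    winners = tuple(s["electrode"] for s in survivors)
    first = survivors[0]
    out.selective = True
    out.electrode = first["electrode"]
    out.electrodes = winners
    out.Istim_mA = first["I_mA"]
    out.I_mA = first["I_mA"]
    out.Iprime_mA = first["Iprime_mA"]
    return out


def sda_select(
    summary: SessionSummary,
    target: str | Sequence[str],
    min_recruitment: float = 0.05,
) -> SelectionOutcome:
    """Selectivity-driven selection: maximize amplitude-resolved SI_T.

    Electrodes must activate at least 50% of target muscles at some
    amplitude; an amplitude is only evaluated when the mean
    normalized target response reaches ``min_recruitment`` (default 5%).
    The winner maximizes SI_T(I); ties prefer the lower amplitude and any
    remaining cross-electrode tie is reported as a tie set.
    """
    target_idx = summary.target_indices(target)
    label = target if isinstance(target, str) else tuple(target)
    n_amp = summary.amplitudes_mA.size
    out = SelectionOutcome(algorithm="SDA", target_group=label, selective=False)
    need = 0.5 * target_idx.size
    candidates = []  # (si, amplitude, electrode index)
    for e in range(len(summary.electrodes)):
        ever_count = int(summary.reflex[e][:, target_idx].any(axis=0).sum())
        eligible = ever_count >= need and ever_count > 0
        rows = []
        for a in range(n_amp):
            mean_target = float(summary.response[e, a, target_idx].mean())
            if not eligible or mean_target < min_recruitment:
                continue
            si = si_group_at_amplitude(summary.response[e, a], target_idx)
            rows.append((a, mean_target, si))
            candidates.append((si, float(summary.amplitudes_mA[a]), e))
        out.audit.append(
            {
                "electrode": summary.electrodes[e],
                "eligible": bool(eligible),
                "evaluated": rows,
            }
        )
    if not candidates:
        return out
    best_si = max(c[0] for c in candidates)
    best = [c for c in candidates if c[0] == best_si]
    best_amp = min(c[1] for c in best)
    best = [c for c in best if c[1] == best_amp]
    winners = tuple(summary.electrodes[e] for _, _, e in sorted(best, key=lambda c: c[2]))
    e_win = min(e for _, _, e in best)
    out.selective = True
    out.electrode = summary.electrodes[e_win]
    out.electrodes = winners
    out.Istim_mA = best_amp
    out.I_mA = best_amp
    out.score = best_si
    reflex_any = summary.reflex[e_win][:, target_idx].any(axis=1)
    if reflex_any.any():
        out.Iprime_mA = float(summary.amplitudes_mA[int(np.argmax(reflex_any))])
    return out


def conventional_select(summary: SessionSummary) -> SelectionOutcome:
    """Conventional calibration: maximize global muscle activation.

    RBA with every muscle as the target; with no non-target muscles the
    full amplitude range is selective.
    """
    out = rba_select(summary, list(summary.muscles))
    out.algorithm = "conventional"
    out.target_group = "all"
    return out


def default_electrode_coding(electrodes: Sequence[str]) -> dict[str, int]:
    """Ordinal coding of electrode labels within a configuration (1-based)."""
    return {e: i + 1 for i, e in enumerate(electrodes)}


def _electrode_of(selection) -> str | None:
    if selection is None:
        return None
    if isinstance(selection, SelectionOutcome):
        return selection.electrode if selection.selective else None
    return str(selection)


def compute_nrd(
    rba_selections: Mapping[object, object],
    sda_selections: Mapping[object, object],
    condition_partition: Mapping[object, str] | None = None,
    electrode_coding: Mapping[str, int] | None = None,
    nonselective: str = "exclude",
) -> NRDResult:
    """Normalized relative deviation between two selection sets.

    Per case, Delta = |code(E_a) - code(E_b)| / code(E_b); cases are
    grouped into conditions, averaged per condition, and the condition
    means combined weighted by case counts. Selections may be
    :class:`SelectionOutcome` objects or plain electrode labels. Cases
    where either selection is non-selective are excluded with a warning
    (``nonselective="exclude"``) or penalized with the maximal coded
    deviation (``nonselective="max"``).
    """
    if set(rba_selections) != set(sda_selections):
        raise ValueError("both selection sets must cover the same cases")
    if condition_partition is None:
        condition_partition = {k: "all" for k in rba_selections}
    if electrode_coding is None:
        labels = []
        for sel in list(rba_selections.values()) + list(sda_selections.values()):
            e = _electrode_of(sel)
            if e is not None and e not in labels:
                labels.append(e)
        electrode_coding = default_electrode_coding(sorted(labels))
    if any(c <= 0 for c in electrode_coding.values()):
        raise ValueError("electrode codes must be positive integers")
    codes = electrode_coding
    max_delta = (
        (max(codes.values()) - min(codes.values())) / min(codes.values())
        if codes
        else 0.0
    )

    deltas: dict[str, list[float]] = {}
    n_excluded = 0
    for case in rba_selections:
        cond = condition_partition[case]
        e_a = _electrode_of(rba_selections[case])
        e_b = _electrode_of(sda_selections[case])
        if e_a is None or e_b is None:
            if nonselective == "max":
                deltas.setdefault(cond, []).append(max_delta)
            else:
                n_excluded += 1
                warnings.warn(
                    f"case {case!r} excluded from NRD: non-selective outcome",
                    stacklevel=2,
                )
            continue
        deltas.setdefault(cond, []).append(abs(codes[e_a] - codes[e_b]) / codes[e_b])

    per_condition = {
        cond: (len(vals), float(np.mean(vals))) for cond, vals in deltas.items()
    }
    total_n = sum(n for n, _ in per_condition.values())
    nrd = (
        sum(n * mean for n, mean in per_condition.values()) / total_n
        if total_n
        else 0.0
    )
    return NRDResult(per_condition=per_condition, nrd=float(nrd), n_excluded=n_excluded)
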