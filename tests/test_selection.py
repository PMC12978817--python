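"""Electrode selection algorithms against a brute-force oracle, plus NRD."""

import numpy as np
import pytest

import tscs_calib as tc
from conftest import make_summary

# ---------------------------------------------------------------------------
# brute-force oracle: plain-python re-derivation of the stated criteria,
# independent of the vectorized implementation
# ---------------------------------------------------------------------------


def oracle_selective_range(summary, target_muscles):
    target = set(target_muscles)
    nt_groups = []
    for members in summary.groups.values():
        if not (set(members) & target):
            nt_groups.append(members)
    n_amp = len(summary.amplitudes_mA)
    if not nt_groups:
        return list(range(n_amp))
    out = []
    for a in range(n_amp):
        active = 0
        for members in nt_groups:
            n_resp = 0
            for m in members:
                mi = summary.muscles.index(m)
                if any(summary.reflex[e, a, mi] for e in range(len(summary.electrodes))):
                    n_resp += 1
            if n_resp >= 0.5 * len(members):
                active += 1
        if active < len(nt_groups) / 2.0:
            out.append(a)
    return out


def oracle_rba(summary, target_muscles):
    """Exhaustive evaluation of the four ranking criteria."""
    rng_idx = oracle_selective_range(summary, target_muscles)
    t_idx = [summary.muscles.index(m) for m in target_muscles]
    if not rng_idx:
        return None
    rows = []
    for e, label in enumerate(summary.electrodes):
        ever = sum(
            1 for m in t_idx if any(summary.reflex[e, a, m] for a in rng_idx)
        )
        if ever < 0.5 * len(t_idx) or ever == 0:
            continue
        counts = [sum(summary.reflex[e, a, m] for m in t_idx) for a in rng_idx]
        best = max(counts)
        I = summary.amplitudes_mA[rng_idx[counts.index(best)]]
        Ip = summary.amplitudes_mA[rng_idx[next(i for i, c in enumerate(counts) if c > 0)]]
        rows.append((label, ever, float(I), float(Ip)))
    if not rows:
        return None
    best_key = min((-r[1], r[2] - r[3], r[2]) for r in rows)
    winners = [r for r in rows if (-r[1], r[2] - r[3], r[2]) == best_key]
    return {
        "electrodes": {r[0] for r in winners},
        "Istim": winners[0][2],
    }


def oracle_sda(summary, target_muscles, min_recruitment=0.05):
    t_idx = [summary.muscles.index(m) for m in target_muscles]
    nt_idx = [i for i in range(len(summary.muscles)) if i not in t_idx]
    pairs = []
    for e, label in enumerate(summary.electrodes):
        ever = sum(
            1
            for m in t_idx
            if any(summary.reflex[e, a, m] for a in range(len(summary.amplitudes_mA)))
        )
        if ever < 0.5 * len(t_idx) or ever == 0:
            continue
        for a, amp in enumerate(summary.amplitudes_mA):
            mean_t = sum(summary.response[e, a, m] for m in t_idx) / len(t_idx)
            if mean_t < min_recruitment:
                continue
            mean_nt = sum(summary.response[e, a, m] for m in nt_idx) / len(nt_idx)
            pairs.append((label, float(amp), mean_t - mean_nt))
    if not pairs:
        return None
    best_si = max(p[2] for p in pairs)
    best = [p for p in pairs if p[2] == best_si]
    best_amp = min(p[1] for p in best)
    best = [p for p in best if p[1] == best_amp]
    return {"electrodes": {p[0] for p in best}, "Istim": best_amp}


def random_summary(rng):
    n_e = int(rng.integers(2, 7))
    n_a = int(rng.integers(3, 16))
    n_m = 14
    muscles = [f"m{i}" for i in range(n_m)]
    reflex = rng.random((n_e, n_a, n_m)) < rng.uniform(0.15, 0.7)
    response = np.where(
        rng.random((n_e, n_a, n_m)) < 0.8, rng.random((n_e, n_a, n_m)), 0.0
    )
    cells = [muscles[0:4], muscles[4:7], muscles[7:11], muscles[11:14]]
    groups = {f"g{i}": c for i, c in enumerate(cells)}
    summary = make_summary(
        reflex,
        response,
        amplitudes=np.arange(n_a) * 2.0 + 20.0,
        muscles=muscles,
        groups=groups,
    )
    k = int(rng.integers(1, len(cells)))
    chosen = rng.choice(len(cells), size=k, replace=False)
    target = [m for i in sorted(chosen) for m in cells[i]]
    return summary, target


class TestOracleEquivalence:
    def test_rba_matches_brute_force(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            summary, target = random_summary(rng)
            got = tc.rba_select(summary, target)
            want = oracle_rba(summary, target)
            if want is None:
                assert not got.selective
            else:
                assert got.selective
                assert set(got.electrodes) == want["electrodes"]
                assert got.Istim_mA == pytest.approx(want["Istim"])

    def test_sda_matches_brute_force(self):
        rng = np.random.default_rng(456)
        for _ in range(100):
            summary, target = random_summary(rng)
            got = tc.sda_select(summary, target)
            want = oracle_sda(summary, target)
            if want is None:
                assert not got.selective
            else:
                assert got.selective
                assert set(got.electrodes) == want["electrodes"]
                assert got.Istim_mA == pytest.approx(want["Istim"])


class TestSelectiveRange:
    def test_no_reflex_gives_full_range(self):
        summary = make_summary(np.zeros((2, 4, 4)), np.zeros((2, 4, 4)))
        assert list(tc.selective_range(summary, ["m0", "m1"])) == [0, 1, 2, 3]

    def test_single_nontarget_group_always_active_empty_range(self):
        reflex = np.zeros((1, 3, 4), dtype=bool)
        reflex[0, :, 2:] = True  # group B always fully active
        summary = make_summary(reflex, np.zeros((1, 3, 4)))
        assert tc.selective_range(summary, ["m0", "m1"]).size == 0

    def test_one_of_three_nontarget_groups_active_included(self):
        muscles = [f"m{i}" for i in range(8)]
        groups = {
            "t": muscles[0:2],
            "n1": muscles[2:4],
            "n2": muscles[4:6],
            "n3": muscles[6:8],
        }
        reflex = np.zeros((1, 2, 8), dtype=bool)
        reflex[0, 0, 2:4] = True  # only n1 active at amplitude 0
        summary = make_summary(
            reflex, np.zeros((1, 2, 8)), muscles=muscles, groups=groups
        )
        assert 0 in tc.selective_range(summary, "t")

    def test_partial_overlap_rejected(self):
        summary = make_summary(np.zeros((1, 2, 4)), np.zeros((1, 2, 4)))
        with pytest.raises(ValueError):
            tc.selective_range(summary, ["m0", "m2"])  # m2 belongs to group B


class TestRbaCriteria:
    def test_criterion2_more_target_muscles_wins(self):
        reflex = np.zeros((2, 3, 4), dtype=bool)
        reflex[0, 1, :] = True  # electrode 0: 4/4 targets
        reflex[1, 1, :2] = True  # electrode 1: 2/4 targets
        summary = make_summary(reflex, np.zeros((2, 3, 4)), groups={"t": ["m0", "m1", "m2", "m3"]})
        out = tc.rba_select(summary, "t")
        assert out.selective and out.electrode == "e0"

    def test_criterion3_tighter_threshold_span_wins(self):
        # both electrodes reach 3 target muscles; (I, I') = (40, 30) vs (40, 36)
        muscles = [f"m{i}" for i in range(4)]
        amps = [30.0, 36.0, 40.0]
        reflex = np.zeros((2, 3, 4), dtype=bool)
        reflex[0, 0, 0] = True  # first response at 30
        reflex[0, 2, :3] = True  # max count 3 at 40 -> delta 10
        reflex[1, 1, 0] = True  # first response at 36
        reflex[1, 2, :3] = True  # max count 3 at 40 -> delta 4
        summary = make_summary(
            reflex, np.zeros((2, 3, 4)), amplitudes=amps, muscles=muscles,
            groups={"t": muscles},
        )
        out = tc.rba_select(summary, "t")
        assert out.selective and out.electrode == "e1"
        assert out.Istim_mA == pytest.approx(40.0)
        assert out.Iprime_mA == pytest.approx(36.0)

    def test_criterion1_insufficient_activation_nonselective(self):
        reflex = np.zeros((2, 3, 4), dtype=bool)
        reflex[0, 1, 0] = True  # only 1/4 target muscles anywhere
        summary = make_summary(reflex, np.zeros((2, 3, 4)), groups={"t": ["m0", "m1", "m2", "m3"]})
        out = tc.rba_select(summary, "t")
        assert not out.selective

    def test_exact_tie_reported_not_broken(self):
        reflex = np.zeros((2, 2, 4), dtype=bool)
        reflex[:, 1, :] = True
        summary = make_summary(reflex, np.zeros((2, 2, 4)), groups={"t": ["m0", "m1", "m2", "m3"]})
        out = tc.rba_select(summary, "t")
        assert set(out.electrodes) == {"e0", "e1"}


class TestSda:
    def test_single_eligible_electrode_argmax_amplitude(self):
        muscles = [f"m{i}" for i in range(4)]
        reflex = np.zeros((2, 3, 4), dtype=bool)
        reflex[0, :, :2] = True
        response = np.zeros((2, 3, 4))
        response[0, :, 0] = [0.2, 0.6, 0.4]
        response[0, :, 1] = [0.2, 0.6, 0.4]
        summary = make_summary(
            reflex, response, muscles=muscles, groups={"t": muscles[:2], "n": muscles[2:]}
        )
        out = tc.sda_select(summary, "t")
        assert out.selective and out.electrode == "e0"
        assert out.Istim_mA == pytest.approx(summary.amplitudes_mA[1])
        assert out.score == pytest.approx(0.6)

    def test_higher_si_electrode_wins(self):
        muscles = [f"m{i}" for i in range(4)]
        reflex = np.ones((2, 2, 4), dtype=bool)
        response = np.zeros((2, 2, 4))
        response[0, 1, :2] = 0.6  # electrode A: SI 0.6
        response[1, 1, :2] = 0.3  # electrode B: SI 0.3
        summary = make_summary(
            reflex, response, muscles=muscles, groups={"t": muscles[:2], "n": muscles[2:]}
        )
        out = tc.sda_select(summary, "t")
        assert out.electrode == "e0"

    def test_equal_si_prefers_lower_amplitude(self):
        muscles = [f"m{i}" for i in range(4)]
        amps = [38.0, 44.0]
        reflex = np.ones((1, 2, 4), dtype=bool)
        response = np.zeros((1, 2, 4))
        response[0, :, :2] = 0.5  # identical SI at both amplitudes
        summary = make_summary(
            reflex, response, amplitudes=amps, muscles=muscles,
            groups={"t": muscles[:2], "n": muscles[2:]},
        )
        out = tc.sda_select(summary, "t")
        assert out.Istim_mA == pytest.approx(38.0)

    def test_min_recruitment_gate(self):
        muscles = [f"m{i}" for i in range(4)]
        reflex = np.ones((1, 2, 4), dtype=bool)
        response = np.zeros((1, 2, 4))
        response[0, :, :2] = 0.03  # below the 5% recruitment requirement
        summary = make_summary(
            reflex, response, muscles=muscles, groups={"t": muscles[:2], "n": muscles[2:]}
        )
        assert not tc.sda_select(summary, "t").selective


class TestConventional:
    def test_global_activation_prefers_lower_amplitude(self):
        reflex = np.zeros((3, 3, 4), dtype=bool)
        reflex[1, 0, :] = True  # E2 reaches all muscles at the lowest amplitude
        reflex[2, 2, :] = True  # E3 only at the highest
        summary = make_summary(reflex, np.zeros((3, 3, 4)), groups={"t": ["m0", "m1"], "n": ["m2", "m3"]})
        out = tc.conventional_select(summary)
        assert out.selective and out.electrode == "e1"
        assert out.algorithm == "conventional"

    def test_no_reflexes_nonselective(self):
        summary = make_summary(np.zeros((2, 2, 4)), np.zeros((2, 2, 4)))
        assert not tc.conventional_select(summary).selective


class TestNrd:
    def test_identical_selections_zero(self):
        sel = {i: "E2" for i in range(10)}
        res = tc.compute_nrd(sel, dict(sel), electrode_coding={"E1": 1, "E2": 2, "E3": 3})
        assert res.nrd == 0.0

    def test_single_case_relative_difference(self):
        res = tc.compute_nrd({0: "E3"}, {0: "E2"}, electrode_coding={"E2": 2, "E3": 3})
        assert res.nrd == pytest.approx(0.5)

    def test_weighted_mean_over_conditions(self):
        rba, sda, cond = {}, {}, {}
        # condition c1: 2 cases with delta 0.2 (codes 6 vs 5)
        for i in range(2):
            rba[f"a{i}"], sda[f"a{i}"], cond[f"a{i}"] = "E6", "E5", "c1"
        # condition c2: 6 cases with delta 0.6 (codes 8 vs 5)
        for i in range(6):
            rba[f"b{i}"], sda[f"b{i}"], cond[f"b{i}"] = "E8", "E5", "c2"
        coding = {"E5": 5, "E6": 6, "E8": 8}
        res = tc.compute_nrd(rba, sda, condition_partition=cond, electrode_coding=coding)
        assert res.per_condition["c1"] == (2, pytest.approx(0.2))
        assert res.per_condition["c2"] == (6, pytest.approx(0.6))
        assert res.nrd == pytest.approx(0.5)

    def test_relabeling_conditions_invariant_and_equal_weights_unweighted(self):
        rba = {0: "E1", 1: "E2", 2: "E3", 3: "E1"}
        sda = {0: "E2", 1: "E2", 2: "E1", 3: "E1"}
        coding = {"E1": 1, "E2": 2, "E3": 3}
        a = tc.compute_nrd(rba, sda, {0: "x", 1: "x", 2: "y", 3: "y"}, coding)
        b = tc.compute_nrd(rba, sda, {0: "u", 1: "u", 2: "v", 3: "v"}, coding)
        assert a.nrd == pytest.approx(b.nrd)
        deltas = [abs(1 - 2) / 2, 0.0, abs(3 - 1) / 1, 0.0]
        assert a.nrd == pytest.approx(np.mean([np.mean(deltas[:2]), np.mean(deltas[2:])]))

    def test_nonselective_excluded_with_warning(self):
        rba = {0: "E1", 1: None}
        sda = {0: "E1", 1: "E2"}
        with pytest.warns(UserWarning):
            res = tc.compute_nrd(rba, sda, electrode_coding={"E1": 1, "E2": 2})
        assert res.nrd == 0.0 and res.n_excluded == 1
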