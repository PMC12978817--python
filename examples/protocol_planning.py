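"""Plan an amplitude schedule and compute calibration durations.

The schedule starts 10 mA below the visually identified reflex
threshold in 5 mA steps; after the first online-detected reflex, 15
amplitudes follow in 2 mA steps, capped at threshold + 30 mA or the
tolerated maximum.
"""

import tscs_calib as tc

sched = tc.build_schedule(
    visual_threshold_mA=30.0, max_tolerated_mA=80.0, first_reflex_mA=30.0
)
print("amplitudes (mA):", list(sched.amplitudes_mA))
print("cap:", sched.cap_mA, "mA, coarse-only:", sched.coarse_only)

for label, n_electrodes, interval in (
    ("midline, 5 s interval", 3, 5.0),
    ("bilateral, 5 s interval", 6, 5.0),
    ("midline, 2 s interval", 3, 2.0),
    ("bilateral, 2 s interval", 6, 2.0),
):
    t = tc.protocol_duration(n_electrodes, 15, 3, interval)
    print(f"{label}: {t.total_s:.0f} s = {t.total_min:.2f} min")

# With 15 amplitudes x 3 repetitions per electrode and one double pulse
# per interstimulus interval, calibration takes 11.25 min (midline) or
# 22.5 min (bilateral) at 5 s, dropping to 4.5 / 9 min at 2 s.
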