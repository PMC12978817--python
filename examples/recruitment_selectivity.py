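"""Recruitment curves and selectivity indices on a noiseless session.

The default gain profile makes rostral electrodes favour proximal
muscles and caudal electrodes distal ones; the SI table should therefore
peak at E3 for the distal group and at E1/E2 for the proximal group.
"""

import tscs_calib as tc

cfg = tc.SynthSessionConfig(
    configuration="midline",
    amplitudes_mA=(20.0, 26.0, 32.0, 38.0, 44.0, 50.0),
    noise_sd_uV=0.0,
    seed=1,
)
session, _ = tc.synth_session(cfg)
analysis = tc.analyze_session(session)

print("REC (normalized area under the recruitment curve), one row per muscle:")
print(analysis.rec.round(3).to_string())

print("\nGroup selectivity index SI_T per electrode:")
print(analysis.si.pivot(index="group", columns="electrode", values="SI_T").round(3))

# SI_T = mean REC of the target group minus mean REC of the non-target
# group, in [-1, 1]: positive values mean the electrode preferentially
# recruits the target group. The distal row peaks at the most caudal
# electrode (E3), the proximal row at a rostral electrode.
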