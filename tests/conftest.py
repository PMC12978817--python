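import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tscs_calib as tc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

FS = 2000.0


@pytest.fixture(scope="session")
def noiseless_midline():
    """Small noiseless midline session with the default gain profile."""
    cfg = tc.SynthSessionConfig(
        configuration="midline",
        amplitudes_mA=(20.0, 26.0, 32.0, 38.0, 44.0, 50.0),
        n_repetitions=3,
        noise_sd_uV=0.0,
        seed=11,
    )
    session, gt = tc.synth_session(cfg)
    return session, gt


@pytest.fixture(scope="session")
def noiseless_midline_analysis(noiseless_midline):
    session, _ = noiseless_midline
    return tc.analyze_session(session)


@pytest.fixture(scope="session")
def noisy_small():
    """Noisy one-electrode session for quick pipeline checks."""
    cfg = tc.SynthSessionConfig(
        configuration="midline",
        electrodes=("E1", "E2", "E3"),
        amplitudes_mA=(15.0, 35.0, 45.0, 55.0),
        n_repetitions=2,
        seed=7,
    )
    session, gt = tc.synth_session(cfg)
    return session, gt


def make_summary(reflex, response, electrodes=None, amplitudes=None, muscles=None, groups=None):
    """Build a SessionSummary from plain arrays with sensible defaults."""
    reflex = np.asarray(reflex, dtype=bool)
    n_e, n_a, n_m = reflex.shape
    electrodes = electrodes or [f"e{i}" for i in range(n_e)]
    amplitudes = amplitudes if amplitudes is not None else np.arange(n_a, dtype=float) * 2 + 20
    muscles = muscles or [f"m{i}" for i in range(n_m)]
    if groups is None:
        half = n_m // 2
        groups = {"A": muscles[:half], "B": muscles[half:]}
    return tc.SessionSummary(
        electrodes=list(electrodes),
        amplitudes_mA=np.asarray(amplitudes, dtype=float),
        muscles=list(muscles),
        groups=groups,
        reflex=reflex,
        response=np.asarray(response, dtype=float),
    )
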