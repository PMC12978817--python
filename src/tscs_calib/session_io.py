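"""Session persistence.

A session directory holds ``session.yaml`` (configuration), one CSV per
trial named ``{electrode}_{amplitude}_{rep}.csv`` (first column time in
seconds, one column per muscle, header row of labels) and, for synthetic
sessions, ``ground_truth.json``. The same hierarchy can be packed into a
single HDF5 container.
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .layouts import SynthSessionConfig
from .synth import Session

__all__ = ["write_session", "read_session", "write_session_hdf5", "read_session_hdf5"]


def _amp_str(a: float) -> str:
    return format(a, "g")


def _config_dict(config: SynthSessionConfig) -> dict:
    d = asdict(config)
    d["electrodes"] = list(config.electrodes)
    d["muscles"] = list(config.muscles)
    d["amplitudes_mA"] = list(config.amplitudes_mA)
    d["artifact_window_s"] = list(config.artifact_window_s)
    return d


def _config_from_dict(d: dict) -> SynthSessionConfig:
    d = dict(d)
    d["artifact_window_s"] = tuple(d["artifact_window_s"])
    return SynthSessionConfig(**d)


def write_session(
    session: Session,
    directory: str | Path,
    ground_truth: pd.DataFrame | None = None,
) -> Path:
    """Write a session as a directory of per-trial CSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "session.yaml", "w") as fh:
        yaml.safe_dump(_config_dict(session.config), fh, sort_keys=False)
    fs = session.config.sampling_rate_Hz
    for (electrode, amplitude, rep), traces in session.trials.items():
        out = traces.copy()
        out.insert(0, "time_s", np.arange(len(out)) / fs)
        out.to_csv(
            directory / f"{electrode}_{_amp_str(amplitude)}_{rep}.csv", index=False
        )
    if ground_truth is not None:
        ground_truth.to_json(
            directory / "ground_truth.json", orient="records", indent=1
        )
    return directory


def read_session(directory: str | Path) -> tuple[Session, pd.DataFrame | None]:
    """Read a session directory written by :func:`write_session`."""
    directory = Path(directory)
    with open(directory / "session.yaml") as fh:
        config = _config_from_dict(yaml.safe_load(fh))
    trials: dict[tuple[str, float, int], pd.DataFrame] = {}
    for electrode in config.electrodes:
        for amplitude in config.amplitudes_mA:
            for rep in range(1, config.n_repetitions + 1):
                path = directory / f"{electrode}_{_amp_str(amplitude)}_{rep}.csv"
                df = pd.read_csv(path).drop(columns=["time_s"])
                trials[(electrode, float(amplitude), rep)] = df
    gt_path = directory / "ground_truth.json"
    ground_truth = pd.read_json(gt_path) if gt_path.exists() else None
    return Session(config=config, trials=trials), ground_truth


def write_session_hdf5(
    session: Session,
    path: str | Path,
    ground_truth: pd.DataFrame | None = None,
) -> Path:
    """Pack a session into one HDF5 file (same hierarchy as the directory)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["session_yaml"] = yaml.safe_dump(
            _config_dict(session.config), sort_keys=False
        )
        grp = f.create_group("trials")
        for (electrode, amplitude, rep), traces in session.trials.items():
            grp.create_dataset(
                f"{electrode}/{_amp_str(amplitude)}/{rep}",
                data=traces.to_numpy(dtype=float),
            )
        if ground_truth is not None:
            f.attrs["ground_truth_json"] = ground_truth.to_json(orient="records")
    return path


def read_session_hdf5(path: str | Path) -> tuple[Session, pd.DataFrame | None]:
    with h5py.File(path, "r") as f:
        config = _config_from_dict(yaml.safe_load(f.attrs["session_yaml"]))
        trials: dict[tuple[str, float, int], pd.DataFrame] = {}
        for electrode in config.electrodes:
            for amplitude in config.amplitudes_mA:
                for rep in range(1, config.n_repetitions + 1):
                    data = f["trials"][electrode][_amp_str(amplitude)][str(rep)][()]
                    trials[(electrode, float(amplitude), rep)] = pd.DataFrame(
                        data, columns=list(config.muscles)
                    )
        ground_truth = None
        if "ground_truth_json" in f.attrs:
            ground_truth = pd.read_json(_io.StringIO(f.attrs["ground_truth_json"]))
    return Session(config=config, trials=trials), ground_truth
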