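"""Epochs container I/O (HDF5 + TSV events sidecar) and config files.

Layout of the HDF5 container:

    /data        trials x channels x samples voltage array
    /time        sample times (ms)
    /channels    channel names
    /roles       channel role per channel (scalp/heog/veog)
    /positions   schematic (x, y) per channel
    attrs        units, subject, group, provenance (JSON)

The events table travels as ``<stem>.events.tsv`` next to the container
so it stays diffable and greppable.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .dataset import EpochsDataset
from .montage import ChannelMontage
from .simulate import EffectSpec, SimulationConfig


def events_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".events.tsv")


def save_epochs(epochs: EpochsDataset, path: str | Path) -> Path:
    """Write an epochs dataset to ``path`` (HDF5) + events TSV sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("time", data=epochs.times)
        f.create_dataset("channels",
                         data=np.array(epochs.montage.names, dtype="S"))
        f.create_dataset(
            "roles",
            data=np.array([epochs.montage.roles[n]
                           for n in epochs.montage.names], dtype="S"))
        f.create_dataset("positions", data=epochs.montage.position_array())
        f.attrs["units"] = epochs.units
        f.attrs["subject"] = epochs.subject
        f.attrs["group"] = epochs.group
        f.attrs["provenance"] = json.dumps(epochs.provenance)
    epochs.events.to_csv(events_path(path), sep="\t", index=False)
    return path


def load_epochs(path: str | Path) -> EpochsDataset:
    """Read an epochs dataset written by ``save_epochs``."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["time"][()]
        names = tuple(n.decode() for n in f["channels"][()])
        roles = [r.decode() for r in f["roles"][()]]
        positions = f["positions"][()]
        units = f.attrs["units"]
        subject = f.attrs["subject"]
        group = f.attrs["group"]
        provenance = json.loads(f.attrs.get("provenance", "[]"))
    montage = ChannelMontage(
        names=names,
        positions={n: tuple(positions[i]) for i, n in enumerate(names)},
        roles=dict(zip(names, roles)))
    events = pd.read_csv(events_path(path), sep="\t")
    return EpochsDataset(data=data, times=times, montage=montage,
                         events=events, subject=str(subject),
                         group=str(group), units=str(units),
                         provenance=provenance)


def simulation_config_to_dict(config: SimulationConfig) -> dict:
    d = {
        "n_subjects": dict(config.n_subjects),
        "n_trials_per_cell": config.n_trials_per_cell,
        "sfreq": config.sfreq,
        "epoch_window_ms": list(config.epoch_window_ms),
        "baseline_window_ms": list(config.baseline_window_ms),
        "noise_sd": config.noise_sd,
        "spatial_scale": config.spatial_scale,
        "ar_coef": config.ar_coef,
        "artifact_fraction": config.artifact_fraction,
        "artifact_heog_uv": config.artifact_heog_uv,
        "artifact_veog_uv": config.artifact_veog_uv,
        "correct_rate": config.correct_rate,
        "seed": config.seed,
    }
    if config.effects is not None:
        d["effects"] = [
            {"name": e.name, "pattern": list(map(float, e.pattern)),
             "center_ms": e.center_ms, "sd_ms": e.sd_ms,
             "amplitudes": {f"{t}:{g}": a
                            for (t, g), a in e.amplitudes.items()},
             "lateralized": e.lateralized}
            for e in config.effects
        ]
    return d


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    effects = d.pop("effects", None)
    if effects is not None:
        effects = [
            EffectSpec(
                name=e["name"], pattern=np.asarray(e["pattern"], dtype=float),
                center_ms=e["center_ms"], sd_ms=e["sd_ms"],
                amplitudes={tuple(k.split(":")): v
                            for k, v in e["amplitudes"].items()},
                lateralized=e.get("lateralized", False))
            for e in effects
        ]
    for key in ("epoch_window_ms", "baseline_window_ms"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(effects=effects, **d)


def save_simulation_config(config: SimulationConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(simulation_config_to_dict(config),
                                   sort_keys=False))
    return path


def load_simulation_config(path: str | Path) -> SimulationConfig:
    return simulation_config_from_dict(
        yaml.safe_load(Path(path).read_text()))


def from_mne_epochs(mne_epochs, events: pd.DataFrame, subject: str,
                    group: str) -> EpochsDataset:
    """Adapt an ``mne.Epochs`` object to the internal container.

    Channel names must match the schematic default montage (32 scalp
    10-20 names + HEOG/VEOG); ``events`` supplies the per-trial task /
    target-side / correctness metadata the recording itself lacks.
    Voltages are converted from Volts (MNE convention) to µV.
    """
    from .montage import default_montage

    montage = default_montage()
    missing = set(montage.names) - set(mne_epochs.ch_names)
    if missing:
        raise ValueError(f"epochs lack required channels: {sorted(missing)}")
    picks = [mne_epochs.ch_names.index(n) for n in montage.names]
    data_uv = mne_epochs.get_data()[:, picks, :] * 1e6
    times_ms = mne_epochs.times * 1000.0
    return EpochsDataset(data=data_uv, times=times_ms, montage=montage,
                         events=events.reset_index(drop=True),
                         subject=subject, group=group, units="uV")
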