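"""File formats and run configuration.

All tabular artifacts are plain delimited files readable by any tool:
electrode montages (label,x,y,z), neuron atlases (id,x,y,z,region,is_input,
channel), synapse sets (pre,post,weight), spike-event tables (channel,
sample_index,polarity), event schedules (onset_ms,stimulus_id,block,class)
and per-frame fired-neuron lists (frame,neuron_id). Epoch stacks travel as
``.npz`` containers with named arrays, or as one delimited matrix per epoch
(samples x channels with a channel-label header row).

Run configuration is a YAML file with one section per pipeline stage;
unknown sections or keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .brain_space import NeuronAtlas, SmallWorldConfig, SynapseSet
from .containers import EpochedRecording, normalize_channel
from .desnn_classifier import DesnnConfig
from .evaluation import ParamGrid, PipelineConfig
from .reservoir_learning import LifConfig, SnapshotTrajectory, StdpConfig
from .spike_encoding import SpikeSequence, TbrConfig, spikes_from_table, spikes_to_table


# ---------------------------------------------------------------- recordings

def write_recording(path: str | Path, rec: EpochedRecording) -> None:
    """Store an epoch stack as an .npz container with named arrays."""
    np.savez(path, data=rec.data, fs=np.array(rec.fs),
             channels=np.array(rec.channels, dtype=object),
             labels=np.array(rec.labels, dtype=object))


def read_recording(path: str | Path) -> EpochedRecording:
    with np.load(path, allow_pickle=True) as z:
        return EpochedRecording(data=z["data"], fs=float(z["fs"]),
                                channels=[str(c) for c in z["channels"]],
                                labels=[str(l) for l in z["labels"]])


def write_matrix(path: str | Path, data: np.ndarray, channels: list[str],
                 sep: str = ",") -> None:
    """One delimited matrix (samples x channels, channel-label header)."""
    df = pd.DataFrame(np.asarray(data).T, columns=channels)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_matrix(path: str | Path, sep: str = ",") -> tuple[list[str], np.ndarray]:
    """Read a delimited matrix; returns (channels, data) with data shaped
    (channels, samples). The header row must hold known channel labels."""
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    try:
        channels = [normalize_channel(str(c)) for c in df.columns]
    except KeyError as e:
        raise ValueError(f"malformed header: {e}") from None
    data = df.to_numpy(dtype=float).T
    if data.ndim != 2:
        raise ValueError("matrix file must be 2-D")
    return channels, data


# -------------------------------------------------------------------- tables

def _to_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def _read_csv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip", **kw)


def write_events(path: str | Path, schedule: pd.DataFrame) -> None:
    _to_csv(schedule, path)


def read_events(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    missing = {"onset_ms", "stimulus_id", "class"} - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return df


def write_spikes(path: str | Path, spikes: dict[str, SpikeSequence]) -> None:
    _to_csv(spikes_to_table(spikes), path)


def read_spikes(path: str | Path) -> dict[str, SpikeSequence]:
    return spikes_from_table(_read_csv(path))


def write_atlas(path: str | Path, atlas: NeuronAtlas) -> None:
    _to_csv(atlas.to_frame(), path)


def read_atlas(path: str | Path, spacing: float) -> NeuronAtlas:
    df = _read_csv(path, keep_default_na=False)
    return NeuronAtlas.from_frame(df, spacing=spacing)


def write_synapses(path: str | Path, syn: SynapseSet) -> None:
    _to_csv(syn.to_frame(), path)


def read_synapses(path: str | Path) -> SynapseSet:
    return SynapseSet.from_frame(_read_csv(path))


def write_trajectory(path: str | Path, traj: SnapshotTrajectory) -> None:
    rows = [(f, int(i)) for f in range(traj.n_frames) for i in traj.fired[f]]
    df = pd.DataFrame(rows, columns=["frame", "neuron_id"])
    with open(path, "w") as fh:
        fh.write(f"# frame_len={traj.frame_len} n_steps={traj.n_steps}\n")
        df.to_csv(fh, index=False)


def read_trajectory(path: str | Path) -> SnapshotTrajectory:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        df = pd.read_csv(fh)
    frame_len, n_steps = int(meta["frame_len"]), int(meta["n_steps"])
    n_frames = (n_steps + frame_len - 1) // frame_len
    fired = [df.loc[df["frame"] == f, "neuron_id"].to_numpy(dtype=int)
             for f in range(n_frames)]
    return SnapshotTrajectory(frame_len=frame_len, n_steps=n_steps, fired=fired)


# ------------------------------------------------------------- configuration

@dataclasses.dataclass
class RunConfig:
    """Top-level run settings: data generation + pipeline + global seed."""

    seed: int = 0
    n_participants: int = 20
    sample_mode: str = "block_average"
    noise_sd: float = 0.5
    fs: float = 256.0
    window_ms: tuple[float, float] = (0.0, 200.0)
    pipeline: PipelineConfig = dataclasses.field(default_factory=PipelineConfig)
    grid: ParamGrid = dataclasses.field(default_factory=ParamGrid)


_SECTION_TYPES = {
    "tbr": TbrConfig, "small_world": SmallWorldConfig, "lif": LifConfig,
    "stdp": StdpConfig, "desnn": DesnnConfig,
}
_TOP_KEYS = {"seed", "n_participants", "sample_mode", "noise_sd", "fs",
             "window_ms", "resolution", "passes", "input_mode", "grid"}


def _build_section(cls: type, data: dict[str, Any], name: str) -> Any:
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown keys in section [{name}]: {sorted(unknown)}")
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return cls(**coerced)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration, rejecting unknown sections/keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS - set(_SECTION_TYPES)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    pipe_kwargs: dict[str, Any] = {}
    for name, cls in _SECTION_TYPES.items():
        if name in raw:
            pipe_kwargs[name] = _build_section(cls, raw[name] or {}, name)
    for key in ("resolution", "passes", "input_mode"):
        if key in raw:
            pipe_kwargs[key] = raw[key]
    cfg = RunConfig(pipeline=PipelineConfig(**pipe_kwargs))
    if "grid" in raw:
        cfg.grid = _build_section(ParamGrid, raw["grid"] or {}, "grid")
    for key in ("seed", "n_participants", "sample_mode", "noise_sd", "fs"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "window_ms" in raw:
        cfg.window_ms = tuple(raw["window_ms"])
    return cfg


def write_manifest(path: str | Path, cfg: RunConfig,
                   extra: dict[str, Any] | None = None) -> None:
    """Record the exact configuration and seed of a run."""
    payload = {"eegsnn_version": __version__,
               "config": _as_jsonable(cfg)}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def _as_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
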