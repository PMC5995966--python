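"""Interpretation metrics for a trained reservoir.

Quantities mirror the standard read-outs of template-mapped SNN models of
EEG: the mean connection weight (globally and per input-channel cluster), a
per-channel spike-intensity measure (fraction of a channel's cluster that
fired within a time frame), its categorization into inactive / low / medium
/ strong activation levels, and an ordered stage trajectory of per-frame
channel activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reservoir_learning import ReservoirModel, SnapshotTrajectory

#: Activation categories and their half-open intensity bins. The published
#: level boundaries overlap at 0.4 and 0.7; here each boundary belongs to the
#: upper bin, so 0.4 is "medium" and 0.7 is "strong".
CATEGORY_BINS = (("inactive", 0.0, 0.1), ("low", 0.1, 0.4),
                 ("medium", 0.4, 0.7), ("strong", 0.7, 1.0 + 1e-12))


@dataclass
class ChannelCluster:
    """The neurons synaptically connected to one input channel's neuron
    (union of pre- and post-synaptic partners, plus the input neuron)."""

    channel: str
    members: np.ndarray

    def __post_init__(self) -> None:
        self.members = np.unique(np.asarray(self.members, dtype=int))
        if self.members.size == 0:
            raise ValueError(f"channel {self.channel!r}: empty cluster")


def channel_clusters(model: ReservoirModel) -> dict[str, ChannelCluster]:
    """Build the cluster of connected neurons around every input channel."""
    out: dict[str, ChannelCluster] = {}
    for ch, nid in model.atlas.input_map.items():
        partners = np.flatnonzero(model.conn[nid, :] | model.conn[:, nid])
        members = np.union1d(partners, [nid])
        out[ch] = ChannelCluster(channel=ch, members=members)
    return out


def mean_weight(model: ReservoirModel, threshold: float | None = None,
                absolute: bool = False) -> tuple[float, int]:
    """Mean connection weight and surviving-edge count.

    With a ``threshold``, only edges with |w| > threshold are averaged (the
    same cut used before visualising connectivity). ``absolute`` averages
    |w| instead of the signed weight.
    """
    syn = model.synapses()
    if syn.n_edges == 0:
        raise ValueError("model has no synapses")
    w = syn.weight
    if threshold is not None:
        w = w[np.abs(w) > threshold]
        if w.size == 0:
            return float("nan"), 0
    vals = np.abs(w) if absolute else w
    return float(vals.mean()), int(w.size)


def cluster_mean_weight(model: ReservoirModel, channel: str,
                        absolute: bool = False) -> float:
    """Mean weight of edges incident to the channel's input neuron."""
    if channel not in model.atlas.input_map:
        raise KeyError(f"channel {channel!r} not mapped")
    nid = model.atlas.input_map[channel]
    mask_out = model.conn[nid, :]
    mask_in = model.conn[:, nid]
    w = np.concatenate([model.W[nid, mask_out], model.W[mask_in, nid]])
    if w.size == 0:
        raise ValueError(f"input neuron of {channel!r} is isolated")
    return float(np.abs(w).mean() if absolute else w.mean())


def spike_intensity(traj: SnapshotTrajectory, cluster: ChannelCluster,
                    frame: int) -> float:
    """Fraction of the cluster's neurons that fired within a frame."""
    fired = traj.fired[frame]
    inter = np.intersect1d(fired, cluster.members, assume_unique=False)
    return float(inter.size / cluster.members.size)


def categorize(intensity: float) -> str:
    """Map an intensity in [0, 1] to inactive / low / medium / strong."""
    if not 0.0 <= intensity <= 1.0:
        raise ValueError(f"intensity {intensity} outside [0, 1]")
    for name, lo, hi in CATEGORY_BINS:
        if lo <= intensity < hi:
            return name
    return "strong"  # intensity == 1 boundary, unreachable via bins epsilon


def activation_report(traj: SnapshotTrajectory,
                      clusters: dict[str, ChannelCluster]) -> pd.DataFrame:
    """Per-channel, per-frame intensity and category table."""
    rows = []
    for frame in range(traj.n_frames):
        for ch, cl in clusters.items():
            inten = spike_intensity(traj, cl, frame)
            rows.append((ch, frame, inten, categorize(inten)))
    return pd.DataFrame(rows, columns=["channel", "frame", "intensity",
                                       "category"])


def stage_trajectory(traj: SnapshotTrajectory,
                     clusters: dict[str, ChannelCluster],
                     fs: float = 256.0) -> pd.DataFrame:
    """Ordered stage table of activation across frames.

    One row per (frame, channel), with the frame's total active-neuron count
    ``A``, the frame end time in ms, and the channel's intensity category.
    Channels are ordered by the first frame in which they reach at least
    "low" activation (never-active channels last, then alphabetical).
    """
    report = activation_report(traj, clusters)
    first_active: dict[str, int] = {}
    for ch in clusters:
        sub = report[(report["channel"] == ch) & (report["intensity"] >= 0.1)]
        first_active[ch] = int(sub["frame"].min()) if len(sub) else traj.n_frames
    order = sorted(clusters, key=lambda c: (first_active[c], c))
    rank = {c: i for i, c in enumerate(order)}

    rows = []
    dt_ms = 1000.0 / fs
    for frame in range(traj.n_frames):
        a_count = int(traj.fired[frame].size)
        t_end = (frame + 1) * traj.frame_len * dt_ms
        for ch in order:
            r = report[(report["channel"] == ch) & (report["frame"] == frame)]
            rows.append((frame, t_end, a_count, ch, rank[ch],
                         float(r["intensity"].iloc[0]), r["category"].iloc[0]))
    return pd.DataFrame(rows, columns=["frame", "t_end_ms", "active_neurons",
                                       "channel", "activation_order",
                                       "intensity", "category"])
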