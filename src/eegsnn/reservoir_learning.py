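"""Leaky integrate-and-fire reservoir dynamics with STDP learning.

The reservoir is driven one EEG sample per simulation step (at 256 Hz a step
is ~3.9 ms). Each step proceeds in a fixed order:

1. leak:      P <- P * exp(-dt_ms / tau_leak)
2. integrate: non-refractory neurons receive external input spikes (signed
              by polarity) on their input neuron plus the weighted spikes
              fired on the *previous* step (one synaptic delay step);
              refractory neurons are clamped at reset and receive nothing
3. fire:      neurons with P >= theta_fire and no pending refractoriness
              fire; their potential resets and a refractory counter starts
4. plasticity (if learning): every synapse with a pre- or post-side fire
              this step is adjusted by the STDP kernel F(dt) evaluated at
              the nearest opposite-side spike time, then clipped to bounds

The STDP kernel follows the classic exponential form with
dt = t_pre - t_post:  F(dt) = A+ exp(dt/tau+) for dt < 0 (pre before post,
potentiation) and F(dt) = -A- exp(-dt/tau-) for dt >= 0 (depression), all
scaled by a global learning rate. Simultaneous pre/post fires take the
dt = 0 branch once.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .brain_space import NeuronAtlas, SynapseSet
from .spike_encoding import SpikeSequence


@dataclass
class LifConfig:
    """Leaky integrate-and-fire neuron parameters.

    ``theta_fire`` is the firing threshold on the post-synaptic potential;
    ``tau_leak_ms`` the exponential leak time constant; ``refractory`` the
    number of steps after a fire during which the neuron is held at
    ``reset`` and cannot fire again.

    The 40 ms leak default lets sub-threshold potential summate over input
    bursts (~10 samples at 256 Hz): with small initial weights and a firing
    threshold of 0.5 this is what allows the best-connected neighbours of an
    input neuron to reach threshold at all, which in turn lets STDP engage
    and strengthen driven pathways.
    """

    theta_fire: float = 0.5
    tau_leak_ms: float = 40.0
    refractory: int = 1
    reset: float = 0.0

    def __post_init__(self) -> None:
        if self.theta_fire <= 0:
            raise ValueError("theta_fire must be positive")
        if self.tau_leak_ms <= 0:
            raise ValueError("tau_leak_ms must be positive")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")


@dataclass
class StdpConfig:
    """Exponential STDP kernel parameters.

    ``rate`` is the global learning-rate multiplier on F(dt); ``a_plus`` /
    ``a_minus`` the maximum adjustments near dt = 0; ``tau_plus_ms`` /
    ``tau_minus_ms`` the decay constants of the potentiation and depression
    branches. Weights are clipped to ``w_bounds`` after every update.
    """

    rate: float = 0.01
    a_plus: float = 1.0
    a_minus: float = 1.0
    tau_plus_ms: float = 10.0
    tau_minus_ms: float = 10.0
    w_bounds: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("a_plus and a_minus must be >= 0")
        if self.tau_plus_ms <= 0 or self.tau_minus_ms <= 0:
            raise ValueError("STDP time constants must be positive")
        if self.w_bounds[0] > self.w_bounds[1]:
            raise ValueError("w_bounds must be (low, high)")


def stdp_delta(dt_ms: float, cfg: StdpConfig) -> float:
    """Weight change for a pre/post spike pair at dt = t_pre - t_post (ms)."""
    if not np.isfinite(dt_ms):
        raise ValueError("dt must be finite")
    if dt_ms < 0:
        return cfg.rate * cfg.a_plus * float(np.exp(dt_ms / cfg.tau_plus_ms))
    return -cfg.rate * cfg.a_minus * float(np.exp(-dt_ms / cfg.tau_minus_ms))


@dataclass
class SnapshotTrajectory:
    """Per-frame sets of fired neuron ids; frames tile the epoch."""

    frame_len: int
    n_steps: int
    fired: list[np.ndarray] = field(default_factory=list)  # per frame, ids

    @property
    def n_frames(self) -> int:
        return len(self.fired)

    def frame_of_step(self, t: int) -> int:
        return t // self.frame_len


@dataclass
class EpochResult:
    """Outcome of simulating one epoch through the reservoir."""

    trajectory: SnapshotTrajectory
    spike_counts: np.ndarray          # (N,) total fires per neuron
    first_spike_step: np.ndarray      # (N,) step of first fire, -1 if silent
    n_steps: int


class ReservoirModel:
    """A wired 3D reservoir: atlas + dense weight matrix + LIF state.

    ``signed_input`` (default) delivers negative input spikes as negative
    potential increments on the mapped input neuron; the alternative
    ``separate_line`` ignores the sign and delivers the magnitude (a distinct
    excitatory line per polarity collapsed onto the same neuron).
    """

    def __init__(self, atlas: NeuronAtlas, synapses: SynapseSet,
                 input_mode: str = "signed_input", input_gain: float = 1.0):
        if input_mode not in ("signed_input", "separate_line"):
            raise ValueError(f"unknown input_mode {input_mode!r}")
        self.atlas = atlas
        self.n = atlas.n_neurons
        self.W = synapses.to_matrix(self.n)
        self.conn = np.zeros((self.n, self.n), dtype=bool)
        self.conn[synapses.pre, synapses.post] = True
        self.input_mode = input_mode
        self.input_gain = input_gain

    def copy(self) -> "ReservoirModel":
        new = object.__new__(ReservoirModel)
        new.atlas = self.atlas
        new.n = self.n
        new.W = self.W.copy()
        new.conn = self.conn
        new.input_mode = self.input_mode
        new.input_gain = self.input_gain
        return new

    def synapses(self) -> SynapseSet:
        pre, post = np.nonzero(self.conn)
        return SynapseSet(pre=pre, post=post, weight=self.W[pre, post])

    def input_drive(self, spikes: dict[str, SpikeSequence], n_steps: int
                    ) -> np.ndarray:
        """Dense (n_steps, N) external-drive matrix from per-channel spikes."""
        drive = np.zeros((n_steps, self.n))
        for ch, seq in spikes.items():
            if ch not in self.atlas.input_map:
                raise KeyError(f"channel {ch!r} has no mapped input neuron")
            nid = self.atlas.input_map[ch]
            if len(seq) == 0:
                continue
            if seq.times.max() >= n_steps:
                raise IndexError(f"spike at step {int(seq.times.max())} beyond "
                                 f"epoch of {n_steps} steps")
            pol = seq.polarities if self.input_mode == "signed_input" \
                else np.abs(seq.polarities)
            np.add.at(drive[:, nid], seq.times, self.input_gain * pol)
        return drive


def run_epoch(model: ReservoirModel, spikes: dict[str, SpikeSequence],
              n_steps: int, lif: LifConfig | None = None,
              stdp: StdpConfig | None = None, learn: bool = False,
              fs: float = 256.0, frame_ms: float = 50.0) -> EpochResult:
    """Simulate one epoch; optionally adapt weights by STDP in place.

    ``n_steps`` is the epoch length in samples (= simulation steps at the
    EEG sampling rate ``fs``).
    """
    lif = lif or LifConfig()
    stdp = stdp or StdpConfig()
    n = model.n
    dt_ms = 1000.0 / fs
    leak = float(np.exp(-dt_ms / lif.tau_leak_ms))
    frame_len = max(1, int(round(frame_ms * fs / 1000.0)))

    drive = model.input_drive(spikes, n_steps)
    P = np.full(n, lif.reset, dtype=float)
    refr = np.zeros(n, dtype=int)
    fired_prev = np.zeros(n, dtype=bool)
    last_spike = np.full(n, -1, dtype=int)       # step of most recent fire
    counts = np.zeros(n, dtype=int)
    first = np.full(n, -1, dtype=int)
    frames: list[list[int]] = [[] for _ in range((n_steps + frame_len - 1) // frame_len)]
    lo, hi = stdp.w_bounds

    for t in range(n_steps):
        blocked = refr > 0
        P *= leak
        incoming = drive[t].copy()
        if fired_prev.any():
            incoming += model.W[fired_prev].sum(axis=0)
        P[~blocked] += incoming[~blocked]
        P[blocked] = lif.reset
        fired = (~blocked) & (P >= lif.theta_fire)
        P[fired] = lif.reset
        refr[blocked] -= 1
        refr[fired] = lif.refractory

        if learn and fired.any():
            _apply_stdp(model, fired, last_spike, t, dt_ms, stdp)
            np.clip(model.W, lo, hi, out=model.W)
            model.W[~model.conn] = 0.0

        fidx = np.flatnonzero(fired)
        if fidx.size:
            frames[t // frame_len].extend(fidx.tolist())
            counts[fired] += 1
            newly = fired & (first < 0)
            first[newly] = t
            last_spike[fired] = t
        fired_prev = fired

    traj = SnapshotTrajectory(frame_len=frame_len, n_steps=n_steps,
                              fired=[np.unique(np.array(f, dtype=int)) for f in frames])
    return EpochResult(trajectory=traj, spike_counts=counts,
                       first_spike_step=first, n_steps=n_steps)


def _apply_stdp(model: ReservoirModel, fired: np.ndarray, last_spike: np.ndarray,
                t: int, dt_ms: float, cfg: StdpConfig) -> None:
    """Nearest-spike STDP for all synapses touching this step's fires.

    Each spike pairs at most once per synapse side: a post fire pairs with
    the pre neuron's most recent spike only if that spike came after the
    post neuron's previous fire, and a pre fire pairs with the post
    neuron's most recent fire only if it came after the pre neuron's
    previous spike. Without this discipline a bursting presynaptic neuron
    would re-pair the same postsynaptic spike many times, and depression
    events would swamp the causal potentiation. ``last_spike`` holds fire
    times up to step t-1; a synapse whose pre and post both fire now is
    updated exactly once, via the post-side rule at dt = 0.
    """
    W, conn = model.W, model.conn
    has_spiked = last_spike >= 0
    # post-side fires (potentiation, dt <= 0): pair with the pre neuron's
    # most recent spike (including a simultaneous one) if it is fresher
    # than the post neuron's previous fire.
    pre_time = np.where(fired, t, last_spike)
    pre_ok = has_spiked | fired
    for j in np.flatnonzero(fired):
        rows = conn[:, j] & pre_ok & (pre_time > last_spike[j])
        if not rows.any():
            continue
        dt = (pre_time[rows] - t) * dt_ms          # <= 0
        f = np.where(dt < 0, cfg.a_plus * np.exp(dt / cfg.tau_plus_ms),
                     -cfg.a_minus * np.exp(-dt / cfg.tau_minus_ms))
        W[rows, j] += cfg.rate * f
    # pre-side fires (depression, dt > 0): pair with the post neuron's most
    # recent earlier fire if it is fresher than the pre neuron's previous
    # spike; simultaneous fires were handled above.
    for i in np.flatnonzero(fired):
        cols = conn[i, :] & has_spiked & ~fired & (last_spike > last_spike[i])
        if not cols.any():
            continue
        dt = (t - last_spike[cols]) * dt_ms        # > 0 -> depression branch
        W[i, cols] += cfg.rate * (-cfg.a_minus * np.exp(-dt / cfg.tau_minus_ms))


def train_unsupervised(model: ReservoirModel,
                       epochs: list[dict[str, SpikeSequence]], n_steps: int,
                       lif: LifConfig | None = None,
                       stdp: StdpConfig | None = None,
                       passes: int = 1, fs: float = 256.0) -> ReservoirModel:
    """Sequential STDP training over a list of encoded epochs, in place.

    Deterministic given the epoch order; ``passes=0`` leaves the model
    untouched.
    """
    if not epochs:
        raise ValueError("at least one epoch required")
    for _ in range(passes):
        for spk in epochs:
            run_epoch(model, spk, n_steps, lif=lif, stdp=stdp, learn=True, fs=fs)
    return model
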