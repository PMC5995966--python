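"""Dynamic evolving SNN (deSNN) output layer.

One output neuron is evolved per training sample, fully connected to the
reservoir. Its weights are initialised by the rank-order (RO) rule: the i-th
reservoir neuron's weight is mod^order(i) where order(i) is the rank of its
first spike within the sample (earlier spikes -> exponentially larger
weight, 0 < mod < 1); neurons that never spike start at 0. Each subsequent
spike of a neuron then raises its weight by ``drift``; with drift-decay
enabled the weight instead falls by ``drift`` on every silent step after the
first spike.

Classification offers two decision rules: ``weight_similarity`` (default)
builds a virtual output neuron from the test sample and assigns the class of
the nearest trained neuron in weight space; ``psp_spiking`` assigns the
class of the trained neuron with the largest rank-order potential
PSP(j) = sum_i mod^order(i) W_ij over the test sample's spiking neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reservoir_learning import EpochResult


@dataclass
class DesnnConfig:
    """deSNN parameters: rank-order base ``mod`` in (0,1), per-spike
    ``drift``, optional per-step drift decay, and the decision mode."""

    mod: float = 0.4
    drift: float = 0.005
    drift_decay: bool = False
    mode: str = "weight_similarity"

    def __post_init__(self) -> None:
        if not 0 < self.mod < 1:
            raise ValueError("mod must be in (0, 1)")
        if self.drift < 0:
            raise ValueError("drift must be >= 0")
        if self.mode not in ("weight_similarity", "psp_spiking"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class OutputNeuron:
    """One rank-order-trained output neuron."""

    label: str
    weights: np.ndarray               # (N,) one weight per reservoir neuron
    orders: np.ndarray                # (N,) first-spike rank, -1 if silent

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.orders = np.asarray(self.orders, dtype=int)
        if self.weights.shape != self.orders.shape:
            raise ValueError("weights and orders must align")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weight")


def spike_orders(record: EpochResult) -> np.ndarray:
    """Global first-spike ranks (0 = earliest) from a reservoir record.

    Ties in first-spike time are broken by neuron index; silent neurons get
    rank -1.
    """
    first = record.first_spike_step
    spiked = np.flatnonzero(first >= 0)
    orders = np.full(first.shape, -1, dtype=int)
    if spiked.size:
        # lexicographic (time, index) sort; spiked is already index-sorted
        ranked = spiked[np.argsort(first[spiked], kind="stable")]
        orders[ranked] = np.arange(ranked.size)
    return orders


def ro_train_output(record: EpochResult, cfg: DesnnConfig | None = None,
                    label: str = "") -> OutputNeuron:
    """Evolve one output neuron from a reservoir spike record."""
    cfg = cfg or DesnnConfig()
    orders = spike_orders(record)
    n = orders.size
    weights = np.zeros(n)
    spiked = orders >= 0
    weights[spiked] = cfg.mod ** orders[spiked].astype(float)
    # each spike after the first raises the weight by drift
    extra = np.clip(record.spike_counts - 1, 0, None)
    weights[spiked] += cfg.drift * extra[spiked]
    if cfg.drift_decay:
        # every silent step lowers the weight by drift: after the first
        # spike for spiking neurons, over the whole record for silent ones
        steps_after = record.n_steps - record.first_spike_step - 1
        silent = steps_after - extra
        weights[spiked] -= cfg.drift * silent[spiked]
        weights[~spiked] -= cfg.drift * record.n_steps
    return OutputNeuron(label=label, weights=weights, orders=orders)


def psp(output: OutputNeuron, test_orders: np.ndarray,
        cfg: DesnnConfig | None = None) -> float:
    """Rank-order potential of an output neuron for a test spike pattern."""
    cfg = cfg or DesnnConfig()
    test_orders = np.asarray(test_orders, dtype=int)
    spiked = test_orders >= 0
    if not spiked.any():
        return 0.0
    contrib = cfg.mod ** test_orders[spiked].astype(float)
    return float(np.sum(contrib * output.weights[spiked]))


def classify(outputs: list[OutputNeuron], test_record: EpochResult,
             cfg: DesnnConfig | None = None) -> tuple[str, dict[str, float]]:
    """Predict the class of a test sample.

    Returns ``(label, per_class_score)``. Scores are distances (smaller is
    better) in ``weight_similarity`` mode and potentials (larger is better)
    in ``psp_spiking`` mode, reduced per class over that class's output
    neurons. Ties go to the lowest-index output neuron.
    """
    cfg = cfg or DesnnConfig()
    if not outputs:
        raise ValueError("no trained output neurons")

    if cfg.mode == "weight_similarity":
        virtual = ro_train_output(test_record, cfg)
        dists = np.array([np.linalg.norm(o.weights - virtual.weights)
                          for o in outputs])
        best = int(np.argmin(dists))           # argmin takes the lowest index
        scores: dict[str, float] = {}
        for o, d in zip(outputs, dists):
            scores[o.label] = min(scores.get(o.label, np.inf), float(d))
        return outputs[best].label, scores
    else:
        test_orders = spike_orders(test_record)
        psps = np.array([psp(o, test_orders, cfg) for o in outputs])
        best = int(np.argmax(psps))
        scores = {}
        for o, p in zip(outputs, psps):
            scores[o.label] = max(scores.get(o.label, -np.inf), float(p))
        return outputs[best].label, scores


def layer_to_frame(outputs: list[OutputNeuron]) -> pd.DataFrame:
    """Serialize an output layer as a labelled weight-matrix table."""
    rows = {f"w{i}": [o.weights[i] for o in outputs]
            for i in range(outputs[0].weights.size)}
    df = pd.DataFrame(rows)
    df.insert(0, "label", [o.label for o in outputs])
    return df
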