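"""Shared test helpers: a slow reference LIF/STDP simulator and toy models."""

import numpy as np

from eegsnn.brain_space import NeuronAtlas, SynapseSet
from eegsnn.reservoir_learning import ReservoirModel
from eegsnn.spike_encoding import SpikeSequence

# Slow reference simulator: plain-python re-statement of the documented
# reservoir update order, used as an independent oracle on small instances.

def reference_run(W0, conn, drive, lif, stdp, learn, dt_ms):
    n = W0.shape[0]
    W = W0.copy()
    leak = np.exp(-dt_ms / lif.tau_leak_ms)
    P = [lif.reset] * n
    refr = [0] * n
    fired_prev = [False] * n
    last = [-1] * n
    fired_steps = []
    for t in range(drive.shape[0]):
        blocked = [refr[i] > 0 for i in range(n)]
        P = [p * leak for p in P]
        for i in range(n):
            if blocked[i]:
                P[i] = lif.reset
                continue
            inc = drive[t, i]
            for j in range(n):
                if fired_prev[j]:
                    inc += W[j, i]
            P[i] += inc
        fired = [not blocked[i] and P[i] >= lif.theta_fire for i in range(n)]
        for i in range(n):
            if fired[i]:
                P[i] = lif.reset
            if blocked[i]:
                refr[i] -= 1
        for i in range(n):
            if fired[i]:
                refr[i] = lif.refractory
        if learn and any(fired):
            for j in range(n):
                if not fired[j]:
                    continue
                for i in range(n):
                    if not conn[i, j]:
                        continue
                    pre_time = t if fired[i] else last[i]
                    if (last[i] >= 0 or fired[i]) and pre_time > last[j]:
                        dt = (pre_time - t) * dt_ms
                        if dt < 0:
                            f = stdp.a_plus * np.exp(dt / stdp.tau_plus_ms)
                        else:
                            f = -stdp.a_minus * np.exp(-dt / stdp.tau_minus_ms)
                        W[i, j] += stdp.rate * f
            for i in range(n):
                if not fired[i]:
                    continue
                for j in range(n):
                    if (conn[i, j] and last[j] >= 0 and not fired[j]
                            and last[j] > last[i]):
                        dt = (t - last[j]) * dt_ms
                        W[i, j] -= stdp.rate * stdp.a_minus * np.exp(
                            -dt / stdp.tau_minus_ms)
            W = np.clip(W, stdp.w_bounds[0], stdp.w_bounds[1])
            W[~conn] = 0.0
        for i in range(n):
            if fired[i]:
                last[i] = t
        fired_steps.append([i for i in range(n) if fired[i]])
        fired_prev = fired
    return W, fired_steps


def _toy_model(rng, n=12, n_inputs=3, p=0.3):
    coords = rng.uniform(-5, 5, (n, 3))
    atlas = NeuronAtlas(coords=coords, regions=np.array(["Frontal"] * n),
                        spacing=1.0,
                        input_map={f"ch{i}": i for i in range(n_inputs)})
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    pre, post = np.nonzero(mask)
    w = rng.uniform(-0.5, 1.0, pre.size)
    return ReservoirModel(atlas, SynapseSet(pre=pre, post=post, weight=w))


def _random_drive(rng, model, n_steps, rate=0.3):
    spikes = {}
    for ch in model.atlas.input_map:
        steps = np.flatnonzero(rng.random(n_steps) < rate)
        steps = steps[steps > 0]
        spikes[ch] = SpikeSequence(ch, times=steps,
                                   polarities=rng.choice([-1, 1], steps.size))
    return spikes


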