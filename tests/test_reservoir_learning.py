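"""LIF reservoir dynamics and STDP learning."""

import numpy as np
import pytest

from helpers import _random_drive, _toy_model, reference_run

from eegsnn.brain_space import NeuronAtlas, SynapseSet
from eegsnn.reservoir_learning import (LifConfig, ReservoirModel, StdpConfig,
                                       run_epoch, stdp_delta,
                                       train_unsupervised)
from eegsnn.spike_encoding import SpikeSequence


class TestStdpKernel:
    def test_boundary_dt_zero_takes_depression_branch(self):
        cfg = StdpConfig(rate=1.0, a_minus=0.7)
        assert stdp_delta(0.0, cfg) == pytest.approx(-0.7)

    def test_causal_pairing_at_minus_tau_gives_a_plus_over_e(self):
        cfg = StdpConfig(rate=1.0, a_plus=1.0, tau_plus_ms=10.0)
        assert stdp_delta(-10.0, cfg) == pytest.approx(np.exp(-1.0))

    def test_change_vanishes_at_large_lag(self):
        cfg = StdpConfig(rate=1.0)
        assert abs(stdp_delta(-500.0, cfg)) < 1e-20
        assert abs(stdp_delta(500.0, cfg)) < 1e-20

    @pytest.mark.parametrize("dt", [-30.0, -7.5, -0.1, 0.0, 0.1, 7.5, 30.0])
    def test_sign_antisymmetry(self, dt):
        cfg = StdpConfig(rate=0.01)
        d = stdp_delta(dt, cfg)
        assert (d > 0) == (dt < 0)

    def test_magnitude_monotone_decreasing_in_lag(self):
        cfg = StdpConfig(rate=0.01)
        lags = np.linspace(0.5, 40, 25)
        pos = [abs(stdp_delta(-l, cfg)) for l in lags]
        neg = [abs(stdp_delta(l, cfg)) for l in lags]
        assert all(a > b for a, b in zip(pos, pos[1:]))
        assert all(a > b for a, b in zip(neg, neg[1:]))


class TestReferenceEquivalence:
    @pytest.mark.parametrize("learn", [False, True])
    def test_step_for_step_agreement_on_random_instances(self, rng, learn):
        fs = 256.0
        lif = LifConfig(theta_fire=0.4, tau_leak_ms=15.0, refractory=1)
        stdp = StdpConfig(rate=0.05)
        for trial in range(8):
            model = _toy_model(rng, n=int(rng.integers(5, 20)))
            n_steps = 40
            spikes = _random_drive(rng, model, n_steps)
            drive = model.input_drive(spikes, n_steps)
            W_ref, fired_ref = reference_run(model.W, model.conn, drive, lif,
                                             stdp, learn, 1000.0 / fs)
            res = run_epoch(model, spikes, n_steps, lif=lif, stdp=stdp,
                            learn=learn, fs=fs, frame_ms=1000.0 / fs)
            got = [f.tolist() for f in res.trajectory.fired]
            assert got == fired_ref
            np.testing.assert_allclose(model.W, W_ref, atol=1e-12)


class TestDynamics:
    def test_zero_input_means_zero_fires_and_frozen_weights(self, small_model):
        W0 = small_model.W.copy()
        spikes = {ch: SpikeSequence(ch) for ch in small_model.atlas.input_map}
        res = run_epoch(small_model, spikes, 50, learn=True)
        assert res.spike_counts.sum() == 0
        assert np.array_equal(small_model.W, W0)

    def test_suprathreshold_synapse_relays_spike_next_step(self, rng):
        atlas = NeuronAtlas(coords=np.array([[0., 0, 0], [1., 0, 0]]),
                            regions=np.array(["Frontal"] * 2), spacing=1.0,
                            input_map={"Cz": 0})
        model = ReservoirModel(atlas, SynapseSet(pre=[0], post=[1],
                                                 weight=[0.6]))
        spikes = {"Cz": SpikeSequence("Cz", times=[3], polarities=[1])}
        res = run_epoch(model, spikes, 10, lif=LifConfig(theta_fire=0.5))
        assert res.first_spike_step[0] == 3       # input neuron fires on input
        assert res.first_spike_step[1] == 4       # one synaptic delay step

    def test_repeated_causal_pairing_strengthens_until_bound(self):
        atlas = NeuronAtlas(coords=np.array([[0., 0, 0], [1., 0, 0]]),
                            regions=np.array(["Frontal"] * 2), spacing=1.0,
                            input_map={"Cz": 0})
        model = ReservoirModel(atlas, SynapseSet(pre=[0], post=[1],
                                                 weight=[0.6]))
        stdp = StdpConfig(rate=0.2)
        # sparse drive: pre fires, post follows one step later, long gaps
        spikes = {"Cz": SpikeSequence("Cz", times=np.arange(2, 60, 6),
                                      polarities=np.ones(10, int))}
        history = []
        for _ in range(10):
            run_epoch(model, spikes, 60, stdp=stdp, learn=True)
            history.append(float(model.W[0, 1]))
        below = [w for w in history if w < stdp.w_bounds[1] - 1e-9]
        assert all(b > a for a, b in zip([0.6] + below, below))
        assert history[-1] <= stdp.w_bounds[1]

    def test_refractory_neuron_skips_steps(self):
        atlas = NeuronAtlas(coords=np.zeros((1, 3)),
                            regions=np.array(["Frontal"]), spacing=1.0,
                            input_map={"Cz": 0})
        model = ReservoirModel(atlas, SynapseSet(pre=np.empty(0, int),
                                                 post=np.empty(0, int),
                                                 weight=np.empty(0)))
        spikes = {"Cz": SpikeSequence("Cz", times=np.arange(1, 10),
                                      polarities=np.ones(9, int))}
        # frame_ms = one sample so frames are individual steps
        res = run_epoch(model, spikes, 10,
                        lif=LifConfig(theta_fire=0.5, refractory=2),
                        frame_ms=1000.0 / 256.0)
        fired_steps = [t for t, f in enumerate(res.trajectory.fired) if f.size]
        assert res.spike_counts[0] > 1
        assert all(b - a >= 3 for a, b in zip(fired_steps, fired_steps[1:]))

    def test_causality_no_path_no_fire(self, rng):
        # neuron 2 is unreachable from the input
        atlas = NeuronAtlas(coords=np.arange(9.0).reshape(3, 3),
                            regions=np.array(["Frontal"] * 3), spacing=1.0,
                            input_map={"Cz": 0})
        model = ReservoirModel(atlas, SynapseSet(pre=[0], post=[1],
                                                 weight=[1.0]))
        spikes = {"Cz": SpikeSequence("Cz", times=np.arange(1, 40),
                                      polarities=np.ones(39, int))}
        res = run_epoch(model, spikes, 40)
        assert res.spike_counts[2] == 0

    def test_weights_stay_within_bounds_under_learning(self, small_model):
        rng = np.random.default_rng(0)
        stdp = StdpConfig(rate=0.5, w_bounds=(-0.3, 0.3))
        for _ in range(3):
            spikes = _random_drive(rng, small_model, 50, rate=0.5)
            run_epoch(small_model, spikes, 50, stdp=stdp, learn=True)
        on_edges = small_model.W[small_model.conn]
        assert on_edges.min() >= -0.3 - 1e-12
        assert on_edges.max() <= 0.3 + 1e-12

    def test_spike_beyond_epoch_rejected(self, small_model):
        spikes = {"O1": SpikeSequence("O1", times=[60], polarities=[1])}
        with pytest.raises(IndexError):
            run_epoch(small_model, spikes, 50)

    def test_unmapped_channel_rejected(self, small_model):
        spikes = {"XX": SpikeSequence("XX", times=[1], polarities=[1])}
        with pytest.raises(KeyError):
            run_epoch(small_model, spikes, 50)


class TestTrainUnsupervised:
    def test_zero_passes_leaves_model_unchanged(self, small_model, rng):
        W0 = small_model.W.copy()
        spikes = [_random_drive(rng, small_model, 50)]
        train_unsupervised(small_model, spikes, 50, passes=0)
        assert np.array_equal(small_model.W, W0)

    def test_training_is_deterministic_given_order(self, coarse_atlas, rng):
        from eegsnn.brain_space import SmallWorldConfig, init_small_world
        epochs = None
        finals = []
        for _ in range(2):
            syn = init_small_world(coarse_atlas, SmallWorldConfig(seed=7))
            model = ReservoirModel(coarse_atlas, syn)
            r = np.random.default_rng(3)
            epochs = [_random_drive(r, model, 50, rate=0.4) for _ in range(4)]
            train_unsupervised(model, epochs, 50)
            finals.append(model.W.copy())
        assert np.array_equal(finals[0], finals[1])

    def test_driven_path_outgrows_reservoir_mean(self, coarse_atlas):
        """Feeding one channel a regular spike train strengthens the synapses
        out of its input neuron relative to the untouched reservoir."""
        from eegsnn.brain_space import SmallWorldConfig, init_small_world
        syn = init_small_world(coarse_atlas,
                               SmallWorldConfig(seed=1, w_init_max=0.2))
        model = ReservoirModel(coarse_atlas, syn)
        W0 = model.W.copy()
        drive = {ch: SpikeSequence(ch) for ch in coarse_atlas.input_map}
        t = np.arange(2, 51, 3)
        drive["O1"] = SpikeSequence("O1", times=t,
                                    polarities=np.ones(t.size, int))
        train_unsupervised(model, [drive] * 30, 51)
        nid = coarse_atlas.input_map["O1"]
        change = np.abs(model.W - W0)
        change_driven = change[nid][model.conn[nid]].mean()
        change_all = change[model.conn].mean()
        assert change_driven > 3 * change_all
        assert change_driven > 0.01
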