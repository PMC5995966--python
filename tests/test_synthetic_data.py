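"""Oddball schedule and ERP epoch generator."""

import numpy as np
import pandas as pd
import pytest

from eegsnn.containers import CHANNELS_1020
from eegsnn.synthetic_data import (ErpComponent, ErpTemplateSpec, ParadigmSpec,
                                   average_epochs, default_template,
                                   generate_dataset, generate_epochs,
                                   generate_schedule, pink_noise)


class TestSchedule:
    def test_default_paradigm_emits_140_stimuli_per_block(self):
        sched = generate_schedule(ParadigmSpec(), seed=0)
        per_block = sched.groupby("block").size()
        assert list(per_block) == [140, 140, 140]

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_event_counts_per_block_match_spec_exactly(self, seed):
        spec = ParadigmSpec()
        sched = generate_schedule(spec, seed)
        for _, block in sched.groupby("block"):
            counts = block["stimulus_id"].value_counts()
            assert counts["target"] == spec.target_reps
            non_targets = counts.drop("target")
            assert len(non_targets) == spec.n_nontarget_logos
            assert (non_targets == spec.nontarget_reps).all()
            assert (block["class"] == "familiar").sum() == 4 * 14
            assert (block["class"] == "unfamiliar").sum() == 4 * 14

    def test_single_stimulus_degenerate_block(self):
        spec = ParadigmSpec(n_nontarget_logos=0, target_reps=1, n_blocks=1)
        assert len(generate_schedule(spec, 0)) == 1

    def test_same_seed_gives_identical_schedule(self):
        a = generate_schedule(ParadigmSpec(), 5)
        b = generate_schedule(ParadigmSpec(), 5)
        pd.testing.assert_frame_equal(a, b)

    def test_onset_spacing_respects_isi_range(self):
        spec = ParadigmSpec()
        sched = generate_schedule(spec, 3)
        gaps = np.diff(sched["onset_ms"].to_numpy())
        lo = spec.stim_duration_ms + spec.isi_range_ms[0]
        hi = spec.stim_duration_ms + spec.isi_range_ms[1]
        assert (gaps >= lo).all() and (gaps <= hi).all()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ParadigmSpec(n_blocks=0)
        with pytest.raises(ValueError):
            ParadigmSpec(isi_range_ms=(1500.0, 1300.0))
        with pytest.raises(ValueError):
            ParadigmSpec(target_reps=0, n_nontarget_logos=0)


def _noiseless_template(seed=0):
    tpl = default_template(seed=seed)
    return ErpTemplateSpec(components=tpl.components, noise_sd=0.0,
                           white_sd=0.0, seed=seed)


class TestEpochs:
    def test_epoch_sample_count_from_window(self):
        sched = generate_schedule(ParadigmSpec(n_blocks=1), 0)
        rec = generate_epochs(default_template(), sched, fs=256.0,
                              window_ms=(0.0, 200.0))
        assert rec.data.shape == (19, 51, 140)  # round(0.2 * 256) = 51

    def test_noiseless_epochs_equal_class_template(self):
        sched = generate_schedule(ParadigmSpec(n_blocks=1), 1)
        rec = generate_epochs(_noiseless_template(), sched)
        fam = [i for i, l in enumerate(rec.labels) if l == "familiar"]
        unf = [i for i, l in enumerate(rec.labels) if l == "unfamiliar"]
        # all epochs of one class identical
        assert np.array_equal(rec.data[:, :, fam[0]], rec.data[:, :, fam[1]])
        # classes differ on posterior channels, where amplitudes differ
        o1 = rec.channels.index("O1")
        assert not np.allclose(rec.data[o1, :, fam[0]], rec.data[o1, :, unf[0]])

    def test_component_peak_at_specified_latency_sample(self):
        comp = ErpComponent("P100", 100.0, 10.0, {"familiar": {"O1": 5.0}})
        tpl = ErpTemplateSpec(components=[comp], noise_sd=0.0, white_sd=0.0)
        sched = pd.DataFrame({"onset_ms": [0.0], "stimulus_id": ["x"],
                              "block": [0], "class": ["familiar"]})
        rec = generate_epochs(tpl, sched, fs=256.0, window_ms=(0.0, 200.0))
        o1 = rec.channels.index("O1")
        peak = np.argmax(rec.data[o1, :, 0])
        assert peak == round(100.0 * 256 / 1000)  # sample nearest 100 ms

    def test_generation_is_bit_reproducible(self):
        sched = generate_schedule(ParadigmSpec(n_blocks=1), 2)
        a = generate_epochs(default_template(seed=9), sched)
        b = generate_epochs(default_template(seed=9), sched)
        assert np.array_equal(a.data, b.data)

    def test_unknown_channel_in_amplitude_map_rejected(self):
        comp = ErpComponent("P100", 100.0, 10.0, {"familiar": {"XX9": 5.0}})
        tpl = ErpTemplateSpec(components=[comp], noise_sd=0.0)
        sched = pd.DataFrame({"onset_ms": [0.0], "stimulus_id": ["x"],
                              "block": [0], "class": ["familiar"]})
        with pytest.raises(KeyError):
            generate_epochs(tpl, sched)

    def test_component_latency_outside_window_rejected(self):
        comp = ErpComponent("late", 300.0, 10.0, {"familiar": {"O1": 1.0}})
        tpl = ErpTemplateSpec(components=[comp], noise_sd=0.0)
        sched = pd.DataFrame({"onset_ms": [0.0], "stimulus_id": ["x"],
                              "block": [0], "class": ["familiar"]})
        with pytest.raises(ValueError):
            generate_epochs(tpl, sched, window_ms=(0.0, 200.0))

    def test_noise_has_near_zero_mean(self):
        comp = ErpComponent("null", 100.0, 10.0, {"familiar": {}})
        tpl = ErpTemplateSpec(components=[comp], noise_sd=1.0, white_sd=0.2,
                              seed=4)
        sched = pd.DataFrame({"onset_ms": np.zeros(200), "stimulus_id": "x",
                              "block": 0, "class": "familiar"})
        rec = generate_epochs(tpl, sched)
        assert abs(rec.data.mean()) < 0.05


class TestAveraging:
    def test_single_epoch_average_is_itself(self):
        sched = generate_schedule(ParadigmSpec(n_blocks=1, target_reps=1,
                                               n_nontarget_logos=0), 0)
        rec = generate_epochs(default_template(), sched)
        assert np.array_equal(average_epochs(rec, "target"), rec.data[:, :, 0])

    def test_noiseless_average_equals_template(self):
        sched = generate_schedule(ParadigmSpec(n_blocks=1), 0)
        rec = generate_epochs(_noiseless_template(), sched)
        fam = [i for i, l in enumerate(rec.labels) if l == "familiar"]
        assert np.allclose(average_epochs(rec, "familiar"),
                           rec.data[:, :, fam[0]])

    def test_average_converges_to_template_at_root_n_rate(self):
        """Monte-Carlo: with n=500 epochs the residual of the class average
        is within ~5 noise-sem of zero."""
        comp = ErpComponent("P100", 100.0, 10.0, {"familiar": {"O1": 5.0}})
        noiseless = ErpTemplateSpec(components=[comp], noise_sd=0.0,
                                    white_sd=0.0)
        noisy = ErpTemplateSpec(components=[comp], noise_sd=1.0, white_sd=0.5,
                                spatial_corr=0.0, seed=11)
        n = 500
        sched = pd.DataFrame({"onset_ms": np.zeros(n), "stimulus_id": "x",
                              "block": 0, "class": "familiar"})
        truth = generate_epochs(noiseless, sched.iloc[:1]).data[:, :, 0]
        avg = average_epochs(generate_epochs(noisy, sched), "familiar")
        total_sd = np.sqrt(1.0**2 + 0.5**2)
        assert np.max(np.abs(avg - truth)) < 5 * total_sd / np.sqrt(n)

    def test_missing_class_rejected(self):
        sched = generate_schedule(ParadigmSpec(n_blocks=1), 0)
        rec = generate_epochs(default_template(), sched)
        with pytest.raises(ValueError):
            average_epochs(rec, "nonexistent")


class TestDataset:
    def test_study_design_counts(self):
        rec = generate_dataset(n_participants=2, seed=0)
        assert rec.n_epochs == 2 * 3 * 2      # participants x blocks x classes
        assert rec.labels.count("familiar") == rec.labels.count("unfamiliar")
        assert rec.channels == list(CHANNELS_1020)
        assert rec.n_samples == 51

    def test_single_trial_mode(self):
        rec = generate_dataset(n_participants=1, mode="single_trial", seed=0)
        assert rec.n_epochs == 6


def test_pink_noise_spectrum_slopes_down(rng):
    x = pink_noise((4000,), 1.0, rng)
    p = np.abs(np.fft.rfft(x)) ** 2
    lo = p[1:20].mean()
    hi = p[-200:].mean()
    assert lo > 10 * hi
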