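"""Synthetic oddball-paradigm ERP generator.

Emulates a three-block visual oddball experiment: one target logo shown 28
times per block among 8 non-target logos (half locally familiar, half
unfamiliar) shown 14 times each, i.e. 140 stimuli per block, 200 ms stimulus
duration, 1300-1500 ms inter-stimulus interval.

Epochs are sums of Gaussian-bump ERP components (P100, N100, P200) whose
per-class differences follow the familiarity phenomenology: familiar
stimuli evoke larger posterior N100/P200 amplitudes, earlier component
latencies, and a faster posterior-to-anterior spread of activation, while
the unfamiliar response stays more restricted to posterior sites. Background
noise is spatially correlated 1/f ("pink") activity plus a little white
sensor noise -- the strong autocorrelation of real scalp EEG matters
downstream, because a delta-modulating spike encoder reacts to
sample-to-sample changes, not to absolute amplitude.

The generator exists so the whole downstream pipeline (encoding, reservoir
learning, classification) is testable end-to-end without any recorded EEG.
Its defaults are an explicitly high signal-to-noise regime (averaged
evoked responses, sub-microvolt residual noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .containers import CHANNELS_1020, EpochedRecording, normalize_channel, window_n_samples

TARGET = "target"
FAMILIAR = "familiar"
UNFAMILIAR = "unfamiliar"


@dataclass
class ParadigmSpec:
    """Oddball stimulus-schedule parameters.

    Defaults reproduce the three-block protocol: 28 target presentations and
    8 non-target logos x 14 presentations per block (140 stimuli/block),
    200 ms stimuli separated by a uniform 1300-1500 ms ISI.
    """

    n_blocks: int = 3
    target_reps: int = 28
    n_nontarget_logos: int = 8
    nontarget_reps: int = 14
    stim_duration_ms: float = 200.0
    isi_range_ms: tuple[float, float] = (1300.0, 1500.0)
    familiar_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_blocks <= 0 or self.target_reps < 0 or self.nontarget_reps < 0:
            raise ValueError("counts must be positive")
        if self.n_nontarget_logos < 0:
            raise ValueError("counts must be positive")
        if self.target_reps + self.n_nontarget_logos * self.nontarget_reps <= 0:
            raise ValueError("empty block: no stimuli at all")
        lo, hi = self.isi_range_ms
        if lo > hi or lo < 0:
            raise ValueError("isi_range_ms must satisfy 0 <= low <= high")
        if not 0.0 <= self.familiar_fraction <= 1.0:
            raise ValueError("familiar_fraction must be in [0, 1]")

    @property
    def stimuli_per_block(self) -> int:
        return self.target_reps + self.n_nontarget_logos * self.nontarget_reps

    @property
    def n_familiar_logos(self) -> int:
        return int(round(self.familiar_fraction * self.n_nontarget_logos))


@dataclass
class ErpComponent:
    """One Gaussian ERP component.

    ``latency_ms`` may be a single number or a per-class mapping;
    ``amplitudes`` maps class -> channel -> peak amplitude (microvolts);
    ``latency_offsets_ms`` optionally adds a per-class, per-channel latency
    shift (used to model propagation of the component across the scalp).
    The channel waveform is ``amp * exp(-(t - lat)^2 / (2 width^2))``.
    """

    name: str
    latency_ms: float | Mapping[str, float]
    width_ms: float
    amplitudes: Mapping[str, Mapping[str, float]]
    latency_offsets_ms: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError(f"component {self.name}: width must be positive")
        for chans in self.amplitudes.values():
            for amp in chans.values():
                if not np.isfinite(amp):
                    raise ValueError(f"component {self.name}: non-finite amplitude")

    def latency(self, cls: str) -> float:
        if isinstance(self.latency_ms, Mapping):
            return float(self.latency_ms[cls])
        return float(self.latency_ms)

    def offset(self, cls: str, channel: str) -> float:
        if self.latency_offsets_ms is None:
            return 0.0
        return float(self.latency_offsets_ms.get(cls, {}).get(channel, 0.0))


@dataclass
class ErpTemplateSpec:
    """Class-conditioned ERP template plus a noise model.

    Noise is ``noise_sd`` microvolts of 1/f^``pink_noise_exponent`` pink
    background (a fraction ``spatial_corr`` of it shared across channels,
    emulating volume conduction) plus ``white_sd`` microvolts of independent
    white sensor noise.
    """

    components: list[ErpComponent]
    noise_sd: float = 0.5
    pink_noise_exponent: float = 1.0
    white_sd: float = 0.1
    spatial_corr: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.white_sd < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if not 0.0 <= self.spatial_corr <= 1.0:
            raise ValueError("spatial_corr must be in [0, 1]")


# posterior-to-anterior scalp ordering used for the propagation sweep
_SWEEP_ORDER = ("O1", "O2", "Pz", "P3", "P4", "T5", "T6", "T3", "T4",
                "C3", "Cz", "C4", "F7", "F3", "Fz", "F4", "F8", "Fp1", "Fp2")

# spatial profile of the posterior-dominant components (volume-conducted)
_TOPOGRAPHY = {"O1": 1.0, "O2": 1.0, "P3": 0.8, "P4": 0.8, "Pz": 0.8,
               "T5": 0.6, "T6": 0.6, "C3": 0.45, "Cz": 0.45, "C4": 0.45,
               "T3": 0.45, "T4": 0.45, "F7": 0.35, "F3": 0.35, "Fz": 0.35,
               "F4": 0.35, "F8": 0.35, "Fp1": 0.35, "Fp2": 0.35}

# anterior attenuation of the unfamiliar response (activation restricted
# to posterior sites); familiar spreads at full gain
_ANTERIOR_ATTN_UNFAMILIAR = {
    **{c: 1.0 for c in ("O1", "O2", "P3", "P4", "Pz", "T5", "T6")},
    **{c: 0.6 for c in ("C3", "Cz", "C4", "T3", "T4")},
    **{c: 0.35 for c in ("F7", "F3", "Fz", "F4", "F8", "Fp1", "Fp2")},
}

# per-class propagation speed of the sweep, ms per scalp site
_SWEEP_MS_PER_SITE = {FAMILIAR: 2.0, UNFAMILIAR: 5.0, TARGET: 3.0}


def _sweep_offsets(cls: str) -> dict[str, float]:
    step = _SWEEP_MS_PER_SITE[cls]
    return {ch: step * i for i, ch in enumerate(_SWEEP_ORDER)}


def default_template(noise_sd: float = 0.5, seed: int = 0) -> ErpTemplateSpec:
    """The documented demo template (high-SNR familiarity contrast).

    Component parameters (peak amplitude on O1/O2 in microvolts; latency in
    ms at the occipital origin of the sweep):

    ==========  ================  ==================
    component   familiar          unfamiliar
    ==========  ================  ==================
    P100        +4.5 at 90 ms     +4.0 at 100 ms
    N100        -7.0 at 120 ms    -4.0 at 135 ms
    P200        +6.5 at 160 ms    +3.5 at 175 ms
    ==========  ================  ==================

    Familiar responses are larger, earlier, sweep anteriorly at 2 ms/site
    (vs 5 ms/site) and are not attenuated frontally. Magnitudes are free
    generator parameters chosen to emulate the reported effect directions;
    they are not measured values.
    """
    offsets = {cls: _sweep_offsets(cls) for cls in (FAMILIAR, UNFAMILIAR, TARGET)}

    def amps(fam: float, unf: float, tgt: float) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {FAMILIAR: {}, UNFAMILIAR: {}, TARGET: {}}
        for ch, w in _TOPOGRAPHY.items():
            out[FAMILIAR][ch] = fam * w
            out[UNFAMILIAR][ch] = unf * w * _ANTERIOR_ATTN_UNFAMILIAR[ch]
            out[TARGET][ch] = tgt * w
        return out

    comps = [
        ErpComponent("P100", {FAMILIAR: 90.0, UNFAMILIAR: 100.0, TARGET: 95.0},
                     12.0, amps(4.5, 4.0, 4.2), offsets),
        ErpComponent("N100", {FAMILIAR: 120.0, UNFAMILIAR: 135.0, TARGET: 128.0},
                     15.0, amps(-7.0, -4.0, -5.5), offsets),
        ErpComponent("P200", {FAMILIAR: 160.0, UNFAMILIAR: 175.0, TARGET: 168.0},
                     18.0, amps(6.5, 3.5, 5.0), offsets),
    ]
    return ErpTemplateSpec(components=comps, noise_sd=noise_sd, seed=seed)


def generate_schedule(spec: ParadigmSpec, seed: int) -> pd.DataFrame:
    """Draw a randomized stimulus schedule.

    Returns a table with columns ``onset_ms``, ``stimulus_id``, ``block`` and
    ``class`` (target / familiar / unfamiliar). Within each block the target
    appears exactly ``target_reps`` times and every non-target logo exactly
    ``nontarget_reps`` times, in a seeded random interleaving; onsets advance
    by stimulus duration plus a uniform ISI draw.
    """
    rng = np.random.default_rng(seed)
    n_fam = spec.n_familiar_logos
    stim_ids: list[str] = [TARGET] * spec.target_reps
    classes: list[str] = [TARGET] * spec.target_reps
    for k in range(spec.n_nontarget_logos):
        cls = FAMILIAR if k < n_fam else UNFAMILIAR
        idx = k + 1 if k < n_fam else k - n_fam + 1
        stim_ids += [f"{cls}_{idx}"] * spec.nontarget_reps
        classes += [cls] * spec.nontarget_reps

    rows = []
    t = 0.0
    lo, hi = spec.isi_range_ms
    for block in range(spec.n_blocks):
        order = rng.permutation(len(stim_ids))
        for i in order:
            rows.append((t, stim_ids[i], block, classes[i]))
            t += spec.stim_duration_ms + rng.uniform(lo, hi)
    return pd.DataFrame(rows, columns=["onset_ms", "stimulus_id", "block", "class"])


def pink_noise(shape: tuple[int, ...], exponent: float,
               rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise along the last axis, unit standard deviation."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    if exponent == 0 or n < 2:
        return white
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC offset
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _component_matrix(template: ErpTemplateSpec, cls: str, channels: list[str],
                      times_ms: np.ndarray, window_ms: tuple[float, float],
                      fs: float) -> np.ndarray:
    """Noiseless (channels x samples) waveform for one class.

    Per-channel latency offsets are clipped so a swept component peak never
    leaves the epoch window (it saturates two samples before the end).
    """
    out = np.zeros((len(channels), times_ms.size))
    ch_index = {c: i for i, c in enumerate(channels)}
    lat_max = window_ms[1] - 2 * 1000.0 / fs
    for comp in template.components:
        base = comp.latency(cls)
        for ch, amp in comp.amplitudes.get(cls, {}).items():
            ch = normalize_channel(ch)
            if ch not in ch_index:
                raise KeyError(f"amplitude map names channel {ch!r} "
                               "absent from the montage")
            lat = min(base + comp.offset(cls, ch), lat_max)
            out[ch_index[ch]] += amp * np.exp(
                -((times_ms - lat) ** 2) / (2 * comp.width_ms ** 2))
    return out


def generate_epochs(template: ErpTemplateSpec, schedule: pd.DataFrame,
                    montage: list[str] | None = None, fs: float = 256.0,
                    window_ms: tuple[float, float] = (0.0, 200.0)) -> EpochedRecording:
    """Simulate one stimulus-locked epoch per scheduled event.

    The epoch window is half-open [t0, t1) with ``round(len * fs / 1000)``
    samples. Every component's base latency must fall inside the window.
    """
    channels = [normalize_channel(c) for c in montage] if montage else list(CHANNELS_1020)
    t0, t1 = window_ms
    n = window_n_samples(window_ms, fs)
    times_ms = t0 + np.arange(n) * 1000.0 / fs
    labels = list(schedule["class"])
    classes = sorted(set(labels))
    for comp in template.components:
        for cls in classes:
            if not (t0 <= comp.latency(cls) < t1):
                raise ValueError(f"component {comp.name} latency "
                                 f"{comp.latency(cls)} ms outside window "
                                 f"[{t0}, {t1})")

    waveforms = {cls: _component_matrix(template, cls, channels, times_ms,
                                        window_ms, fs) for cls in classes}
    rng = np.random.default_rng(template.seed)
    n_ep = len(labels)
    n_ch = len(channels)
    data = np.empty((n_ch, n, n_ep))
    for e, cls in enumerate(labels):
        data[:, :, e] = waveforms[cls]
    if template.noise_sd > 0:
        g = template.spatial_corr
        shared = pink_noise((n_ep, n), template.pink_noise_exponent, rng)
        own = pink_noise((n_ch, n_ep, n), template.pink_noise_exponent, rng)
        pink = g * shared[None, :, :] + np.sqrt(1.0 - g * g) * own
        data += template.noise_sd * np.swapaxes(pink, 1, 2)
    if template.white_sd > 0:
        data += template.white_sd * rng.standard_normal(data.shape)
    return EpochedRecording(data=data, fs=fs, channels=channels, labels=labels)


def average_epochs(rec: EpochedRecording, cls: str) -> np.ndarray:
    """Mean (channels x samples) waveform over all epochs with label ``cls``."""
    if not rec.labels:
        raise ValueError("recording carries no class labels")
    idx = [i for i, lab in enumerate(rec.labels) if lab == cls]
    if not idx:
        raise ValueError(f"no epochs of class {cls!r}")
    return rec.data[:, :, idx].mean(axis=2)


def generate_dataset(n_participants: int = 20,
                     template: ErpTemplateSpec | None = None,
                     paradigm: ParadigmSpec | None = None,
                     fs: float = 256.0,
                     window_ms: tuple[float, float] = (0.0, 200.0),
                     mode: Literal["block_average", "single_trial"] = "block_average",
                     seed: int = 0) -> EpochedRecording:
    """Build a familiar-vs-unfamiliar classification set.

    Emulates the study design of 20 participants x 3 blocks x 2 classes =
    120 samples. ``block_average`` (default) averages each participant's
    non-target trials of one class within one block into one sample -- the
    natural reading of "three EEG samples per class per participant";
    ``single_trial`` instead picks one random trial per (participant, block,
    class) cell. Each participant gets an independent schedule and noise
    stream derived from ``seed``.
    """
    template = template if template is not None else default_template()
    paradigm = paradigm if paradigm is not None else ParadigmSpec()
    root = np.random.default_rng(seed)

    samples = []
    labels = []
    channels: list[str] | None = None
    for _ in range(n_participants):
        sched_seed, noise_seed = root.integers(0, 2**31 - 1, size=2)
        schedule = generate_schedule(paradigm, int(sched_seed))
        tpl = ErpTemplateSpec(components=template.components,
                              noise_sd=template.noise_sd,
                              pink_noise_exponent=template.pink_noise_exponent,
                              white_sd=template.white_sd,
                              spatial_corr=template.spatial_corr,
                              seed=int(noise_seed))
        rec = generate_epochs(tpl, schedule, fs=fs, window_ms=window_ms)
        channels = rec.channels
        for block in range(paradigm.n_blocks):
            in_block = schedule["block"].to_numpy() == block
            for cls in (FAMILIAR, UNFAMILIAR):
                idx = np.flatnonzero(in_block & (schedule["class"].to_numpy() == cls))
                if idx.size == 0:
                    continue
                if mode == "block_average":
                    samples.append(rec.data[:, :, idx].mean(axis=2))
                elif mode == "single_trial":
                    samples.append(rec.data[:, :, root.choice(idx)])
                else:
                    raise ValueError(f"unknown mode {mode!r}")
                labels.append(cls)
    data = np.stack(samples, axis=2)
    return EpochedRecording(data=data, fs=fs, channels=list(channels), labels=labels)
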