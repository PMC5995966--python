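# Methods

`eegsnn` models multichannel EEG as spatio-temporal spike patterns in a
three-dimensional spiking neural network and classifies the evoked activity
with a rank-order output layer. This note records the model, its parameters
and defaults, the design decisions taken where more than one reasonable
choice existed, and what the synthetic validation data can and cannot show.

## Pipeline overview

1. **Spike encoding** — each channel's time series becomes a bipolar spike
   train via threshold-based representation (TBR).
2. **Brain space** — neurons fill an ellipsoidal head volume on a regular
   lattice; the 19 electrodes of the 10–20 montage bind to nearest lattice
   neurons; initial synapses follow a distance-decaying small-world rule.
3. **Reservoir learning** — leaky integrate-and-fire (LIF) dynamics driven
   one EEG sample per step, with spike-time-dependent plasticity (STDP)
   adapting the weights during unsupervised training.
4. **Analytics** — mean connection weights (global and per input-channel
   cluster), per-channel spike intensity, activation categories, and stage
   trajectories summarise what the reservoir learned.
5. **Classification** — a dynamic evolving SNN (deSNN) output layer, one
   rank-order-initialised neuron per training sample, evaluated by
   leave-one-out cross-validation (LOOCV) with an optional exhaustive grid
   search over (STDP rate, firing threshold, `mod`).

## Spike encoding (TBR)

For a signal `S(t)` a baseline `V` starts at `S(1)`. At each sample, if
`S(t) >= V + θ` a `+1` spike fires and `V` steps up by `θ`; if
`S(t) <= V − θ` a `−1` spike fires and `V` steps down by `θ`; otherwise
nothing happens. Ties fire. Some published statements of this rule print the
negative branch with a `+θ`, which would make it overlap the positive
branch; the implementation uses the symmetric, mutually exclusive form.

Because at most one spike fires per sample, `V` can fall arbitrarily far
behind a signal whose steps repeatedly exceed `θ`; the tracked invariants
are therefore: lag `< θ` at spike-free samples, and lag `< 2θ` throughout
whenever all steps are `≤ θ`.

**Threshold default.** `θ = 1.0 ×` the standard deviation of the
first differences of the *whole recording, pooled over channels*
(`TbrConfig(per_channel=False, k=1.0)`). Two alternatives were rejected
after analysis:

- *Per-channel* thresholds make the encoder amplitude-scale-invariant per
  channel, which erases amplitude topography — and push the thresholds of
  low-signal channels down to their noise floor, so their random early
  crossings dominate the rank-order code downstream.
- *`k = 0.5`* places `θ` below the typical per-sample change of smooth
  averaged evoked responses, saturating the encoder (a spike nearly every
  sample) and flattening all between-condition differences.

Both alternatives remain available through `TbrConfig`.

## Brain space

Neurons occupy lattice points inside an ellipsoid with semi-axes
(7.5, 9, 6) grid units (right, anterior, superior). `resolution` is the
lattice spacing: 1.0 gives ≈1,700 neurons (the full model), 2.0 gives ≈220
(the standard analysis scale used for cross-validation). Electrode positions
come from the packaged standard 10–20 montage, are projected radially to
90 % of the ellipsoid surface, and bind to their nearest lattice neuron.
Region labels use a bundled nearest-centroid table over the eight coarse
lobes (Temporal, Parietal, Frontal, Sub-lobar, Cerebellar, Limbic,
Pituitary, Occipital), with multiple centroids per region to capture
laterality; a user-supplied table can replace it.

**Small-world wiring.** Candidate pairs lie within a Chebyshev radius of 2
lattice steps ("two neurons away in each direction"); each direction of a
candidate pair is wired independently with probability
`p0 · exp(−d/decay)`, `d` Euclidean in lattice steps. Defaults `p0 = 0.75`,
`decay = 2.0` give a mean in-degree of ≈30 for interior neurons
(`Σ_offsets p0·e^{−d/2} ≈ 29.8` over the 124 radius-2 offsets). Weight
magnitudes are Uniform(0, `w_init_max = 0.1`); signs are positive with
probability 0.8.

## Reservoir dynamics

One simulation step per EEG sample (≈3.9 ms at 256 Hz), in a fixed order:
leak (`P ← P·e^{−Δt/τ}`), integrate (external input spikes, signed by
polarity, plus last step's fires scaled by the weights — one synaptic delay
step), fire (`P ≥ θ_fire` → spike, reset to 0, refractory 1 step;
refractory neurons are clamped and receive nothing), then plasticity.

- `θ_fire = 0.5` — the value found optimal by the original grid search.
- `τ_leak = 40 ms`. This is deliberately slower than a textbook PSP decay:
  with initial weights ≤ 0.1 and threshold 0.5, a 10 ms leak makes it
  *impossible* for any non-input neuron ever to reach threshold (maximum
  sustained drive ≈ 0.16), so no postsynaptic spike ever occurs and STDP —
  which needs a spike pair — never engages. A 40 ms membrane constant lets
  input bursts summate (≈5.7× a single weight at steady state), so the
  best-connected neighbours of input neurons can ignite and plasticity can
  bootstrap.
- Negative input spikes hyperpolarise the mapped input neuron
  (`signed_input`, default); a `separate_line` mode that rectifies the
  polarity is available, since how inhibitory input events enter such
  models is usually left unstated.

**STDP.** `F(Δt) = A₊·e^{Δt/τ₊}` for `Δt < 0` and `−A₋·e^{−Δt/τ₋}` for
`Δt ≥ 0`, with `Δt = t_pre − t_post`, all scaled by the learning rate
(default 0.01, the grid-search optimum; `A₊ = A₋ = 1`,
`τ₊ = τ₋ = 10 ms`). Pairing is nearest-spike with a *pair-once*
discipline: a post fire pairs with the presynaptic neuron's most recent
spike only if that spike is fresher than the post neuron's previous fire,
and symmetrically for depression. Without this, a presynaptic burst
re-pairs the same postsynaptic spike on every one of its spikes, and the
accumulated depression swamps causal potentiation — in simulation this
froze or extinguished all weight growth. Weights clip to [−1, 1]; absent
edges never appear.

## Analytics

- `mean_weight` — signed mean over all edges, optionally restricted to
  `|w| >` a visualisation cut-off (0.08 is the conventional display
  threshold); an absolute-value mode reports mean `|w|`, appropriate when
  inhibitory links count as formed structure.
- A channel's *cluster* is its input neuron plus all pre- and post-synaptic
  partners. `cluster_mean_weight` averages the incident edge weights.
- *Spike intensity* of a cluster in a 50 ms frame is the fraction of its
  members that fired, in [0, 1]; categories are half-open bins
  inactive < 0.1 ≤ low < 0.4 ≤ medium < 0.7 ≤ strong ≤ 1 (the published
  level boundaries overlap at 0.4 and 0.7; each boundary is assigned to the
  upper bin).
- `stage_trajectory` orders channels by the first frame they reach at least
  "low" activation and tabulates per-frame active-neuron counts and
  categories — the numeric form of the snapshot-trajectory figures.

## deSNN classifier

For each training sample, one output neuron is evolved, fully connected to
the reservoir. At reservoir neuron `i`'s first spike its weight is set to
`mod^order(i)` (`order` = global rank of first spikes, ties by neuron
index; `mod = 0.4`, the grid-search optimum); each later spike adds
`drift = 0.005`. With `drift_decay` enabled, every silent step subtracts
`drift` instead (silent neurons decay from 0); this follows the original
description's "otherwise decrease" clause but is off by default so that
never-spiking neurons keep weight exactly 0.

Decision modes: `weight_similarity` (default) evolves a virtual output
neuron from the test sample and picks the class of the nearest trained
neuron in weight space; `psp_spiking` picks the neuron with maximal
rank-order potential `PSP(j) = Σ mod^order(i)·W_ij`. Both are computed on
every evaluation run and reported side by side; which decision rule the
original study used is not stated.

## Evaluation

LOOCV re-initialises the reservoir from a fixed seed each fold (folds
differ only in data), STDP-trains on the n−1 training samples in one pass,
evolves one output neuron per training sample, and classifies the holdout.
Metrics come from the pooled confusion matrix (rows = real,
columns = predicted; "familiar" is the positive class); undefined ratios
are NaN, not zero. Grid search evaluates every combination of the
three-parameter grid (10 evenly spaced values per parameter inclusive of
the bounds → 1,000 combinations by default) and selects the combination
that is best on the most folds, ties broken by mean accuracy then
lexicographic order — the historical protocol; for new studies a nested
selection (per-outer-fold) is the statistically safer construction and can
be built directly on `grid_search`.

## Synthetic data

The generator emulates the three-block visual oddball study: 28 target
presentations plus 8 non-target logos × 14 presentations per block
(140 stimuli/block, 200 ms duration, 1300–1500 ms ISI), 19 channels at
256 Hz, and a familiar/unfamiliar contrast carried by P100/N100/P200
Gaussian components. Default class differences, chosen once to emulate the
reported effect directions at high signal-to-noise:

| aspect | familiar | unfamiliar |
|---|---|---|
| P100 (O1/O2 peak, latency) | +4.5 µV, 90 ms | +4.0 µV, 100 ms |
| N100 | −7.0 µV, 120 ms | −4.0 µV, 135 ms |
| P200 | +6.5 µV, 160 ms | +3.5 µV, 175 ms |
| posterior→anterior sweep | 2 ms per scalp site | 5 ms per site |
| anterior gain | full | ×0.6 central, ×0.35 frontal |

The topography scales posterior components into central and frontal sites
(volume conduction); the faster sweep and unattenuated anterior spread of
the familiar response mirror the reported more rapid, more widespread
activation for familiar stimuli, and the earlier latencies reflect faster
peri-perceptual processing of familiar material. Noise is 0.5 µV of 1/f
pink background per single trial (60 % of it shared across channels) plus
0.1 µV white sensor noise. Classification samples are per-block averages of
≈14 single trials per class ("block_average"), emulating three samples per
class per participant; 20 participants give the 120-sample set. A
"single_trial" mode exists for the alternative reading.

**What this does and does not show.** The defaults are an explicitly
high-SNR regime: averaged responses with sub-microvolt residual noise,
deterministic component timing, no eye/muscle artifacts, no ongoing
oscillatory rhythms, no per-subject latency or topography variability, and
no realistic volume-conduction mixing. Passing the end-to-end tests shows
the pipeline transmits class information faithfully from waveform to
decision when that information is present — it says nothing about
single-trial, artifact-laden recordings, where real-data accuracy is far
below the near-perfect synthetic figures.

## Numerical conventions

- Epoch windows are half-open `[t0, t1)` with `round((t1−t0)·fs/1000)`
  samples; event extraction starts at `round((onset+t0)·fs/1000)`.
- Snapshot frames tile the epoch at `round(50·fs/1000)` steps.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; every run writes a manifest with the full
  configuration.
- Classification ties break to the lowest output-neuron index; rank ties to
  the lowest neuron id; grid ties as above.

## Validation problem sizes

The shipped test-suite and demo profiles use a ≈220-neuron reservoir
(lattice spacing 2.0) and 51-sample epochs for cross-validation runs, a
≈60-neuron reservoir for the 1,000-combination grid-search check, and the
full ≈1,700-neuron model for structural statistics (edge counts, sign
fractions). These sizes are the package's standard desk-scale profiles; all
are configuration, not constants.

## Known limitations

- Additive STDP with hard bounds is bistable by nature: depending on the
  coupling scale the reservoir is silent, balanced, or (with a
  potentiation-biased kernel) runs away. The defaults sit in the balanced
  regime; experiments that need visible pathway strengthening should raise
  `w_init_max` to ≈0.2, as the driven-pathway tests do.
- The deSNN rank code is sensitive to which neurons fire *first*; data whose
  earliest spikes are noise-driven will classify at chance regardless of
  later structure. The global-threshold encoder default exists precisely to
  keep early crossings signal-driven.
- The coarse parcellation is a centroid table, not a true atlas
  segmentation; region labels are approximate, especially near lobe
  boundaries.
- No EDF/BDF reader; recordings enter as delimited matrices or `.npz`
  containers.
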