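# eegsnn

Spatio-temporal modelling of multichannel EEG with a brain-template-mapped
spiking neural network (SNN) reservoir and a rank-order deSNN classifier.

EEG experiments that contrast conditions — here, the event-related response
to *familiar* versus *unfamiliar* visual stimuli in an oddball paradigm —
usually reduce each channel to a few component amplitudes and analyse them
independently. `eegsnn` instead treats the multichannel recording as one
spatio-temporal spike pattern: signals are delta-encoded into bipolar spike
trains, fed through spatially mapped input neurons into a 3D reservoir of
leaky integrate-and-fire neurons wired by a small-world rule, adapted by
spike-time-dependent plasticity (STDP), summarised through connectivity and
spike-intensity analytics, and classified by a dynamic evolving SNN (deSNN)
output layer evaluated with leave-one-out cross-validation (LOOCV). A
synthetic oddball-ERP generator makes the whole pipeline testable without
any recorded data.

Intended users: computational-neuroscience and EEG-methods researchers who
want a transparent, scriptable implementation of the reservoir-SNN
methodology for event-related potentials.

## The model in brief

- **Encoding (TBR).** With baseline `V(1)=S(1)`: a `+1` spike and `V ← V+θ`
  when `S(t) ≥ V+θ`; a `−1` spike and `V ← V−θ` when `S(t) ≤ V−θ`; else
  nothing.
- **Reservoir.** LIF neurons on a lattice inside a head-shaped ellipsoid,
  regions labelled from a coarse eight-lobe template; synapses exist only
  within a Chebyshev radius of 2 lattice steps, wired with probability
  `p0·e^{−d/decay}` and small random weights, 80 % excitatory.
- **Learning (STDP).** `F(Δt) = A₊e^{Δt/τ₊}` for `Δt<0`, `−A₋e^{−Δt/τ₋}`
  for `Δt≥0`, `Δt = t_pre − t_post`, scaled by a global learning rate
  (default 0.01), nearest-spike pairing, weights clipped to [−1, 1].
- **Classifier (deSNN).** One output neuron per training sample with
  rank-order initial weights `mod^order(i)` (default `mod = 0.4`) plus a
  per-spike drift; prediction by nearest weight vector (default) or maximal
  rank-order potential `PSP(j)=Σ mod^{order(i)}W_ij`.
- **Evaluation.** LOOCV with a fixed reservoir-initialisation seed across
  folds; optional exhaustive grid search over (STDP rate, firing threshold,
  `mod`), 10 values each → 1,000 combinations.

See `docs/methods.md` for assumptions, parameter rationale and limitations.

## Worked example

Simulate the emulated study (20 participants × 3 blocks × 2 classes = 120
block-averaged samples) and run the full LOOCV pipeline on a ≈220-neuron
reservoir:

```python
import eegsnn as E

rec = E.generate_dataset(n_participants=20, seed=1)   # 19 ch x 51 samples x 120
report = E.loocv(rec, E.PipelineConfig())
print(report.confusion)
print(report.metrics)
```

which prints

```
            familiar  unfamiliar
familiar          60           0
unfamiliar         0          60
{'accuracy': 100.0, 'f_score': 100.0, 'sensitivity': 100.0, 'specificity': 100.0}
```

Each row of the confusion matrix is a true class, each column a predicted
class; at the generator's default high signal-to-noise settings every one
of the 120 held-out samples is classified correctly (shuffling the labels
drops accuracy to chance, ≈50 %). On real single-trial EEG, accuracies are
far lower; the synthetic figures validate the plumbing, not clinical
performance.

The same pipeline is scriptable from the shell:

```bash
eegsnn simulate --seed 1 --out rec.npz
eegsnn evaluate --recording rec.npz --out-prefix results/demo
eegsnn analyze --recording rec.npz --label familiar --out-prefix results/fam
```

`evaluate` writes the confusion matrix, per-fold predictions, metrics under
both deSNN decision rules, and a JSON manifest of the full configuration;
`analyze` exports mean connection weights (with the conventional |w| > 0.08
display cut-off), per-channel cluster weights, spike-intensity categories
per 50 ms frame, and the stage-trajectory table.

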