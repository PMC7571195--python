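# spikevalence

Spiking-neural-network pipeline for classifying binary emotional **valence**
(pleasant vs unpleasant) from multimodal feature time series — ten facial
landmark-distance features plus six peripheral physiological features (heart
rate variability, respiration variability and depth, skin temperature, GSR,
pupil diameter).

It is aimed at affective-computing researchers who want a NeuCube-style
evolving-SNN classifier that runs end to end without any gated dataset: a
bundled synthetic generator emulates the structure of a stimulus-response
cohort (subjects × trials, binary labels, class effects concentrated in the
mouth-opening, mouth-length and pupil features) both as ready feature
matrices and as raw signals (ECG, respiration, temperature, GSR, pupil,
68-point facial landmarks) with ground-truth annotations.

## The model

1. **Feature extraction.** Facial distances f1–f10 from 68-point landmarks
   (baselined against the first 2 s of neutral face); ECG band-passed
   0.05–40 Hz and R-waves detected with Pan–Tompkins for the RR/HRV series;
   respiration cycles from peak/valley analysis; mean pupil diameter of both
   eyes with blink gaps interpolated. Every series is restricted to the last
   30 s of the trial, resampled to 64 samples, and first-sample subtracted,
   giving a 16×64 matrix per trial.
2. **Population spike encoding.** Each feature gets five input neurons whose
   receptive fields are the equal-count (quantile) partition of the pooled
   feature values. At each of the 64 samples exactly one neuron of the
   population spikes; zeros are interleaved, so each train is 129 steps and
   the raster is 80×129.
3. **Reservoir.** 11×11×7 = 847 leaky integrate-and-fire neurons on a 3D
   grid (spacing 10), input populations laid out as 16 lines of five on
   three layers. Small-world wiring within radius r = 25, initial weights
   u/d with exactly 80 % of recurrent edges excitatory; edges leaving input
   neurons are positive and doubled. LIF: threshold θ = 0.5, constant leak
   0.002 per step, refractory 1 step. Unsupervised training is nearest-spike
   STDP, Δw = sgn(Δt)·LR/(|Δt|+1) with LR = 0.001.
4. **deSNN readout.** One output neuron per sample over the frozen
   reservoir: rank-order initialisation w_i = α·mod^order(i) (α = 1,
   mod = 0.8), then ±drift (0.005) per step after each synapse's first
   spike.
5. **Classification & evaluation.** KNN (K = 3, Euclidean) on the
   output-neuron weight vectors, under leave-one-subject-out (LOSO)
   cross-validation, with feature-level fusion (all 16 features in one
   reservoir) or decision-level fusion (per subject, the single modality
   that classifies the training subjects better).

## Worked example

```python
import spikevalence as sv

cfg = sv.SynthConfig(n_subjects=4, trials_per_subject=8, effect_size=3.0, seed=42)
trials = sv.generate_dataset(cfg)
report = sv.loso_evaluate(trials, eval_params=sv.EvalParams(seed=42))
for s, r in report.per_subject.items():
    print(f"subject {s}: accuracy {r.accuracy:.1f}%  F1 {r.f1:.2f}  ({r.n_trials} trials)")
print(f"total: accuracy {report.total_accuracy:.2f}%  F1 {report.total_f1:.3f}")
```

prints

```
subject 0: accuracy 87.5%  F1 0.67  (8 trials)
subject 1: accuracy 75.0%  F1 0.75  (8 trials)
subject 2: accuracy 100.0%  F1 1.00  (8 trials)
subject 3: accuracy 100.0%  F1 1.00  (8 trials)
total: accuracy 90.62%  F1 0.857
```

Each subject's row is the accuracy/F1 of classifying that subject's trials
with a pipeline trained only on the other subjects; the total pools all
predictions. With `effect_size=0` the generator emits no class signal and
the same pipeline scores at chance.

The same pipeline is scriptable from the shell:

```sh
spikevalence simulate --seed 1 --n-subjects 6 --trials-per-subject 12 \
    --effect-size 3.0 --out features.csv
spikevalence loso --features features.csv --seed 1 --fusion feature --out report.csv
```

Other subcommands: `extract` (raw recordings → feature table), `encode`
(feature table → spike rasters), `train` (unsupervised STDP stage),
`clusters` (spike-communication cluster sizes per input neuron).

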