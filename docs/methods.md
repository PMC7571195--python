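# Methods

## Pipeline overview

The package classifies binary emotional valence from 16 multimodal feature
time series per trial (ten facial landmark distances, six peripheral
physiological features), each reduced to 64 samples over the last 30 s of
the stimulus response. The classifier is an evolving spiking neural network
of the NeuCube family: quantile population encoding → 3D LIF reservoir with
STDP → rank-order + drift (deSNN) readout → KNN, evaluated leave-one-
subject-out (LOSO). This note records the modelling assumptions, the
defaults and why, and what the synthetic experiments do and do not show.

## Feature extraction

* **Facial distances.** Landmarks follow the iBUG 68-point convention; the
  mapping is exposed in `features.LANDMARK_MAP` and configurable. f1/f2 are
  perpendicular distances from the outer-brow probes (18/25) to the line
  through the inner eye corners (39/42) — equal to the "vertical distance"
  reading for an upright face, and invariant under rigid transforms like
  every other feature (all are point-point or point-line distances).
  Frames with missing landmarks yield interpolated feature values.
* **Neutral baseline.** The mean of each facial series over the first 2 s
  is subtracted, assuming a neutral face at stimulus onset.
* **ECG.** Mean subtraction, then a 0.05–40 Hz band-pass built from two
  linear-phase stages: a 301-tap least-squares FIR low-pass (passband to
  40 Hz, stopband from 45 Hz, ≈120 dB at 50 Hz) applied as a centred
  convolution, and a high-pass realised as subtraction of a centred 10-s
  moving-average baseline (first notch at 0.1 Hz, −3 dB near 0.05 Hz).
  Both stages have zero net group delay, so R-peak times are not shifted.
  A very long FIR could realise the 0.05 Hz corner directly; the
  moving-average baseline was chosen for its benign edge behaviour on
  short trials.
* **R detection.** Pan–Tompkins: 5–15 Hz band-pass, five-point derivative,
  squaring, 150-ms moving-window integration, adaptive dual thresholds with
  search-back for long gaps; peak times refined to the band-passed local
  maximum. On the generator's ground truth this recovers RR intervals to
  ~1 ms mean absolute error at 60 and 75 bpm.
* **Respiration.** Peaks and valleys (prominence 20 % of range) on a copy
  low-passed at 2 Hz — breathing lives well below 1 Hz and the smoothing
  keeps sensor noise from biasing cycle amplitudes. Cycle duration is
  peak-to-peak time (the most common "time between cycles" convention);
  depth is peak minus preceding valley; both are placed at the cycle's peak
  time.
* **HRV enters as the raw RR-interval series** (one value per beat), not a
  windowed variability statistic: the per-beat series is itself a time
  series on the trial axis, which is what the encoder consumes.
  Temperature and GSR are used unfiltered.
* **Assembly.** Dense series are linearly interpolated onto the 64-point
  grid over the last 30 s; sparse event series (RR, respiration cycles) are
  step-interpolated first — holding the previous value invents no
  intermediate dynamics. The first sample is subtracted from every row, so
  column 0 is always zero.

## Spike encoding

Five input neurons per feature; the four range boundaries are equal-count
cuts of the pooled per-feature values (midpoints between the relevant order
statistics, so occupancies differ by at most one for distinct values). At
sample k exactly one neuron spikes, at time step 2k+1; zeros between
opportunities give trains of 2·64+1 = 129 steps, with step 0 silent so the
reservoir integrates from rest. A value equal to a boundary goes to the
lower range; values outside all boundaries go to the edge neurons; an
all-identical (degenerate) feature routes everything to the middle neuron.
Under LOSO the receptive fields are fitted on the training subjects only by
default; `pool_all` reproduces the legacy pooled-fit behaviour at the cost
of mild test-set leakage.

## Reservoir

847 neurons at grid spacing 10 (x, y ∈ [−50, 50], z ∈ [−30, 30]), which
makes the three input layers exact grid planes: five facial populations at
z = −30, five at z = +30, six peripheral at z = 0, each population a line
of five adjacent neurons (n1 lowest range … n5 highest) so that neighbours
code similar values.

Wiring: every pair within radius r = 25 is a candidate; connection
probability p(d) = p0 · spacing/d capped at 1 (the simplest monotone
decreasing rule); one random direction per connected pair; weight magnitude
u/d with u uniform on (0, 1]. Exactly round(80 %) of recurrent edges are
excitatory by stratified sign assignment — a testable identity rather than
a Bernoulli approximation. Edges whose presynaptic neuron is an input are
always positive with doubled weight ("input edges"; edges *into* input
neurons carry no consequence because input firing is forced from the
raster).

**Connection-probability default p0 = 0.30.** Under the inverse-distance
rule, p0 = 0.30 reproduces the edge count of the conventional uniform
small-world wiring (p = 0.15 for every pair within r) and leaves ≥95 % of
neurons reachable by spike traffic. At half that density the mean total
degree falls below 5, over half the reservoir never receives a spike, and
the communication-cluster analysis degenerates to near-singleton clusters;
classification accuracy is statistically indistinguishable between the two
densities, so the denser default costs nothing.

LIF dynamics (one synchronous step per encoder step): non-refractory
neurons leak a constant 0.002 (floored at 0), integrate arriving weighted
spikes, and fire at θ = 0.5, resetting to 0 with a 1-step refractory period
during which input is ignored ("refractory time 1" is read as one
simulation step — the simulation has no physical clock). Spikes travel one
connection per step with no per-edge delays. Input neurons fire exactly
their raster rows; their own membrane dynamics are bypassed.

STDP (during the unsupervised pass only; the readout pass is frozen):
nearest-spike pairing with Δw = sgn(Δt)·LR/(|Δt|+1), LR = 0.001,
sgn(0) = 0 so simultaneous spikes change nothing. Every update is bounded
by LR; weights are not clipped.

## deSNN readout

Per sample, after propagation through the frozen reservoir: rank-order
initialisation w_i = α·mod^rank(i) with ranks by ascending first-spike step
(ties broken by neuron index), α = 1, mod = 0.8; silent neurons stay at 0.
The drift clock starts at each synapse's initialising spike: +0.005 per
subsequent firing step, −0.005 per silent step, giving the closed-form
final weight α·mod^rank + drift·(fires − silences). `mod` appears as both
0.8 and 0.84 in common parameterisations of this readout; 0.8 is the
default here and 0.84 is reachable through the config.

## Classification and fusion

KNN with K = 3 and Euclidean distance on the output-neuron weight vectors.
Distance ties break by training order (stable sort); a tied vote falls to
the single nearest neighbour — with odd K and two classes the latter only
matters in degenerate metrics. Decision-level fusion estimates each
modality's accuracy by an internal LOSO over the training subjects
(resubstitution would be trivially near-perfect, since every training
sample owns an output neuron) and classifies the held-out subject with the
winner, ties to facial. Totals pool all predictions rather than averaging
per-subject rates.

## Synthetic data

`generate_dataset` emulates the structure of a stimulus-response affect
cohort: per-subject baseline offsets (SD 0.5), per-trial slow drift
(low-pass-filtered Gaussian random walks, unit SD), i.i.d. measurement
noise (SD 0.3), and a class effect on the mouth-opening (f9), mouth-length
(f10) and pupil rows of high-valence trials — `effect_size` scaled by a
half-sine template over the window, so the effect ramps in and out
smoothly. `generate_raw_trial` produces raw signals with ground truth:
PQRST-like ECG at a configurable heart rate with wander and noise, a
sinusoidal respiration signal, SCR-bumped GSR, drifting temperature, a
pupil series with class shift and blink gaps (NaN sentinel), and animated
synthetic 68-point landmarks.

The end-to-end experiments use a 6-subject × 12-trial cohort with
`effect_size = 3.0` — three times the trial-process SD, i.e. an
unambiguously large effect — which the pipeline classifies at 80–90 %
pooled LOSO accuracy depending on seed, falling to the binomial chance band
under label permutation. These sizes keep a full LOSO run (a fresh
847-neuron reservoir per fold, 129 steps per trial) around ten seconds.

What this does **not** show: the generator's smooth-drift processes are far
cleaner than real physiology (no artifacts, no missing channels, no
inter-subject differences in effect *direction*), so passing tests
demonstrate that the pipeline recovers the statistical structure it assumes
— not that it attains any particular accuracy on real recordings.

## Cluster analysis

After propagating one class's rasters through a trained reservoir
(plasticity off), each connection carries a transmitted-spike count. Every
neuron is assigned to the input neuron reachable along the directed path
maximising the minimum transmitted count (widest path, Dijkstra-style);
capacity ties go to the Euclidean-nearest input. Neurons with no
positive-traffic path remain unassigned, and each input always owns itself
— so with zero activity every cluster is exactly its own input neuron, and
in general assigned + unassigned partition the 847 neurons. Cluster sizes
are small integers (typically 1–25), so between-class comparisons on a
single input neuron are granular and can tie on particular wirings; the
direction (inputs coding high mouth-length/pupil values grow larger
clusters under high valence) is the robust signal.

## Numerical and degenerate-input choices

* All randomness flows from one integer seed through named substreams
  (simulate / reservoir / evaluation / permutation), so a change in one
  stage's consumption cannot perturb another.
* Equal-count cuts with heavy ties can produce non-ascending boundaries;
  the all-identical case is flagged degenerate and routed to the middle
  neuron, partial ties resolve through the same searchsorted path.
* Empty event series (no R peaks, fewer than two respiration peaks) warn
  and return empty; the full-trial extractor substitutes a constant-zero
  row rather than failing the trial.
* Feature tables are validated on read: missing feature rows, wrong sample
  counts and unknown labels are rejected naming the offending
  subject/trial/feature.

## Known limitations

* The synthetic landmark animation controls only the feature-relevant
  points precisely; the remaining face is plausible filler.
* Respiration "variability" is the raw cycle-duration series, not a
  dispersion statistic, mirroring the HRV choice.
* Decision fusion with fewer than three subjects cannot run its internal
  LOSO and falls back to the facial modality.
* The EEG modality, face detection/tracking and landmark localisation are
  out of scope: the pipeline consumes landmark coordinates and 1-D signals
  directly.
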