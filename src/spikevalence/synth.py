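"""Synthetic multimodal valence datasets.

Emulates the structure of a stimulus-response affect study: a cohort of
subjects each watching a number of clips, with a binary valence label per
trial, recorded through ECG, respiration, skin temperature, GSR, eye-tracker
pupil diameter and 68-point facial landmarks. Two entry points:

* :func:`generate_dataset` produces ready 16x64 feature matrices
  (``LabeledTrial``) with a class-dependent shift concentrated in the
  mouth-opening, mouth-length and pupil features — the features that carry
  the discriminative signal in real valence data.
* :func:`generate_raw_trial` produces raw signals plus ground-truth
  annotations (R-peak times, respiration cycles) so the feature extractors
  can be validated end to end.

The generator emulates slow physiological drift (low-pass filtered Gaussian
random walks), not the full richness of real recordings; see the methods note
for what that does and does not demonstrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ._rng import substream

__all__ = [
    "FEATURE_NAMES",
    "FACIAL_FEATURES",
    "PERIPHERAL_FEATURES",
    "SynthConfig",
    "LabeledTrial",
    "RawRecording",
    "generate_dataset",
    "generate_raw_trial",
    "temporal_template",
    "PUPIL_MISSING",
]

#: Canonical feature order used everywhere (rows of the 16x64 matrix,
#: raster blocks, reservoir input lines).
FACIAL_FEATURES = tuple(f"f{i}" for i in range(1, 11))
PERIPHERAL_FEATURES = (
    "hrv",
    "resp_variability",
    "resp_depth",
    "temperature",
    "gsr",
    "pupil",
)
FEATURE_NAMES = FACIAL_FEATURES + PERIPHERAL_FEATURES

#: Sentinel for missing pupil samples (eye closed). NaN keeps arithmetic
#: honest: any unhandled gap propagates loudly instead of biasing a mean.
PUPIL_MISSING = np.nan

N_FEATURES = 16
N_SAMPLES = 64

#: Row indices that receive the class effect (mouth opening f9, mouth length
#: f10, pupil diameter).
DISCRIMINATIVE_ROWS = (8, 9, 15)


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters for the synthetic cohort.

    ``trials_per_subject`` may be a single count or a per-subject sequence
    (real cohorts have uneven trial counts; ~14-17 per subject is typical).
    ``class_balance`` is the fraction of *low*-valence trials.
    """

    n_subjects: int = 27
    trials_per_subject: int | Sequence[int] = 14
    class_balance: float = 0.5307
    effect_size: float = 1.0
    noise_sd: float = 0.3
    fs_physio: float = 256.0
    fs_video: float = 60.0
    fs_gaze: float = 60.0
    trial_duration: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        counts = self.trial_counts()
        if min(counts) < 2:
            raise ValueError(
                f"trials_per_subject must be >= 2 everywhere, got min {min(counts)}"
            )
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError(
                f"class_balance must lie strictly in (0, 1), got {self.class_balance}"
            )
        if self.trial_duration < 32.0:
            raise ValueError(
                "trial_duration must be >= 32 s (30-s analysis window plus 2-s "
                f"neutral baseline), got {self.trial_duration}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for name in ("fs_physio", "fs_video", "fs_gaze"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def trial_counts(self) -> list[int]:
        if isinstance(self.trials_per_subject, (int, np.integer)):
            return [int(self.trials_per_subject)] * self.n_subjects
        counts = [int(c) for c in self.trials_per_subject]
        if len(counts) != self.n_subjects:
            raise ValueError(
                f"trials_per_subject sequence has {len(counts)} entries "
                f"for {self.n_subjects} subjects"
            )
        return counts


@dataclass
class LabeledTrial:
    """One stimulus response: a 16x64 feature matrix with a binary label."""

    subject_id: int
    trial_id: int
    label: str  # "low" | "high"
    features: np.ndarray  # (16, 64)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (N_FEATURES, N_SAMPLES):
            raise ValueError(
                f"features must be {N_FEATURES}x{N_SAMPLES}, "
                f"got {self.features.shape}"
            )
        if self.label not in ("low", "high"):
            raise ValueError(f"label must be 'low' or 'high', got {self.label!r}")


@dataclass
class RawRecording:
    """Raw multimodal signals for one trial, with generator ground truth."""

    label: str
    duration: float
    fs_physio: float
    fs_video: float
    fs_gaze: float
    ecg: np.ndarray            # mV @ fs_physio
    respiration: np.ndarray    # a.u. @ fs_physio
    temperature: np.ndarray    # degC @ fs_physio
    gsr: np.ndarray            # a.u. @ fs_physio
    pupil_left: np.ndarray     # mm @ fs_gaze, NaN while the eye is closed
    pupil_right: np.ndarray    # mm @ fs_gaze
    landmarks: np.ndarray      # (n_frames, 68, 2) pixels @ fs_video
    true_r_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_resp_cycles: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


def temporal_template(n: int = N_SAMPLES) -> np.ndarray:
    """Half-sine emotional-response envelope over the analysis window.

    Zero at both window ends, peaking mid-window: the class effect ramps in
    and out smoothly, giving the reservoir a temporal pattern to learn.
    """
    return np.sin(np.pi * np.arange(n) / (n - 1))


def _smooth_series(rng: np.random.Generator, n: int, sd: float = 1.0) -> np.ndarray:
    """Low-pass filtered Gaussian random walk: slow physiological drift."""
    walk = np.cumsum(rng.normal(0.0, 1.0, n))
    walk = gaussian_filter1d(walk, sigma=4.0, mode="nearest")
    walk -= walk.mean()
    scale = walk.std()
    if scale > 0:
        walk *= sd / scale
    return walk


def generate_dataset(config: SynthConfig) -> list[LabeledTrial]:
    """Generate the full labeled cohort as ready feature matrices.

    Each feature series is a smooth subject+trial random process, plus — on
    the mouth-opening (f9), mouth-length (f10) and pupil rows of
    high-valence trials — ``effect_size`` scaled by the half-sine temporal
    template, plus i.i.d. Gaussian noise. Deterministic given ``config.seed``.
    """
    rng = substream(config.seed, "simulate")
    template = temporal_template()
    trials: list[LabeledTrial] = []
    counts = config.trial_counts()
    for subject in range(config.n_subjects):
        # stable per-subject offsets: inter-individual baseline differences
        subject_offset = rng.normal(0.0, 0.5, N_FEATURES)
        for trial in range(counts[subject]):
            label = "low" if rng.random() < config.class_balance else "high"
            feats = np.empty((N_FEATURES, N_SAMPLES))
            for row in range(N_FEATURES):
                feats[row] = subject_offset[row] + _smooth_series(rng, N_SAMPLES)
            if label == "high":
                for row in DISCRIMINATIVE_ROWS:
                    feats[row] += config.effect_size * template
            feats += rng.normal(0.0, config.noise_sd, feats.shape)
            trials.append(LabeledTrial(subject, trial, label, feats))
    return trials


def _ecg_waveform(
    t: np.ndarray, r_times: np.ndarray, rr: float
) -> np.ndarray:
    """Sum of PQRST-like bumps centred on each R time."""
    ecg = np.zeros_like(t)

    def bump(center: np.ndarray, width: float, amp: float) -> None:
        for c in center:
            lo = np.searchsorted(t, c - 4 * width)
            hi = np.searchsorted(t, c + 4 * width)
            seg = t[lo:hi] - c
            ecg[lo:hi] += amp * np.exp(-0.5 * (seg / width) ** 2)

    bump(r_times, 0.012, 1.0)              # R spike
    bump(r_times - 0.035, 0.02, -0.12)     # Q
    bump(r_times + 0.04, 0.02, -0.1)       # S
    bump(r_times - 0.18 * rr, 0.03, 0.1)   # P
    bump(r_times + 0.30 * rr, 0.06, 0.22)  # T
    return ecg


def generate_raw_trial(
    label: str,
    config: SynthConfig,
    seed: int,
    heart_rate_bpm: float = 60.0,
    resp_rate_hz: float = 0.25,
    resp_amplitude: float = 1.0,
    blink_fraction: float = 0.04,
) -> RawRecording:
    """Generate raw signals for one trial with ground-truth annotations.

    ECG is a train of PQRST-like templates at ``heart_rate_bpm`` (small
    cycle-to-cycle jitter) riding on baseline wander; respiration is a
    sinusoid at ``resp_rate_hz``; the pupil series carries a class-dependent
    mean shift and blink gaps (NaN). Ground-truth R times and respiration
    cycles are returned alongside the signals.
    """
    if label not in ("low", "high"):
        raise ValueError(f"label must be 'low' or 'high', got {label!r}")
    dur = config.trial_duration
    if dur < 32.0:
        raise ValueError(f"trial_duration must be >= 32 s, got {dur}")
    rng = substream(seed, "raw-trial")

    n_physio = int(round(dur * config.fs_physio))
    t = np.arange(n_physio) / config.fs_physio

    # --- ECG ----------------------------------------------------------------
    rr = 60.0 / heart_rate_bpm
    r_times = [0.35]
    while r_times[-1] + rr < dur - 0.3:
        r_times.append(r_times[-1] + rr * (1.0 + rng.normal(0.0, 0.005)))
    r_times = np.asarray(r_times)
    ecg = _ecg_waveform(t, r_times, rr)
    # baseline wander (respiratory shifting) + mains-like noise + offset
    ecg += 0.15 * np.sin(2 * np.pi * resp_rate_hz * t + rng.uniform(0, 2 * np.pi))
    ecg += 0.02 * rng.normal(size=n_physio)
    ecg += 0.3  # electrode DC offset

    # --- respiration --------------------------------------------------------
    phase = rng.uniform(0, 2 * np.pi)
    respiration = resp_amplitude * np.sin(2 * np.pi * resp_rate_hz * t + phase)
    respiration += 0.01 * resp_amplitude * rng.normal(size=n_physio)
    # ground-truth peak times: sin peaks where the phase hits pi/2 (mod 2pi)
    first_peak = ((np.pi / 2 - phase) % (2 * np.pi)) / (2 * np.pi * resp_rate_hz)
    peak_times = np.arange(first_peak, dur, 1.0 / resp_rate_hz)
    true_resp_cycles = np.column_stack(
        [peak_times, np.full_like(peak_times, 2.0 * resp_amplitude)]
    )

    # --- temperature & GSR --------------------------------------------------
    temperature = 34.0 + 0.1 * _smooth_series(rng, n_physio)
    gsr = 5.0 + 0.5 * _smooth_series(rng, n_physio)
    # a few skin-conductance-response bumps
    for _ in range(rng.integers(2, 5)):
        onset = rng.uniform(2.0, dur - 5.0)
        tau_r, tau_d = 0.75, 2.0
        seg = t - onset
        scr = np.where(seg > 0, (1 - np.exp(-seg / tau_r)) * np.exp(-seg / tau_d), 0.0)
        gsr += rng.uniform(0.2, 0.6) * scr

    # --- pupil --------------------------------------------------------------
    n_gaze = int(round(dur * config.fs_gaze))
    t_gaze = np.arange(n_gaze) / config.fs_gaze
    base = 4.0 + (0.4 * config.effect_size if label == "high" else 0.0)
    pupil = base + 0.15 * _smooth_series(rng, n_gaze) + 0.02 * rng.normal(size=n_gaze)
    asym = 0.05 * rng.normal(size=n_gaze)
    pupil_left = pupil + asym
    pupil_right = pupil - asym
    if blink_fraction > 0:
        n_blinks = max(1, int(blink_fraction * dur / 0.2))
        for _ in range(n_blinks):
            start = rng.uniform(0.5, dur - 0.5)
            width = rng.uniform(0.1, 0.25)
            gap = (t_gaze >= start) & (t_gaze < start + width)
            pupil_left[gap] = PUPIL_MISSING
            pupil_right[gap] = PUPIL_MISSING

    # --- facial landmarks ---------------------------------------------------
    n_frames = int(round(dur * config.fs_video))
    t_vid = np.arange(n_frames) / config.fs_video
    window_start = dur - 30.0
    envelope = np.zeros(n_frames)
    in_win = t_vid >= window_start
    envelope[in_win] = np.sin(np.pi * (t_vid[in_win] - window_start) / 30.0)
    amp = 8.0 * config.effect_size if label == "high" else 0.0
    mouth_w = 60.0 + 2.0 * _smooth_series(rng, n_frames) + amp * envelope
    mouth_h = 10.0 + 1.0 * _smooth_series(rng, n_frames) + 0.5 * amp * envelope
    brow = 5.0 + 0.5 * _smooth_series(rng, n_frames)
    eye_open = 12.0 + 0.5 * _smooth_series(rng, n_frames)
    landmarks = np.empty((n_frames, 68, 2))
    for k in range(n_frames):
        landmarks[k] = synthetic_face(
            mouth_width=mouth_w[k],
            mouth_opening=mouth_h[k],
            brow_raise=brow[k],
            eye_opening=eye_open[k],
        )

    return RawRecording(
        label=label,
        duration=dur,
        fs_physio=config.fs_physio,
        fs_video=config.fs_video,
        fs_gaze=config.fs_gaze,
        ecg=ecg,
        respiration=respiration,
        temperature=temperature,
        gsr=gsr,
        pupil_left=pupil_left,
        pupil_right=pupil_right,
        landmarks=landmarks,
        true_r_times=r_times,
        true_resp_cycles=true_resp_cycles,
    )


def synthetic_face(
    mouth_width: float = 60.0,
    mouth_opening: float = 10.0,
    brow_raise: float = 5.0,
    eye_opening: float = 12.0,
    origin: tuple[float, float] = (300.0, 300.0),
) -> np.ndarray:
    """A bilaterally symmetric 68-point face in iBUG ordering.

    Only the landmarks the facial-distance features consume are controlled
    precisely; the rest (jaw, nose, remaining contour points) are plausible
    filler. Coordinates are pixels, y growing downward, face centred on
    ``origin`` with the inter-eye line at the origin's y.
    """
    ox, oy = origin
    pts = np.zeros((68, 2))

    # jaw 0..16: lower half-ellipse
    ang = np.linspace(np.pi, 2 * np.pi, 17)
    pts[0:17, 0] = ox + 70.0 * np.cos(ang)
    pts[0:17, 1] = oy + 20.0 - 110.0 * np.sin(ang)  # dips to oy+130 at chin

    e = eye_opening / 2.0
    # left eye 36..41 (36 outer corner, 39 inner corner)
    pts[36] = (ox - 45, oy)
    pts[37] = (ox - 39, oy - e)
    pts[38] = (ox - 33, oy - e)
    pts[39] = (ox - 27, oy)
    pts[40] = (ox - 33, oy + e)
    pts[41] = (ox - 39, oy + e)
    # right eye 42..47 (42 inner corner, 45 outer corner)
    pts[42] = (ox + 27, oy)
    pts[43] = (ox + 33, oy - e)
    pts[44] = (ox + 39, oy - e)
    pts[45] = (ox + 45, oy)
    pts[46] = (ox + 39, oy + e)
    pts[47] = (ox + 33, oy + e)

    # brows 17..21 and 22..26, raised above the eye line
    by = oy - 15.0 - brow_raise
    pts[17:22, 0] = ox + np.linspace(-52, -22, 5)
    pts[17:22, 1] = by + np.array([3.0, 0.0, -1.0, 0.0, 2.0])
    # spec'd brow probes are 18 and 25; pin them exactly at the raised height
    pts[18, 1] = by
    pts[22:27, 0] = ox + np.linspace(22, 52, 5)
    pts[22:27, 1] = by + np.array([2.0, 0.0, -1.0, 0.0, 3.0])
    pts[25, 1] = by

    # nose 27..35
    pts[27:31, 0] = ox
    pts[27:31, 1] = oy + np.linspace(5, 35, 4)
    pts[31:36, 0] = ox + np.linspace(-12, 12, 5)
    pts[31:36, 1] = oy + 42.0

    # mouth: centre line at oy + 70
    my = oy + 70.0
    w = mouth_width / 2.0
    h = mouth_opening / 2.0
    pts[48] = (ox - w, my)                       # left corner
    pts[54] = (ox + w, my)                       # right corner
    pts[49] = (ox - 0.6 * w, my - 0.9 * h)
    pts[50] = (ox - 0.3 * w, my - h)
    pts[51] = (ox, my - h)                       # upper-lip midpoint
    pts[52] = (ox + 0.3 * w, my - h)
    pts[53] = (ox + 0.6 * w, my - 0.9 * h)
    pts[55] = (ox + 0.6 * w, my + 0.9 * h)
    pts[56] = (ox + 0.3 * w, my + h)
    pts[57] = (ox, my + h)                       # lower-lip midpoint
    pts[58] = (ox - 0.3 * w, my + h)
    pts[59] = (ox - 0.6 * w, my + 0.9 * h)
    # inner lips 60..67
    pts[60] = (ox - 0.8 * w, my)
    pts[61] = (ox - 0.3 * w, my - 0.6 * h)
    pts[62] = (ox, my - 0.6 * h)
    pts[63] = (ox + 0.3 * w, my - 0.6 * h)
    pts[64] = (ox + 0.8 * w, my)
    pts[65] = (ox + 0.3 * w, my + 0.6 * h)
    pts[66] = (ox, my + 0.6 * h)
    pts[67] = (ox - 0.3 * w, my + 0.6 * h)
    return pts
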