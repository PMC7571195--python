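"""Multimodal feature extraction.

Turns raw recordings into the canonical 16x64 feature matrix:

* ten facial landmark-distance features f1..f10 (eyebrow heights over the
  inter-eye line, eyelid openings, lip-to-mouth-corner distances, lip gap,
  mouth length), baselined against the first 2 s of neutral face;
* six peripheral features — HRV (the RR-interval series from Pan-Tompkins
  R detection on band-passed ECG), respiration variability and depth from
  peak/valley analysis, raw skin temperature, raw GSR, and mean pupil
  diameter of both eyes;
* everything restricted to the last 30 s of the trial, resampled to 64
  samples, first sample subtracted.

Landmark indices follow the iBUG 68-point convention and are configurable
via :data:`LANDMARK_MAP`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .synth import FEATURE_NAMES, N_SAMPLES, RawRecording

__all__ = [
    "LANDMARK_MAP",
    "FacialFeatureSet",
    "PhysioFeatureSet",
    "extract_facial_features",
    "subtract_neutral_baseline",
    "design_ecg_filters",
    "preprocess_ecg",
    "detect_r_peaks",
    "extract_respiration_features",
    "extract_pupil",
    "assemble_feature_matrix",
    "extract_trial_features",
]

#: iBUG-68 landmark indices consumed by the facial distances. Override a copy
#: of this dict to adapt to a different landmark convention.
LANDMARK_MAP = {
    "inner_eye_corners": (39, 42),   # define the inter-eye line
    "outer_brows": (18, 25),         # f1, f2 probes
    "eyelid_left": (37, 41),         # f3
    "eyelid_right": (43, 47),        # f4
    "upper_lip": 51,                 # f5/f6 apex, f9 upper point
    "lower_lip": 57,                 # f7/f8 apex, f9 lower point
    "mouth_corners": (48, 54),       # f5..f8 anchors, f10
}

ANALYSIS_WINDOW = 30.0  # seconds, taken from the end of the trial
BASELINE_SECONDS = 2.0  # neutral-face reference at trial start


@dataclass
class FacialFeatureSet:
    """Ten distance series (pixels) sampled at the video frame rate."""

    data: np.ndarray  # (10, n_frames)
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 10:
            raise ValueError(f"expected (10, n_frames), got {self.data.shape}")


@dataclass
class PhysioFeatureSet:
    """Six peripheral feature series, each as (times, values).

    ``hrv``, ``resp_variability`` and ``resp_depth`` are sparse event series
    (one value per heart beat / respiration cycle); the rest are dense.
    """

    hrv: tuple[np.ndarray, np.ndarray]
    resp_variability: tuple[np.ndarray, np.ndarray]
    resp_depth: tuple[np.ndarray, np.ndarray]
    temperature: tuple[np.ndarray, np.ndarray]
    gsr: tuple[np.ndarray, np.ndarray]
    pupil: tuple[np.ndarray, np.ndarray]


def _point_line_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Perpendicular distance from point(s) p to the line through a and b.

    Frame-wise: p, a, b are (..., 2). Rigid-transform invariant, and equal to
    the vertical distance when the line is horizontal (upright face).
    """
    d = b - a
    norm = np.linalg.norm(d, axis=-1)
    cross = d[..., 0] * (p - a)[..., 1] - d[..., 1] * (p - a)[..., 0]
    return np.abs(cross) / norm


def extract_facial_features(
    landmarks: np.ndarray, fs: float, landmark_map: dict | None = None
) -> FacialFeatureSet:
    """Compute f1..f10 distance series from per-frame 68x2 landmarks.

    Frames containing NaN landmarks yield NaN features, linearly
    interpolated from neighbouring frames.
    """
    lm = np.asarray(landmarks, dtype=float)
    if lm.ndim != 3 or lm.shape[1:] != (68, 2):
        raise ValueError(f"landmarks must be (n_frames, 68, 2), got {lm.shape}")
    m = dict(LANDMARK_MAP if landmark_map is None else landmark_map)
    ie_l, ie_r = m["inner_eye_corners"]
    brow_l, brow_r = m["outer_brows"]
    lid_l, lid_r = m["eyelid_left"], m["eyelid_right"]
    ul, ll = m["upper_lip"], m["lower_lip"]
    mc_l, mc_r = m["mouth_corners"]

    def dist(i: int, j: int) -> np.ndarray:
        return np.linalg.norm(lm[:, i] - lm[:, j], axis=-1)

    feats = np.empty((10, lm.shape[0]))
    feats[0] = _point_line_distance(lm[:, brow_l], lm[:, ie_l], lm[:, ie_r])  # f1
    feats[1] = _point_line_distance(lm[:, brow_r], lm[:, ie_l], lm[:, ie_r])  # f2
    feats[2] = dist(*lid_l)          # f3 left eyelid opening
    feats[3] = dist(*lid_r)          # f4 right eyelid opening
    feats[4] = dist(ul, mc_l)        # f5 upper lip to left mouth corner
    feats[5] = dist(ul, mc_r)        # f6 upper lip to right mouth corner
    feats[6] = dist(ll, mc_l)        # f7 lower lip to left mouth corner
    feats[7] = dist(ll, mc_r)        # f8 lower lip to right mouth corner
    feats[8] = dist(ul, ll)          # f9 lip gap
    feats[9] = dist(mc_l, mc_r)      # f10 mouth length

    for row in feats:
        bad = ~np.isfinite(row)
        if bad.any():
            if bad.all():
                raise ValueError("all frames have missing landmarks")
            idx = np.arange(row.size)
            row[bad] = np.interp(idx[bad], idx[~bad], row[~bad])
    return FacialFeatureSet(feats, fs)


def subtract_neutral_baseline(
    features: FacialFeatureSet, fs: float | None = None
) -> FacialFeatureSet:
    """Subtract each series' mean over the first 2 s (assumed neutral face)."""
    fs = features.fs if fs is None else fs
    n0 = int(round(BASELINE_SECONDS * fs))
    if features.data.shape[1] < n0:
        raise ValueError(
            f"series of {features.data.shape[1]} frames is shorter than the "
            f"{BASELINE_SECONDS}-s baseline ({n0} frames at {fs} fps)"
        )
    baseline = features.data[:, :n0].mean(axis=1, keepdims=True)
    return FacialFeatureSet(features.data - baseline, fs)


def design_ecg_filters(fs: float, numtaps: int = 301) -> tuple[np.ndarray, int]:
    """Design the ECG band-pass pair: (low-pass FIR taps, high-pass window).

    Low-pass: least-squares linear-phase FIR, passband to 40 Hz, stopband
    from 45 Hz, stopband weighting sized for ~70 dB attenuation. High-pass:
    the 0.05 Hz corner is realised as subtraction of a centred moving-average
    baseline; the returned integer is that window length in samples.
    """
    if fs < 128:
        raise ValueError(f"sampling rate must be >= 128 Hz for the 40 Hz band, got {fs}")
    taps = signal.firls(
        numtaps, [0, 40, 45, fs / 2], [1, 1, 0, 0], weight=[1, 300], fs=fs
    )
    hp_window = int(round(10.0 * fs))  # 10-s boxcar ~ 0.05 Hz corner
    return taps, hp_window


def preprocess_ecg(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Mean-subtract and band-pass the ECG (0.05-40 Hz, zero net delay).

    Both stages are linear phase and applied centred, so R-peak times are
    not shifted.
    """
    x = np.asarray(ecg, dtype=float)
    taps, hp_window = design_ecg_filters(fs)
    x = x - x.mean()
    # high-pass: remove slow baseline (wander, respiration shifting)
    baseline = uniform_filter1d(x, size=min(hp_window, x.size), mode="reflect")
    x = x - baseline
    # low-pass: centred convolution with the symmetric FIR = zero group delay
    return signal.fftconvolve(x, taps, mode="same")


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins R-wave detection on a preprocessed ECG; times in seconds.

    Stages: 5-15 Hz band-pass, five-point derivative, squaring, 150-ms
    moving-window integration, adaptive dual thresholds with search-back for
    missed beats. R times are refined to the band-passed signal's local
    maximum near each integration peak.
    """
    x = np.asarray(ecg, dtype=float)
    if x.size < fs or np.ptp(x) == 0:
        warnings.warn("no R peaks found", stacklevel=2)
        return np.empty(0)
    sos = signal.butter(2, [5, 15], btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    deriv = np.convolve(bp, np.array([1, 2, 0, -2, -1]) * (fs / 8), mode="same")
    sq = deriv**2
    mwi = uniform_filter1d(sq, size=max(1, int(round(0.150 * fs))), mode="nearest")

    min_dist = int(round(0.2 * fs))  # physiological refractory
    cand, _ = signal.find_peaks(mwi, distance=min_dist)
    if cand.size == 0:
        warnings.warn("no R peaks found", stacklevel=2)
        return np.empty(0)

    spki = float(np.max(mwi[: int(2 * fs)])) * 0.5 if x.size >= 2 * fs else float(mwi[cand[0]])
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5
    peaks: list[int] = []
    rr_avg = None
    for c in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[c] > thr:
            # search-back: a long gap suggests a missed beat above thr/2
            if peaks and rr_avg is not None and (c - peaks[-1]) > 1.66 * rr_avg:
                seg = cand[(cand > peaks[-1] + min_dist) & (cand < c)]
                if seg.size:
                    back = seg[np.argmax(mwi[seg])]
                    if mwi[back] > thr / 2:
                        peaks.append(int(back))
                        spki = 0.25 * float(mwi[back]) + 0.75 * spki
            peaks.append(int(c))
            spki = 0.125 * float(mwi[c]) + 0.875 * spki
            if len(peaks) >= 2:
                recent = np.diff(peaks[-9:])
                rr_avg = float(np.mean(recent))
        else:
            npki = 0.125 * float(mwi[c]) + 0.875 * npki
    if not peaks:
        warnings.warn("no R peaks found", stacklevel=2)
        return np.empty(0)

    # refine each peak to the band-passed local maximum (MWI adds lag)
    half = int(round(0.10 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half)
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined = np.unique(refined)
    return refined / fs


def extract_respiration_features(
    resp: np.ndarray, fs: float
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Per-cycle respiration variability and depth via peak/valley detection.

    Variability = peak-to-peak duration (s), placed at the later peak's
    time; depth = peak amplitude minus the preceding valley, placed at the
    peak's time. Returns ((var_times, var), (depth_times, depth)).
    """
    x = np.asarray(resp, dtype=float)
    rng_ptp = np.ptp(x)
    empty = (np.empty(0), np.empty(0))
    if rng_ptp == 0:
        warnings.warn("no respiration cycles detected", stacklevel=2)
        return empty, empty
    # breathing lives well below 1 Hz; a gentle low-pass keeps sensor noise
    # from biasing peak/valley amplitudes
    if fs > 8:
        sos = signal.butter(2, 2.0, btype="lowpass", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, x)
        rng_ptp = np.ptp(x)
    prom = 0.2 * rng_ptp
    peaks, _ = signal.find_peaks(x, prominence=prom)
    valleys, _ = signal.find_peaks(-x, prominence=prom)
    if peaks.size < 2:
        warnings.warn("fewer than 2 respiration peaks detected", stacklevel=2)
        return empty, empty
    var_times = peaks[1:] / fs
    variability = np.diff(peaks) / fs
    depth_times, depths = [], []
    for p in peaks:
        prev = valleys[valleys < p]
        if prev.size:
            depth_times.append(p / fs)
            depths.append(x[p] - x[prev[-1]])
    return (var_times, variability), (np.asarray(depth_times), np.asarray(depths))


def extract_pupil(pupil_left: np.ndarray, pupil_right: np.ndarray) -> np.ndarray:
    """Samplewise mean pupil diameter of the available eyes; gaps interpolated.

    One eye missing -> the other eye's value; both missing -> linear
    interpolation across the gap (edges held at the nearest valid value).
    """
    left = np.asarray(pupil_left, dtype=float)
    right = np.asarray(pupil_right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left/right pupil series must have the same length")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN sample slices
        mean = np.nanmean(np.vstack([left, right]), axis=0)
    bad = ~np.isfinite(mean)
    if bad.all():
        raise ValueError("entire pupil series is missing")
    if bad.any():
        idx = np.arange(mean.size)
        mean[bad] = np.interp(idx[bad], idx[~bad], mean[~bad])
    return mean


def _resample_to_window(
    t: np.ndarray,
    v: np.ndarray,
    grid: np.ndarray,
    name: str,
    kind: str,
) -> np.ndarray:
    if v.size == 0:
        raise ValueError(f"series '{name}' has no samples in the trial")
    if kind == "linear":
        # allow one sample period of slack at the ends (last sample sits at
        # (n-1)/fs); np.interp holds edge values there
        slack = (t[-1] - t[0]) / max(t.size - 1, 1)
        if t[0] > grid[0] + slack or t[-1] < grid[-1] - slack:
            raise ValueError(
                f"series '{name}' (span {t[0]:.2f}-{t[-1]:.2f} s) does not cover "
                f"the analysis window {grid[0]:.2f}-{grid[-1]:.2f} s"
            )
        return np.interp(grid, t, v)
    # step interpolation for sparse event series: hold the previous value,
    # extrapolate flat on both sides (no invented intermediate dynamics)
    idx = np.clip(np.searchsorted(t, grid, side="right") - 1, 0, v.size - 1)
    return v[idx]


def assemble_feature_matrix(
    facial: FacialFeatureSet,
    physio: PhysioFeatureSet,
    trial_duration: float,
) -> np.ndarray:
    """Build the canonical 16x64 matrix over the last 30 s of the trial.

    Each series is restricted to the window, resampled to 64 uniformly
    spaced samples (linear interpolation for dense series, step
    interpolation for per-beat/per-cycle series), then its first sample is
    subtracted. Row order: f1..f10, hrv, resp_variability, resp_depth,
    temperature, gsr, pupil.
    """
    if trial_duration < ANALYSIS_WINDOW:
        raise ValueError(
            f"trial_duration {trial_duration} s shorter than the "
            f"{ANALYSIS_WINDOW}-s analysis window"
        )
    grid = np.linspace(trial_duration - ANALYSIS_WINDOW, trial_duration, N_SAMPLES)
    out = np.empty((16, N_SAMPLES))
    t_vid = np.arange(facial.data.shape[1]) / facial.fs
    for i in range(10):
        out[i] = _resample_to_window(
            t_vid, facial.data[i], grid, FEATURE_NAMES[i], "linear"
        )
    sparse = {"hrv", "resp_variability", "resp_depth"}
    for i, name in enumerate(FEATURE_NAMES[10:], start=10):
        t, v = getattr(physio, name)
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        kind = "step" if name in sparse else "linear"
        out[i] = _resample_to_window(t, v, grid, name, kind)
    out -= out[:, :1]
    return out


def extract_trial_features(raw: RawRecording) -> np.ndarray:
    """Full raw-recording -> 16x64 pipeline (facial + peripheral)."""
    facial = extract_facial_features(raw.landmarks, raw.fs_video)
    facial = subtract_neutral_baseline(facial)

    ecg = preprocess_ecg(raw.ecg, raw.fs_physio)
    r_times = detect_r_peaks(ecg, raw.fs_physio)
    if r_times.size >= 2:
        hrv = (r_times[1:], np.diff(r_times))
    else:
        hrv = (np.array([0.0]), np.array([0.0]))

    (var_t, var), (dep_t, dep) = extract_respiration_features(
        raw.respiration, raw.fs_physio
    )
    if var.size == 0:
        var_t, var = np.array([0.0]), np.array([0.0])
    if dep.size == 0:
        dep_t, dep = np.array([0.0]), np.array([0.0])

    t_physio = np.arange(raw.ecg.size) / raw.fs_physio
    pupil = extract_pupil(raw.pupil_left, raw.pupil_right)
    t_gaze = np.arange(pupil.size) / raw.fs_gaze
    physio = PhysioFeatureSet(
        hrv=hrv,
        resp_variability=(var_t, var),
        resp_depth=(dep_t, dep),
        temperature=(t_physio, raw.temperature),
        gsr=(t_physio, raw.gsr),
        pupil=(t_gaze, pupil),
    )
    return assemble_feature_matrix(facial, physio, raw.duration)
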