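"""Beat segmentation, fiducial-point detection, morphological features.

A denoised pulse signal is cut into beats at the onset troughs that
precede each systolic upstroke.  Within a beat, six landmarks are
located in their physiological order — diastolic point 1 (onset),
maximum-slope point, systolic peak, dicrotic notch, dicrotic peak,
diastolic point 2 (end-of-beat trough) — and eleven features are
derived from them:

heart rate (systolic-peak-to-peak interval), five amplitudes, the
maximum upstroke slope, the augmentation index (systolic/dicrotic
amplitude ratio), and the three time intervals T1 (onset→systolic),
T2 (systolic→dicrotic) and T3 (dicrotic→end).

Amplitude convention: the beat onset (diastolic point 1) is the
amplitude baseline; systolic, dicrotic, notch and end amplitudes are
reported as offsets from it, while the onset amplitude itself is kept
in raw signal units.  This makes the augmentation index invariant to
both the signal's offset and its overall scale.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "Beat",
    "FiducialPoints",
    "FeatureVector",
    "FEATURE_NAMES",
    "DegenerateBeatError",
    "RecordRejectedError",
    "segment_beats",
    "detect_fiducials",
    "compute_features",
    "featurize_recording",
]

FEATURE_NAMES = (
    "heart_rate_bpm",
    "systolic_peak_amp",
    "dicrotic_peak_amp",
    "dp1_amp",
    "dp2_amp",
    "notch_amp",
    "max_slope",
    "aug_index",
    "t1_s",
    "t2_s",
    "t3_s",
)

DEFAULT_HR_BOUNDS_BPM = (40.0, 180.0)


class DegenerateBeatError(ValueError):
    """Beat without a usable dicrotic complex (or otherwise malformed)."""


def _trough_smooth(x: np.ndarray, width: int = 9) -> np.ndarray:
    """Short Hann smoothing used only to localise onset troughs; all
    amplitudes and slopes are still read from the unsmoothed signal."""
    k = np.hanning(width)
    k /= k.sum()
    return np.convolve(x, k, mode="same")


class RecordRejectedError(ValueError):
    """Recording with fewer than the minimum number of analysable beats."""

    def __init__(self, reason: str, n_valid: int = 0):
        super().__init__(reason)
        self.reason = reason
        self.n_valid = n_valid


@dataclass
class Beat:
    """One beat cut from a parent signal at consecutive onset troughs."""

    onset_index: int
    samples: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.samples) < int(0.25 * self.sampling_rate_hz):
            raise ValueError("beat shorter than 0.25 s")

    @property
    def onset_time_s(self) -> float:
        return self.onset_index / self.sampling_rate_hz


@dataclass
class FiducialPoints:
    """Six landmarks of one beat; times are absolute (seconds from the
    start of the parent signal), amplitudes in raw signal units except
    ``max_slope_point`` whose second element is a slope (units/s)."""

    diastolic_point_1: tuple[float, float]
    max_slope_point: tuple[float, float]
    systolic_peak: tuple[float, float]
    dicrotic_notch: tuple[float, float]
    dicrotic_peak: tuple[float, float]
    diastolic_point_2: tuple[float, float]

    def __post_init__(self) -> None:
        times = [self.diastolic_point_1[0], self.max_slope_point[0],
                 self.systolic_peak[0], self.dicrotic_notch[0],
                 self.dicrotic_peak[0], self.diastolic_point_2[0]]
        if not np.all(np.diff(times) > 0):
            raise DegenerateBeatError(
                "fiducial times not strictly increasing: "
                f"{np.round(times, 4).tolist()}")
        # 1% slack admits ties (equal-height peaks sampled off-grid)
        span = abs(self.systolic_peak[1] - self.diastolic_point_1[1])
        tol = 0.01 * span
        if not (self.systolic_peak[1] + tol >= self.dicrotic_peak[1]
                >= self.dicrotic_notch[1] - tol):
            raise DegenerateBeatError(
                "amplitude ordering systolic >= dicrotic >= notch violated")


@dataclass
class FeatureVector:
    heart_rate_bpm: float
    systolic_peak_amp: float
    dicrotic_peak_amp: float
    dp1_amp: float
    dp2_amp: float
    notch_amp: float
    max_slope: float
    aug_index: float
    t1_s: float
    t2_s: float
    t3_s: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("feature vector contains non-finite values")
        if not 25 < self.heart_rate_bpm < 250:
            raise ValueError(
                f"heart rate {self.heart_rate_bpm:.1f} bpm outside (25, 250)")
        if min(self.t1_s, self.t2_s, self.t3_s) <= 0:
            raise ValueError("time intervals must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


def segment_beats(
    signal: np.ndarray,
    sampling_rate: float,
    hr_bounds_bpm: tuple[float, float] = DEFAULT_HR_BOUNDS_BPM,
) -> list[Beat]:
    """Cut a (denoised) signal into complete beats.

    Systolic peaks are detected first (minimum separation 60/hr_max s,
    prominence 25% of the robust signal range); each beat then runs
    from the trough before one peak to the trough before the next, so
    every beat contains exactly one systolic peak and partial first and
    last periods are discarded.  Returns an empty list when no beats
    are found.
    """
    x = np.asarray(signal, dtype=float)
    lo, hi = hr_bounds_bpm
    if not (25 < lo < hi < 250):
        raise ValueError("hr_bounds_bpm must lie within (25, 250)")
    if np.ptp(x) == 0:
        return []
    min_dist = max(1, int(round(sampling_rate * 60.0 / hi)))
    prom = 0.25 * float(np.percentile(x, 98) - np.percentile(x, 2))
    if prom <= 0:
        return []
    peaks, _ = find_peaks(x, distance=min_dist, prominence=prom)
    if len(peaks) < 2:
        return []
    # locate onset troughs on a lightly smoothed copy (residual in-band
    # noise makes a raw argmin wander over the shallow diastolic valley),
    # then pin the exact sample on the raw signal near the smoothed seed.
    # Only the last 45% of each peak-to-peak interval is searched: the
    # onset immediately precedes the upstroke, and a full-interval argmin
    # can be captured by a deep dicrotic notch under baseline tilt.
    xs = _trough_smooth(x)

    def _onset(w0: int, p2: int) -> int:
        seed = w0 + int(np.argmin(xs[w0:p2]))
        a = max(w0, seed - 4)
        b = min(p2, seed + 5)
        return a + int(np.argmin(x[a:b]))

    spacing = float(np.median(np.diff(peaks)))
    onsets = []
    first_w0 = peaks[0] - int(0.45 * spacing)
    if first_w0 >= 0:  # enough lead-in to place the first beat's onset
        onsets.append(_onset(first_w0, peaks[0]))
    for p1, p2 in zip(peaks[:-1], peaks[1:]):
        onsets.append(_onset(p1 + int(0.55 * (p2 - p1)), p2))
    onsets = np.array(onsets)
    max_len = sampling_rate * 60.0 / lo
    beats = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        if b - a > max_len:
            continue
        try:
            beats.append(Beat(int(a), x[a: b + 1], sampling_rate))
        except ValueError:
            continue
    return beats


def detect_fiducials(beat: Beat) -> FiducialPoints:
    """Locate the six landmarks within one beat.

    Raises :class:`DegenerateBeatError` when the beat lacks a usable
    dicrotic complex (monotone-rise-then-fall morphology) or violates
    the landmark ordering.
    """
    x = beat.samples
    fs = beat.sampling_rate_hz
    t0 = beat.onset_time_s
    n = len(x)

    prom = 0.25 * float(np.ptp(x))
    sys_candidates, _ = find_peaks(x, prominence=prom)
    if len(sys_candidates) == 0:
        raise DegenerateBeatError("no prominent systolic peak")
    sys_idx = int(sys_candidates[0])  # "first peak in the pulse waveform"

    dp1_idx = 0  # the segmentation trough is the beat onset
    if sys_idx <= dp1_idx + 1:
        raise DegenerateBeatError("systolic peak at beat onset")
    upstroke = np.diff(x[dp1_idx: sys_idx + 1])
    slope_rel = int(np.argmax(upstroke))
    slope_idx = dp1_idx + slope_rel
    max_slope = float(upstroke[slope_rel]) * fs

    # small prominence floor keeps residual-noise wiggles from being
    # mistaken for the notch or the dicrotic peak
    small = 0.05 * float(np.ptp(x))
    notch_candidates, _ = find_peaks(-x[sys_idx:], prominence=small)
    if len(notch_candidates) == 0:
        raise DegenerateBeatError("no dicrotic notch after systolic peak")
    notch_idx = sys_idx + int(notch_candidates[0])
    dic_candidates, _ = find_peaks(x[notch_idx:], prominence=small)
    if len(dic_candidates) == 0:
        raise DegenerateBeatError("no dicrotic peak after notch")
    dic_idx = notch_idx + int(dic_candidates[0])
    dp2_idx = n - 1
    if dic_idx >= dp2_idx:
        raise DegenerateBeatError("dicrotic peak at beat end")

    def point(i: int) -> tuple[float, float]:
        return (t0 + i / fs, float(x[i]))

    return FiducialPoints(
        diastolic_point_1=point(dp1_idx),
        max_slope_point=(t0 + slope_idx / fs, max_slope),
        systolic_peak=point(sys_idx),
        dicrotic_notch=point(notch_idx),
        dicrotic_peak=point(dic_idx),
        diastolic_point_2=point(dp2_idx),
    )


def compute_features(
    fiducials: FiducialPoints,
    prev_systolic_time: float,
    sampling_rate: float,
    ai_convention: str = "systolic_over_dicrotic",
) -> FeatureVector:
    """Turn one beat's landmarks into the eleven-feature vector.

    Heart rate is 60 over the systolic-peak-to-peak interval with the
    previous beat.  Amplitudes (systolic, dicrotic, notch, end) are
    offsets from the onset amplitude; the augmentation index is the
    ratio of the systolic and dicrotic offsets (direction switchable via
    ``ai_convention``: ``"systolic_over_dicrotic"`` or
    ``"dicrotic_over_systolic"``).
    """
    f = fiducials
    sys_t, sys_a = f.systolic_peak
    if not prev_systolic_time < sys_t:
        raise ValueError("prev_systolic_time must precede this beat's peak")
    hr = 60.0 / (sys_t - prev_systolic_time)

    base = f.diastolic_point_1[1]
    sys_rel = sys_a - base
    dic_rel = f.dicrotic_peak[1] - base
    notch_rel = f.dicrotic_notch[1] - base
    dp2_rel = f.diastolic_point_2[1] - base
    if dic_rel <= 0:
        raise DegenerateBeatError(
            "dicrotic amplitude non-positive after baseline shift; "
            "augmentation index undefined")
    if ai_convention == "systolic_over_dicrotic":
        ai = sys_rel / dic_rel
    elif ai_convention == "dicrotic_over_systolic":
        ai = dic_rel / sys_rel
    else:
        raise ValueError(f"unknown ai_convention {ai_convention!r}")

    return FeatureVector(
        heart_rate_bpm=hr,
        systolic_peak_amp=sys_rel,
        dicrotic_peak_amp=dic_rel,
        dp1_amp=base,
        dp2_amp=dp2_rel,
        notch_amp=notch_rel,
        max_slope=f.max_slope_point[1],
        aug_index=ai,
        t1_s=sys_t - f.diastolic_point_1[0],
        t2_s=f.dicrotic_peak[0] - sys_t,
        t3_s=f.diastolic_point_2[0] - f.dicrotic_peak[0],
    )


def featurize_recording(
    signal: np.ndarray,
    sampling_rate: float,
    hr_bounds_bpm: tuple[float, float] = DEFAULT_HR_BOUNDS_BPM,
    ai_convention: str = "systolic_over_dicrotic",
    min_beats: int = 3,
) -> tuple[FeatureVector, int]:
    """Per-record feature vector: componentwise median over valid beats.

    Degenerate beats are skipped.  The first beat has no preceding
    systolic peak, so its heart rate is filled with the record median.
    Raises :class:`RecordRejectedError` with a diagnostic when fewer
    than ``min_beats`` beats survive.
    """
    beats = segment_beats(signal, sampling_rate, hr_bounds_bpm)
    if len(beats) < min_beats:
        raise RecordRejectedError(
            f"only {len(beats)} beats segmented (need {min_beats})",
            n_valid=len(beats))

    fids: list[FiducialPoints] = []
    for beat in beats:
        try:
            fids.append(detect_fiducials(beat))
        except DegenerateBeatError:
            continue
    if len(fids) < min_beats:
        raise RecordRejectedError(
            f"only {len(fids)} beats with valid fiducials "
            f"(need {min_beats})", n_valid=len(fids))

    sys_times = np.array([f.systolic_peak[0] for f in fids])
    intervals = np.diff(sys_times)
    intervals = intervals[intervals > 0]
    if len(intervals) == 0:
        raise RecordRejectedError("no usable peak-to-peak intervals")
    median_interval = float(np.median(intervals))

    vectors = []
    for i, f in enumerate(fids):
        prev_t = (sys_times[i - 1] if i > 0
                  else sys_times[0] - median_interval)
        try:
            vectors.append(compute_features(
                f, prev_t, sampling_rate, ai_convention).as_array())
        except (DegenerateBeatError, ValueError):
            continue
    if len(vectors) < min_beats:
        raise RecordRejectedError(
            f"only {len(vectors)} beats with valid features "
            f"(need {min_beats})", n_valid=len(vectors))
    median_vec = np.median(np.asarray(vectors), axis=0)
    fv = FeatureVector(**dict(zip(FEATURE_NAMES, median_vec)))
    return fv, len(vectors)
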