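"""Synthetic tonometric pulse-wave corpus with known ground truth.

Emulates a measurement campaign in which a 3-element pressure-sensing
array is worn over the radial artery while a cuff sphygmomanometer
provides per-recording reference SBP/DBP.  Only one array element sits
well over the artery: it carries the clean pulse at full gain while its
neighbours see an attenuated copy.  All channels share additive baseline
wander (respiration/movement drift), white sensor noise, and occasional
motion-artifact transients.

Each beat is built from two Gaussian bumps (systolic and dicrotic) on a
diastolic baseline, which reproduces the canonical radial morphology:
onset (diastolic point 1), steep upstroke with a maximum-slope point,
systolic peak, dicrotic notch, dicrotic peak, decay to the next onset
(diastolic point 2).

Blood pressure drives beat morphology through an explicit monotone map
(:func:`beat_params_from_bp`): SBP sets the systolic amplitude (and
hence the upstroke slope) and, via pulse pressure, the time-to-peak;
DBP sets the dicrotic-to-systolic amplitude ratio, the dicrotic timing
and the onset baseline.  The map is invented but monotone and smooth,
so that feature-based regression can in principle recover BP exactly —
which is what makes the downstream stages testable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from pulsebp.records import WaveformRecording

__all__ = [
    "SimulationConfig",
    "BeatTemplateParams",
    "GroundTruth",
    "beat_params_from_bp",
    "generate_beat_template",
    "generate_recording",
    "generate_dataset",
]

#: order of the six fiducial landmarks within one beat
LANDMARKS = ("dp1", "max_slope", "systolic", "notch", "dicrotic", "dp2")


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic corpus.

    Defaults reproduce the measurement campaign scale: 23 participants,
    49 recordings each (~1128 records), SBP drawn in 98–138 mmHg and
    DBP in 58–81 mmHg, a 3-channel array with one well-aligned element.
    """

    n_subjects: int = 23
    records_per_subject: int = 49
    duration_s: float = 10.0
    sampling_rate_hz: float = 250.0
    hr_range_bpm: tuple[float, float] = (55.0, 85.0)
    sbp_range_mmHg: tuple[float, float] = (98.0, 138.0)
    dbp_range_mmHg: tuple[float, float] = (58.0, 81.0)
    noise_sd: float = 0.05          # white-noise SD, fraction of systolic amplitude
    baseline_amp: float = 0.2       # wander amplitude, fraction of systolic amplitude
    baseline_freq_hz: float = 0.1
    artifact_prob: float = 0.02     # per-beat probability of a motion transient
    channel_gains: tuple[float, ...] = (0.35, 1.0, 0.45)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.records_per_subject < 1:
            raise ValueError("n_subjects and records_per_subject must be >= 1")
        if not self.sampling_rate_hz >= 100:
            raise ValueError("sampling_rate_hz must be >= 100 Hz")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("hr_range_bpm", "sbp_range_mmHg", "dbp_range_mmHg"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy low < high")
        if self.sbp_range_mmHg[0] <= self.dbp_range_mmHg[1]:
            raise ValueError("SBP range must lie entirely above DBP range")
        for name in ("noise_sd", "baseline_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.artifact_prob <= 1:
            raise ValueError("artifact_prob must be a probability")
        gains = np.asarray(self.channel_gains, dtype=float)
        if gains.size < 1 or np.any(gains < 0) or np.any(gains > 1):
            raise ValueError("channel_gains must lie in [0, 1]")
        if np.sum(gains == gains.max()) != 1:
            raise ValueError("exactly one channel gain must equal the maximum "
                             "(the aligned channel)")

    @property
    def aligned_channel(self) -> int:
        return int(np.argmax(self.channel_gains))


@dataclass
class BeatTemplateParams:
    """Analytic parameters of one beat: two Gaussian bumps on a baseline.

    ``notch_time_s`` is the nominal (validation) notch location between
    the bumps; the ground-truth notch is always re-derived numerically
    from the sampled template.
    """

    systolic_time_s: float
    systolic_amp: float
    dicrotic_time_s: float
    dicrotic_amp: float
    notch_time_s: float
    beat_period_s: float
    onset_amp: float = 0.0
    systolic_width_s: float = 0.045  # Gaussian sigma of the systolic bump
    dicrotic_width_s: float = 0.065  # Gaussian sigma of the dicrotic bump
    # height of the late-diastolic run-off at the dicrotic complex.  The
    # run-off declines towards the beat end and finishes as the exact
    # time-mirror of the systolic foot, so the inter-beat trough is a
    # symmetric V at every scale (an asymmetric trough would bias any
    # minimum-based onset estimate once the signal is band-limited).
    runoff_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.beat_period_s <= 0:
            raise ValueError("beat_period_s must be positive")
        if not (0 < self.systolic_time_s < self.notch_time_s
                < self.dicrotic_time_s < self.beat_period_s):
            raise ValueError(
                "times must satisfy 0 < systolic < notch < dicrotic < period")
        if self.dicrotic_amp < 0:
            raise ValueError("dicrotic_amp must be >= 0")
        if not self.systolic_amp > self.dicrotic_amp:
            raise ValueError("systolic_amp must exceed dicrotic_amp")
        if not self.dicrotic_amp >= 0 or self.systolic_amp <= 0:
            raise ValueError("amplitudes must be positive (dicrotic may be 0)")
        if self.systolic_width_s <= 0 or self.dicrotic_width_s <= 0:
            raise ValueError("bump widths must be positive")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the analytic beat at times ``t`` (seconds from onset)."""
        t = np.asarray(t, dtype=float)
        sys_bump = self.systolic_amp * np.exp(
            -0.5 * ((t - self.systolic_time_s) / self.systolic_width_s) ** 2)
        dic_bump = self.dicrotic_amp * np.exp(
            -0.5 * ((t - self.dicrotic_time_s) / self.dicrotic_width_s) ** 2)
        decay = 0.0
        if self.runoff_amp > 0:
            # linear decline from the dicrotic complex, finishing as the
            # time-mirror of the systolic foot so the inter-beat trough
            # is a symmetric V
            u = self.beat_period_s - t  # time to beat end
            foot = self.systolic_amp * np.exp(
                -0.5 * ((u - self.systolic_time_s) / self.systolic_width_s) ** 2)
            h0 = 0.15 * self.systolic_amp
            u_cut = (self.systolic_time_s - self.systolic_width_s
                     * np.sqrt(2.0 * np.log(self.systolic_amp / h0)))
            t_cut = self.beat_period_s - max(u_cut, 1e-3)
            denom = max(t_cut - self.dicrotic_time_s, 1e-6)
            ramp = h0 + (self.runoff_amp - h0) * (t_cut - t) / denom
            gate = 1.0 / (1.0 + np.exp(-(t - self.dicrotic_time_s) / 0.02))
            decay = gate * np.where(t >= t_cut, foot, np.clip(ramp, 0.0, None))
        return self.onset_amp + sys_bump + dic_bump + decay


@dataclass
class GroundTruth:
    """Per-record truth ledger used as the oracle for downstream stages.

    ``fiducials`` maps each landmark name to an array of per-beat times
    in seconds from the start of the recording; ``None`` entries mark
    degenerate (single-bump) beats without dicrotic landmarks.
    """

    record_id: str
    subject_id: str
    sbp_mmHg: float
    dbp_mmHg: float
    aligned_channel: int
    beat_onset_times_s: np.ndarray
    fiducials: dict[str, np.ndarray]
    params: BeatTemplateParams | None = None

    def __post_init__(self) -> None:
        if not self.sbp_mmHg > self.dbp_mmHg:
            raise ValueError("SBP must exceed DBP")
        times = np.column_stack([self.fiducials[k] for k in LANDMARKS])
        finite = np.all(np.isfinite(times), axis=1)
        if np.any(finite) and not np.all(np.diff(times[finite], axis=1) > 0):
            raise ValueError("fiducial times must be strictly increasing per beat")

    def median_intervals(self) -> dict[str, float]:
        """Median T1/T2/T3 over non-degenerate beats (seconds)."""
        f = self.fiducials
        ok = np.isfinite(f["dicrotic"])
        return {
            "t1_s": float(np.median((f["systolic"] - f["dp1"])[ok])),
            "t2_s": float(np.median((f["dicrotic"] - f["systolic"])[ok])),
            "t3_s": float(np.median((f["dp2"] - f["dicrotic"])[ok])),
        }


def beat_params_from_bp(sbp: float, dbp: float,
                        hr_bpm: float = 70.0) -> BeatTemplateParams:
    """Monotone map from a (SBP, DBP) pair to beat-template parameters.

    The map is the generator's stand-in for unknown physiology and is
    deliberately simple and invertible:

    * systolic amplitude is affine in SBP (higher pressure, taller peak),
      which also raises the maximum upstroke slope;
    * time-to-peak narrows affinely with pulse pressure SBP − DBP;
    * the dicrotic/systolic amplitude ratio, the dicrotic timing and the
      onset baseline are affine in DBP.
    """
    pp = sbp - dbp
    systolic_amp = 0.50 + 0.012 * (sbp - 118.0)
    amp_ratio = 0.28 + 0.006 * (dbp - 70.0)
    t_sys = 0.130 - 0.0008 * (pp - 45.0)
    t_dic = 0.350 + 0.0015 * (dbp - 70.0)
    onset = 0.05 + 0.002 * (dbp - 70.0)
    return BeatTemplateParams(
        systolic_time_s=t_sys,
        systolic_amp=systolic_amp,
        dicrotic_time_s=t_dic,
        dicrotic_amp=amp_ratio * systolic_amp,
        notch_time_s=0.5 * (t_sys + t_dic),
        beat_period_s=60.0 / hr_bpm,
        onset_amp=onset,
        runoff_amp=0.35 * systolic_amp,
    )


def generate_beat_template(
    params: BeatTemplateParams, sampling_rate: float,
) -> tuple[np.ndarray, dict[str, float]]:
    """Sample one beat period and derive its true fiducial landmarks.

    Returns
    -------
    samples : np.ndarray
        One beat period sampled at ``sampling_rate``.
    truth : dict
        Landmark name -> time in seconds from beat onset.  Dicrotic
        landmarks (``notch``, ``dicrotic``) are NaN when the beat is
        degenerate (no secondary bump), and ``degenerate`` is True.
        Landmarks are derived numerically from the sampled template so
        they serve as an exact oracle for detector accuracy.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    n = int(round(params.beat_period_s * sampling_rate))
    if n < 2:
        raise ValueError("beat period shorter than two samples")
    t = np.arange(n) / sampling_rate
    y = params.waveform(t)

    sys_idx = int(np.argmax(y))
    dp1_idx = int(np.argmin(y[: sys_idx + 1]))
    slope_idx = dp1_idx + int(np.argmax(np.diff(y[dp1_idx: sys_idx + 1])))

    truth: dict[str, float] = {
        "dp1": t[dp1_idx],
        "max_slope": t[slope_idx],
        "systolic": t[sys_idx],
        "degenerate": False,
    }

    def _degenerate() -> tuple[np.ndarray, dict[str, float]]:
        dp2_idx = sys_idx + int(np.argmin(y[sys_idx:]))
        truth.update(notch=np.nan, dicrotic=np.nan, dp2=t[dp2_idx],
                     degenerate=True)
        return y, truth

    # dicrotic landmarks: local min then local max after the systolic peak
    mid = int(round(0.5 * (params.systolic_time_s + params.dicrotic_time_s)
                    * sampling_rate))
    mid = max(mid, sys_idx + 1)
    dic_search = y[mid:]
    if params.dicrotic_amp <= 0 or len(dic_search) < 3:
        return _degenerate()
    dic_idx = mid + int(np.argmax(dic_search))
    if dic_idx <= sys_idx + 1 or dic_idx >= len(y) - 1:
        return _degenerate()
    notch_idx = sys_idx + int(np.argmin(y[sys_idx: dic_idx + 1]))
    if not (sys_idx < notch_idx < dic_idx) or y[dic_idx] <= y[notch_idx]:
        return _degenerate()
    dp2_idx = dic_idx + int(np.argmin(y[dic_idx:]))
    if dp2_idx <= dic_idx:
        return _degenerate()
    truth.update(notch=t[notch_idx], dicrotic=t[dic_idx], dp2=t[dp2_idx])
    return y, truth


def _artifact(t_rel: np.ndarray, amplitude: float,
              freq_hz: float = 15.0, tau_s: float = 0.08) -> np.ndarray:
    """Damped sinusoid transient emulating a motion artifact."""
    out = np.zeros_like(t_rel)
    mask = t_rel >= 0
    tr = t_rel[mask]
    out[mask] = amplitude * np.exp(-tr / tau_s) * np.sin(2 * np.pi * freq_hz * tr)
    return out


def generate_recording(
    config: SimulationConfig,
    subject_bp: tuple[float, float],
    seed: int | np.random.SeedSequence,
    hr_bpm: float | None = None,
    record_id: str = "",
    subject_id: str = "",
) -> tuple[WaveformRecording, GroundTruth]:
    """Generate one multi-channel recording with its ground-truth ledger.

    The clean signal is a concatenation of beats with per-beat lognormal
    period jitter.  Channel ``k`` is ``gain[k] * clean + wander + noise
    (+ artifacts)``; wander is a sinusoid at ``baseline_freq_hz`` with a
    random per-channel phase, noise is white Gaussian, and artifacts are
    damped 15 Hz transients placed with per-beat probability
    ``artifact_prob`` (common to all channels, as a motion event would be).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    sbp, dbp = float(subject_bp[0]), float(subject_bp[1])
    if hr_bpm is None:
        hr_bpm = float(rng.uniform(*config.hr_range_bpm))
    params = beat_params_from_bp(sbp, dbp, hr_bpm=hr_bpm)

    fs = config.sampling_rate_hz
    n_total = int(round(config.duration_s * fs))
    if config.duration_s < params.beat_period_s:
        raise ValueError("duration_s is shorter than one beat period")

    # concatenate beats until the window is covered
    pieces: list[np.ndarray] = []
    onsets: list[float] = []
    ends: list[float] = []
    fid: dict[str, list[float]] = {k: [] for k in LANDMARKS}
    t_cursor = 0.0
    n_done = 0
    while n_done < n_total:
        period = params.beat_period_s * float(rng.lognormal(mean=0.0, sigma=0.03))
        period = max(period, params.dicrotic_time_s + 3 * params.dicrotic_width_s)
        beat_params = dataclasses.replace(params, beat_period_s=period)
        y, truth = generate_beat_template(beat_params, fs)
        pieces.append(y)
        onsets.append(t_cursor)
        for k in LANDMARKS:
            fid[k].append(t_cursor + truth[k])
        t_cursor += len(y) / fs
        ends.append(t_cursor)
        n_done += len(y)
    clean = np.concatenate(pieces)[:n_total]
    t = np.arange(n_total) / fs

    # keep only beats fully inside the window
    onset_arr = np.asarray(onsets)
    keep = np.asarray(ends) <= config.duration_s + 1e-9
    fiducials = {k: np.asarray(v)[keep] for k, v in fid.items()}

    # re-derive onset/end troughs on the concatenated clean signal: at a
    # beat junction the true minimum is the junction sample itself, which
    # can differ by a sample from the isolated template's own argmin
    w = max(2, int(round(0.02 * fs)))
    dp1 = fiducials["dp1"].copy()
    for i, tv in enumerate(dp1):
        c = int(round(tv * fs))
        a, b = max(0, c - w), min(n_total, c + w + 1)
        dp1[i] = (a + int(np.argmin(clean[a:b]))) / fs
    dp2 = fiducials["dp2"].copy()
    dp2[:-1] = dp1[1:]
    fiducials["dp1"], fiducials["dp2"] = dp1, dp2

    # shared motion artifacts
    artifact_sig = np.zeros(n_total)
    for o in onset_arr[keep]:
        if rng.uniform() < config.artifact_prob:
            t0 = o + rng.uniform(0, params.beat_period_s)
            artifact_sig += _artifact(t - t0, 0.8 * params.systolic_amp)

    noise_abs = config.noise_sd * params.systolic_amp
    wander_abs = config.baseline_amp * params.systolic_amp
    gains = np.asarray(config.channel_gains, dtype=float)
    channels = np.empty((len(gains), n_total))
    for k, g in enumerate(gains):
        phase = rng.uniform(0, 2 * np.pi)
        wander = wander_abs * np.sin(2 * np.pi * config.baseline_freq_hz * t + phase)
        white = rng.normal(0.0, noise_abs, n_total) if noise_abs > 0 else 0.0
        channels[k] = g * clean + wander + white + artifact_sig

    rec = WaveformRecording(channels, fs, record_id=record_id,
                            subject_id=subject_id)
    truth_obj = GroundTruth(
        record_id=record_id, subject_id=subject_id,
        sbp_mmHg=sbp, dbp_mmHg=dbp,
        aligned_channel=config.aligned_channel,
        beat_onset_times_s=onset_arr[keep],
        fiducials=fiducials, params=params,
    )
    return rec, truth_obj


def generate_dataset(
    config: SimulationConfig,
) -> tuple[list[WaveformRecording], "pandas.DataFrame", list[GroundTruth]]:
    """Generate the full corpus: recordings, reference table, truth ledger.

    Per-subject BP is drawn as a subject mean plus a small per-record
    excursion, so that subjects cluster in BP space as real participants
    do; empirical SBP/DBP stay strictly inside the configured ranges.
    Deterministic for a fixed ``config.seed``.
    """
    import pandas as pd

    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    sbp_lo, sbp_hi = config.sbp_range_mmHg
    dbp_lo, dbp_hi = config.dbp_range_mmHg

    recordings: list[WaveformRecording] = []
    truths: list[GroundTruth] = []
    rows = []
    for si, sseed in enumerate(subject_seeds):
        srng = np.random.default_rng(sseed)
        mean_sbp = srng.uniform(sbp_lo + 5, sbp_hi - 5)
        mean_dbp = srng.uniform(dbp_lo + 4, dbp_hi - 4)
        hr = srng.uniform(*config.hr_range_bpm)
        rec_seeds = sseed.spawn(config.records_per_subject)
        for ri, rseed in enumerate(rec_seeds):
            rrng = np.random.default_rng(rseed)
            sbp = mean_sbp + rrng.uniform(-5, 5)
            dbp = mean_dbp + rrng.uniform(-4, 4)
            subject_id = f"s{si + 1:02d}"
            record_id = f"{subject_id}r{ri + 1:03d}"
            rec, truth = generate_recording(
                config, (sbp, dbp), rseed.spawn(1)[0],
                hr_bpm=hr * float(rrng.lognormal(0.0, 0.02)),
                record_id=record_id, subject_id=subject_id,
            )
            recordings.append(rec)
            truths.append(truth)
            rows.append({"record_id": record_id, "subject_id": subject_id,
                         "sbp_mmHg": sbp, "dbp_mmHg": dbp})
    references = pd.DataFrame(rows)
    return recordings, references, truths
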