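"""Detection of breathing pauses, desaturation and bradycardia episodes.

Breathing pauses are scored from the thoraco-abdominal effort signal: breath
cycles are found on a band-passed (0.3-2.5 Hz) effort trace with an adaptive
amplitude threshold, and a pause is the silent time in an inter-breath interval
beyond one median breath period.  Pauses of more than 3 and up to 5 s are
"short", pauses of more than 5 s are "long".

Intermittent-hypoxia episodes are maximal runs of SpO2 strictly below 90, 88
and 85 % sustained for at least 5 s, evaluated independently per threshold on
the oximeter-averaged saturation trace (the study oximeters used an 8-second
averaging time, reproduced by :func:`smooth_spo2`).  Bradycardia episodes are
runs of heart rate strictly below 110 bpm (mild) and 100 bpm (moderate).

All detectors treat masked (artifact) samples as gaps: an invalid sample ends
an episode run, and episodes are never scored inside invalid time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import BRADY, DESAT, PAUSE_LONG, PAUSE_SHORT, Channel, Event, EventList

DESAT_THRESHOLDS = (90.0, 88.0, 85.0)
BRADY_THRESHOLDS = (110.0, 100.0)


@dataclass
class BreathSeries:
    """Breath onset times (s, strictly increasing) and per-breath amplitudes."""

    onsets: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("breath onsets must be strictly increasing")

    def __len__(self) -> int:
        return self.onsets.size

    @property
    def median_period(self) -> float:
        if len(self) < 2:
            return np.nan
        return float(np.median(np.diff(self.onsets)))


def _runs(below: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index pairs [start, stop)."""
    if below.size == 0:
        return []
    padded = np.concatenate(([False], below, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def threshold_events(
    ch: Channel,
    event_type: str,
    thresholds,
    min_dur: float,
    start_time: float = 0.0,
    gap_merge: float = 0.0,
    subject_id: str = "S00",
) -> EventList:
    """Score runs strictly below each threshold, independently per threshold.

    A run must last at least ``min_dur`` seconds to become an event; invalid
    samples break runs.  ``gap_merge`` > 0 joins runs separated by no more than
    that many seconds of recovery (default 0: any recovery splits episodes).
    """
    events = []
    dt = 1.0 / ch.rate
    for thr in thresholds:
        below = ch.valid & (ch.data < thr)
        runs = _runs(below)
        if gap_merge > 0 and runs:
            merged = [list(runs[0])]
            for s, e in runs[1:]:
                if (s - merged[-1][1]) * dt <= gap_merge:
                    merged[-1][1] = e
                else:
                    merged.append([s, e])
            runs = [(s, e) for s, e in merged]
        label = f"<{thr:g}"
        for s, e in runs:
            dur = (e - s) * dt
            if dur >= min_dur:
                events.append(
                    Event(event_type, start_time + s * dt, dur, threshold_label=label)
                )
    return EventList(subject_id, events)


def _rolling_median(x: np.ndarray, k: int) -> np.ndarray:
    med = np.empty_like(x)
    half = k // 2
    for i in range(x.size):  # x.size is #breaths, not #samples: cheap
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        med[i] = np.median(x[lo:hi])
    return med


def detect_breaths(
    resp: Channel,
    band: tuple[float, float] = (0.3, 2.5),
    amp_frac: float = 0.3,
    median_breaths: int = 60,
    start_time: float = 0.0,
) -> BreathSeries:
    """Find breath cycles on a band-passed respiratory-effort signal.

    Candidate breath peaks are located on the band-passed trace; each
    candidate's amplitude is then measured as the peak-to-trough excursion of
    the raw (detrended) effort signal within half a breath cycle, so that
    filter ringing into apneic silence produces no breaths.  A candidate is
    kept if its amplitude is at least ``amp_frac`` of the rolling median
    amplitude over ``median_breaths`` neighbouring breaths, making scoring
    robust to slow amplitude drift.  Flat or invalid segments contribute no
    breaths.
    """
    if resp.valid.sum() < 10 * resp.rate:
        raise ValueError("need at least 10 s of valid respiratory signal")
    x = np.where(resp.valid, resp.data, 0.0)
    x = x - np.median(x[resp.valid])
    nyq = resp.rate / 2.0
    hi = min(band[1], 0.95 * nyq)
    sos = sps.butter(4, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    f = sps.sosfiltfilt(sos, x)

    min_dist = max(1, int(resp.rate / band[1] * 0.8))
    global_scale = np.percentile(np.abs(f[resp.valid]), 90)
    if global_scale <= 0:
        return BreathSeries(np.empty(0), np.empty(0))
    peaks, _ = sps.find_peaks(f, distance=min_dist, prominence=0.05 * global_scale)
    peaks = peaks[resp.valid[peaks]]
    if peaks.size == 0:
        return BreathSeries(np.empty(0), np.empty(0))

    # amplitude from the raw signal around each candidate (half a cycle wide)
    period = np.median(np.diff(peaks)) if peaks.size > 1 else resp.rate
    half_w = max(2, int(round(0.5 * period)))
    amp = np.empty(peaks.size)
    for j, p in enumerate(peaks):
        lo, hi_ = max(0, p - half_w), min(x.size, p + half_w + 1)
        seg = x[lo:hi_]
        amp[j] = seg.max() - seg.min()

    keep = amp >= amp_frac * _rolling_median(amp, max(3, median_breaths))
    peaks, amp = peaks[keep], amp[keep]
    return BreathSeries(start_time + peaks / resp.rate, amp)


def detect_pauses(
    breaths: BreathSeries,
    short_bounds: tuple[float, float] = (3.0, 5.0),
    long_min: float = 5.0,
    subject_id: str = "S00",
) -> EventList:
    """Score breathing pauses from inter-breath intervals.

    The pause in an interval is the silent time beyond one expected breath
    cycle: ``d = interval - median breath period`` (clipped at 0), so normal
    slow breaths do not count as pauses.  ``short_bounds[0] < d <=
    short_bounds[1]`` is a short pause, ``d > long_min`` a long pause; onset is
    the last breath onset plus one median period.
    """
    if len(breaths) < 2:
        return EventList(subject_id, [])
    period = breaths.median_period
    intervals = np.diff(breaths.onsets)
    d = np.clip(intervals - period, 0.0, None)
    events = []
    for i, dur in enumerate(d):
        if dur <= short_bounds[0]:
            continue
        etype = PAUSE_SHORT if dur <= short_bounds[1] else PAUSE_LONG
        if etype == PAUSE_LONG and dur <= long_min:
            etype = PAUSE_SHORT
        events.append(Event(etype, breaths.onsets[i] + period, float(dur)))
    return EventList(subject_id, events)


def smooth_spo2(spo2: Channel, window: float = 8.0) -> Channel:
    """Trailing moving average reproducing the pulse-oximeter averaging time.

    Output sample i averages the valid samples among the last
    ``round(window * rate)`` samples up to and including i; invalid samples are
    excluded from the average, and the output is invalid where the window
    contains no valid sample.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n = max(1, int(round(window * spo2.rate)))
    x = np.where(spo2.valid, spo2.data, 0.0)
    v = spo2.valid.astype(float)
    kernel = np.ones(n)
    num = np.convolve(x, kernel)[: x.size]
    cnt = np.convolve(v, kernel)[: v.size]
    out = np.full(x.size, np.nan)
    ok = cnt > 0
    out[ok] = num[ok] / cnt[ok]
    return Channel(out, spo2.rate, ok)


def detect_desaturations(
    spo2: Channel,
    thresholds=DESAT_THRESHOLDS,
    min_dur: float = 5.0,
    start_time: float = 0.0,
    gap_merge: float = 0.0,
    subject_id: str = "S00",
) -> EventList:
    """Intermittent-hypoxia episodes: SpO2 strictly below each threshold >= min_dur s."""
    return threshold_events(
        spo2, DESAT, thresholds, min_dur, start_time, gap_merge, subject_id
    )


def detect_bradycardia(
    hr: Channel,
    thresholds=BRADY_THRESHOLDS,
    min_dur: float = 1.0,
    start_time: float = 0.0,
    gap_merge: float = 0.0,
    subject_id: str = "S00",
) -> EventList:
    """Bradycardia episodes: heart rate strictly below each threshold >= min_dur s.

    The study defines no minimum duration; the 1-s default suppresses
    single-sample artifacts and is configurable.
    """
    return threshold_events(
        hr, BRADY, thresholds, min_dur, start_time, gap_merge, subject_id
    )


def detect_r_peaks(ecg: Channel, refractory: float = 0.2) -> np.ndarray:
    """R-peak times (s) by derivative-and-threshold detection.

    The rectified ECG is compared against an adaptive threshold (half the
    median of 2-s block maxima, i.e. half a robust R amplitude) with a
    refractory period during which no second peak is accepted.
    """
    if ecg.valid.sum() < 10 * ecg.rate:
        raise ValueError("need at least 10 s of valid ECG")
    x = np.where(ecg.valid, ecg.data, 0.0)
    x = np.abs(x - np.median(x[ecg.valid]))
    block = max(1, int(2 * ecg.rate))
    n_blocks = x.size // block
    height = 0.5 * np.median(
        x[: n_blocks * block].reshape(n_blocks, block).max(axis=1)
    )
    if height <= 0:
        raise ValueError("no QRS activity detectable")
    peaks, _ = sps.find_peaks(
        x, height=height, distance=max(1, int(refractory * ecg.rate))
    )
    peaks = peaks[ecg.valid[peaks]]
    return peaks / ecg.rate


def instantaneous_hr(r_times: np.ndarray, rr_bounds=(0.2, 3.0)):
    """Per-beat heart rate 60/RR, assigned at each R peak.

    Returns (times, hr, ok): implausible RR intervals outside ``rr_bounds``
    are flagged invalid rather than dropped.
    """
    r_times = np.asarray(r_times, dtype=float)
    rr = np.diff(r_times)
    ok = (rr >= rr_bounds[0]) & (rr <= rr_bounds[1])
    with np.errstate(divide="ignore"):
        hr = 60.0 / rr
    return r_times[1:], hr, ok


def compute_heart_rate(
    ecg: Channel,
    out_rate: float = 1.0,
    refractory: float = 0.2,
    rr_bounds=(0.2, 3.0),
) -> Channel:
    """Heart-rate channel (bpm) derived from ECG, resampled by previous-value hold.

    Samples before the first valid beat, or further than ``rr_bounds[1]`` s
    from the last accepted beat (undetectable QRS), are marked invalid.
    """
    r = detect_r_peaks(ecg, refractory)
    if r.size < 2:
        raise ValueError("fewer than 2 R peaks detected")
    t_beat, hr, ok = instantaneous_hr(r, rr_bounds)
    t_beat, hr = t_beat[ok], hr[ok]
    n_out = int(np.floor(ecg.duration * out_rate))
    t_out = np.arange(n_out) / out_rate
    out = np.full(n_out, np.nan)
    valid = np.zeros(n_out, dtype=bool)
    if t_beat.size:
        idx = np.searchsorted(t_beat, t_out, side="right") - 1
        has = idx >= 0
        out[has] = hr[idx[has]]
        # previous-value hold expires when no beat was seen for rr_bounds[1] s
        fresh = has & (t_out - np.where(has, t_beat[np.clip(idx, 0, None)], np.inf) <= rr_bounds[1])
        valid = fresh
    out[~valid] = np.nan
    return Channel(out, out_rate, valid)
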