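"""Synthetic neonatal cardiorespiratory recordings and cohort tables.

The generator emulates the structure the analysis assumes rather than a
mechanistic cardiopulmonary model: quasi-periodic respiratory effort with
apneic pauses drawn from a point process whose rate drops by ``stim_rate_ratio``
during stimulation-ON blocks; oxygen saturation that falls, after a lag, by an
amount proportional to the pause duration (observed through the oximeter's
8-second trailing average); heart rate that slows earlier and recovers faster
than SpO2, reproducing the pause -> bradycardia -> desaturation cascade seen in
premature infants; and an ECG impulse train consistent with the heart-rate
trace.  Every inserted event is logged as ground truth so detector accuracy
can be scored exactly.

Pause onsets follow a rate-matched renewal process: successive gaps are a
30-s minimum separation plus the mean pause duration plus an exponential whose
mean is chosen so the realised event rate equals the nominal rate in each
block.  This keeps ground truth unambiguous (events never overlap) while
preserving the ON/OFF rate ratio, which naive hard-core thinning would bias.

``generate_cohort`` produces 15-subject summary tables either by full signal
simulation + detection, or by a fast count-level model (Poisson counts with a
log-normal subject severity effect, a symmetric log-normal between-period
effect, and a multiplicative stimulation effect per outcome), whose default
baselines and ratios reflect a cohort with frequent periodic breathing and a
stimulation effect of the size the analysis is meant to resolve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .core import (
    BRADY,
    DESAT,
    ECG,
    HR,
    OFF,
    ON,
    OUTCOMES,
    PAUSE_LONG,
    PAUSE_SHORT,
    RESP,
    SPO2,
    Channel,
    Event,
    EventList,
    Recording,
    StimulationSchedule,
    outcome_stem,
)
from .detect import smooth_spo2
from .io import CohortTable


@dataclass
class SimParams:
    """Parameters of one synthetic 24-h study.

    Rates are per hour of the relevant condition; lags, durations and the
    oximeter window are seconds; ``stim_rate_ratio`` multiplies the apnea
    hazard during ON blocks (0.61 ~ a 39 % reduction).  Baseline heart rate
    defaults inside the 150-165 bpm range typical of this population.
    """

    duration_h: float = 24.0
    sample_rate: float = 250.0
    spo2_rate: float | None = None  #: default: sample_rate
    hr_rate: float | None = None  #: default: sample_rate
    breath_rate: float = 55.0  #: breaths/min
    breath_jitter_sd: float = 0.0  #: s, jitter of individual breath times
    apnea_rate_off: float = 47.0  #: pauses/h while unstimulated
    pause_mu: float = math.log(5.0)  #: log-normal location of pause duration (s)
    pause_sigma: float = 0.6
    stim_rate_ratio: float = 0.61
    min_separation: float = 30.0  #: s between successive apneas
    baseline_hr: float = 157.0
    baseline_spo2: float = 96.0
    desat_lag: float = 8.0  #: s from pause onset to start of SpO2 fall
    desat_depth_slope: float = 0.8  #: % SpO2 per s of pause
    desat_floor: float = 75.0
    desat_fall: float = 10.0
    desat_recovery: float = 15.0
    brady_lag: float = 4.0  #: s; bradycardia precedes the desaturation
    brady_depth_slope: float = 6.0  #: bpm per s of pause
    brady_floor: float = 70.0
    brady_fall: float = 5.0
    brady_recovery: float = 10.0
    oximeter_window: float = 8.0  #: s, device averaging time
    resp_noise_sd: float = 0.05
    spo2_noise_sd: float = 0.3
    hr_noise_sd: float = 1.0
    ecg_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.apnea_rate_off < 0 or self.breath_rate <= 0:
            raise ValueError("rates must be non-negative (breath rate positive)")
        if self.stim_rate_ratio <= 0:
            raise ValueError("stim_rate_ratio must be positive")
        if not (0 < self.baseline_hr < 300):
            raise ValueError("baseline_hr must lie in (0, 300) bpm")
        mean_pause = math.exp(self.pause_mu + self.pause_sigma**2 / 2)
        for cond_rate in (
            self.apnea_rate_off,
            self.apnea_rate_off * self.stim_rate_ratio,
        ):
            if cond_rate > 0 and 3600.0 / cond_rate <= self.min_separation + mean_pause:
                raise ValueError(
                    "infeasible apnea rate: expected apnea + separation time "
                    "exceeds available block time"
                )

    @property
    def breath_period(self) -> float:
        return 60.0 / self.breath_rate

    @property
    def mean_pause(self) -> float:
        return math.exp(self.pause_mu + self.pause_sigma**2 / 2)


@dataclass
class GroundTruth:
    """The simulator's log of inserted events, for scoring detectors."""

    pauses: EventList
    desats: EventList
    bradys: EventList
    schedule: StimulationSchedule
    breath_times: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for etype, thr in OUTCOMES:
            src = {PAUSE_SHORT: self.pauses, PAUSE_LONG: self.pauses}.get(etype)
            if src is None:
                src = self.desats if etype == DESAT else self.bradys
            out[outcome_stem(etype, thr)] = len(src.sublist(etype, thr))
        return out


def _draw_apnea_windows(
    params: SimParams, schedule: StimulationSchedule, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Apnea windows (start, nominal duration) from the rate-matched renewal process."""
    start, end = schedule.span
    end = min(end, start + params.duration_h * 3600.0)
    windows: list[tuple[float, float]] = []
    t = start
    guard = params.breath_period * 2
    while t < end - guard:
        block = next(b for b in schedule.blocks if b[0] <= t < b[1])
        rate = params.apnea_rate_off * (
            params.stim_rate_ratio if block[2] == ON else 1.0
        )
        if rate <= 0:
            t = block[1]
            continue
        mean_gap = 3600.0 / rate - params.min_separation - params.mean_pause
        t = t + params.min_separation + rng.exponential(mean_gap)
        dur = rng.lognormal(params.pause_mu, params.pause_sigma)
        if t + dur >= end - guard:
            break
        windows.append((t, dur))
        t += dur
    return windows


def _scan_runs(x: np.ndarray, thr: float, rate: float, min_dur: float):
    """Threshold-run scanner used to derive ground-truth labels."""
    from .detect import _runs

    out = []
    for s, e in _runs(x < thr):
        dur = (e - s) / rate
        if dur >= min_dur:
            out.append((s / rate, dur))
    return out


def _trapezoid_deflect(
    n: int,
    rate: float,
    events: list[tuple[float, float, float]],
    fall: float,
    recovery: float,
) -> np.ndarray:
    """Max-combined trapezoidal deflections; events are (start_s, hold_s, depth)."""
    out = np.zeros(n)
    t = np.arange(n) / rate
    for start, hold, depth in events:
        i0 = max(0, int(np.floor((start - 0.5) * rate)))
        i1 = min(n, int(np.ceil((start + fall + hold + recovery + 0.5) * rate)))
        if i0 >= i1:
            continue
        tt = t[i0:i1] - start
        d = np.zeros(i1 - i0)
        up = (tt >= 0) & (tt < fall)
        d[up] = depth * tt[up] / fall
        flat = (tt >= fall) & (tt < fall + hold)
        d[flat] = depth
        down = (tt >= fall + hold) & (tt < fall + hold + recovery)
        d[down] = depth * (1.0 - (tt[down] - fall - hold) / recovery)
        out[i0:i1] = np.maximum(out[i0:i1], d)
    return out


def generate_recording(
    params: SimParams,
    schedule: StimulationSchedule | None = None,
    channels: tuple[str, ...] = (RESP, SPO2, HR, ECG),
    subject_id: str = "S00",
) -> tuple[Recording, GroundTruth]:
    """Simulate one multichannel study and its ground-truth event log.

    The returned ground truth records *realised* pause durations (the silent
    time between the flanking breaths beyond one breath period), and the
    desaturation/bradycardia episodes present in the noise-free channels after
    the oximeter averaging model, so a detector run on a noise-free recording
    should recover it exactly.
    """
    if schedule is None:
        schedule = StimulationSchedule.standard("off_first")
    span = schedule.span
    if span[1] - span[0] < params.duration_h * 3600.0 - 1e-6:
        raise ValueError("schedule does not cover the requested duration")
    rng = np.random.default_rng(params.seed)
    dur_s = params.duration_h * 3600.0
    T = params.breath_period

    windows = _draw_apnea_windows(params, schedule, rng)

    breath_times = np.arange(T / 2, dur_s, T)
    if params.breath_jitter_sd > 0:
        breath_times = np.sort(
            breath_times + rng.normal(0, params.breath_jitter_sd, breath_times.size)
        )
    keep = np.ones(breath_times.size, dtype=bool)
    for a, d in windows:
        keep &= ~((breath_times >= a) & (breath_times < a + d))
    kept = breath_times[keep]
    t_med = float(np.median(np.diff(kept)))

    pause_events = []
    for a, d in windows:
        i_prev = np.searchsorted(kept, a) - 1
        i_next = np.searchsorted(kept, a + d)
        if i_prev < 0 or i_next >= kept.size:
            continue
        realized = kept[i_next] - kept[i_prev] - t_med
        if realized <= 3.0:
            continue
        etype = PAUSE_SHORT if realized <= 5.0 else PAUSE_LONG
        pause_events.append(Event(etype, kept[i_prev] + t_med, float(realized)))
    pauses = EventList(subject_id, pause_events)

    chans: dict[str, Channel] = {}

    if RESP in channels:
        fs = params.sample_rate
        n = int(round(dur_s * fs))
        impulses = np.zeros(n)
        idx = np.clip(np.round(kept * fs).astype(int), 0, n - 1)
        amp = 1.0 + 0.2 * np.sin(2 * np.pi * 0.02 * kept)
        np.add.at(impulses, idx, amp)
        width = max(3, int(round(0.8 * T * fs)) | 1)
        bump = np.hanning(width)
        resp = fftconvolve(impulses, bump, mode="same")
        if params.resp_noise_sd > 0:
            resp = resp + rng.normal(0, params.resp_noise_sd, n)
        chans[RESP] = Channel(resp, fs)

    # SpO2: lagged, pause-scaled desaturation observed through the oximeter average
    spo2_rate = params.spo2_rate or params.sample_rate
    n_s = int(round(dur_s * spo2_rate))
    desat_spec = [
        (
            e.onset + params.desat_lag,
            e.duration,
            min(params.desat_depth_slope * e.duration, params.baseline_spo2 - params.desat_floor),
        )
        for e in pauses
    ]
    spo2_clean = params.baseline_spo2 - _trapezoid_deflect(
        n_s, spo2_rate, desat_spec, params.desat_fall, params.desat_recovery
    )
    spo2_obs = smooth_spo2(Channel(spo2_clean, spo2_rate), params.oximeter_window)
    desat_events = [
        Event(DESAT, onset, dur, threshold_label=f"<{thr:g}")
        for thr in (90.0, 88.0, 85.0)
        for onset, dur in _scan_runs(spo2_obs.data, thr, spo2_rate, 5.0)
    ]
    desats = EventList(subject_id, desat_events)
    if SPO2 in channels:
        data = spo2_obs.data.copy()
        if params.spo2_noise_sd > 0:
            data = data + rng.normal(0, params.spo2_noise_sd, n_s)
        chans[SPO2] = Channel(np.clip(data, 0.0, 100.0), spo2_rate)

    # heart rate: earlier, deeper-per-second response with faster recovery
    hr_rate = params.hr_rate or params.sample_rate
    n_h = int(round(dur_s * hr_rate))
    brady_spec = [
        (
            e.onset + params.brady_lag,
            e.duration,
            min(params.brady_depth_slope * e.duration, params.baseline_hr - params.brady_floor),
        )
        for e in pauses
    ]
    hr_clean = params.baseline_hr - _trapezoid_deflect(
        n_h, hr_rate, brady_spec, params.brady_fall, params.brady_recovery
    )
    brady_events = [
        Event(BRADY, onset, dur, threshold_label=f"<{thr:g}")
        for thr in (110.0, 100.0)
        for onset, dur in _scan_runs(hr_clean, thr, hr_rate, 1.0)
    ]
    bradys = EventList(subject_id, brady_events)
    if HR in channels:
        data = hr_clean.copy()
        if params.hr_noise_sd > 0:
            data = data + rng.normal(0, params.hr_noise_sd, n_h)
        chans[HR] = Channel(np.clip(data, 1.0, 300.0), hr_rate)

    if ECG in channels:
        fs = params.sample_rate
        n = int(round(dur_s * fs))
        t_h = np.arange(n_h) / hr_rate
        phase = np.cumsum(hr_clean / 60.0) / hr_rate
        beats = np.interp(np.arange(1.0, phase[-1]), phase, t_h)
        ecg = np.zeros(n)
        bidx = np.clip(np.round(beats * fs).astype(int), 0, n - 1)
        np.add.at(ecg, bidx, 1.0)
        qrs_w = max(3, int(round(0.04 * fs)) | 1)
        qrs = np.exp(-0.5 * ((np.arange(qrs_w) - qrs_w // 2) / (qrs_w / 6.0)) ** 2)
        ecg = fftconvolve(ecg, qrs, mode="same")
        if params.ecg_noise_sd > 0:
            ecg = ecg + rng.normal(0, params.ecg_noise_sd, n)
        chans[ECG] = Channel(ecg, fs)

    recording = Recording(chans, subject_id=subject_id)
    truth = GroundTruth(pauses, desats, bradys, schedule, breath_times=kept)
    return recording, truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: per-outcome OFF-period baselines (count / 12 h, mean episode duration s) and
#: stimulation ON/OFF ratios, describing a cohort with frequent periodic
#: breathing and a stimulation effect of the size the paired design resolves.
DEFAULT_BASELINES: dict[str, tuple[float, float]] = {
    "pause_long": (282.0, 7.6),
    "pause_short": (186.0, 4.5),
    "desat_lt90": (150.0, 18.6),
    "desat_lt88": (100.0, 23.4),
    "desat_lt85": (71.0, 22.3),
    "brady_lt110": (63.0, 12.2),
    "brady_lt100": (54.0, 12.3),
}
DEFAULT_RATIOS: dict[str, float] = {
    "pause_long": 0.61,
    "pause_short": 0.79,
    "desat_lt90": 0.72,
    "desat_lt88": 0.72,
    "desat_lt85": 0.72,
    "brady_lt110": 0.33,
    "brady_lt100": 0.33,
}


@dataclass
class CohortModel:
    """Count-level generative model for fast cohort simulation.

    Per subject, a log-normal severity multiplier (sd ``between_sd``) scales
    all outcome baselines; each 12-h condition period gets an independent
    symmetric log-normal multiplier (sd ``period_sd``) representing
    state/sleep variability between halves of the study, so that with
    ``ratios`` of 1 the two conditions are exchangeable; stimulation
    multiplies each outcome's ON-period mean by its ratio.  Counts are
    Poisson; total durations are Gamma sums of per-episode durations.
    """

    baselines: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    ratios: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATIOS))
    between_sd: float = 0.8
    period_sd: float = 0.177
    outcome_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.between_sd <= 0:
            raise ValueError(
                "between_sd must be positive: a zero-variance subject random "
                "effect makes the random-effect model degenerate"
            )

    def with_ratio(self, ratio: float) -> "CohortModel":
        return replace(self, ratios={k: ratio for k in self.ratios})


def generate_cohort(
    n_subjects: int = 15,
    model: CohortModel | None = None,
    seed: int = 0,
    mode: str = "counts",
    params: SimParams | None = None,
) -> CohortTable:
    """Simulate a per-subject, per-condition cohort summary table.

    ``mode='counts'`` draws outcome counts/durations from :class:`CohortModel`
    (fast, used for statistical calibration); ``mode='signals'`` simulates
    full recordings per subject with :func:`generate_recording`, runs the
    detectors and summarises the labelled events (slow, end-to-end).  The
    ON/OFF order is randomised per subject by coin flip.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    if mode == "counts":
        model = model or CohortModel()
        rows = []
        for i in range(n_subjects):
            severity = math.exp(
                model.between_sd * rng.standard_normal() - model.between_sd**2 / 2
            )
            order = "on_first" if rng.integers(2) else "off_first"
            row: dict = {"subject_id": f"SYN{i + 1:02d}", "order": order}
            for stem, (lam0, mdur) in model.baselines.items():
                jitter = math.exp(
                    model.outcome_sd * rng.standard_normal() - model.outcome_sd**2 / 2
                )
                lam = lam0 * severity * jitter
                u_off = math.exp(
                    model.period_sd * rng.standard_normal() - model.period_sd**2 / 2
                )
                u_on = math.exp(
                    model.period_sd * rng.standard_normal() - model.period_sd**2 / 2
                )
                c_off = int(rng.poisson(lam * u_off))
                c_on = int(rng.poisson(lam * model.ratios[stem] * u_on))
                row[f"{stem}_count_off"] = c_off
                row[f"{stem}_count_on"] = c_on
                row[f"{stem}_dur_off"] = (
                    float(rng.gamma(c_off, mdur)) if c_off else 0.0
                )
                row[f"{stem}_dur_on"] = float(rng.gamma(c_on, mdur)) if c_on else 0.0
            row["valid_time_off"] = 12 * 3600.0
            row["valid_time_on"] = 12 * 3600.0
            rows.append(row)
        return CohortTable(pd.DataFrame(rows))

    if mode == "signals":
        from .pipeline import process_recording

        params = params or SimParams()
        model = model or CohortModel()
        summaries = []
        for i in range(n_subjects):
            severity = math.exp(
                model.between_sd * rng.standard_normal() - model.between_sd**2 / 2
            )
            ratio = params.stim_rate_ratio * math.exp(
                model.period_sd * rng.standard_normal()
            )
            sub_params = replace(
                params,
                apnea_rate_off=params.apnea_rate_off * severity,
                stim_rate_ratio=min(ratio, 0.99),
                seed=int(rng.integers(2**31 - 1)),
            )
            order = "on_first" if rng.integers(2) else "off_first"
            schedule = StimulationSchedule.standard(
                order, block_hours=params.duration_h / 4.0
            )
            rec, _ = generate_recording(
                sub_params, schedule, subject_id=f"SYN{i + 1:02d}"
            )
            _, summary = process_recording(rec, schedule)
            summaries.append(summary)
        return CohortTable.from_summaries(summaries)

    raise ValueError(f"unknown cohort mode {mode!r}")
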