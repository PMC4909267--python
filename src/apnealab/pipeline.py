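"""End-to-end orchestration: recording -> events -> per-condition summary."""

from __future__ import annotations

from dataclasses import dataclass

from .blocks import assign_events, summarize_subject
from .core import (
    ECG,
    HR,
    RESP,
    SPO2,
    EventList,
    Recording,
    StimulationSchedule,
    SubjectSummary,
)
from . import detect


@dataclass
class DetectionConfig:
    """Detection thresholds and windows; defaults are the study's definitions."""

    spo2_thresholds: tuple[float, ...] = (90.0, 88.0, 85.0)
    desat_min_dur: float = 5.0
    brady_thresholds: tuple[float, ...] = (110.0, 100.0)
    brady_min_dur: float = 1.0
    pause_short_bounds: tuple[float, float] = (3.0, 5.0)
    pause_long_min: float = 5.0
    oximeter_window: float = 8.0
    #: apply the 8-s oximeter average before desaturation scoring; leave False
    #: when the SpO2 channel already comes device-averaged (monitors and the
    #: synthetic generator both emit averaged saturation)
    smooth_spo2: bool = False
    gap_merge: float = 0.0
    breath_band: tuple[float, float] = (0.3, 2.5)
    hr_out_rate: float = 1.0


def detect_events(recording: Recording, config: DetectionConfig | None = None) -> EventList:
    """Run all detectors on a recording and pool the events.

    Requires a respiratory channel and SpO2; heart rate is taken from the HR
    channel when present, otherwise derived from ECG.
    """
    cfg = config or DetectionConfig()
    sid = recording.subject_id
    t0 = recording.start_time
    events = EventList(sid, [])

    breaths = detect.detect_breaths(
        recording[RESP], band=cfg.breath_band, start_time=t0
    )
    events.extend(
        detect.detect_pauses(
            breaths, cfg.pause_short_bounds, cfg.pause_long_min, subject_id=sid
        )
    )

    spo2 = recording[SPO2]
    if cfg.smooth_spo2:
        spo2 = detect.smooth_spo2(spo2, cfg.oximeter_window)
    events.extend(
        detect.detect_desaturations(
            spo2,
            cfg.spo2_thresholds,
            cfg.desat_min_dur,
            start_time=t0,
            gap_merge=cfg.gap_merge,
            subject_id=sid,
        )
    )

    if HR in recording:
        hr = recording[HR]
    elif ECG in recording:
        hr = detect.compute_heart_rate(recording[ECG], out_rate=cfg.hr_out_rate)
    else:
        raise ValueError("recording has neither an HR nor an ECG channel")
    events.extend(
        detect.detect_bradycardia(
            hr,
            cfg.brady_thresholds,
            cfg.brady_min_dur,
            start_time=t0,
            gap_merge=cfg.gap_merge,
            subject_id=sid,
        )
    )
    return events


def process_recording(
    recording: Recording,
    schedule: StimulationSchedule,
    config: DetectionConfig | None = None,
) -> tuple[EventList, SubjectSummary]:
    """Detect, assign to ON/OFF blocks and summarise one subject's study."""
    events = detect_events(recording, config)
    labeled = assign_events(events, schedule)
    summary = summarize_subject(labeled, schedule, recording=recording)
    return labeled, summary
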