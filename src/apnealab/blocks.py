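"""Assignment of events to stimulation blocks and per-subject summaries.

Each subject's 24-h study is divided into four 6-h blocks alternating between
stimulation ON and OFF (starting condition randomised).  Events are assigned
to the block containing their *onset* and are never split across boundaries,
so whole episodes are counted; totals per condition therefore conserve the
overall totals exactly.
"""

from __future__ import annotations

import numpy as np

from .core import (
    OFF,
    ON,
    OUTCOMES,
    EventList,
    Recording,
    StimulationSchedule,
    SubjectSummary,
    outcome_stem,
)


def assign_events(events: EventList, schedule: StimulationSchedule) -> EventList:
    """Label each event with the condition of the block containing its onset.

    Events are not truncated at block boundaries; an event whose onset lies in
    a block belongs wholly to that block's condition.  An onset outside the
    schedule span is an error.
    """
    labeled = []
    for e in events:
        cond = schedule.condition_at(e.onset)
        labeled.append(
            type(e)(e.type, e.onset, e.duration, e.threshold_label, condition=cond)
        )
    return EventList(events.subject_id, labeled)


def condition_valid_time(
    recording: Recording, schedule: StimulationSchedule
) -> dict[str, float]:
    """Artifact-free monitored seconds per condition.

    A second of the study is counted as monitored when every channel present
    in the recording is valid at that time; this is the denominator for
    comparing event *rates* when artifact time differs between conditions.
    """
    start, end = schedule.span
    t = np.arange(start, min(end, start + recording.duration), 1.0)
    monitored = np.ones(t.size, dtype=bool)
    for ch in recording.channels.values():
        idx = np.clip(((t - recording.start_time) * ch.rate).astype(int), 0, ch.n - 1)
        monitored &= ch.valid[idx]
    out = {}
    for cond in (ON, OFF):
        out[cond] = float((monitored & schedule.condition_mask(t, cond)).sum())
    return out


def summarize_subject(
    labeled: EventList,
    schedule: StimulationSchedule,
    valid_time: dict[str, float] | None = None,
    recording: Recording | None = None,
) -> SubjectSummary:
    """Counts and total durations per outcome and condition for one subject.

    ``valid_time`` may be passed directly or computed from ``recording``;
    with neither, the full schedule span is assumed artifact-free.
    """
    if valid_time is None:
        if recording is not None:
            valid_time = condition_valid_time(recording, schedule)
        else:
            valid_time = {
                cond: sum(e - s for s, e, c in schedule.blocks if c == cond)
                for cond in (ON, OFF)
            }
    counts: dict[tuple[str, str], int] = {}
    durations: dict[tuple[str, str], float] = {}
    for etype, thr in OUTCOMES:
        stem = outcome_stem(etype, thr)
        sub = labeled.sublist(etype, thr)
        for cond in (ON, OFF):
            evs = [e for e in sub if e.condition == cond]
            counts[(stem, cond)] = len(evs)
            durations[(stem, cond)] = float(sum(e.duration for e in evs))
    return SubjectSummary(
        subject_id=labeled.subject_id,
        counts=counts,
        durations=durations,
        valid_time=valid_time,
        order=schedule.order,
    )
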