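"""Core containers for neonatal cardiorespiratory analysis.

A :class:`Recording` bundles the synchronised bedside-monitor channels
(respiratory effort, ECG, heart rate, SpO2), each with its own sampling rate
and a per-sample validity mask.  Detected physiological events (breathing
pauses, desaturations, bradycardias) are carried as :class:`Event` /
:class:`EventList`, assigned to the 6-hour stimulation ON/OFF blocks of a
:class:`StimulationSchedule`, and tallied per subject and condition in a
:class:`SubjectSummary`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical channel roles
RESP, ECG, HR, SPO2 = "resp", "ecg", "hr", "spo2"

#: event types
PAUSE_SHORT, PAUSE_LONG, DESAT, BRADY = "pause_short", "pause_long", "desat", "brady"

ON, OFF = "ON", "OFF"

#: the seven outcome categories reported per condition: (event type, threshold label)
OUTCOMES: tuple[tuple[str, str | None], ...] = (
    (PAUSE_SHORT, None),
    (PAUSE_LONG, None),
    (DESAT, "<90"),
    (DESAT, "<88"),
    (DESAT, "<85"),
    (BRADY, "<110"),
    (BRADY, "<100"),
)


def outcome_stem(event_type: str, threshold_label: str | None) -> str:
    """Column-name stem for an outcome, e.g. ``desat_lt90`` or ``pause_long``."""
    if threshold_label is None:
        return event_type
    return f"{event_type}_lt{threshold_label.lstrip('<')}"


@dataclass
class Channel:
    """One monitor channel: samples, sampling rate (Hz) and validity mask."""

    data: np.ndarray
    rate: float
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("channel data must be 1-D")
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")
        if self.valid is None:
            self.valid = np.isfinite(self.data)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.data.shape:
            raise ValueError("valid mask and data must have equal length")

    @property
    def n(self) -> int:
        return self.data.size

    @property
    def duration(self) -> float:
        """Channel span in seconds."""
        return self.n / self.rate

    def times(self, start_time: float = 0.0) -> np.ndarray:
        return start_time + np.arange(self.n) / self.rate

    def valid_seconds(self) -> float:
        return float(self.valid.sum()) / self.rate


@dataclass
class Recording:
    """Synchronised multichannel recording for one subject.

    Channel roles are drawn from {``resp``, ``ecg``, ``hr``, ``spo2``}.  Time is
    seconds from recording start; ``start_time`` is an offset applied to all
    derived event onsets.  SpO2 must lie in [0, 100] and HR must be positive
    wherever the mask says the sample is valid.
    """

    channels: dict[str, Channel]
    start_time: float = 0.0
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        for role, ch in self.channels.items():
            if role == SPO2:
                v = ch.data[ch.valid]
                if v.size and ((v < 0).any() or (v > 100).any()):
                    raise ValueError("valid SpO2 samples must lie in [0, 100]")
            if role == HR:
                v = ch.data[ch.valid]
                if v.size and (v <= 0).any():
                    raise ValueError("valid HR samples must be positive")

    def __getitem__(self, role: str) -> Channel:
        return self.channels[role]

    def __contains__(self, role: str) -> bool:
        return role in self.channels

    @property
    def duration(self) -> float:
        return max(ch.duration for ch in self.channels.values())


@dataclass(frozen=True)
class Event:
    """A detected physiological event.

    ``threshold_label`` is ``"<90"``/``"<88"``/``"<85"`` for desaturations,
    ``"<110"``/``"<100"`` for bradycardias and ``None`` for pauses.  Onset and
    duration are seconds; ``condition`` is filled in by block assignment.
    """

    type: str
    onset: float
    duration: float
    threshold_label: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("event duration must be positive")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class EventList:
    """Events for one subject, kept sorted by onset."""

    subject_id: str = "S00"
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.onset, e.type))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EventList)
            and self.subject_id == other.subject_id
            and self.events == other.events
        )

    def extend(self, events) -> None:
        self.events = sorted(
            list(self.events) + list(events), key=lambda e: (e.onset, e.type)
        )

    def sublist(self, type: str, threshold_label: str | None = None) -> "EventList":
        """Events of one (type, threshold) category, e.g. the ``<90`` desats."""
        return EventList(
            self.subject_id,
            [
                e
                for e in self.events
                if e.type == type
                and (threshold_label is None or e.threshold_label == threshold_label)
            ],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "type": [e.type for e in self.events],
                "threshold_label": [
                    "" if e.threshold_label is None else e.threshold_label
                    for e in self.events
                ],
                "onset_s": [e.onset for e in self.events],
                "duration_s": [e.duration for e in self.events],
                "condition": [
                    "" if e.condition is None else e.condition for e in self.events
                ],
            },
            columns=[
                "subject_id",
                "type",
                "threshold_label",
                "onset_s",
                "duration_s",
                "condition",
            ],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventList":
        subject = str(df["subject_id"].iloc[0]) if len(df) else "S00"
        events = [
            Event(
                type=row.type,
                onset=float(row.onset_s),
                duration=float(row.duration_s),
                threshold_label=(row.threshold_label or None),
                condition=(row.condition or None),
            )
            for row in df.itertuples()
        ]
        return cls(subject, events)


@dataclass
class StimulationSchedule:
    """Ordered contiguous stimulation blocks covering the study window.

    The study design is four 6-hour blocks over 24 h, alternating ON/OFF with
    the starting condition decided by coin flip, giving 12 h per condition.
    """

    blocks: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("schedule must contain at least one block")
        for (s0, e0, c0), (s1, e1, c1) in zip(self.blocks, self.blocks[1:]):
            if not np.isclose(e0, s1):
                raise ValueError("blocks must be contiguous and non-overlapping")
        for s, e, c in self.blocks:
            if e <= s:
                raise ValueError("block end must exceed start")
            if c not in (ON, OFF):
                raise ValueError(f"block condition must be ON or OFF, got {c!r}")

    @classmethod
    def standard(
        cls,
        order: str = "off_first",
        block_hours: float = 6.0,
        n_blocks: int = 4,
        start: float = 0.0,
    ) -> "StimulationSchedule":
        """The study's alternating schedule: ``order`` is ``on_first`` or ``off_first``."""
        if order not in ("on_first", "off_first"):
            raise ValueError("order must be 'on_first' or 'off_first'")
        first, second = (ON, OFF) if order == "on_first" else (OFF, ON)
        blocks = []
        t = start
        for i in range(n_blocks):
            cond = first if i % 2 == 0 else second
            blocks.append((t, t + block_hours * 3600.0, cond))
            t += block_hours * 3600.0
        return cls(blocks)

    @property
    def order(self) -> str:
        return "on_first" if self.blocks[0][2] == ON else "off_first"

    @property
    def span(self) -> tuple[float, float]:
        return self.blocks[0][0], self.blocks[-1][1]

    def condition_at(self, t: float) -> str:
        start, end = self.span
        if not (start <= t < end) and not np.isclose(t, end):
            raise ValueError(f"time {t} s outside schedule span [{start}, {end}]")
        for s, e, c in self.blocks:
            if s <= t < e:
                return c
        return self.blocks[-1][2]

    def condition_mask(self, times: np.ndarray, condition: str) -> np.ndarray:
        """Boolean mask of which sample times fall in blocks of ``condition``."""
        out = np.zeros(times.shape, dtype=bool)
        for s, e, c in self.blocks:
            if c == condition:
                out |= (times >= s) & (times < e)
        return out


@dataclass
class SubjectSummary:
    """Per-subject, per-condition counts and total durations for every outcome.

    ``counts[(stem, condition)]`` and ``durations[(stem, condition)]`` with
    ``stem`` from :func:`outcome_stem`; ``valid_time[condition]`` is the
    artifact-free monitored time in seconds, so rates can be compared when
    artifact time differs between conditions.
    """

    subject_id: str
    counts: dict[tuple[str, str], int]
    durations: dict[tuple[str, str], float]
    valid_time: dict[str, float]
    order: str = "off_first"

    def to_row(self) -> dict:
        row: dict = {"subject_id": self.subject_id, "order": self.order}
        for etype, thr in OUTCOMES:
            stem = outcome_stem(etype, thr)
            for cond in (OFF, ON):
                row[f"{stem}_count_{cond.lower()}"] = self.counts[(stem, cond)]
                row[f"{stem}_dur_{cond.lower()}"] = self.durations[(stem, cond)]
        row["valid_time_off"] = self.valid_time[OFF]
        row["valid_time_on"] = self.valid_time[ON]
        return row
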