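"""Reading and writing recordings, event lists and cohort tables.

Recordings come in two formats:

* **EDF/EDF+** — read through :mod:`mne`.  A minimal 16-bit EDF writer is
  provided so that synthetic recordings can be round-tripped; it writes one
  data record per second with all channels at the highest channel rate.
* **CSV bundle** — one CSV per channel with columns ``time_s,value[,valid]``
  plus a YAML manifest mapping channel roles to files.  NICU monitor exports
  vary widely; the bundle is the permissive interchange format.

Cohort tables (one row per subject with per-condition counts and durations for
every outcome) are CSV or XLSX with the column layout of
:meth:`~apnealab.core.SubjectSummary.to_row`.  Event lists are CSV, ordered by
onset.  Physically impossible samples (SpO2 outside [0, 100], non-positive HR)
are masked invalid, never imputed or dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    HR,
    OUTCOMES,
    RESP,
    SPO2,
    Channel,
    EventList,
    Recording,
    SubjectSummary,
    outcome_stem,
)

#: columns a cohort table must provide, besides subject_id
COHORT_VALUE_COLUMNS = tuple(
    f"{outcome_stem(et, th)}_{kind}_{cond}"
    for et, th in OUTCOMES
    for kind in ("count", "dur")
    for cond in ("off", "on")
)

_PHYSICAL_RANGE = {SPO2: (0.0, 100.0), HR: (0.0, 300.0)}


def _mask_physical(role: str, data: np.ndarray, valid: np.ndarray) -> np.ndarray:
    valid = valid & np.isfinite(data)
    if role in _PHYSICAL_RANGE:
        lo, hi = _PHYSICAL_RANGE[role]
        valid = valid & (data >= lo) & (data <= hi)
        if role == HR:
            valid &= data > 0
    return valid


@dataclass
class CohortTable:
    """Validated per-subject, per-condition outcome table (the cohort unit of analysis)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise ValueError("cohort table is empty")
        if "subject_id" not in self.df.columns:
            raise ValueError("cohort table must have a subject_id column")
        missing = [c for c in COHORT_VALUE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort table missing outcome columns: {missing}")
        if self.df["subject_id"].duplicated().any():
            dups = self.df.loc[self.df["subject_id"].duplicated(), "subject_id"]
            raise ValueError(f"duplicate subject ids: {sorted(set(dups))}")
        vals = self.df[list(COHORT_VALUE_COLUMNS)]
        if (vals.to_numpy(dtype=float) < 0).any():
            raise ValueError("counts and durations must be non-negative")
        count_cols = [c for c in COHORT_VALUE_COLUMNS if "_count_" in c]
        cnt = self.df[count_cols].to_numpy(dtype=float)
        if not np.allclose(cnt, np.round(cnt)):
            raise ValueError("event counts must be integers")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    def column(self, outcome_stem_: str, kind: str, condition: str) -> np.ndarray:
        """Vector of one outcome across subjects, e.g. ('pause_long','count','off')."""
        return self.df[f"{outcome_stem_}_{kind}_{condition.lower()}"].to_numpy(float)

    @classmethod
    def from_summaries(cls, summaries: list[SubjectSummary]) -> "CohortTable":
        return cls(pd.DataFrame([s.to_row() for s in summaries]))


def read_cohort_table(path, column_map: dict[str, str] | None = None) -> CohortTable:
    """Read a cohort table from CSV or XLSX.

    ``column_map`` renames source headers to the canonical names (reported by
    header name on mismatch).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        unknown = [c for c in column_map if c not in df.columns]
        if unknown:
            raise ValueError(f"column_map names headers not in file: {unknown}")
        df = df.rename(columns=column_map)
    return CohortTable(df)


def write_cohort_table(cohort: CohortTable, path) -> Path:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        cohort.df.to_excel(path, index=False)
    else:
        cohort.df.to_csv(path, index=False)
    return path


def write_events(events: EventList, path) -> Path:
    """Write an event list as CSV, one row per event, sorted by onset."""
    path = Path(path)
    events.to_frame().to_csv(path, index=False, float_format="%.6f")
    return path


def read_events(path) -> EventList:
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"threshold_label": str, "condition": str}, keep_default_na=False
    )
    return EventList.from_frame(df)


# ---------------------------------------------------------------------------
# CSV bundle
# ---------------------------------------------------------------------------

def write_csv_bundle(recording: Recording, directory) -> Path:
    """Write one CSV per channel plus a YAML manifest naming the roles."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subject_id": recording.subject_id,
        "start_time": float(recording.start_time),
        "channels": {},
    }
    for role, ch in recording.channels.items():
        fname = f"{role}.csv"
        df = pd.DataFrame(
            {
                "time_s": ch.times(),
                "value": ch.data,
                "valid": ch.valid.astype(int),
            }
        )
        df.to_csv(directory / fname, index=False, float_format="%.7g")
        manifest["channels"][role] = {"file": fname, "rate": float(ch.rate)}
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return directory


def _read_csv_bundle(directory: Path) -> Recording:
    mpath = directory / "manifest.yaml"
    if not mpath.exists():
        raise FileNotFoundError(f"CSV bundle manifest not found: {mpath}")
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)
    channels = {}
    for role, info in manifest["channels"].items():
        df = pd.read_csv(directory / info["file"])
        data = df["value"].to_numpy(float)
        valid = (
            df["valid"].to_numpy(bool)
            if "valid" in df.columns
            else np.ones(data.size, dtype=bool)
        )
        valid = _mask_physical(role, data, valid)
        data = np.where(valid, data, np.nan)
        channels[role] = Channel(data, float(info["rate"]), valid)
    return Recording(
        channels,
        start_time=float(manifest.get("start_time", 0.0)),
        subject_id=str(manifest.get("subject_id", "S00")),
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_PHYS = {
    RESP: (-10.0, 10.0),
    "ecg": (-5.0, 5.0),
    HR: (0.0, 300.0),
    SPO2: (0.0, 100.0),
}


def write_edf(recording: Recording, path) -> Path:
    """Write a recording as 16-bit EDF (one data record per second).

    All channels are written at the highest channel rate; slower trend
    channels (heart rate, SpO2) are upsampled by sample-and-hold, which keeps
    threshold crossings where they were (EDF readers commonly interpolate
    mixed-rate files, which distorts step-like trends).  Invalid samples are
    written clipped to the physical range (EDF has no mask), so prefer the
    CSV bundle when artifact masks must survive a round trip.
    """
    path = Path(path)
    roles = list(recording.channels)
    n_sig = len(roles)
    rates = {r: recording.channels[r].rate for r in roles}
    top = max(rates.values())
    if abs(top - round(top)) > 1e-9:
        raise ValueError(f"EDF writer needs an integer top rate in Hz, got {top}")
    channels = {}
    for role in roles:
        ch = recording.channels[role]
        factor = top / ch.rate
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError(
                f"channel rate {ch.rate} Hz does not divide the top rate {top} Hz"
            )
        factor = int(round(factor))
        if factor == 1:
            channels[role] = ch
        else:
            channels[role] = Channel(
                np.repeat(ch.data, factor), top, np.repeat(ch.valid, factor)
            )
    spr = {role: int(round(top)) for role in roles}
    n_records = int(min(ch.n / ch.rate for ch in channels.values()))
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad(recording.subject_id, 80),
            pad("apnealab", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_sig)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(n_sig), 4),
        ]
    )
    phys = {r: _EDF_PHYS.get(r, (-1000.0, 1000.0)) for r in roles}
    sig_header = b"".join(
        [pad(r.upper(), 16) for r in roles]
        + [pad("", 80) for _ in roles]
        + [pad("", 8) for _ in roles]
        + [pad(f"{phys[r][0]:g}", 8) for r in roles]
        + [pad(f"{phys[r][1]:g}", 8) for r in roles]
        + [pad("-32768", 8) for _ in roles]
        + [pad("32767", 8) for _ in roles]
        + [pad("", 80) for _ in roles]
        + [pad(str(spr[r]), 8) for r in roles]
        + [pad("", 32) for _ in roles]
    )
    digitized = {}
    for r in roles:
        ch = channels[r]
        lo, hi = phys[r]
        x = np.clip(np.where(ch.valid, ch.data, lo), lo, hi)
        d = np.round((x - lo) / (hi - lo) * 65535.0 - 32768.0).astype("<i2")
        digitized[r] = d
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for rec in range(n_records):
            for r in roles:
                n = spr[r]
                fh.write(digitized[r][rec * n : (rec + 1) * n].tobytes())
    return path


def _read_edf(path: Path, subject_id: str | None = None) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    channels = {}
    for name in raw.ch_names:
        role = name.strip().lower()
        data = raw.get_data(picks=[name])[0]
        rate = float(raw.info["sfreq"])
        if role == SPO2:
            data = data * 1.0  # mne returns physical units already for EDF
        valid = _mask_physical(role, data, np.ones(data.size, dtype=bool))
        channels[role] = Channel(np.where(valid, data, np.nan), rate, valid)
    sid = subject_id or (raw.info.get("subject_info") or {}).get("his_id") or path.stem
    return Recording(channels, subject_id=str(sid))


def read_recording(
    path,
    format: str | None = None,
    require: tuple[str, ...] = (RESP, SPO2),
    subject_id: str | None = None,
) -> Recording:
    """Read a multichannel recording from EDF or a CSV-bundle directory.

    ``require`` lists mandatory channel roles; the respiratory channel, SpO2
    and at least one of ECG/HR are needed for the full analysis.  A missing
    mandatory role is a hard error naming the role.  Unreadable/implausible
    samples are masked invalid, never dropped, so valid + invalid sample
    counts always equal the file length.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv-bundle" if path.is_dir() else "edf"
    if format == "edf":
        rec = _read_edf(path, subject_id)
    elif format in ("csv", "csv-bundle"):
        rec = _read_csv_bundle(path)
    else:
        raise ValueError(f"unknown recording format {format!r}")
    missing = [r for r in require if r not in rec]
    if missing:
        raise ValueError(f"recording is missing mandatory channel role(s): {missing}")
    if require and RESP in require and not ({"ecg", HR} & set(rec.channels)):
        raise ValueError(
            "recording must contain at least one of the 'ecg' or 'hr' channel roles"
        )
    if subject_id:
        rec.subject_id = subject_id
    return rec
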