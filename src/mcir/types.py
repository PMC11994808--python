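"""Core data containers shared across the pipeline.

A :class:`BiosignalSeries` is the universal input: a timestamped 1-minute
multichannel feature stream for one individual.  Channels may be missing
(NaN) per record; quality filters null out values rather than dropping
rows, so timestamps stay aligned across channels.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: The five modeled physiologic channels, in canonical order.
CHANNELS = ("hr", "hrv", "rr", "activity", "skin_temp")

#: All value columns of a biosignal record (channels plus signal quality).
COLUMNS = CHANNELS + ("sqi",)


@dataclass
class BiosignalSeries:
    """One individual's 1-minute multichannel biosignal stream.

    Parameters
    ----------
    participant_id
        Opaque participant identifier.
    data
        Frame with a ``timestamp`` column (naive datetimes, strictly
        increasing) and float columns ``hr`` (bpm), ``hrv`` (s), ``rr``
        (breaths/min), ``activity`` (g), ``skin_temp`` (degC), ``sqi``
        (0-1).  NaN marks a missing value for that channel at that minute.
    """

    participant_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        ts = pd.to_datetime(self.data["timestamp"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")
        sqi = self.data["sqi"].dropna()
        if len(sqi) and ((sqi < 0).any() or (sqi > 1).any()):
            raise ValueError("sqi must lie in [0, 1]")
        self.data = self.data.assign(timestamp=ts).reset_index(drop=True)

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        ts = self.data["timestamp"]
        return ts.iloc[0], ts.iloc[-1]

    def copy(self) -> "BiosignalSeries":
        return BiosignalSeries(self.participant_id, self.data.copy())

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        """Write as CSV with ISO-8601 timestamps."""
        out = self.data.copy()
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(path, index=False, float_format="%.6g",
                   columns=["timestamp", *COLUMNS])

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase,
                 participant_id: str | None = None) -> "BiosignalSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        if participant_id is None:
            participant_id = Path(str(path)).stem if not isinstance(
                path, io.TextIOBase) else "unknown"
        return cls(participant_id, df[["timestamp", *COLUMNS]])


@dataclass(frozen=True)
class DoseEvent:
    """A recorded vaccine administration for one participant."""

    participant_id: str
    dose_time: pd.Timestamp
    dose_number: int = 1
    vaccine_label: str = ""

    def __post_init__(self) -> None:
        if self.dose_number < 1:
            raise ValueError("dose_number must be >= 1")
        object.__setattr__(self, "dose_time", pd.Timestamp(self.dose_time))


def read_dose_events(path: str | Path) -> list[DoseEvent]:
    """Read dose events from CSV ``participant_id,dose_time,dose_number,vaccine_label``."""
    df = pd.read_csv(path, parse_dates=["dose_time"])
    return [
        DoseEvent(str(r.participant_id), r.dose_time, int(r.dose_number),
                  str(getattr(r, "vaccine_label", "")))
        for r in df.itertuples(index=False)
    ]


def write_dose_events(events: Iterable[DoseEvent], path: str | Path) -> None:
    rows = [
        {
            "participant_id": e.participant_id,
            "dose_time": e.dose_time.strftime("%Y-%m-%dT%H:%M:%S"),
            "dose_number": e.dose_number,
            "vaccine_label": e.vaccine_label,
        }
        for e in events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def minutes_grid(start: pd.Timestamp, n_minutes: int) -> pd.DatetimeIndex:
    """A 1-minute cadence timestamp grid of length ``n_minutes``."""
    return pd.date_range(start, periods=n_minutes, freq="min")


def as_float_array(x: Iterable[float]) -> np.ndarray:
    return np.asarray(list(x) if not isinstance(x, np.ndarray) else x,
                      dtype=float)
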