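"""Per-dose reactogenicity summaries from an MCIR series.

The AUC Total Response is the MCIR area accumulated in the fixed 72-hour
post-dose window as a fraction of the maximal rectangular area A_T = 72 h
x 1.0.  A detectable response requires (a) some 6-hour sliding window in
which at least 50% of 15-minute steps exceed 0.10 and (b) a persistent
non-zero trend of more than one hour (>= 5 consecutive non-zero blocks)
anywhere in the 72-hour window.  Missing blocks count as zero everywhere
(missing data can never create a response); the number of valid blocks is
reported for audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from mcir.index import BLOCK_MINUTES, MCIRSeries

WINDOW_H = 72
SLIDE_WINDOW_H = 6
DETECT_THRESHOLD = 0.10     # strict >
WINDOW_FRACTION = 0.5
PERSISTENCE_BLOCKS = 5      # > 1 h at 15-min cadence

N_BLOCKS = WINDOW_H * 60 // BLOCK_MINUTES          # 288
WINDOW_BLOCKS = SLIDE_WINDOW_H * 60 // BLOCK_MINUTES  # 24


def _post_dose_values(mcir: MCIRSeries, dose_time: pd.Timestamp,
                      window_h: float = WINDOW_H) -> np.ndarray:
    """Align the post-dose window onto a fixed-length block array.

    The MCIR grid must be anchored at the dose time (block edges at
    dose_time + 15k minutes).  Blocks absent from the series are NaN.
    """
    dose_time = pd.Timestamp(dose_time)
    n_blocks = int(round(window_h * 60 / BLOCK_MINUTES))
    offset_min = (mcir.block_start - dose_time) / pd.Timedelta(minutes=1)
    offset = np.asarray(offset_min, dtype=float) / BLOCK_MINUTES
    idx = np.round(offset).astype(int)
    if np.abs(offset - idx).max() > 1e-9:
        raise ValueError("MCIR block grid is not anchored at dose_time")
    out = np.full(n_blocks, np.nan)
    inside = (idx >= 0) & (idx < n_blocks)
    out[idx[inside]] = mcir.values[inside]
    if np.isnan(out).all():
        raise ValueError("MCIR series covers no block of the post-dose window")
    return out


def total_response(mcir: MCIRSeries, dose_time: pd.Timestamp,
                   window_h: float = WINDOW_H) -> float:
    """AUC Total Response A_i/A_T over the fixed post-dose window."""
    v = _post_dose_values(mcir, dose_time, window_h)
    a_i = np.nansum(v) * BLOCK_MINUTES  # minute-units of area
    a_t = window_h * 60.0
    return float(a_i / a_t)


def _qualifying_window_starts(v0: np.ndarray) -> np.ndarray:
    """Start indices of 6-h windows with >= 50% of blocks above threshold."""
    above = (v0 > DETECT_THRESHOLD).astype(int)
    if len(above) < WINDOW_BLOCKS:
        return np.array([], dtype=int)
    counts = np.convolve(above, np.ones(WINDOW_BLOCKS, dtype=int), "valid")
    need = int(np.ceil(WINDOW_FRACTION * WINDOW_BLOCKS))
    return np.flatnonzero(counts >= need)


def _max_nonzero_run(v0: np.ndarray) -> int:
    nz = v0 > 0
    best = run = 0
    for x in nz:
        run = run + 1 if x else 0
        best = max(best, run)
    return best


def detectable_response(mcir: MCIRSeries, dose_time: pd.Timestamp
                        ) -> tuple[bool, list[pd.Timestamp]]:
    """Classify the 72-h post-dose window as a detectable response.

    Returns the flag and the start times of all qualifying 6-h windows.
    """
    dose_time = pd.Timestamp(dose_time)
    v0 = np.nan_to_num(_post_dose_values(mcir, dose_time))
    starts = _qualifying_window_starts(v0)
    persistent = _max_nonzero_run(v0) >= PERSISTENCE_BLOCKS
    detectable = bool(len(starts) > 0 and persistent)
    times = [dose_time + pd.Timedelta(minutes=int(s) * BLOCK_MINUTES)
             for s in starts]
    return detectable, times


def onset_offset(mcir: MCIRSeries, dose_time: pd.Timestamp
                 ) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Onset/offset of the detectable response.

    Onset is the start of the first above-threshold block inside the
    earliest qualifying window; offset is the end of the last
    above-threshold block inside the latest qualifying window.
    """
    dose_time = pd.Timestamp(dose_time)
    v0 = np.nan_to_num(_post_dose_values(mcir, dose_time))
    starts = _qualifying_window_starts(v0)
    persistent = _max_nonzero_run(v0) >= PERSISTENCE_BLOCKS
    if len(starts) == 0 or not persistent:
        raise ValueError("onset_offset requires a detectable response")
    step = pd.Timedelta(minutes=BLOCK_MINUTES)
    first_win = v0[starts[0]:starts[0] + WINDOW_BLOCKS]
    i_on = starts[0] + int(np.flatnonzero(first_win > DETECT_THRESHOLD)[0])
    last_win = v0[starts[-1]:starts[-1] + WINDOW_BLOCKS]
    i_off = starts[-1] + int(np.flatnonzero(last_win > DETECT_THRESHOLD)[-1])
    return dose_time + i_on * step, dose_time + (i_off + 1) * step


@dataclass
class ResponseSummary:
    """Per-dose reactogenicity outputs."""

    participant_id: str
    dose_number: int
    auc_total: float
    detectable: bool
    onset: pd.Timestamp | None
    offset: pd.Timestamp | None
    n_blocks_valid: int

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "dose_number": self.dose_number,
            "auc_total": self.auc_total,
            "detectable": self.detectable,
            "onset": self.onset.isoformat() if self.onset is not None else None,
            "offset": self.offset.isoformat() if self.offset is not None else None,
            "n_blocks_valid": self.n_blocks_valid,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def summarize_response(mcir: MCIRSeries, dose_time: pd.Timestamp,
                       dose_number: int = 1) -> ResponseSummary:
    """Compute all per-dose outputs for one MCIR series."""
    v = _post_dose_values(mcir, dose_time)
    auc = total_response(mcir, dose_time)
    detectable, _ = detectable_response(mcir, dose_time)
    onset = offset = None
    if detectable:
        onset, offset = onset_offset(mcir, dose_time)
    return ResponseSummary(mcir.participant_id, dose_number, auc, detectable,
                           onset, offset, int((~np.isnan(v)).sum()))
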