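"""Quality filtering, 48-h baseline z-scoring and 3-h uni-parametric analysis.

Single-channel change detection works on z-scores relative to each
individual's 48-hour pre-dose baseline, aggregated into contiguous 3-hour
bins anchored at the dose time; a channel is flagged when any post-dose
bin deviates by at least one baseline SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mcir.types import BiosignalSeries, CHANNELS

log = logging.getLogger(__name__)

SQI_THRESHOLD = 0.9          # cardiorespiratory channels kept where sqi > 0.9
TEMP_BOUNDS = (33.0, 42.0)   # degC, inclusive; outside is ignored
BASELINE_HOURS = 48
MIN_BASELINE_SAMPLES = 60
#: ECG-derived channels subject to the SQI filter (activity and skin
#: temperature are not ECG-based and are never SQI-filtered).
SQI_CHANNELS = ("hr", "hrv", "rr")


def filter_uniparametric(series: BiosignalSeries) -> BiosignalSeries:
    """Apply the single-channel quality filters.

    HR/HRV/RR are retained only where SQI > 0.9 (strict); skin temperature
    only within [33, 42] degC; activity passes through untouched.  Values
    are nulled, never altered, and rows are kept so timestamps stay
    aligned.
    """
    out = series.data.copy()
    good_sqi = out["sqi"] > SQI_THRESHOLD
    for ch in SQI_CHANNELS:
        out.loc[~good_sqi.fillna(False), ch] = np.nan
    lo, hi = TEMP_BOUNDS
    bad_temp = ~out["skin_temp"].between(lo, hi)
    out.loc[bad_temp, "skin_temp"] = np.nan
    return BiosignalSeries(series.participant_id, out)


@dataclass
class ZScoredSeries:
    """Per-channel z-scores relative to a 48-h pre-dose baseline."""

    participant_id: str
    dose_time: pd.Timestamp
    data: pd.DataFrame = field(repr=False)   # timestamp + z per channel
    baseline_mean: dict[str, float] = field(default_factory=dict)
    baseline_sd: dict[str, float] = field(default_factory=dict)
    valid_channels: tuple[str, ...] = ()


def zscore_baseline(series: BiosignalSeries, dose_time: pd.Timestamp,
                    min_samples: int = MIN_BASELINE_SAMPLES) -> ZScoredSeries:
    """Z-score each channel against its 48-h pre-dose mean and SD.

    A channel with fewer than ``min_samples`` valid baseline minutes, or a
    degenerate (zero-SD) baseline, is marked invalid and excluded
    downstream; no exception is raised.
    """
    dose_time = pd.Timestamp(dose_time)
    df = series.data
    in_baseline = (df["timestamp"] >= dose_time - pd.Timedelta(hours=BASELINE_HOURS)) \
        & (df["timestamp"] < dose_time)
    out = pd.DataFrame({"timestamp": df["timestamp"]})
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    valid: list[str] = []
    for ch in CHANNELS:
        base = df.loc[in_baseline, ch].dropna()
        if len(base) < min_samples:
            log.warning("%s: channel %s has %d baseline samples (<%d); invalid",
                        series.participant_id, ch, len(base), min_samples)
            out[ch] = np.nan
            continue
        mu, sd = float(base.mean()), float(base.std(ddof=1))
        # relative tolerance: a numerically-constant channel is degenerate
        if not np.isfinite(sd) or sd <= 1e-10 * max(1.0, abs(mu)):
            log.warning("%s: channel %s has degenerate baseline SD; invalid",
                        series.participant_id, ch)
            out[ch] = np.nan
            continue
        means[ch], sds[ch] = mu, sd
        out[ch] = (df[ch] - mu) / sd
        valid.append(ch)
    return ZScoredSeries(series.participant_id, dose_time, out,
                         means, sds, tuple(valid))


@dataclass
class ThreeHourAggregates:
    """Mean z-score per channel in contiguous 3-h bins anchored at the dose."""

    participant_id: str
    dose_time: pd.Timestamp
    data: pd.DataFrame = field(repr=False)   # bin_start + per-channel z_mean
    baseline_mean: dict[str, float] = field(default_factory=dict)
    baseline_sd: dict[str, float] = field(default_factory=dict)
    valid_channels: tuple[str, ...] = ()


def aggregate_3h(zscored: ZScoredSeries,
                 window: tuple[pd.Timestamp, pd.Timestamp] | None = None
                 ) -> ThreeHourAggregates:
    """Aggregate z-scored minutes into 3-h bins (edges at dose_time + 3k h).

    Bin value is the arithmetic mean of valid z-scored 1-min values; bins
    with no valid sample are NaN.  Anchoring at the dose time guarantees
    no bin straddles the dose.
    """
    df = zscored.data
    if window is not None:
        start, end = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
        if end <= start:
            raise ValueError("window must be non-empty")
        df = df[(df["timestamp"] >= start) & (df["timestamp"] < end)]
    bin_h = pd.Timedelta(hours=3)
    offset = (df["timestamp"] - zscored.dose_time) // bin_h
    # floor-divide of negative offsets already bins pre-dose data correctly
    grouped = df[list(CHANNELS)].groupby(offset.to_numpy()).mean()
    grouped.index = [zscored.dose_time + int(k) * bin_h for k in grouped.index]
    agg = grouped.rename_axis("bin_start").reset_index()
    return ThreeHourAggregates(zscored.participant_id, zscored.dose_time, agg,
                               zscored.baseline_mean, zscored.baseline_sd,
                               zscored.valid_channels)


def detect_uniparam_change(aggregates: ThreeHourAggregates,
                           dose_time: pd.Timestamp | None = None,
                           post_window_h: float = 96.0) -> dict[str, bool]:
    """Flag each channel whose post-dose 3-h aggregates deviate by >= 1 SD.

    Two-sided: a channel is flagged iff any bin starting in
    [dose_time, dose_time + post_window_h) has ``|z_mean| >= 1``.  Only
    channels with a valid baseline can be flagged.
    """
    dose_time = pd.Timestamp(dose_time) if dose_time is not None \
        else aggregates.dose_time
    df = aggregates.data
    post = df[(df["bin_start"] >= dose_time)
              & (df["bin_start"] < dose_time + pd.Timedelta(hours=post_window_h))]
    if post.empty:
        raise ValueError("no post-dose 3-h bins in the scan window")
    flags: dict[str, bool] = {}
    for ch in CHANNELS:
        if ch not in aggregates.valid_channels:
            flags[ch] = False
            continue
        vals = post[ch].dropna()
        flags[ch] = bool((vals.abs() >= 1.0).any())
    return flags
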