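"""Synthetic wearable-cohort generator with ground-truth vaccine responses.

Emulates torso-patch physiology at 1-minute cadence: circadian rhythm in
heart rate and skin temperature, daytime activity bouts that raise HR and
respiration and depress HRV, AR(1)-persistent sensor noise, ECG
signal-quality (SQI) dropout episodes, and short wear gaps.  A vaccine
response is injected additively as a piecewise-linear envelope (zero at
onset, one at peak, zero at offset) scaled per channel, and each injection
is recorded as ground truth together with downstream symptom and
immunogenicity labels whose links to the true magnitude are stated and
therefore recoverable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from mcir.types import BiosignalSeries, CHANNELS, minutes_grid

# Per-channel marginal noise SDs at the 1-minute scale (native units).
NOISE_SD = {"hr": 2.5, "hrv": 0.008, "rr": 0.8, "activity": 0.004,
            "skin_temp": 0.12}
#: AR(1) persistence of the 1-minute noise; gives 48-h baselines realistic
#: autocorrelation so twin residuals are not trivially white.
AR1_COEF = 0.9

# Couplings: HR gain per g of activity, HRV loss per bpm of HR excess,
# RR gain per g and per bpm.
HR_PER_G = 60.0
HRV_PER_BPM = 0.0008
RR_PER_G = 15.0
RR_PER_BPM = 0.03
#: Skin-temperature circadian amplitude per bpm of HR circadian amplitude.
TEMP_AMP_PER_HR_AMP = 0.1

REST_ACTIVITY = 0.015  # g, quiet wear baseline
SQI_BASE = 0.97

DEFAULT_EPOCH = pd.Timestamp("2021-01-04 00:00:00")

PHYSIOLOGIC_BOUNDS = {
    "hr": (30.0, 220.0),
    "hrv": (0.001, 0.5),
    "rr": (4.0, 45.0),
    "activity": (0.0, 3.0),
    "skin_temp": (30.0, 42.0),
}


@dataclass(frozen=True)
class IndividualProfile:
    """Baseline physiology and wear behavior of one simulated individual."""

    participant_id: str = "P000"
    hr_mean: float = 65.0            # bpm
    hr_circadian_amp: float = 3.0    # bpm
    hrv_mean: float = 0.05           # seconds
    rr_mean: float = 14.0            # breaths/min
    skin_temp_mean: float = 35.0     # degC
    activity_day_rate: float = 1.5   # bouts/hour during waking hours
    sqi_dropout_prob: float = 0.03   # fraction of minutes in low-SQI episodes
    rng_seed: int = 0
    noise_scale: float = 1.0         # multiplier on all per-channel noise SDs

    def __post_init__(self) -> None:
        checks = {
            "hr_mean": 40.0 <= self.hr_mean <= 120.0,
            "hrv_mean": self.hrv_mean > 0,
            "rr_mean": 8.0 <= self.rr_mean <= 35.0,
            "skin_temp_mean": 33.0 <= self.skin_temp_mean <= 38.0,
            "sqi_dropout_prob": 0.0 <= self.sqi_dropout_prob <= 1.0,
            "hr_circadian_amp": self.hr_circadian_amp >= 0,
            "activity_day_rate": self.activity_day_rate >= 0,
            "noise_scale": self.noise_scale >= 0,
        }
        for name, ok in checks.items():
            if not ok:
                raise ValueError(f"invalid profile field: {name}")


@dataclass(frozen=True)
class ResponseParams:
    """Shape and per-channel amplitude of an injected vaccine response.

    The temporal envelope g(t) ramps linearly from 0 at ``onset_h`` (hours
    post dose) to 1 at ``peak_h`` and back to 0 at ``onset_h + duration_h``.
    Channel deltas are the peak additive changes in native units; the whole
    response scales with ``magnitude_scale`` (0 = null response).
    """

    onset_h: float = 6.0
    peak_h: float = 24.0
    duration_h: float = 72.0
    delta_hr: float = 4.0        # bpm
    delta_hrv: float = -0.010    # seconds
    delta_rr: float = 1.5        # breaths/min
    delta_temp: float = 0.5      # degC
    delta_activity: float = 0.0  # g
    magnitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.onset_h < self.peak_h
                < self.onset_h + self.duration_h):
            raise ValueError("require 0 <= onset_h < peak_h < onset_h + duration_h")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        if self.magnitude_scale < 0:
            raise ValueError("magnitude_scale must be >= 0")

    @property
    def deltas(self) -> dict[str, float]:
        return {"hr": self.delta_hr, "hrv": self.delta_hrv,
                "rr": self.delta_rr, "activity": self.delta_activity,
                "skin_temp": self.delta_temp}

    def envelope(self, hours_post_dose: np.ndarray) -> np.ndarray:
        """Piecewise-linear envelope g(t) on [0, 1]."""
        t = np.asarray(hours_post_dose, dtype=float)
        up = (t - self.onset_h) / (self.peak_h - self.onset_h)
        end = self.onset_h + self.duration_h
        down = (end - t) / (end - self.peak_h)
        g = np.minimum(up, down)
        return np.clip(g, 0.0, 1.0)


@dataclass
class GroundTruth:
    """What was actually injected for one dose, plus downstream labels."""

    participant_id: str
    dose_time: pd.Timestamp
    true_magnitude: float
    systemic_symptom_label: bool = False
    immunogenicity_value: float = 1.0

    def __post_init__(self) -> None:
        if self.true_magnitude < 0:
            raise ValueError("true_magnitude must be >= 0")
        if self.immunogenicity_value <= 0:
            raise ValueError("immunogenicity_value must be > 0")
        self.dose_time = pd.Timestamp(self.dose_time)

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "dose_time": self.dose_time.strftime("%Y-%m-%dT%H:%M:%S"),
            "true_magnitude": self.true_magnitude,
            "systemic_symptom_label": bool(self.systemic_symptom_label),
            "immunogenicity_value": self.immunogenicity_value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(d["participant_id"], pd.Timestamp(d["dose_time"]),
                   float(d["true_magnitude"]),
                   bool(d["systemic_symptom_label"]),
                   float(d["immunogenicity_value"]))


def _ar1(rng: np.random.Generator, n: int, marginal_sd: float) -> np.ndarray:
    """Stationary AR(1) noise with the requested marginal SD."""
    if marginal_sd == 0:
        return np.zeros(n)
    innov_sd = marginal_sd * np.sqrt(1.0 - AR1_COEF ** 2)
    e = rng.normal(0.0, innov_sd, size=n)
    e[0] = rng.normal(0.0, marginal_sd)  # stationary start
    return lfilter([1.0], [1.0, -AR1_COEF], e)


def _activity_trace(rng: np.random.Generator, index: pd.DatetimeIndex,
                    bouts_per_hour: float) -> np.ndarray:
    """Rest baseline plus daytime (08:00-22:00) activity bouts."""
    n = len(index)
    act = np.full(n, REST_ACTIVITY)
    if bouts_per_hour <= 0:
        return act
    hours = index.hour.to_numpy()
    day = (hours >= 8) & (hours < 22)
    # Expected bout count over the daytime minutes present in the span.
    n_bouts = rng.poisson(bouts_per_hour * day.sum() / 60.0)
    day_idx = np.flatnonzero(day)
    if len(day_idx) == 0 or n_bouts == 0:
        return act
    starts = rng.choice(day_idx, size=n_bouts, replace=True)
    for s in starts:
        dur = int(rng.integers(5, 21))          # minutes
        level = rng.uniform(0.08, 0.25)          # g
        seg = slice(s, min(s + dur, n))
        jitter = rng.uniform(0.8, 1.2, size=seg.stop - seg.start)
        act[seg] = np.maximum(act[seg], level * jitter)
    return act


def _sqi_trace(rng: np.random.Generator, n: int, dropout_prob: float,
               noise_scale: float) -> np.ndarray:
    sqi = SQI_BASE + rng.normal(0.0, 0.01 * noise_scale, size=n)
    if dropout_prob > 0:
        mean_dur = 30.0  # minutes per low-quality episode
        n_episodes = rng.poisson(dropout_prob * n / mean_dur)
        for _ in range(n_episodes):
            s = int(rng.integers(0, n))
            dur = int(rng.integers(10, 61))
            sqi[s:s + dur] = rng.uniform(0.0, 0.85)
    return np.clip(sqi, 0.0, 1.0)


def simulate_individual(profile: IndividualProfile, duration_days: int,
                        start: pd.Timestamp = DEFAULT_EPOCH) -> BiosignalSeries:
    """Simulate one individual's baseline (pre-dose) biosignal stream.

    Fully deterministic given ``profile.rng_seed``.  HR carries a 24-h
    sinusoid (peak late afternoon) and rises with activity; HRV falls as HR
    rises; skin temperature carries a 24-h sinusoid (trough early morning).
    A small fraction of minutes is removed entirely to emulate wear gaps.
    """
    if duration_days < 1:
        raise ValueError("duration_days must be >= 1")
    rng = np.random.default_rng(profile.rng_seed)
    n = int(duration_days * 1440)
    index = minutes_grid(pd.Timestamp(start), n)
    hour_of_day = (index - index.normalize()) / pd.Timedelta(hours=1)
    hod = np.asarray(hour_of_day, dtype=float)

    ns = profile.noise_scale
    noise = {c: _ar1(rng, n, NOISE_SD[c] * ns) for c in CHANNELS}

    activity = _activity_trace(rng, index, profile.activity_day_rate)
    activity = activity + noise["activity"]
    act_excess = np.maximum(activity - REST_ACTIVITY, 0.0)

    circ = np.sin(2 * np.pi * (hod - 10.0) / 24.0)  # peaks at 16:00
    hr = (profile.hr_mean + profile.hr_circadian_amp * circ
          + HR_PER_G * act_excess + noise["hr"])
    hrv = profile.hrv_mean - HRV_PER_BPM * (hr - profile.hr_mean) + noise["hrv"]
    rr = (profile.rr_mean + RR_PER_G * act_excess
          + RR_PER_BPM * (hr - profile.hr_mean) + noise["rr"])
    temp_amp = TEMP_AMP_PER_HR_AMP * profile.hr_circadian_amp
    skin_temp = (profile.skin_temp_mean + temp_amp * circ + noise["skin_temp"])
    sqi = _sqi_trace(rng, n, profile.sqi_dropout_prob, ns)

    df = pd.DataFrame({
        "timestamp": index,
        "hr": np.clip(hr, *PHYSIOLOGIC_BOUNDS["hr"]),
        "hrv": np.clip(hrv, *PHYSIOLOGIC_BOUNDS["hrv"]),
        "rr": np.clip(rr, *PHYSIOLOGIC_BOUNDS["rr"]),
        "activity": np.clip(activity, *PHYSIOLOGIC_BOUNDS["activity"]),
        "skin_temp": np.clip(skin_temp, *PHYSIOLOGIC_BOUNDS["skin_temp"]),
        "sqi": sqi,
    })
    # Wear gaps: drop whole rows so downstream code sees explicit holes.
    if ns > 0:
        n_gaps = rng.poisson(duration_days)  # about one short gap per day
        drop = np.zeros(n, dtype=bool)
        for _ in range(n_gaps):
            s = int(rng.integers(0, n))
            drop[s:s + int(rng.integers(5, 31))] = True
        df = df.loc[~drop].reset_index(drop=True)
    return BiosignalSeries(profile.participant_id, df)


def inject_vaccine_response(series: BiosignalSeries, dose_time: pd.Timestamp,
                            params: ResponseParams) -> tuple[BiosignalSeries, GroundTruth]:
    """Additively perturb post-dose samples with the response envelope.

    Pre-dose samples are untouched.  Returns the perturbed series and the
    injected ground truth (labels left at defaults; ``simulate_cohort``
    fills them).
    """
    dose_time = pd.Timestamp(dose_time)
    first, last = series.span
    if not (first <= dose_time <= last):
        raise ValueError("dose_time outside series span")
    out = series.data.copy()
    hours = (out["timestamp"] - dose_time) / pd.Timedelta(hours=1)
    g = params.envelope(hours.to_numpy()) * params.magnitude_scale
    if params.magnitude_scale > 0:
        for ch, delta in params.deltas.items():
            if delta == 0.0:
                continue
            lo, hi = PHYSIOLOGIC_BOUNDS[ch]
            out[ch] = np.clip(out[ch] + delta * g, lo, hi)
    truth = GroundTruth(series.participant_id, dose_time,
                        params.magnitude_scale)
    return BiosignalSeries(series.participant_id, out), truth


# Symptom model: logistic in true magnitude with a nocebo floor of ~20%
# positives at magnitude zero.
SYMPTOM_INTERCEPT = float(np.log(0.2 / 0.8))
SYMPTOM_SLOPE = 1.5
# Immunogenicity: titer = IMMUNO_BASE * exp(IMMUNO_SLOPE * magnitude + eps),
# eps ~ N(0, IMMUNO_NOISE_SD); monotone in magnitude so rank correlation is
# recoverable.
IMMUNO_BASE = 100.0
IMMUNO_SLOPE = 0.8
IMMUNO_NOISE_SD = 0.5


def _draw_profile(rng: np.random.Generator, pid: str, seed: int) -> IndividualProfile:
    return IndividualProfile(
        participant_id=pid,
        hr_mean=float(np.clip(rng.normal(65, 8), 50, 90)),
        hr_circadian_amp=float(np.clip(rng.normal(3.0, 0.8), 1.0, 6.0)),
        hrv_mean=float(np.clip(rng.lognormal(np.log(0.05), 0.3), 0.02, 0.15)),
        rr_mean=float(np.clip(rng.normal(14, 2), 10, 20)),
        skin_temp_mean=float(np.clip(rng.normal(35.0, 0.4), 33.5, 37.0)),
        activity_day_rate=float(rng.uniform(1.0, 2.5)),
        sqi_dropout_prob=float(rng.uniform(0.01, 0.05)),
        rng_seed=seed,
    )


def simulate_cohort(
    n: int,
    dose_schedule: float | Sequence[float] = 5.0,
    magnitude_distribution: Callable[[np.random.Generator], float] | float | None = None,
    seed: int = 0,
    baseline_days: float = 5.0,
    post_days: float = 5.0,
    response_params: ResponseParams = ResponseParams(),
) -> tuple[list[BiosignalSeries], list[GroundTruth]]:
    """Simulate ``n`` heterogeneous individuals with injected responses.

    ``dose_schedule`` gives the dose time in days from each individual's
    wear start (a scalar, or one value per individual).
    ``magnitude_distribution`` draws each individual's true response
    magnitude: a callable of an rng, a scalar for a degenerate
    distribution, or None for the default Uniform(0, 3).  Symptom labels
    follow a logistic model with a nocebo floor; immunogenicity follows a
    stated monotone log-link with lognormal noise.  Wear start times are
    staggered across the day so dose clock times vary between individuals.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if magnitude_distribution is None:
        mag_draw = lambda r: float(r.uniform(0.0, 3.0))  # noqa: E731
    elif callable(magnitude_distribution):
        mag_draw = magnitude_distribution
    else:
        const = float(magnitude_distribution)
        mag_draw = lambda r: const  # noqa: E731
    dose_days = (np.full(n, float(dose_schedule))
                 if np.isscalar(dose_schedule)
                 else np.asarray(dose_schedule, dtype=float))
    if len(dose_days) != n:
        raise ValueError("dose_schedule length must match n")

    master = np.random.default_rng(seed)
    duration = int(np.ceil(float(np.max(dose_days)) + post_days))
    series_list: list[BiosignalSeries] = []
    truths: list[GroundTruth] = []
    for i in range(n):
        pid = f"P{i:03d}"
        child_seed = int(master.integers(0, 2 ** 31 - 1))
        profile = _draw_profile(master, pid, child_seed)
        start = DEFAULT_EPOCH + pd.Timedelta(minutes=int(master.integers(0, 1440)))
        base = simulate_individual(profile, duration, start=start)
        dose_time = start + pd.Timedelta(days=float(dose_days[i]))
        magnitude = float(mag_draw(master))
        params = dataclasses.replace(response_params,
                                     magnitude_scale=magnitude)
        if magnitude > 0:
            injected, truth = inject_vaccine_response(base, dose_time, params)
        else:
            injected, truth = base, GroundTruth(pid, dose_time, 0.0)
        p_sym = 1.0 / (1.0 + np.exp(-(SYMPTOM_INTERCEPT
                                      + SYMPTOM_SLOPE * magnitude)))
        truth.systemic_symptom_label = bool(master.uniform() < p_sym)
        truth.immunogenicity_value = float(
            IMMUNO_BASE * np.exp(IMMUNO_SLOPE * magnitude
                                 + master.normal(0.0, IMMUNO_NOISE_SD)))
        series_list.append(injected)
        truths.append(truth)
    return series_list, truths


def write_ground_truth(truths: Sequence[GroundTruth], path: str | Path) -> None:
    Path(path).write_text(json.dumps([t.to_dict() for t in truths], indent=1))


def read_ground_truth(path: str | Path) -> list[GroundTruth]:
    return [GroundTruth.from_dict(d) for d in json.loads(Path(path).read_text())]
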