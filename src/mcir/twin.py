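"""Per-individual similarity-based baseline model ("digital twin").

The twin is an auto-associative kernel regression over a memory of
exemplar vectors drawn from pre-dose data: a query vector's estimate is
the similarity-weighted average of exemplars, with similarity given by an
inverse-distance kernel in per-channel z-units.  Residuals (observed minus
estimated, z-units) are near zero under baseline behavior and carry the
vaccine-induced deviation afterwards.  The exemplar memory is an explicit,
documented realization of the similarity-based-modeling family; the kernel
and exemplar-selection strategy are swappable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from mcir.types import BiosignalSeries, CHANNELS

MIN_TRAINING_SAMPLES = 2500
MIN_TRAINING_DAYS = 3
#: Each of the three required calendar days must hold at least this
#: fraction of the training samples, so "distributed over 3 days" cannot
#: be satisfied by token coverage.
MIN_DAY_FRACTION = 0.10
DEFAULT_N_EXEMPLARS = 250

# Scoring-mode filters (apply always).
MAX_ACTIVITY_G = 0.05          # strict <
TWIN_TEMP_BOUNDS = (30.0, 40.0)
TWIN_SQI_MIN = 0.9             # inclusive >=
# Training-mode additional bounds.
TRAIN_HR_BOUNDS = (40.0, 250.0)
TRAIN_RR_BOUNDS = (8.0, 35.0)


class InsufficientBaselineError(ValueError):
    """Raised when pre-dose data cannot support twin training."""


class DegenerateBaselineError(ValueError):
    """Raised when a training channel has zero variance."""


def filter_for_twin(series: BiosignalSeries, mode: str = "training") -> pd.DataFrame:
    """Select complete 5-channel samples eligible as twin input.

    Both modes require activity < 0.05 g, skin temperature in [30, 40]
    degC and SQI >= 0.9; training mode additionally requires HR in
    [40, 250] bpm and RR in [8, 35] breaths/min.  Records with any missing
    channel are dropped.  Returns a frame with ``timestamp`` plus the five
    channels.
    """
    if mode not in ("training", "scoring"):
        raise ValueError("mode must be 'training' or 'scoring'")
    df = series.data
    keep = (
        df[list(CHANNELS)].notna().all(axis=1)
        & (df["activity"] < MAX_ACTIVITY_G)
        & df["skin_temp"].between(*TWIN_TEMP_BOUNDS)
        & (df["sqi"] >= TWIN_SQI_MIN)
    )
    if mode == "training":
        keep &= df["hr"].between(*TRAIN_HR_BOUNDS)
        keep &= df["rr"].between(*TRAIN_RR_BOUNDS)
    return df.loc[keep, ["timestamp", *CHANNELS]].reset_index(drop=True)


def select_exemplars(training: np.ndarray, m: int) -> np.ndarray:
    """Pick ``m`` exemplar vectors from a training matrix (z-units).

    The vectors attaining each channel's minimum and maximum are always
    included (at most 10); the remainder is filled by rank-uniform
    subsampling of the remaining vectors ordered by Euclidean norm.
    Deterministic given input order.
    """
    X = np.asarray(training, dtype=float)
    n = len(X)
    if not (2 <= m <= n):
        raise ValueError(f"need 2 <= m <= n_training ({m} vs {n})")
    forced: list[int] = []
    for j in range(X.shape[1]):
        forced.append(int(np.argmin(X[:, j])))
        forced.append(int(np.argmax(X[:, j])))
    forced_idx = sorted(set(forced))
    if m <= len(forced_idx):
        return X[forced_idx[:m]]
    rest = np.setdiff1d(np.arange(n), forced_idx)
    order = rest[np.argsort(np.linalg.norm(X[rest], axis=1), kind="stable")]
    k = m - len(forced_idx)
    picks = order[np.unique(np.round(np.linspace(0, len(order) - 1, k)).astype(int))]
    idx = np.sort(np.concatenate([forced_idx, picks]))
    # rounding collisions can lose a few slots; backfill from unused vectors
    while len(idx) < m:
        unused = np.setdiff1d(np.arange(n), idx)
        idx = np.sort(np.append(idx, unused[: m - len(idx)]))
    return X[idx]


@dataclass
class TwinModel:
    """Trained per-individual baseline model.

    ``exemplars`` live in z-units defined by ``channel_means`` /
    ``channel_sds`` (native units, training data); ``bandwidth`` is the
    inverse-distance kernel scale.
    """

    participant_id: str
    exemplars: np.ndarray            # (m, 5), z-units
    channel_means: np.ndarray        # (5,)
    channel_sds: np.ndarray          # (5,)
    bandwidth: float
    training_span: tuple[pd.Timestamp, pd.Timestamp]
    n_training: int

    def zscore(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.channel_means) / self.channel_sds

    def save(self, path: str | Path) -> None:
        doc = {
            "participant_id": self.participant_id,
            "exemplars": self.exemplars.tolist(),
            "channel_means": self.channel_means.tolist(),
            "channel_sds": self.channel_sds.tolist(),
            "bandwidth": self.bandwidth,
            "training_span": [t.isoformat() for t in self.training_span],
            "n_training": self.n_training,
            "channels": list(CHANNELS),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "TwinModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            participant_id=doc["participant_id"],
            exemplars=np.asarray(doc["exemplars"], dtype=float),
            channel_means=np.asarray(doc["channel_means"], dtype=float),
            channel_sds=np.asarray(doc["channel_sds"], dtype=float),
            bandwidth=float(doc["bandwidth"]),
            training_span=tuple(pd.Timestamp(t) for t in doc["training_span"]),
            n_training=int(doc["n_training"]),
        )


def train_twin(series: BiosignalSeries,
               dose_time: pd.Timestamp | None = None,
               n_exemplars: int = DEFAULT_N_EXEMPLARS) -> TwinModel:
    """Train a twin on all filtered pre-dose samples.

    Requires at least 2500 valid 1-minute training samples distributed
    over at least 3 distinct calendar days (each of 3 days holding >= 10%
    of the samples).  Channel means/SDs are computed on the training
    samples; the kernel bandwidth is the median pairwise exemplar
    distance.
    """
    samples = filter_for_twin(series, "training")
    if dose_time is not None:
        samples = samples[samples["timestamp"] < pd.Timestamp(dose_time)]
    n = len(samples)
    if n < MIN_TRAINING_SAMPLES:
        raise InsufficientBaselineError(
            f"{n} valid training samples < required {MIN_TRAINING_SAMPLES}")
    day_counts = samples["timestamp"].dt.normalize().value_counts()
    big_days = int((day_counts / n >= MIN_DAY_FRACTION).sum())
    if len(day_counts) < MIN_TRAINING_DAYS or big_days < MIN_TRAINING_DAYS:
        raise InsufficientBaselineError(
            f"training samples span {len(day_counts)} days with {big_days} "
            f"substantial days; require >= {MIN_TRAINING_DAYS}")
    X = samples[list(CHANNELS)].to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    degenerate = ~np.isfinite(sds) | (sds <= 1e-10 * np.maximum(1.0, np.abs(means)))
    if degenerate.any():
        bad = [CHANNELS[i] for i in np.flatnonzero(degenerate)]
        raise DegenerateBaselineError(f"zero-variance training channels: {bad}")
    Z = (X - means) / sds
    m = min(n_exemplars, n)
    D = select_exemplars(Z, m)
    h = float(np.median(pdist(D)))
    if not h > 0:
        raise DegenerateBaselineError("exemplar memory is degenerate")
    ts = samples["timestamp"]
    return TwinModel(series.participant_id, D, means, sds, h,
                     (ts.iloc[0], ts.iloc[-1]), n)


def estimate_and_residual(model: TwinModel, samples: pd.DataFrame) -> pd.DataFrame:
    """Score samples against the twin; residuals in z-units.

    For each z-scored query x the estimate is the kernel-weighted exemplar
    average with weights ``w_i = k(||x - D_i||)``, ``k(d) = 1/(1 + d/h)``,
    normalized to sum to one; the residual is ``x - x_hat``.  Estimates
    therefore always lie in the exemplars' componentwise convex hull.

    Parameters
    ----------
    samples
        Frame with ``timestamp`` and the five channels in native units
        (typically the output of :func:`filter_for_twin` in scoring mode).
    """
    Z = model.zscore(samples[list(CHANNELS)].to_numpy(dtype=float))
    dist = cdist(Z, model.exemplars)
    W = 1.0 / (1.0 + dist / model.bandwidth)
    W /= W.sum(axis=1, keepdims=True)
    est = W @ model.exemplars
    resid = Z - est
    out = pd.DataFrame(resid, columns=list(CHANNELS))
    out.insert(0, "timestamp", samples["timestamp"].to_numpy())
    return out
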