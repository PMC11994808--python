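"""Fusion of multichannel twin residuals into the 15-minute MCIR.

Residual minutes are averaged into 15-minute blocks on a grid anchored at
the dose time.  Each block's Mahalanobis distance from the baseline
residual distribution is passed through the empirical CDF of baseline
block distances and zero-floored at a quantile q (default 0.95):

    mcir = max(0, (F(d) - q) / (1 - q))

so the index lives on [0, 1], is exactly zero for the typical baseline
block, and saturates at 1 when a block is more extreme than every
baseline block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mcir.types import CHANNELS

BLOCK_MINUTES = 15
MIN_VALID_MINUTES = 3
MIN_CALIBRATION_BLOCKS = 50
DEFAULT_ZERO_QUANTILE = 0.95


class CalibrationError(ValueError):
    """Raised when too few baseline blocks are available."""


def block_residuals(residuals: pd.DataFrame, anchor: pd.Timestamp,
                    block_minutes: int = BLOCK_MINUTES,
                    min_valid: int = MIN_VALID_MINUTES) -> pd.DataFrame:
    """Average residual minutes into blocks on the anchored 15-minute grid.

    Returns one row per grid block covering the residual span, with
    ``block_start``, per-channel mean residuals and ``n_valid``; blocks
    with fewer than ``min_valid`` minutes have NaN means (missing).
    """
    anchor = pd.Timestamp(anchor)
    ts = residuals["timestamp"]
    step = pd.Timedelta(minutes=block_minutes)
    k = np.floor((ts - anchor) / step).astype(int)
    grouped = residuals[list(CHANNELS)].groupby(k.to_numpy())
    means = grouped.mean()
    counts = grouped.size()
    full = np.arange(k.min(), k.max() + 1)
    means = means.reindex(full)
    counts = counts.reindex(full, fill_value=0).astype(int)
    means[counts < min_valid] = np.nan
    out = means.reset_index(drop=True)
    out.insert(0, "block_start", anchor + full * step)
    out["n_valid"] = counts.to_numpy()
    return out


@dataclass
class NullCalibration:
    """Baseline (null) distribution of 15-minute block residual statistics."""

    mu: np.ndarray                     # (5,) mean baseline block residual
    cov: np.ndarray                    # (5, 5) ridge-regularized covariance
    null_d: np.ndarray = field(repr=False)  # sorted baseline Mahalanobis distances
    q: float = DEFAULT_ZERO_QUANTILE

    def __post_init__(self) -> None:
        if not (0.5 < self.q < 1.0):
            raise ValueError("zero quantile q must lie in (0.5, 1)")
        if len(self.null_d) == 0:
            raise ValueError("null distance pool is empty")

    def mahalanobis(self, X: np.ndarray) -> np.ndarray:
        L = np.linalg.cholesky(self.cov)
        y = np.linalg.solve(L, (np.atleast_2d(X) - self.mu).T)
        return np.sqrt((y ** 2).sum(axis=0))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "mu": self.mu.tolist(), "cov": self.cov.tolist(),
            "null_d": self.null_d.tolist(), "q": self.q,
            "channels": list(CHANNELS),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "NullCalibration":
        doc = json.loads(Path(path).read_text())
        return cls(np.asarray(doc["mu"]), np.asarray(doc["cov"]),
                   np.asarray(doc["null_d"]), float(doc["q"]))


def calibrate_null(baseline_blocks: pd.DataFrame,
                   q: float = DEFAULT_ZERO_QUANTILE) -> NullCalibration:
    """Estimate the null block-residual distribution from baseline blocks.

    Covariance gets a ridge ``eps*I`` with ``eps = 1e-6 * trace/5`` so a
    degenerate baseline (identical blocks) stays invertible.  Order of the
    input blocks is irrelevant.
    """
    X = baseline_blocks[list(CHANNELS)].dropna().to_numpy(dtype=float)
    if len(X) < MIN_CALIBRATION_BLOCKS:
        raise CalibrationError(
            f"{len(X)} valid baseline blocks < required {MIN_CALIBRATION_BLOCKS}")
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    eps = 1e-6 * np.trace(cov) / 5.0
    if eps == 0:
        eps = 1e-12
    cov = cov + eps * np.eye(5)
    calib = NullCalibration(mu, cov, np.array([0.0]), q)
    d = calib.mahalanobis(X)
    calib.null_d = np.sort(d)
    return calib


@dataclass
class MCIRSeries:
    """15-minute-cadence change index on [0, 1]; NaN marks missing blocks."""

    participant_id: str
    block_start: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values[~np.isnan(self.values)]
        if len(v) and ((v < 0).any() or (v > 1).any()):
            raise ValueError("MCIR values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "block_start": self.block_start.strftime("%Y-%m-%dT%H:%M:%S"),
            "mcir": self.values,
        }).to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path, participant_id: str = "unknown") -> "MCIRSeries":
        df = pd.read_csv(path, parse_dates=["block_start"])
        return cls(participant_id, pd.DatetimeIndex(df["block_start"]),
                   df["mcir"].to_numpy(dtype=float))


def compute_mcir(blocks: pd.DataFrame, calibration: NullCalibration,
                 participant_id: str = "unknown") -> MCIRSeries:
    """Score 15-minute blocks through the calibrated null distribution.

    Missing blocks stay missing.  Monotone non-decreasing in the block's
    Mahalanobis distance; exactly zero whenever the block is no more
    extreme than the q-quantile of baseline blocks.
    """
    X = blocks[list(CHANNELS)].to_numpy(dtype=float)
    valid = ~np.isnan(X).any(axis=1)
    values = np.full(len(X), np.nan)
    if valid.any():
        d = calibration.mahalanobis(X[valid])
        F = np.searchsorted(calibration.null_d, d, side="right") \
            / len(calibration.null_d)
        q = calibration.q
        values[valid] = np.clip((F - q) / (1.0 - q), 0.0, 1.0)
    return MCIRSeries(participant_id, pd.DatetimeIndex(blocks["block_start"]),
                      values)
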