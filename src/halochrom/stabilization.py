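"""Stabilization-time detection: when is the color transition complete?

The response time of a film is defined operationally: compute the numerical
gradient of a color channel over the frame sequence, smooth its absolute
value with a moving average, and declare the transition complete at the
first frame from which the smoothed |slope| stays below a threshold
(default 0.001 channel units/frame) for the remainder of the recording,
with a minimum of ``consecutive_frames`` (default 50) qualifying frames so
that a short quiet spell at the very end cannot count as steady state. The
"stays below through the end" requirement is what distinguishes the final
plateau from the equally flat stretch *before* a late transition begins: a
steady state, by definition, persists. The detected time is reported at the
start of the qualifying run. Frames are numbered from 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from halochrom.color import CHANNELS


@dataclass
class StabilizationParams:
    slope_threshold: float = 0.001  # channel units per frame
    consecutive_frames: int = 50
    ma_window: int = 10

    def validate(self) -> None:
        if self.slope_threshold <= 0:
            raise ValueError("slope_threshold must be > 0")
        if self.consecutive_frames < 1:
            raise ValueError("consecutive_frames must be >= 1")
        if self.ma_window < 1:
            raise ValueError("ma_window must be >= 1")


@dataclass
class StabilizationResult:
    channel: str
    stabilized: bool
    stabilization_frame: int | None  # 1-based
    stabilization_time_s: float | None

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "stabilized": self.stabilized,
            "frame": self.stabilization_frame,
            "time_s": self.stabilization_time_s,
        }


def clean_series(series: pd.DataFrame) -> pd.DataFrame:
    """Drop rows with a missing value in any channel column.

    Timestamps of the surviving rows are preserved. Raises ``ValueError``
    if fewer than 2 valid rows remain.
    """
    channel_cols = [c for c in CHANNELS if c in series.columns]
    if not channel_cols:
        raise ValueError("series contains no channel columns")
    cleaned = series.dropna(subset=channel_cols).reset_index(drop=True)
    if len(cleaned) < 2:
        raise ValueError(f"only {len(cleaned)} valid rows remain after cleaning (need >= 2)")
    return cleaned


def numerical_gradient(values, t_s=None) -> np.ndarray:
    """Per-frame slope: central differences inside, one-sided at the ends.

    With ``t_s`` omitted the spacing is taken as one frame, so slopes are in
    channel units per frame; with timestamps given, slopes are rescaled by
    the actual (possibly non-uniform) spacing.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 frames for a gradient")
    if t_s is None:
        return np.gradient(values)
    return np.gradient(values, np.asarray(t_s, dtype=float))


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    # Centered moving average with shrinking windows at the edges
    # (same convention as MATLAB's movmean).
    return (
        pd.Series(x).rolling(window=window, center=True, min_periods=1).mean().to_numpy()
    )


def detect_stabilization(
    series: pd.DataFrame, channel: str, params: StabilizationParams | None = None
) -> StabilizationResult:
    """Find the first frame from which the smoothed |slope| stays small.

    Returns a :class:`StabilizationResult`; ``stabilized`` is False when
    the moving-averaged ``|gradient|`` does not remain below
    ``slope_threshold`` from some frame through the end of the series for
    at least ``consecutive_frames`` frames. Raises ``ValueError`` for a
    missing channel or a series shorter than ``consecutive_frames``.
    """
    if params is None:
        params = StabilizationParams()
    params.validate()
    if channel not in series.columns:
        raise ValueError(f"channel {channel!r} not present in series")
    values = series[channel].to_numpy(dtype=float)
    n = values.size
    if n < params.consecutive_frames:
        raise ValueError(
            f"series has {n} frames, fewer than consecutive_frames={params.consecutive_frames}"
        )
    slopes = numerical_gradient(values)
    smoothed = _moving_average(np.abs(slopes), params.ma_window)
    below = smoothed < params.slope_threshold

    # First index f with below[f:] all True, i.e. one past the last
    # above-threshold frame; the closing run must span >= consecutive_frames.
    above = np.flatnonzero(~below)
    start = int(above[-1]) + 1 if above.size else 0
    if n - start < params.consecutive_frames:
        return StabilizationResult(channel, False, None, None)
    t = float(series["t_s"].iloc[start]) if "t_s" in series.columns else float(start)
    return StabilizationResult(channel, True, start + 1, t)


def response_time(
    series: pd.DataFrame,
    params: StabilizationParams | None = None,
    channel: str = "H",
    require_all: bool = False,
) -> StabilizationResult:
    """The pH response time of a film: stabilization time of the primary channel.

    Hue is the default primary channel — it shows the most distinct and
    reliable sigmoidal transition of the twelve. With ``require_all=True``
    the film counts as stabilized only once Hue, Saturation and the Lab `a`
    channel have all stabilized, and the latest of their times is reported.
    """
    if not require_all:
        return detect_stabilization(series, channel, params)
    results = [detect_stabilization(series, ch, params) for ch in ("H", "S", "a")]
    if not all(r.stabilized for r in results):
        return StabilizationResult("H+S+a", False, None, None)
    latest = max(results, key=lambda r: r.stabilization_frame)
    return StabilizationResult(
        "H+S+a", True, latest.stabilization_frame, latest.stabilization_time_s
    )
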