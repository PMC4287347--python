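"""Run-level preparation: motion exclusion, band-pass filtering, windowing.

A *run* is one continuous acquisition for one subject and one task,
represented as a region x sample matrix together with the sampling period
(TR) and an optional framewise-displacement (FD) trace.  Preparation
proceeds in three steps, in this order:

1. runs whose mean FD exceeds a threshold (default 0.25 mm) are excluded;
2. each region's time series is band-pass filtered (Butterworth,
   forward-backward for zero phase) to the low-frequency band in which
   task-related BOLD fluctuations live (default 0.06-0.125 Hz);
3. the filtered run is cut into contiguous, non-overlapping windows
   (default 60 s), each labelled with the run's task.  Windows never
   straddle run boundaries and trailing partial windows are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal


@dataclass
class RegionTimeSeriesRun:
    """One subject/task acquisition: region x sample matrix plus metadata.

    ``fd`` holds per-transition framewise displacement in mm and therefore
    has length ``n_samples - 1`` when present.
    """

    subject_id: str
    task: str
    sampling_period: float  # TR, seconds
    data: np.ndarray        # shape (n_regions, n_samples)
    fd: Optional[np.ndarray] = None
    run_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("run data must be a 2-D region x sample matrix")
        if not np.isfinite(self.data).all():
            raise ValueError(f"run {self.name} contains missing/non-finite values")
        if self.sampling_period <= 0:
            raise ValueError("sampling_period must be positive")
        if self.fd is not None:
            self.fd = np.asarray(self.fd, dtype=float)
            if self.fd.ndim != 1 or self.fd.shape[0] != self.data.shape[1] - 1:
                raise ValueError(
                    f"run {self.name}: fd must have length n_samples - 1"
                )

    @property
    def name(self) -> str:
        rid = f"/{self.run_id}" if self.run_id else ""
        return f"{self.subject_id}/{self.task}{rid}"

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class BandpassSpec:
    """Butterworth band edges in Hz and the filter order (per direction)."""

    low: float = 0.06
    high: float = 0.125
    order: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError("require 0 < low < high")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass(frozen=True)
class WindowingSpec:
    """Non-overlapping windowing, by duration (seconds) or by point count."""

    mode: str = "duration"          # "duration" | "points"
    window_seconds: float = 60.0
    window_points: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in ("duration", "points"):
            raise ValueError(f"unknown windowing mode {self.mode!r}")
        if self.mode == "duration" and self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if self.mode == "points":
            if self.window_points is None or self.window_points < 3:
                raise ValueError("points mode requires window_points >= 3")

    def points_for(self, sampling_period: float) -> int:
        if self.mode == "points":
            return int(self.window_points)  # type: ignore[arg-type]
        return int(np.floor(self.window_seconds / sampling_period))


def exclude_high_motion(
    runs: list[RegionTimeSeriesRun], threshold: float = 0.25
) -> tuple[list[RegionTimeSeriesRun], list[str]]:
    """Keep runs with mean framewise displacement strictly below ``threshold``.

    Returns (kept runs, excluded run names), both in input order.  A run
    without an FD trace is an error, because motion screening cannot be
    silently skipped.
    """
    kept: list[RegionTimeSeriesRun] = []
    excluded: list[str] = []
    for run in runs:
        if run.fd is None:
            raise ValueError(f"run {run.name} has no framewise-displacement trace")
        if float(np.mean(run.fd)) < threshold:
            kept.append(run)
        else:
            excluded.append(run.name)
    return kept, excluded


def bandpass(run: RegionTimeSeriesRun, spec: BandpassSpec = BandpassSpec()) -> RegionTimeSeriesRun:
    """Zero-phase Butterworth band-pass of every region row independently.

    The filter is applied forward and backward (``sosfiltfilt``), which
    squares the magnitude response and cancels the phase, so no inter-region
    lags are introduced.
    """
    nyquist = 0.5 / run.sampling_period
    if spec.high >= nyquist:
        raise ValueError(
            f"band edge {spec.high} Hz is not below the Nyquist frequency "
            f"{nyquist} Hz of run {run.name} (TR = {run.sampling_period} s)"
        )
    sos = signal.butter(
        spec.order, [spec.low, spec.high], btype="bandpass",
        fs=1.0 / run.sampling_period, output="sos",
    )
    filtered = signal.sosfiltfilt(sos, run.data, axis=1)
    return replace(run, data=np.ascontiguousarray(filtered))


def segment_windows(
    run: RegionTimeSeriesRun, spec: WindowingSpec = WindowingSpec()
) -> list[tuple[np.ndarray, str]]:
    """Cut a run into contiguous non-overlapping (window data, task) pairs.

    Duration mode uses ``floor(window_seconds / TR)`` samples per window;
    trailing samples short of a full window are discarded.
    """
    pts = spec.points_for(run.sampling_period)
    if pts < 3:
        raise ValueError(
            f"window of {pts} samples for run {run.name} is too short (< 3)"
        )
    n_win = run.n_samples // pts
    if n_win == 0:
        raise ValueError(f"run {run.name} is shorter than one window")
    return [
        (run.data[:, k * pts:(k + 1) * pts], run.task) for k in range(n_win)
    ]
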