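"""Windowed peak search for glottal-width and other physiological waveforms.

The detector slides a window along the signal one sample at a time (or by a
configurable step), splits each window into left / center / right thirds,
applies a summary statistic (max by default; min, median and mean are also
available) to each third, and marks the window-center sample as a peak when
the center section dominates both side sections and the center sample is
the (leftmost) maximum of the whole window.  With a 3-sample window and the
max statistic this reduces exactly to a strict local-maximum test.

Detected peaks feed cycle analysis: peak-to-peak intervals give per-cycle
periods, peak heights give amplitudes, and their mean absolute successive
relative variation gives the conventional local jitter and shimmer percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["PeakSearchConfig", "PeakSet", "CycleStats", "detect_peaks", "peak_intervals"]

_SECTION_STATS = {
    "min": np.min,
    "median": np.median,
    "max": np.max,
    "mean": np.mean,
}


@dataclass(frozen=True)
class PeakSearchConfig:
    """Window length in samples, section statistic, and slide step.

    Window lengths not divisible by 3 put the remainder samples in the
    center section (left and right sections each get ``window_len // 3``).
    """

    window_len: int
    section_stat: str = "max"
    step: int = 1

    def __post_init__(self) -> None:
        if self.window_len < 3:
            raise ValueError("window_len must be >= 3")
        if self.section_stat not in _SECTION_STATS:
            raise ValueError(
                f"section_stat must be one of {sorted(_SECTION_STATS)}"
            )
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass(frozen=True)
class PeakSet:
    """Sorted peak sample positions and the signal values there."""

    indices: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=np.int64))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if len(self.indices) != len(self.values):
            raise ValueError("indices and values must have equal length")
        if len(self.indices) > 1 and not (np.diff(self.indices) > 0).all():
            raise ValueError("peak indices must be strictly increasing")


@dataclass(frozen=True)
class CycleStats:
    """Per-cycle periods (s), amplitudes, and local jitter/shimmer (%).

    Jitter is ``100 * mean|T_{c+1} - T_c| / mean T``; shimmer is the same
    functional on peak amplitudes.  Both are NaN when fewer than two
    successive differences exist.
    """

    periods: np.ndarray
    amplitudes: np.ndarray
    jitter: float
    shimmer: float


def detect_peaks(signal: np.ndarray, cfg: PeakSearchConfig) -> PeakSet:
    """Run the sliding-window three-section peak search over a 1-D signal.

    A window-center sample ``c`` is marked as a peak iff

    * ``stat(center section) > stat(left section)``,
    * ``stat(center section) >= stat(right section)``, and
    * ``signal[c]`` is the maximum of the window and ``c`` is the leftmost
      position attaining it (plateau ties resolve to the leftmost sample).

    Each sample is marked at most once regardless of how many windows cover
    it.
    """
    x = np.asarray(signal, dtype=np.float64).ravel()
    n = len(x)
    if n < cfg.window_len:
        raise ValueError(f"signal of length {n} shorter than window {cfg.window_len}")
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite values")
    L = cfg.window_len
    side = L // 3
    stat = _SECTION_STATS[cfg.section_stat]
    windows = sliding_window_view(x, L)[:: cfg.step]
    left = stat(windows[:, :side], axis=1)
    center = stat(windows[:, side : L - side], axis=1)
    right = stat(windows[:, L - side :], axis=1)
    center_pos = L // 2
    # leftmost argmax == center <=> center holds the window max, plateau-left
    is_window_max = windows.argmax(axis=1) == center_pos
    marked = (center > left) & (center >= right) & is_window_max
    starts = np.arange(0, n - L + 1, cfg.step)
    idx = np.unique(starts[marked] + center_pos)
    return PeakSet(indices=idx, values=x[idx])


def peak_intervals(peaks: PeakSet, fps: float) -> CycleStats:
    """Per-cycle periods/amplitudes and local jitter/shimmer from a peak set."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    if len(peaks.indices) < 2:
        raise ValueError("need at least 2 peaks to form a cycle")
    periods = np.diff(peaks.indices) / fps
    amplitudes = peaks.values.copy()

    def _perturbation(values: np.ndarray) -> float:
        if len(values) < 2:
            return float("nan")
        mean = np.mean(values)
        if mean == 0:
            return float("nan")
        return float(100.0 * np.mean(np.abs(np.diff(values))) / mean)

    return CycleStats(
        periods=periods,
        amplitudes=amplitudes,
        jitter=_perturbation(periods),
        shimmer=_perturbation(amplitudes),
    )
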