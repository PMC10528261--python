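"""Background removal by slow-time average subtraction.

Static scatterers contribute the same trace to every sounding, so the
per-channel slow-time mean estimates the static background; subtracting it
leaves only the pulsation-induced residual.  Over an integer number of
pulsation periods the mean of the cosine modulation is exactly zero, so the
residual keeps the pulsation amplitude unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .forward import RadarDataCube

__all__ = ["BackgroundModel", "estimate_background", "remove_background"]


@dataclass(eq=False)
class BackgroundModel:
    """Per-channel mean trace over a slow-time averaging window."""

    mean_trace: np.ndarray  # [n_fast, n_channel]
    window: tuple[int, int]  # slow-time sample indices [start, stop)

    def __post_init__(self) -> None:
        self.mean_trace = np.asarray(self.mean_trace, dtype=float)
        if self.mean_trace.ndim != 2:
            raise ValueError("mean_trace must be [n_fast, n_channel]")
        if self.window[1] <= self.window[0]:
            raise ValueError("empty averaging window")


def _whole_period_count(n_slow: int, slow_rate: float, pulsation_hz: float) -> int:
    """Largest sample count <= n_slow spanning whole pulsation periods."""
    samples_per_period = slow_rate / pulsation_hz
    n_periods = int(np.floor(n_slow / samples_per_period + 1e-9))
    return int(round(n_periods * samples_per_period))


def estimate_background(
    cube: RadarDataCube, window: tuple[int, int] | None = None
) -> BackgroundModel:
    """Estimate the static background as the slow-time mean per channel.

    When no window is given the full record is used, truncated (with a
    warning) to the largest whole number of pulsation periods if the cube
    carries a known pulsation frequency.
    """
    if window is None:
        stop = cube.n_slow
        nu = float(cube.attrs.get("pulsation_hz", 0.0) or 0.0)
        if nu > 0.0 and cube.n_slow > 1:
            whole = _whole_period_count(cube.n_slow, cube.slow_rate, nu)
            if 0 < whole < cube.n_slow:
                warnings.warn(
                    f"averaging window truncated from {cube.n_slow} to {whole} "
                    "samples to span whole pulsation periods",
                    stacklevel=2,
                )
                stop = whole
        window = (0, stop)
    start, stop = window
    if not (0 <= start < stop <= cube.n_slow):
        raise ValueError(f"invalid averaging window {window}")
    mean = cube.data[:, start:stop, :].mean(axis=1)
    return BackgroundModel(mean_trace=mean, window=(start, stop))


def remove_background(
    cube: RadarDataCube, bg: BackgroundModel | None = None
) -> RadarDataCube:
    """Subtract the background mean trace from every sounding."""
    if bg is None:
        bg = estimate_background(cube)
    if bg.mean_trace.shape != (cube.n_fast, cube.n_channels):
        raise ValueError("background shape does not match the cube")
    residual = cube.data - bg.mean_trace[:, None, :]
    out = cube.copy_with(data=residual)
    out.attrs["background_removed"] = True
    return out
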