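"""M-mode time series, spectra and detection scoring.

The M-mode series of a point is the gated, gain-compensated channel sum of
the background-removed traces at that point's round-trip delays, evaluated
per sounding — the time-domain analogue of the beamformer without the
slow-time FFT.  A pulsating artery at the probed point produces a sinusoid
at the pulsation frequency; artery-free points stay near zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import peak_local_max

from .forward import RadarDataCube
from .geometry import ArrayGeometry, PhantomModel
from .imaging import BeamformerConfig, ImageGrid, VoxelImage, delay_table, _sample_traces

__all__ = [
    "MModeSeries",
    "DetectionReport",
    "mmode",
    "dominant_frequency",
    "detect_and_match",
]


@dataclass(eq=False)
class MModeSeries:
    """Slow-time series of one spatial point plus its magnitude spectrum."""

    point: tuple[float, float, float]
    times: np.ndarray
    series: np.ndarray
    freqs: np.ndarray
    spectrum: np.ndarray

    def __post_init__(self) -> None:
        if len(self.series) != len(self.times):
            raise ValueError("series/times length mismatch")
        if len(self.spectrum) != len(self.freqs):
            raise ValueError("spectrum/freqs length mismatch")


@dataclass(eq=False)
class DetectionReport:
    """Peaks found in a lateral image matched to ground-truth positions."""

    peaks: list[tuple[tuple[float, float], float]]
    matched: int
    n_truth: int
    tolerance: float

    def __post_init__(self) -> None:
        if self.matched > self.n_truth:
            raise ValueError("matched count cannot exceed the truth count")


def mmode(
    cube: RadarDataCube,
    point,
    geom: ArrayGeometry,
    medium: PhantomModel,
    cfg: BeamformerConfig | None = None,
) -> MModeSeries:
    """M-mode series at a point from a background-removed cube.

    The cube should be background-removed (slow-time residual); statics
    otherwise dominate the series with a constant offset.
    """
    cfg = cfg or BeamformerConfig()
    point = tuple(float(v) for v in point)
    r_lat = float(np.hypot(point[0], point[1]))
    if r_lat >= medium.radius:
        raise ValueError("probe point outside the phantom")

    grid = ImageGrid(
        axis0=np.array([point[0]]),
        axis1=np.array([point[1]]),
        plane="lateral",
        plane_coord=point[2],
    )
    table = delay_table(grid, geom, medium)
    fs = cube.fast_rate
    t0 = cube.fast_time_axis[0]
    base = (table.tau - t0) * fs  # [1, n_ch]

    series = np.zeros(cube.n_slow)
    for off in cfg.offsets:
        for ti in range(cube.n_slow):
            sampled = _sample_traces(cube.data[:, ti, :], base + off)
            series[ti] += float(np.sum(table.gain * sampled))

    spectrum = np.abs(np.fft.rfft(series, norm="ortho"))
    freqs = np.fft.rfftfreq(cube.n_slow, d=1.0 / cube.slow_rate)
    return MModeSeries(
        point=point,
        times=cube.slow_time_axis.copy(),
        series=series,
        freqs=freqs,
        spectrum=spectrum,
    )


def dominant_frequency(series: MModeSeries) -> float:
    """Frequency of the largest non-DC spectral magnitude.

    Ties break toward the lower frequency.
    """
    if np.allclose(series.series, series.series[0]):
        raise ValueError("series is constant; no dominant frequency")
    if len(series.spectrum) < 2:
        raise ValueError("spectrum has no non-DC bins")
    k = 1 + int(np.argmax(series.spectrum[1:]))
    return float(series.freqs[k])


def detect_and_match(
    image: VoxelImage,
    truth: list[tuple[float, float]],
    tolerance: float = 0.010,
    min_prominence: float = 0.1,
) -> DetectionReport:
    """Find local maxima in a lateral image and match them to truth points.

    Peaks must exceed ``min_prominence`` times the global maximum; matching
    is greedy nearest-first, each truth position matched at most once and
    only within ``tolerance`` metres.
    """
    if not truth:
        raise ValueError("truth list must not be empty")
    if image.grid.plane != "lateral":
        raise ValueError("detection operates on lateral images")
    vals = image.values
    vmax = float(vals.max())
    peaks: list[tuple[tuple[float, float], float]] = []
    if vmax > 0.0:
        coords = peak_local_max(
            vals, threshold_abs=min_prominence * vmax, exclude_border=False
        )
        for i, j in coords:
            pos = (float(image.grid.axis0[i]), float(image.grid.axis1[j]))
            peaks.append((pos, float(vals[i, j])))

    # greedy nearest assignment
    pairs = []
    for pi, (pos, _) in enumerate(peaks):
        for tj, tpos in enumerate(truth):
            d = float(np.hypot(pos[0] - tpos[0], pos[1] - tpos[1]))
            if d <= tolerance:
                pairs.append((d, pi, tj))
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    for d, pi, tj in pairs:
        if pi in used_p or tj in used_t:
            continue
        used_p.add(pi)
        used_t.add(tj)
    return DetectionReport(
        peaks=peaks, matched=len(used_t), n_truth=len(truth), tolerance=tolerance
    )
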