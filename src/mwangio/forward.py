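"""Forward synthesis of the MIMO radar data cube.

Each bistatic channel is modeled as a chain of: M-sequence sounding signal,
transmit-antenna impulse response, spherical-spreading delay line to each
point scatterer (amplitude ``1/(2*pi*r)`` per leg), a reflectivity that is
the sum of a static part and a part modulated linearly by the instantaneous
artery radius change, and the receive-antenna impulse response.  Pulse
compression (circular correlation with the sounding sequence) recovers a
trace proportional to the channel impulse response.

The slow-time axis samples repeated soundings; pulsating scatterers make
the compressed traces sinusoidal along it at the pulsation frequency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    FILL_PERMITTIVITY,
    ArrayGeometry,
    ArteryModel,
    PhantomModel,
    Scenario,
)

__all__ = [
    "MSequence",
    "SystemIRF",
    "ScattererResponse",
    "RadarDataCube",
    "AcquisitionConfig",
    "generate_msequence",
    "pulse_compress",
    "radius_waveform",
    "fresnel_reflectivity",
    "scatterers_for_scenario",
    "channel_response",
    "simulate_from_scatterers",
    "simulate_cube",
    "center_frequency",
]

#: Device bandwidth in Hz; the baseband center frequency is half of it.
DEFAULT_BANDWIDTH_HZ = 6.5e9


def center_frequency(bandwidth_hz: float = DEFAULT_BANDWIDTH_HZ) -> float:
    """Center frequency of a baseband span of the given bandwidth (Hz)."""
    if bandwidth_hz <= 0:
        raise ValueError("bandwidth must be positive")
    return bandwidth_hz / 2.0


# Primitive polynomial exponents (including the register length) for
# maximal-length LFSRs, one standard choice per order.
_PRIMITIVE_TAPS = {
    2: (2, 1),
    3: (3, 2),
    4: (4, 3),
    5: (5, 3),
    6: (6, 5),
    7: (7, 6),
    8: (8, 6, 5, 4),
    9: (9, 5),
    10: (10, 7),
    11: (11, 9),
    12: (12, 6, 4, 1),
    13: (13, 4, 3, 1),
    14: (14, 5, 3, 1),
    15: (15, 14),
    16: (16, 15, 13, 4),
}


@dataclass(frozen=True, eq=False)
class MSequence:
    """Maximal-length +/-1 sounding sequence of length ``2**order - 1``."""

    order: int
    chips: np.ndarray
    chip_rate: float = 13.0e9

    def __post_init__(self) -> None:
        object.__setattr__(self, "chips", np.asarray(self.chips, dtype=float))
        if len(self.chips) != 2**self.order - 1:
            raise ValueError("chip count must be 2**order - 1")
        if not np.all(np.isin(self.chips, (-1.0, 1.0))):
            raise ValueError("chips must be +/-1")

    def __len__(self) -> int:
        return len(self.chips)

    def circular_autocorrelation(self) -> np.ndarray:
        """Circular autocorrelation via FFT (N at lag 0, -1 elsewhere)."""
        spec = np.fft.fft(self.chips)
        return np.fft.ifft(spec * np.conj(spec)).real


def generate_msequence(
    order: int, taps: tuple[int, ...] | None = None, chip_rate: float = 13.0e9
) -> MSequence:
    """Generate an M-sequence with a Fibonacci LFSR.

    Parameters
    ----------
    order:
        Register length; the sequence has length ``2**order - 1``.
    taps:
        Optional polynomial exponents (including ``order``).  Defaults to a
        standard primitive polynomial.  Non-maximal taps raise.
    """
    if not 2 <= order <= 16:
        raise ValueError("order must be in 2..16")
    if taps is None:
        taps = _PRIMITIVE_TAPS[order]
    taps = tuple(sorted(set(int(t) for t in taps), reverse=True))
    if taps[0] != order or any(t < 1 for t in taps):
        raise ValueError("taps must include the order and be >= 1")

    n = 2**order - 1
    state = (1 << order) - 1  # all-ones seed
    seed = state
    tap_masks = [1 << (order - t) for t in taps]
    bits = np.empty(n, dtype=np.int8)
    for i in range(n):
        bits[i] = state & 1
        fb = 0
        for m in tap_masks:
            fb ^= 1 if (state & m) else 0
        state = (state >> 1) | (fb << (order - 1))
        if state == seed and i != n - 1:
            raise ValueError(f"taps {taps} are not primitive (period {i + 1} < {n})")
    if state != seed:
        raise ValueError(f"taps {taps} are not primitive")
    chips = 2.0 * bits - 1.0
    return MSequence(order=order, chips=chips, chip_rate=chip_rate)


@dataclass(frozen=True, eq=False)
class SystemIRF:
    """Transmit/receive antenna impulse responses, defined on the fast-time
    grid with their center sample at time zero (zero group delay)."""

    tx_irf: np.ndarray
    rx_irf: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "tx_irf", np.asarray(self.tx_irf, dtype=float))
        object.__setattr__(self, "rx_irf", np.asarray(self.rx_irf, dtype=float))
        for irf in (self.tx_irf, self.rx_irf):
            if irf.ndim != 1 or len(irf) % 2 == 0:
                raise ValueError("IRFs must be 1D with odd length (centered)")

    @property
    def combined(self) -> np.ndarray:
        """tx * rx convolution, again centered (odd length)."""
        return np.convolve(self.tx_irf, self.rx_irf)

    @property
    def effective_length(self) -> int:
        return len(self.combined)


def default_irf(fs: float = 13.0e9, fc: float = 3.25e9, half_width: int = 2) -> SystemIRF:
    """Gaussian-windowed carrier pulse; the tx*rx cascade spans ~9 samples."""
    k = np.arange(-half_width, half_width + 1)
    sigma = max(half_width / 1.6, 0.5)
    env = np.exp(-0.5 * (k / sigma) ** 2)
    pulse = env * np.cos(2.0 * math.pi * fc / fs * k)
    return SystemIRF(tx_irf=pulse, rx_irf=pulse)


def radius_waveform(artery: ArteryModel, T) -> np.ndarray:
    """Radius change Delta-d(T) = (DeltaP / K) * cos(2 pi nu T) in metres."""
    if not artery.pulsating:
        raise ValueError("radius_waveform requires a pulsating artery")
    if artery.pulsation_frequency <= 0:
        raise ValueError("pulsation frequency must be positive")
    T = np.asarray(T, dtype=float)
    return artery.pulsation_amplitude * np.cos(2.0 * math.pi * artery.pulsation_frequency * T)


def fresnel_reflectivity(eps_medium: float, eps_target: float) -> float:
    """Normal-incidence amplitude reflection coefficient between two media."""
    n1, n2 = math.sqrt(eps_medium), math.sqrt(eps_target)
    return (n1 - n2) / (n1 + n2)


@dataclass(frozen=True)
class ScattererResponse:
    """Point scatterer with a static amplitude and an optional pulsation-
    modulated gain (reflectivity change per metre of radius change)."""

    position: tuple[float, float, float]
    static_amplitude: float
    modulation_gain: float = 0.0
    artery: ArteryModel | None = None

    def __post_init__(self) -> None:
        if self.modulation_gain != 0.0 and (self.artery is None or not self.artery.pulsating):
            raise ValueError("modulated scatterers need a pulsating artery reference")

    def radius_change(self, T) -> np.ndarray:
        if self.artery is None or not self.artery.pulsating:
            return np.zeros_like(np.asarray(T, dtype=float))
        return radius_waveform(self.artery, T)


def scatterers_for_scenario(
    scenario: Scenario,
    n_per_artery: int = 11,
    include_clutter: bool = True,
    n_clutter: int = 16,
    clutter_amplitude: float = 0.3,
) -> list[ScattererResponse]:
    """Discretize a scenario into point scatterers.

    Each artery becomes a vertical line of ``n_per_artery`` points over its
    z extent.  The static amplitude is the Fresnel coefficient between the
    phantom and the tube fill; the modulation gain is that amplitude per
    rest radius.  Optional static clutter points sit on a ring just inside
    the phantom wall to exercise background removal.
    """
    eps = scenario.phantom.rel_permittivity
    out: list[ScattererResponse] = []
    for artery in scenario.arteries:
        lam0 = fresnel_reflectivity(eps, FILL_PERMITTIVITY[artery.fill])
        pi_amp = lam0 / artery.rest_radius
        z_top, z_bot = artery.z_extent
        zs = np.linspace(z_top, z_bot, n_per_artery)
        x, y = artery.center_xy
        for z in zs:
            out.append(
                ScattererResponse(
                    position=(x, y, float(z)),
                    static_amplitude=lam0 / n_per_artery,
                    modulation_gain=(pi_amp / n_per_artery) if artery.pulsating else 0.0,
                    artery=artery if artery.pulsating else None,
                )
            )
    if include_clutter:
        r = 0.92 * scenario.phantom.radius
        z = scenario.phantom.top_surface_z - scenario.phantom.height / 2.0
        for k in range(n_clutter):
            theta = 2.0 * math.pi * (k + 0.5) / n_clutter
            out.append(
                ScattererResponse(
                    position=(r * math.cos(theta), r * math.sin(theta), z),
                    static_amplitude=clutter_amplitude / n_clutter,
                )
            )
    return out


@dataclass(eq=False)
class RadarDataCube:
    """Fast-time x slow-time x channel measurement tensor with axes."""

    data: np.ndarray
    fast_time_axis: np.ndarray
    slow_time_axis: np.ndarray
    channel_tx: np.ndarray
    channel_rx: np.ndarray
    compressed: bool = False
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.fast_time_axis = np.asarray(self.fast_time_axis, dtype=float)
        self.slow_time_axis = np.asarray(self.slow_time_axis, dtype=float)
        self.channel_tx = np.asarray(self.channel_tx, dtype=int)
        self.channel_rx = np.asarray(self.channel_rx, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be [n_fast, n_slow, n_channel]")
        nf, ns, nc = self.data.shape
        if len(self.fast_time_axis) != nf or len(self.slow_time_axis) != ns:
            raise ValueError("axis lengths must match the data shape")
        if len(self.channel_tx) != nc or len(self.channel_rx) != nc:
            raise ValueError("channel maps must match the channel axis")
        for ax in (self.fast_time_axis, self.slow_time_axis):
            if len(ax) > 1:
                d = np.diff(ax)
                if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-9):
                    raise ValueError("axes must be strictly increasing and uniform")

    @property
    def n_fast(self) -> int:
        return self.data.shape[0]

    @property
    def n_slow(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def fast_rate(self) -> float:
        if self.n_fast < 2:
            raise ValueError("need at least 2 fast-time samples")
        return 1.0 / (self.fast_time_axis[1] - self.fast_time_axis[0])

    @property
    def slow_rate(self) -> float:
        if self.n_slow < 2:
            raise ValueError("need at least 2 slow-time samples")
        return 1.0 / (self.slow_time_axis[1] - self.slow_time_axis[0])

    def copy_with(self, **updates) -> "RadarDataCube":
        base = dict(
            data=self.data,
            fast_time_axis=self.fast_time_axis,
            slow_time_axis=self.slow_time_axis,
            channel_tx=self.channel_tx,
            channel_rx=self.channel_rx,
            compressed=self.compressed,
            attrs=dict(self.attrs),
        )
        base.update(updates)
        return RadarDataCube(**base)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Sampling and noise parameters for a simulated acquisition.

    Defaults: fast-time sampling at twice the 6.5 GHz bandwidth, slow-time
    sampling at 0.8 Hz over 125 s (100 soundings, exactly 10 pulsation
    periods at 0.08 Hz so the pulsation lands on FFT bin 10).
    """

    fast_rate: float = 2.0 * DEFAULT_BANDWIDTH_HZ
    slow_rate: float = 0.8
    duration: float = 125.0
    m_order: int = 9
    snr_db: float | None = None
    seed: int = 0
    n_per_artery: int = 11
    include_clutter: bool = True
    compress: bool = True

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("observation duration must be positive")
        if self.fast_rate <= 0 or self.slow_rate <= 0:
            raise ValueError("sampling rates must be positive")
        n = self.slow_rate * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * slow_rate must be an integer sample count")

    @property
    def n_slow(self) -> int:
        return int(round(self.slow_rate * self.duration))

    @property
    def slow_time_axis(self) -> np.ndarray:
        return np.arange(self.n_slow) / self.slow_rate


def _fractional_impulse(n: int, delays: np.ndarray, amps: np.ndarray) -> np.ndarray:
    """Sum of linearly interpolated unit impulses on an n-sample grid."""
    h = np.zeros(n)
    i0 = np.floor(delays).astype(int)
    frac = delays - i0
    if np.any(delays < 0) or np.any(i0 + 1 >= n):
        raise ValueError("scatterer delay outside the fast-time window")
    np.add.at(h, i0, amps * (1.0 - frac))
    np.add.at(h, i0 + 1, amps * frac)
    return h


def _channel_impulse_parts(
    scatterers: list[ScattererResponse],
    tx_pos: np.ndarray,
    rx_pos: np.ndarray,
    medium: PhantomModel,
    fast_rate: float,
    n_fast: int,
) -> tuple[np.ndarray, dict]:
    """Static impulse response plus one modulated part per pulsating artery.

    Returns ``(h_static, {artery: h_mod})`` where the cube trace at slow
    time T is ``h_static + sum_a radius_waveform(a, T) * h_mod[a]`` before
    convolution with the IRFs and the sounding sequence.
    """
    c = medium.wave_speed
    h_static = np.zeros(n_fast)
    h_mod: dict[ArteryModel, np.ndarray] = {}
    for sc in scatterers:
        p = np.asarray(sc.position, dtype=float)
        ri = float(np.linalg.norm(tx_pos - p))
        rj = float(np.linalg.norm(rx_pos - p))
        if ri < 1e-9 or rj < 1e-9:
            raise ValueError("scatterer coincides with an antenna (singular 1/r)")
        amp = 1.0 / (2.0 * math.pi * ri) / (2.0 * math.pi * rj)
        delay = (ri + rj) / c * fast_rate
        imp = _fractional_impulse(n_fast, np.array([delay]), np.array([amp]))
        h_static += sc.static_amplitude * imp
        if sc.modulation_gain != 0.0 and sc.artery is not None:
            h_mod.setdefault(sc.artery, np.zeros(n_fast))
            h_mod[sc.artery] += sc.modulation_gain * imp
    return h_static, h_mod


def _centered_kernel_spectrum(kernel: np.ndarray, n: int) -> np.ndarray:
    """FFT of an odd-length kernel placed with its center at sample 0."""
    if len(kernel) > n:
        raise ValueError("kernel longer than the fast-time record")
    padded = np.zeros(n)
    padded[: len(kernel)] = kernel
    return np.fft.fft(np.roll(padded, -(len(kernel) // 2)))


def channel_response(
    scatterers: list[ScattererResponse],
    tx_pos,
    rx_pos,
    T: float,
    medium: PhantomModel,
    irf: SystemIRF,
    m: MSequence,
) -> np.ndarray:
    """Raw (uncompressed) fast-time trace of one channel at slow time T.

    Reference implementation: impulse placement per scatterer, centered
    convolution with the tx/rx IRF cascade, then circular convolution with
    the sounding sequence.
    """
    n = len(m)
    tx_pos = np.asarray(tx_pos, dtype=float)
    rx_pos = np.asarray(rx_pos, dtype=float)
    h_static, h_mod = _channel_impulse_parts(
        scatterers, tx_pos, rx_pos, medium, m.chip_rate, n
    )
    h = h_static.copy()
    for artery, hm in h_mod.items():
        h += float(radius_waveform(artery, T)) * hm
    spec = np.fft.fft(h) * _centered_kernel_spectrum(irf.combined, n) * np.fft.fft(m.chips)
    return np.fft.ifft(spec).real


def pulse_compress(raw: RadarDataCube, m: MSequence) -> RadarDataCube:
    """Circularly correlate every fast-time trace with the M-sequence.

    A trace equal to the sequence itself compresses to the ideal two-valued
    autocorrelation (N at lag 0, -1 elsewhere); a circular delay of k chips
    moves the peak to lag k.  The operation is linear in the input.
    """
    if raw.compressed:
        raise ValueError("cube is already pulse-compressed")
    if raw.n_fast != len(m):
        raise ValueError(f"fast-time length {raw.n_fast} != sequence length {len(m)}")
    mspec = np.conj(np.fft.fft(m.chips))
    spec = np.fft.fft(raw.data, axis=0)
    comp = np.fft.ifft(spec * mspec[:, None, None], axis=0).real
    return raw.copy_with(data=comp, compressed=True)


def simulate_from_scatterers(
    scatterers: list[ScattererResponse],
    geom: ArrayGeometry,
    acq: AcquisitionConfig,
    medium: PhantomModel | None = None,
    m: MSequence | None = None,
    irf: SystemIRF | None = None,
    attrs: dict | None = None,
) -> RadarDataCube:
    """Synthesize the full data cube for an arbitrary scatterer set.

    Exploits the separability of the model: the trace of a channel at slow
    time T is a static part plus, per pulsating artery, a part scaled by
    cos(2 pi nu T).  Noise (if configured) is white Gaussian on the final
    traces at the configured SNR, seeded for reproducibility.
    """
    medium = medium or PhantomModel()
    m = m or generate_msequence(acq.m_order, chip_rate=acq.fast_rate)
    irf = irf or default_irf(fs=acq.fast_rate)
    n_fast = len(m)
    T = acq.slow_time_axis
    n_slow = acq.n_slow
    n_ch = geom.n_channels

    freqs = sorted(
        {
            sc.artery.pulsation_frequency
            for sc in scatterers
            if sc.artery is not None and sc.modulation_gain != 0.0
        }
    )
    for nu in freqs:
        if acq.slow_rate < 2.0 * nu:
            warnings.warn(
                f"slow-time rate {acq.slow_rate} Hz below twice the pulsation "
                f"frequency {nu} Hz: aliasing",
                stacklevel=2,
            )

    kernel_spec = _centered_kernel_spectrum(irf.combined, n_fast)
    mspec = np.fft.fft(m.chips)
    # compressed output multiplies by |M|^2; raw output by M
    shape_spec = kernel_spec * (np.abs(mspec) ** 2 if acq.compress else mspec)

    tx_all, rx_all = geom.channel_endpoints()
    static = np.zeros((n_fast, n_ch))
    mods: dict[ArteryModel, np.ndarray] = {}
    for ch in range(n_ch):
        h_static, h_mod = _channel_impulse_parts(
            scatterers, tx_all[ch], rx_all[ch], medium, acq.fast_rate, n_fast
        )
        static[:, ch] = np.fft.ifft(np.fft.fft(h_static) * shape_spec).real
        for artery, hm in h_mod.items():
            mods.setdefault(artery, np.zeros((n_fast, n_ch)))
            mods[artery][:, ch] = np.fft.ifft(np.fft.fft(hm) * shape_spec).real

    data = np.repeat(static[:, None, :], n_slow, axis=1)
    for artery, hm in mods.items():
        wav = radius_waveform(artery, T)
        data += hm[:, None, :] * wav[None, :, None]

    if acq.snr_db is not None:
        rng = np.random.default_rng(acq.seed)
        signal_rms = float(np.sqrt(np.mean(data**2)))
        noise_std = signal_rms * 10.0 ** (-acq.snr_db / 20.0)
        data = data + rng.normal(0.0, noise_std, size=data.shape)

    cube_attrs = {
        "permittivity": medium.rel_permittivity,
        "pulsation_hz": freqs[0] if freqs else 0.0,
        "seed": acq.seed,
    }
    if attrs:
        cube_attrs.update(attrs)
    channel_tx = np.array([t for t, _ in geom.channels])
    channel_rx = np.array([r for _, r in geom.channels])
    return RadarDataCube(
        data=data,
        fast_time_axis=np.arange(n_fast) / acq.fast_rate,
        slow_time_axis=T,
        channel_tx=channel_tx,
        channel_rx=channel_rx,
        compressed=acq.compress,
        attrs=cube_attrs,
    )


def simulate_cube(
    scenario: Scenario,
    geom: ArrayGeometry,
    acq: AcquisitionConfig,
    m: MSequence | None = None,
    irf: SystemIRF | None = None,
) -> RadarDataCube:
    """Simulate the full measurement cube for a scenario (compressed by
    default, with optional boundary clutter and additive noise)."""
    scatterers = scatterers_for_scenario(
        scenario,
        n_per_artery=acq.n_per_artery,
        include_clutter=acq.include_clutter,
    )
    return simulate_from_scatterers(
        scatterers,
        geom,
        acq,
        medium=scenario.phantom,
        m=m,
        irf=irf,
        attrs={"scenario": scenario.id},
    )
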