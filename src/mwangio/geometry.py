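"""Coordinate frame, antenna array, phantom and measurement scenarios.

The frame is right-handed with its origin on the cylinder axis at the top
surface of the phantom; ``z`` is negative downward.  All lengths are metres
and all times seconds internally; the CLI converts from cm/mm at the
boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "C0",
    "PhantomModel",
    "ArteryModel",
    "ArrayGeometry",
    "Scenario",
    "propagation_speed",
    "half_wavelength",
    "build_default_array",
    "build_scenario",
    "min_distance_to_array",
    "lateral_ring_depth",
    "DEFAULT_ARTERY_CENTERS",
]

#: Vacuum speed of light in m/s.
C0 = 299_792_458.0

#: Lateral (x, y) artery-surrogate centers in metres.
DEFAULT_ARTERY_CENTERS = (
    (0.05, 0.0),
    (0.0, 0.04),
    (-0.03, 0.0),
    (0.0, -0.02),
)

#: Relative permittivity used for the tube fillings.
FILL_PERMITTIVITY = {"air": 1.0, "water": 78.0}


def propagation_speed(rel_permittivity: float) -> float:
    """Wave speed in a homogeneous medium of the given relative permittivity.

    Parameters
    ----------
    rel_permittivity:
        Dimensionless relative permittivity, must be >= 1.

    Returns
    -------
    float
        Phase speed ``c0 / sqrt(rel_permittivity)`` in m/s.
    """
    if rel_permittivity < 1.0:
        raise ValueError(f"relative permittivity must be >= 1, got {rel_permittivity}")
    return C0 / math.sqrt(rel_permittivity)


def half_wavelength(rel_permittivity: float, frequency_hz: float) -> float:
    """Half wavelength in the medium at the given frequency (metres)."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    return propagation_speed(rel_permittivity) / (2.0 * frequency_hz)


@dataclass(frozen=True)
class PhantomModel:
    """Cylindrical tissue-mimicking phantom.

    Defaults follow the laboratory phantom: 13 cm diameter, 10 cm height,
    relative permittivity ~30 at the radar center frequency.
    """

    radius: float = 0.065
    height: float = 0.10
    rel_permittivity: float = 30.0
    top_surface_z: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("phantom radius must be positive")
        if self.height <= 0:
            raise ValueError("phantom height must be positive")
        if self.rel_permittivity < 1.0:
            raise ValueError("phantom permittivity must be >= 1")

    @property
    def wave_speed(self) -> float:
        """Propagation speed inside the phantom (m/s)."""
        return propagation_speed(self.rel_permittivity)

    def contains_lateral(self, x: float, y: float) -> bool:
        return math.hypot(x, y) < self.radius


@dataclass(frozen=True)
class ArteryModel:
    """Elastic-tube artery surrogate with sinusoidal radius pulsation.

    The pulsation amplitude is tied to the driving pressure amplitude and
    the tube stiffness: ``pulsation_amplitude == pressure_amplitude /
    stiffness`` holds exactly by construction.
    """

    center_xy: tuple[float, float]
    rest_radius: float = 0.0025
    stiffness: float = 1.0
    pressure_mean: float = 0.0
    pressure_amplitude: float = 0.15e-3
    pulsation_frequency: float = 0.08
    fill: str = "air"
    pulsating: bool = True
    z_extent: tuple[float, float] = (0.0, -0.10)

    def __post_init__(self) -> None:
        if self.fill not in FILL_PERMITTIVITY:
            raise ValueError(f"unknown fill {self.fill!r}")
        if self.stiffness <= 0:
            raise ValueError("stiffness must be positive")
        if self.pressure_amplitude < 0:
            raise ValueError("pressure amplitude must be non-negative")
        if self.rest_radius <= self.pulsation_amplitude:
            raise ValueError("rest radius must exceed the pulsation amplitude")
        if self.z_extent[0] <= self.z_extent[1]:
            raise ValueError("z_extent must be (top, bottom) with top > bottom")

    @property
    def pulsation_amplitude(self) -> float:
        """Radial amplitude in metres, equal to pressure_amplitude / stiffness."""
        return self.pressure_amplitude / self.stiffness

    @classmethod
    def with_amplitude(
        cls,
        center_xy: tuple[float, float],
        pulsation_amplitude: float = 0.15e-3,
        **kwargs,
    ) -> "ArteryModel":
        """Construct an artery from a target radial amplitude (stiffness = 1)."""
        return cls(
            center_xy=center_xy,
            stiffness=1.0,
            pressure_amplitude=pulsation_amplitude,
            **kwargs,
        )


@dataclass(frozen=True, eq=False)
class ArrayGeometry:
    """Antenna positions, roles, and the enumerated bistatic channels.

    ``channels`` lists (tx antenna index, rx antenna index) pairs into
    ``positions``; there are exactly ``kT * kR`` of them.
    """

    positions: np.ndarray
    roles: tuple[str, ...]
    channels: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_antennas, 3)")
        if len(self.roles) != len(self.positions):
            raise ValueError("one role per antenna required")
        if any(r not in ("TX", "RX") for r in self.roles):
            raise ValueError("roles must be 'TX' or 'RX'")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channels")
        if len(self.channels) != self.kT * self.kR:
            raise ValueError("channel count must equal kT * kR")

    @property
    def tx_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == "TX"]

    @property
    def rx_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == "RX"]

    @property
    def kT(self) -> int:
        return sum(1 for r in self.roles if r == "TX")

    @property
    def kR(self) -> int:
        return sum(1 for r in self.roles if r == "RX")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def ring_radius(self) -> float:
        """Lateral radius of the antenna ring(s)."""
        return float(np.hypot(self.positions[:, 0], self.positions[:, 1]).max())

    def channel_endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-channel TX and RX positions as two (n_channels, 3) arrays."""
        tx = np.array([self.positions[t] for t, _ in self.channels])
        rx = np.array([self.positions[r] for _, r in self.channels])
        return tx, rx


@dataclass(frozen=True)
class Scenario:
    """A phantom plus its artery surrogates for one measurement run."""

    id: int
    phantom: PhantomModel
    arteries: tuple[ArteryModel, ...]
    description: str = ""


def build_default_array(
    n_tx: int = 16,
    n_rx: int = 16,
    ring_z: tuple[float, ...] = (-0.04, -0.06),
    ring_radius: float = 0.065,
) -> ArrayGeometry:
    """Build the two-ring interleaved TX/RX array on the phantom wall.

    Antennas alternate TX, RX, TX, ... at equal angular spacing within each
    ring; the second ring starts with RX so that the bistatic coverage is
    azimuthally uniform.  With the defaults this yields 32 antennas (16 TX,
    16 RX) in rings at z = -4 cm and -6 cm and 256 enumerated channels.
    """
    n_rings = len(ring_z)
    total = n_tx + n_rx
    if total % n_rings != 0:
        raise ValueError("antenna count must divide evenly across rings")
    per_ring = total // n_rings
    if per_ring % 2 != 0:
        raise ValueError(f"odd antenna count per ring ({per_ring}); TX/RX interleaving needs an even count")

    positions = []
    roles: list[str] = []
    for ring, z in enumerate(ring_z):
        for slot in range(per_ring):
            theta = 2.0 * math.pi * slot / per_ring
            positions.append(
                (ring_radius * math.cos(theta), ring_radius * math.sin(theta), z)
            )
            # ring 0 starts with TX, ring 1 with RX, etc.
            is_tx = (slot + ring) % 2 == 0
            roles.append("TX" if is_tx else "RX")

    # asymmetric TX/RX counts: keep the interleaved ordering but reassign so
    # that exactly n_tx slots are transmitters
    tx_count = roles.count("TX")
    if tx_count != n_tx:
        order = [i for i, r in enumerate(roles) if r == "TX"] + [
            i for i, r in enumerate(roles) if r == "RX"
        ]
        roles = ["RX"] * len(roles)
        for i in order[:n_tx]:
            roles[i] = "TX"

    tx_idx = [i for i, r in enumerate(roles) if r == "TX"]
    rx_idx = [i for i, r in enumerate(roles) if r == "RX"]
    channels = tuple((t, r) for t in tx_idx for r in rx_idx)
    return ArrayGeometry(positions=np.array(positions), roles=tuple(roles), channels=channels)


#: Pulsating flags per scenario: scenario 1 all pulsating, scenarios 2-5
#: clip exactly one artery each (cycling through the four), scenario 6 all
#: pulsating with water fill.
SCENARIO_CLIPS = {1: (), 2: (0,), 3: (1,), 4: (2,), 5: (3,), 6: ()}


def build_scenario(
    scenario_id: int,
    pulsation_amplitude: float = 0.15e-3,
    pulsation_frequency: float = 0.08,
    phantom: PhantomModel | None = None,
) -> Scenario:
    """Build one of the six canonical four-artery scenarios.

    Scenarios 1-5 have air-filled tubes, scenario 6 water-filled; scenarios
    2-5 each clip (freeze) one artery.  Artery centers, diameter and
    pulsation parameters follow the laboratory phantom.
    """
    if scenario_id not in SCENARIO_CLIPS:
        raise ValueError(f"unknown scenario id {scenario_id}; expected 1..6")
    phantom = phantom or PhantomModel()
    fill = "water" if scenario_id == 6 else "air"
    clipped = SCENARIO_CLIPS[scenario_id]
    arteries = []
    for k, center in enumerate(DEFAULT_ARTERY_CENTERS):
        if not phantom.contains_lateral(*center):
            raise ValueError(f"artery center {center} outside the phantom")
        arteries.append(
            ArteryModel.with_amplitude(
                center_xy=center,
                pulsation_amplitude=pulsation_amplitude,
                pulsation_frequency=pulsation_frequency,
                fill=fill,
                pulsating=k not in clipped,
                z_extent=(phantom.top_surface_z, phantom.top_surface_z - phantom.height),
            )
        )
    desc = f"scenario {scenario_id}: fill={fill}, clipped={clipped or 'none'}"
    return Scenario(id=scenario_id, phantom=phantom, arteries=tuple(arteries), description=desc)


def min_distance_to_array(point, geom: ArrayGeometry) -> float:
    """Minimum Euclidean distance from a 3D point to any antenna."""
    if len(geom.positions) == 0:
        raise ValueError("empty array geometry")
    p = np.asarray(point, dtype=float)
    return float(np.linalg.norm(geom.positions - p, axis=1).min())


def lateral_ring_depth(point_xy, ring_radius: float = 0.065) -> float:
    """Lateral distance from an (x, y) point to the antenna ring circle.

    For points inside the ring this is the depth below the phantom wall,
    ``ring_radius - ||(x, y)||``.
    """
    x, y = point_xy
    return ring_radius - math.hypot(x, y)
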