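"""Run configuration: parsing, validation and hashing.

Configuration files use cm/mm/Hz units (matching the laboratory
conventions); everything is converted to metres/seconds on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .forward import AcquisitionConfig
from .geometry import ArteryModel, PhantomModel, Scenario, build_scenario

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for one end-to-end simulate/reconstruct run."""

    seed: int
    scenario_id: int = 1
    # acquisition
    fast_rate_hz: float = 13.0e9
    slow_rate_hz: float = 0.8
    duration_s: float = 125.0
    m_order: int = 9
    snr_db: float | None = None
    include_clutter: bool = True
    # phantom overrides
    phantom_diameter_cm: float = 13.0
    phantom_height_cm: float = 10.0
    permittivity: float = 30.0
    # pulsation
    pulsation_hz: float = 0.08
    delta_d_mm: float = 0.15
    # beamformer
    mode: str = "coherent"
    window_samples: int = 4
    voxel_mm: float = 2.0
    plane: str = "lateral"
    plane_coord_cm: float = -5.0
    apply_postfilter: bool = True
    # evaluation
    tolerance_mm: float = 10.0
    min_prominence: float = 0.1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        for name in (
            "fast_rate_hz",
            "slow_rate_hz",
            "duration_s",
            "phantom_diameter_cm",
            "phantom_height_cm",
            "pulsation_hz",
            "voxel_mm",
            "tolerance_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n = self.slow_rate_hz * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * slow_rate_hz must be an integer")
        if self.plane not in ("lateral", "longitudinal"):
            raise ValueError("plane must be 'lateral' or 'longitudinal'")

    def phantom(self) -> PhantomModel:
        return PhantomModel(
            radius=self.phantom_diameter_cm / 200.0,
            height=self.phantom_height_cm / 100.0,
            rel_permittivity=self.permittivity,
        )

    def scenario(self) -> Scenario:
        return build_scenario(
            self.scenario_id,
            pulsation_amplitude=self.delta_d_mm * 1e-3,
            pulsation_frequency=self.pulsation_hz,
            phantom=self.phantom(),
        )

    def acquisition(self) -> AcquisitionConfig:
        return AcquisitionConfig(
            fast_rate=self.fast_rate_hz,
            slow_rate=self.slow_rate_hz,
            duration=self.duration_s,
            m_order=self.m_order,
            snr_db=self.snr_db,
            seed=self.seed,
            include_clutter=self.include_clutter,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration; ``seed`` is mandatory."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    if "seed" not in raw:
        raise ValueError(f"{path}: configuration is missing the required 'seed'")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    return RunConfig(**raw)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the canonical configuration."""
    canon = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
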