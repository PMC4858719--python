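"""Core data containers shared across the pipeline.

All physical quantities are in micrometres (μm) unless stated otherwise.
Voxel grids are indexed (z, y, x); multi-channel stacks are (c, z, y, x).
Physical positions are voxel-centre coordinates: voxel index ``i`` along an
axis with spacing ``d`` sits at ``(i + 0.5) * d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd


class Compartment(IntEnum):
    """Per-voxel compartment labels around a microvessel.

    INTERIOR is everything enclosed by the basal-lamina shell (endothelium,
    lumen and intracellular space — the study does not separate them),
    BASAL_LAMINA is the CollagenIV-positive shell itself, PARENCHYMA is the
    brain tissue outside the vessel.
    """

    UNASSIGNED = 0
    INTERIOR = 1
    BASAL_LAMINA = 2
    PARENCHYMA = 3


@dataclass
class ImageStack:
    """A multi-channel 3D fluorescence stack with anisotropic voxel spacing.

    Parameters
    ----------
    voxels
        Integer array of shape (channels, z, y, x).
    voxel_size_zyx
        Physical voxel spacing in μm, (dz, dy, dx); strictly positive.
    channel_names
        One label per channel, e.g. ``("collagen", "cargo", "lysosome")``.
    bit_depth
        Acquisition bit depth; values are expected in [0, 2**bit_depth - 1].
    """

    voxels: np.ndarray
    voxel_size_zyx: tuple[float, float, float]
    channel_names: tuple[str, ...]
    bit_depth: int = 12
    stack_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be (c, z, y, x); got shape {self.voxels.shape}")
        self.voxel_size_zyx = tuple(float(v) for v in self.voxel_size_zyx)
        if len(self.voxel_size_zyx) != 3 or any(v <= 0 for v in self.voxel_size_zyx):
            raise ValueError(f"voxel spacing must be three positive values; got {self.voxel_size_zyx}")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.voxels.shape[0]} channels"
            )

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size_zyx
        return dz * dy * dx

    @property
    def field_size_um(self) -> tuple[float, float, float]:
        return tuple(n * d for n, d in zip(self.shape_zyx, self.voxel_size_zyx))

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) array for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r}; available: {self.channel_names}") from None
        return self.voxels[idx]


@dataclass
class CompartmentMask:
    """Voxel-wise partition of a field into the three vessel compartments."""

    labels: np.ndarray  # (z, y, x) of Compartment values
    voxel_size_zyx: tuple[float, float, float]
    source_threshold: float = float("nan")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.voxel_size_zyx = tuple(float(v) for v in self.voxel_size_zyx)
        valid = {int(Compartment.INTERIOR), int(Compartment.BASAL_LAMINA), int(Compartment.PARENCHYMA)}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"labels contain values outside {sorted(valid)}: {sorted(present - valid)}")

    def mask(self, compartment: Compartment) -> np.ndarray:
        return self.labels == int(compartment)

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size_zyx
        return dz * dy * dx


@dataclass
class CompartmentGeometry:
    """Physical geometry of a compartment mask (volumes in μm³, areas in μm²)."""

    volume_um3: dict[Compartment, float]
    shell_surface_area_um2: float

    @property
    def total_volume_um3(self) -> float:
        return sum(self.volume_um3.values())


@dataclass
class Spot:
    """One detected punctum (vesicle-scale bright object)."""

    centroid_zyx: tuple[float, float, float]  # μm
    radius_um: float
    intensity: float  # background-corrected integrated counts
    quality: float  # detector response at the peak
    channel: str = ""
    compartment: Compartment = Compartment.UNASSIGNED

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("spot radius must be positive")
        if self.intensity < 0:
            raise ValueError("integrated intensity must be non-negative")


class SpotSet:
    """An ordered collection of spots from one stack/channel with provenance."""

    def __init__(self, spots: Sequence[Spot], provenance: Mapping | None = None):
        self.spots = list(spots)
        self.provenance = dict(provenance or {})

    def __len__(self) -> int:
        return len(self.spots)

    def __iter__(self) -> Iterator[Spot]:
        return iter(self.spots)

    def __getitem__(self, i: int) -> Spot:
        return self.spots[i]

    @property
    def centroids(self) -> np.ndarray:
        """(n, 3) array of centroids in μm (z, y, x)."""
        if not self.spots:
            return np.zeros((0, 3))
        return np.array([s.centroid_zyx for s in self.spots], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([s.radius_um for s in self.spots], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([s.intensity for s in self.spots], dtype=float)

    def filter(self, predicate) -> "SpotSet":
        return SpotSet([s for s in self.spots if predicate(s)], self.provenance)

    def in_compartment(self, compartment: Compartment) -> "SpotSet":
        return self.filter(lambda s: s.compartment == compartment)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stack_id": self.provenance.get("stack_id", ""),
                "channel": s.channel,
                "z_um": s.centroid_zyx[0],
                "y_um": s.centroid_zyx[1],
                "x_um": s.centroid_zyx[2],
                "radius_um": s.radius_um,
                "intensity": s.intensity,
                "quality": s.quality,
                "compartment": Compartment(s.compartment).name,
            }
            for s in self.spots
        ]
        cols = [
            "stack_id", "channel", "z_um", "y_um", "x_um",
            "radius_um", "intensity", "quality", "compartment",
        ]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class DistributionFit:
    """Maximum-likelihood log-normal fit of per-object values."""

    mu_ln: float
    sigma_ln: float
    n: int
    family: str = "log-normal"
    method: str = "mle"

    @property
    def median(self) -> float:
        return float(np.exp(self.mu_ln))


@dataclass
class ColocalizationResult:
    """Object-based colocalization with a randomization null.

    ``observed_fraction`` is the fraction of total cargo object intensity in
    cargo objects matched to a marker object. ``random_fraction_mean/sd``
    summarise the same statistic after re-placing marker objects uniformly at
    random in the INTERIOR compartment. ``corrected_fraction`` is the
    chance-corrected value clamped to [0, observed]; ``excess_fraction`` is
    the same difference left unclamped (useful for null calibration, where
    its mean should be ~0).
    """

    observed_fraction: float
    random_fraction_mean: float
    random_fraction_sd: float
    corrected_fraction: float
    excess_fraction: float
    n_randomizations: int
    match_rule: dict = field(default_factory=dict)


@dataclass
class VesselQuantification:
    """Per-vessel normalized cargo metrics."""

    stack_id: str
    genotype: str
    animal: str
    bl_intensity_per_um2: float
    parenchyma_intensity_per_um3: float
    vesicles_per_um3: float
    background: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "stack_id": self.stack_id,
            "genotype": self.genotype,
            "animal": self.animal,
            "bl_intensity_per_um2": self.bl_intensity_per_um2,
            "parenchyma_intensity_per_um3": self.parenchyma_intensity_per_um3,
            "vesicles_per_um3": self.vesicles_per_um3,
            "background": self.background,
        }
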