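"""Core data containers for 4D-flow velocity data on regular voxel grids.

Velocity components are stored in cm/s (the native phase-contrast unit),
spatial metadata in mm, and timing metadata in ms.  All derived physical
quantities (kinetic energy, flow volumes, viscous dissipation) are computed
in SI internally and presented in the units conventional for 4D-flow
reporting (J, m/s, mL/cycle, W).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "VoxelGrid",
    "VelocityField4D",
    "MagnitudeSeries",
    "LumenMasks",
    "FluidConstants",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid: shape ``(nx, ny, nz)``, spacing and origin in mm.

    World coordinates are voxel-centered: ``world = origin + index * spacing``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Voxel volume dV in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0]))

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def world_coordinates(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center world coordinates in mm."""
        ax = self.axis_coordinates()
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)


@dataclass
class VelocityField4D:
    """Time-resolved three-component velocity field in cm/s.

    Each component has shape ``grid.shape + (T,)``.  ``venc`` is the velocity
    encoding limit in cm/s; values beyond +/-venc alias (phase wrap).
    ``temporal_resolution`` and ``rr_interval`` are in ms.
    """

    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray
    grid: VoxelGrid
    venc: float
    temporal_resolution: float
    rr_interval: float
    gating_mode: Literal["prospective", "retrospective"] = "retrospective"

    def __post_init__(self) -> None:
        if not (self.vx.shape == self.vy.shape == self.vz.shape):
            raise ValueError("velocity components must share a common shape")
        if self.vx.shape[:3] != tuple(self.grid.shape):
            raise ValueError(
                f"component shape {self.vx.shape[:3]} does not match grid {self.grid.shape}"
            )
        if self.vx.ndim != 4 or self.n_timepoints < 2:
            raise ValueError("velocity field must have at least 2 timepoints")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        for name in ("vx", "vy", "vz"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in component {name}")

    @property
    def n_timepoints(self) -> int:
        return self.vx.shape[3]

    @property
    def components(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.vx, self.vy, self.vz

    def speed(self) -> np.ndarray:
        """Voxel-wise speed |v| in cm/s, shape grid + (T,)."""
        return np.sqrt(self.vx**2 + self.vy**2 + self.vz**2)

    def full_cycle_frames(self) -> int:
        """Number of frames spanning the full R-R interval."""
        return int(round(self.rr_interval / self.temporal_resolution))

    def copy(self) -> "VelocityField4D":
        return replace(
            self, vx=self.vx.copy(), vy=self.vy.copy(), vz=self.vz.copy()
        )


@dataclass
class MagnitudeSeries:
    """Time-resolved magnitude (anatomy) image in arbitrary units."""

    magnitude: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        if self.magnitude.shape[:3] != tuple(self.grid.shape):
            raise ValueError("magnitude shape does not match grid")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")

    def time_averaged(self) -> np.ndarray:
        if self.magnitude.ndim == 4:
            return self.magnitude.mean(axis=3)
        return self.magnitude


@dataclass
class LumenMasks:
    """Binary segmentations on a common grid.

    ``whole`` is the full aorta (TL + FL); ``fl`` is derived by subtracting the
    true lumen from the whole-aorta mask.  ``static_tissue`` marks voxels with
    no true flow, used to fit the eddy-current background phase.
    """

    whole: np.ndarray
    tl: np.ndarray
    fl: np.ndarray
    static_tissue: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.whole = np.asarray(self.whole, dtype=bool)
        self.tl = np.asarray(self.tl, dtype=bool)
        self.fl = np.asarray(self.fl, dtype=bool)
        if self.static_tissue is None:
            self.static_tissue = np.zeros_like(self.whole)
        self.static_tissue = np.asarray(self.static_tissue, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if np.any(self.tl & self.fl):
            raise ValueError("TL and FL masks overlap")
        if np.any((self.tl | self.fl) != self.whole):
            raise ValueError("TL union FL must equal the whole-aorta mask")
        if np.any(self.static_tissue & self.whole):
            raise ValueError("static-tissue mask overlaps the lumen")


@dataclass(frozen=True)
class FluidConstants:
    """Blood model constants: density rho (kg/m^3) and viscosity mu (cP)."""

    rho: float = 1060.0
    mu: float = 3.2

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")

    @property
    def mu_pa_s(self) -> float:
        """Dynamic viscosity in Pa*s (1 cP = 1e-3 Pa*s)."""
        return self.mu * 1e-3
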