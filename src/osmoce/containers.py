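"""Core data containers for phase-resolved OCT elastography.

The containers follow the acquisition geometry of a spectral-domain OCT
system: a B-scan is a 2D complex array with axial index ``m`` (rows,
increasing depth, sampled at the *optical* pitch measured in air) and
lateral index ``j`` (columns).  Everything downstream — interframe phase
products, strain maps, cumulative maps — keeps that grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "OpticalParams",
    "ComplexBScan",
    "BScanSeries",
    "InterframeProduct",
    "StrainMap",
    "CumulativeStrainMap",
    "SurfaceMap",
]


@dataclass(frozen=True)
class OpticalParams:
    """Optical constants and pixel geometry of an OCT B-scan.

    Parameters
    ----------
    lambda0_nm
        Central wavelength of the source in vacuum, nm.
    n
        Refractive index of the imaged medium (dimensionless, >= 1).
        Must be supplied explicitly in file metadata; the default of 1.4
        is a typical value for hydrated collagenous tissue.
    dz_air_um
        Axial pixel pitch as measured in air (optical path), µm/pixel.
    dx_um
        Lateral pixel pitch, µm/pixel.
    """

    lambda0_nm: float = 1300.0
    n: float = 1.4
    dz_air_um: float = 2000.0 / 512
    dx_um: float = 4000.0 / 256

    def __post_init__(self) -> None:
        if not self.lambda0_nm > 0:
            raise ValueError("lambda0_nm must be positive")
        if not self.n >= 1.0:
            raise ValueError("refractive index n must be >= 1")
        if not self.dz_air_um > 0:
            raise ValueError("dz_air_um must be positive")
        if not self.dx_um > 0:
            raise ValueError("dx_um must be positive")

    @property
    def lambda0_um(self) -> float:
        return self.lambda0_nm * 1e-3

    @property
    def dz_phys_um(self) -> float:
        """Axial pixel pitch in physical (in-tissue) µm: optical pitch / n."""
        return self.dz_air_um / self.n


@dataclass
class ComplexBScan:
    """One complex-valued OCT frame a(m, j) = A·exp(iϕ)."""

    data: np.ndarray
    optics: OpticalParams
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        if self.data.ndim != 2 or min(self.data.shape) < 2:
            raise ValueError("a B-scan must be 2D with at least 2 rows and 2 columns")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("B-scan contains non-finite values")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class BScanSeries:
    """Time-ordered B-scans with a uniform interframe interval ``dt`` (s)."""

    frames: Sequence[ComplexBScan]
    dt: float

    def __post_init__(self) -> None:
        self.frames = list(self.frames)
        if not self.frames:
            raise ValueError("series must contain at least one frame")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        shape = self.frames[0].shape
        optics = self.frames[0].optics
        for f in self.frames:
            if f.shape != shape:
                raise ValueError("all frames in a series must share the grid shape")
            if f.optics != optics:
                raise ValueError("all frames in a series must share optics")
        ts = np.array([f.timestamp for f in self.frames], dtype=float)
        if len(ts) > 1:
            spacing = np.diff(ts)
            if np.any(spacing <= 0):
                raise ValueError("frame timestamps must be strictly increasing")
            if np.any(np.abs(spacing - self.dt) > 0.01 * self.dt):
                raise ValueError("frame spacing deviates from dt by more than 1%")

    @property
    def optics(self) -> OpticalParams:
        return self.frames[0].optics

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class InterframeProduct:
    """Element-wise product b(m, j) = a2 · a1* of two consecutive frames.

    ``arg b`` is the interframe phase variation Φ ∈ (−π, π]; ``|b|`` is the
    product of the two amplitudes, which is what gives the vector strain
    estimator its intrinsic amplitude weighting.
    """

    b: np.ndarray
    optics: OpticalParams

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.b)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.b)


@dataclass
class StrainMap:
    """Per-pixel interframe axial strain ∂U/∂z with a validity mask.

    ``depth_convention`` records whether the axial derivative was taken with
    respect to optical depth in air or physical in-tissue depth; the strain
    value itself is identical in the two conventions (the factors of n
    cancel), so the tag is bookkeeping, not a unit switch.
    """

    eps: np.ndarray
    mask: np.ndarray
    window_z_um: float
    window_x_um: float
    depth_convention: str = "optical"
    optics: Optional[OpticalParams] = None

    def __post_init__(self) -> None:
        if self.eps.shape != self.mask.shape:
            raise ValueError("eps and mask must share a shape")
        if not np.all(np.isfinite(self.eps[self.mask])):
            raise ValueError("strain map has non-finite values on valid pixels")

    @property
    def resolution_um(self) -> float:
        """Spatial resolution of the strain map: half the processing window."""
        return 0.5 * self.window_z_um


@dataclass
class CumulativeStrainMap:
    """Running sum of interframe strain maps up to elapsed time ``t`` (s)."""

    eps_cum: np.ndarray
    mask: np.ndarray
    t: float
    n_frames: int
    window_z_um: float = float("nan")
    window_x_um: float = float("nan")
    optics: Optional[OpticalParams] = None

    def __post_init__(self) -> None:
        if self.eps_cum.shape != self.mask.shape:
            raise ValueError("eps_cum and mask must share a shape")


@dataclass
class SurfaceMap:
    """Per-column axial pixel index of the sample surface."""

    surf: np.ndarray
    threshold_frac: float
    smooth_px: int
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.surf = np.asarray(self.surf, dtype=int)
        if self.interpolated is None:
            self.interpolated = np.zeros(self.surf.shape, dtype=bool)
        if np.any(self.surf < 0):
            raise ValueError("surface indices must be non-negative")
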