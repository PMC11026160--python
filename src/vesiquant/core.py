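"""Core in-memory containers shared by every stage of the pipeline.

All volumetric data live on anisotropic voxel grids in fixed Z, Y, X axis
order (plane index first), with the physical voxel pitch stored in
micrometres per axis.  Physical-unit morphology, depth measurements and
volume conversions all read the pitch from here, so a volume and any mask
derived from it must share the same geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VoxelVolume",
    "Mask3D",
    "PlanarROI",
    "LayerSet",
    "RegionStats",
    "HistogramResult",
    "PenetrationStats",
    "Trajectory",
    "MSDCurve",
    "ActivityMeasurement",
    "SubjectRecord",
    "DWIPair",
    "GeometryError",
]

#: seconds in one day, used when half-lives are quoted in days
SECONDS_PER_DAY = 86400.0

#: iodine-131 half-life in days, the radionuclide used for therapy
I131_HALF_LIFE_DAYS = 8.01

#: fluorine-18 half-life in minutes (standard physical constant; the PET tracer)
F18_HALF_LIFE_MIN = 109.77


class GeometryError(ValueError):
    """Raised when a geometric precondition fails (mismatched grids,
    shapes that do not fit the voxel grid, invalid spacing)."""


def _validate_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3 or any(s <= 0 for s in sp):
        raise GeometryError(f"spacing must be 3 positive floats (z,y,x), got {spacing!r}")
    return sp  # type: ignore[return-value]


@dataclass
class VoxelVolume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    data:
        Intensity grid, axis order (z, y, x).
    spacing:
        Voxel pitch in µm per axis, same order.
    origin:
        Physical position of voxel (0, 0, 0) in µm.  Only carried through;
        no operation in the package depends on it.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel in µm³."""
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "VoxelVolume | Mask3D") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class Mask3D:
    """A binary volume on the same grid as its parent :class:`VoxelVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise GeometryError(f"mask must be 3D, got shape {self.data.shape}")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())

    def physical_volume_um3(self) -> float:
        return self.count() * self.voxel_volume_um3

    def same_geometry(self, other: "VoxelVolume | Mask3D") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def copy(self) -> "Mask3D":
        return Mask3D(self.data.copy(), self.spacing)


@dataclass
class PlanarROI:
    """A closed polygon annotated on one plane of a stack.

    ``polygon`` is an (n, 2) array of (y, x) vertices in continuous pixel
    coordinates; pixel centres sit at integer positions.
    """

    plane_index: int
    polygon: np.ndarray

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
            raise ValueError("polygon must be an (n, 2) array of (y, x) vertices")
        if len(np.unique(self.polygon, axis=0)) < 3:
            raise ValueError("polygon needs at least 3 distinct vertices")


@dataclass
class LayerSet:
    """Ordered concentric tissue layers produced by cavity-mask dilation.

    ``layers`` maps a role label (``"L1"``, ``"TL2"``, ``"HL"``, ...) to its
    mask.  ``shells`` keeps the successive cavity masks BC1..BC(n+1) that the
    layers were differenced from, so conservation checks remain possible.
    """

    layers: dict[str, Mask3D]
    thickness_um: float
    shells: list[Mask3D] = field(default_factory=list)

    def __getitem__(self, role: str) -> Mask3D:
        return self.layers[role]

    def roles(self) -> list[str]:
        return list(self.layers)


@dataclass
class RegionStats:
    """Intensity summary of one masked region."""

    integrated_intensity: float
    voxel_count: int
    physical_volume_um3: float
    normalized_intensity: float  # a.u. per µm³


@dataclass
class HistogramResult:
    """Histogram of voxel (or pixel) intensities inside a mask."""

    bin_edges: np.ndarray
    counts: np.ndarray
    axis_scale: str = "linear"  # or "log"

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PenetrationStats:
    """Depth-of-penetration summary for detected signal inside a region.

    ``median_depth_um`` is ``None`` when the region holds no foreground:
    an absent median, not zero, so that summaries are not biased.
    """

    median_depth_um: float | None
    occupancy: float
    n_foreground_voxels: int


@dataclass
class Trajectory:
    """A timestamped 2D particle track (positions in µm)."""

    times: np.ndarray
    positions: np.ndarray  # (n, 2) as (x, y)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("a trajectory needs at least two time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.positions.shape != (len(self.times), 2):
            raise ValueError("positions must be (n, 2) matching times")


@dataclass
class MSDCurve:
    """Time-and-ensemble averaged mean square displacement with power-law fit.

    The fit is MSD(τ) = 4 D τ^α (two dimensions): α = 1 for free diffusion,
    α = 2 for ballistic transport.
    """

    lags: np.ndarray
    msd: np.ndarray
    diffusion_coeff: float  # µm² s⁻¹ (generalized: MSD/4 prefactor)
    alpha: float


@dataclass
class ActivityMeasurement:
    """A radioactivity reading with its timestamp and isotope half-life.

    ``time_s`` is seconds since the common reference time; decay correction
    back-computes the activity at that reference.
    """

    activity_mbq: float
    time_s: float
    half_life_s: float

    def __post_init__(self) -> None:
        if self.half_life_s <= 0:
            raise ValueError("half-life must be positive")
        if self.activity_mbq < 0:
            raise ValueError("activity must be non-negative")


@dataclass
class SubjectRecord:
    """One animal: group membership, tumour volumes and activities."""

    subject_id: str
    group: str
    pre_volume_mm3: float | None = None
    post_volume_mm3: float | None = None
    injected_activity: ActivityMeasurement | None = None
    voi_activity: ActivityMeasurement | None = None
    tumour_volume_cm3: float | None = None

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError("group label must be non-empty")
        for v in (self.pre_volume_mm3, self.post_volume_mm3, self.tumour_volume_cm3):
            if v is not None and v <= 0:
                raise ValueError("volumes must be positive where present")


@dataclass
class DWIPair:
    """A diffusion-weighted MRI acquisition pair: b = 0 baseline and b > 0."""

    b0: VoxelVolume
    b_dw: VoxelVolume
    b_value: float = 650.0  # s mm⁻²

    def __post_init__(self) -> None:
        if not self.b0.same_geometry(self.b_dw):
            raise GeometryError("b0 and diffusion-weighted volumes must share geometry")
        if self.b_value <= 0:
            raise ValueError("the diffusion-weighted b-value must be positive")
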