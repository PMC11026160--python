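"""Quantification of scattered light-sheet signal inside 3D masks.

The primary readout is integrated intensity normalized by the physical
volume of the mask — intensity, not particle counting, since individual
nanobots below the diffraction limit are not resolved.  The module also
provides masked 16-bit voxel histograms (linear or logarithmic intensity
axis), signal/background separation, penetration-depth and occupancy
statistics, and a Gaussian-fit estimate of lateral resolution from a
single-particle image.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, optimize

from .core import (
    GeometryError,
    HistogramResult,
    LayerSet,
    Mask3D,
    PenetrationStats,
    RegionStats,
    VoxelVolume,
)

__all__ = [
    "masked_stats",
    "masked_histogram",
    "foreground_detect",
    "penetration_stats",
    "layer_profile",
    "estimate_lateral_resolution",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


def masked_stats(scattered: VoxelVolume, mask: Mask3D) -> RegionStats:
    """Integrated and volume-normalized intensity inside one mask."""
    if not scattered.same_geometry(mask):
        raise GeometryError("volume and mask must share geometry")
    if not mask.data.any():
        raise ValueError("mask is empty: normalized intensity undefined")
    vals = np.asarray(scattered.data)[mask.data]
    integrated = float(vals.sum(dtype=np.float64))
    count = int(vals.size)
    volume = count * mask.voxel_volume_um3
    return RegionStats(
        integrated_intensity=integrated,
        voxel_count=count,
        physical_volume_um3=volume,
        normalized_intensity=integrated / volume,
    )


def masked_histogram(
    scattered: VoxelVolume,
    mask: Mask3D,
    n_bins: int = 4096,
    scale: str = "linear",
    bit_depth: int = 16,
) -> HistogramResult:
    """Voxel intensity histogram of the masked volume on the full bit range.

    ``scale="log"`` uses log-spaced bin edges above intensity 1 (with one
    leading bin for [0, 1)); the counts always sum to the mask size.
    """
    if n_bins < 2:
        raise ValueError("need at least two bins")
    if scale not in ("linear", "log"):
        raise ValueError("scale must be 'linear' or 'log'")
    top = float(2**bit_depth - 1)
    if scale == "linear":
        edges = np.linspace(0.0, top, n_bins + 1)
    else:
        edges = np.concatenate([[0.0], np.geomspace(1.0, top, n_bins)])
    if not mask.data.any():
        warnings.warn("empty mask: empty histogram returned")
        return HistogramResult(edges, np.zeros(len(edges) - 1, dtype=np.int64), scale)
    vals = np.asarray(scattered.data)[mask.data]
    counts, _ = np.histogram(np.clip(vals, 0, top), bins=edges)
    return HistogramResult(edges, counts.astype(np.int64), scale)


def foreground_detect(
    scattered: VoxelVolume,
    mask: Mask3D,
    threshold: float | None = None,
) -> tuple[Mask3D, float | None]:
    """Separate nanobot signal from background inside a mask.

    With no explicit ``threshold``, Otsu's threshold is computed on the
    masked intensities.  Returns the foreground mask together with the
    threshold used (``None`` when the masked intensities are constant, in
    which case the foreground is empty and a warning is issued).
    """
    if not mask.data.any():
        raise ValueError("mask is empty")
    if not scattered.same_geometry(mask):
        raise GeometryError("volume and mask must share geometry")
    vals = np.asarray(scattered.data)[mask.data]
    if threshold is None:
        if np.ptp(vals) == 0:
            warnings.warn("constant masked intensities: empty foreground")
            return Mask3D(np.zeros(mask.shape, bool), mask.spacing), None
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(vals))
    fg = (np.asarray(scattered.data) > threshold) & mask.data
    return Mask3D(fg, mask.spacing), float(threshold)


def penetration_stats(
    foreground: Mask3D,
    surface: Mask3D,
    region: Mask3D,
) -> PenetrationStats:
    """Median penetration depth and occupancy of foreground in a region.

    Depth of a voxel is its anisotropy-aware Euclidean distance to the
    ``surface`` mask (typically the bladder cavity).  Occupancy is the
    fraction of the region's voxels that are foreground.  When the region
    holds no foreground the median is reported as missing (``None``).
    """
    for m in (surface, region):
        if not foreground.same_geometry(m):
            raise GeometryError("masks must share geometry")
    if not surface.data.any():
        raise ValueError("surface mask is empty")
    region_n = region.count()
    if region_n == 0:
        raise ValueError("region mask is empty")
    fg_in = foreground.data & region.data
    n_fg = int(fg_in.sum())
    occupancy = n_fg / region_n
    if n_fg == 0:
        return PenetrationStats(None, occupancy, 0)
    depth = ndimage.distance_transform_edt(~surface.data, sampling=surface.spacing)
    return PenetrationStats(float(np.median(depth[fg_in])), occupancy, n_fg)


def layer_profile(
    scattered: VoxelVolume,
    layers: LayerSet,
) -> dict:
    """Per-layer volume-normalized intensity with the two headline ratios.

    Returns ``{"stats": {role: RegionStats | None}, "ratios": {...}}`` where
    the ratios are TL1/HL (tumour-surface enrichment over healthy
    urothelium) and TLn/TL1 (depth attenuation across the layer stack) of
    normalized intensity.  Empty layers are reported as missing and
    excluded from ratios that need them.
    """
    stats: dict[str, RegionStats | None] = {}
    for role, mask in layers.layers.items():
        if mask.data.any():
            stats[role] = masked_stats(scattered, mask)
        else:
            warnings.warn(f"layer {role} is empty: reported as missing")
            stats[role] = None

    ratios: dict[str, float | None] = {}
    tl1, hl = stats.get("TL1"), stats.get("HL")
    ratios["TL1_over_HL"] = (
        tl1.normalized_intensity / hl.normalized_intensity
        if tl1 and hl and hl.normalized_intensity > 0
        else None
    )
    tl_roles = sorted(
        (r for r in stats if r.startswith("TL")), key=lambda r: int(r[2:])
    )
    if len(tl_roles) >= 2:
        last = stats.get(tl_roles[-1])
        key = f"{tl_roles[-1]}_over_TL1"
        ratios[key] = (
            last.normalized_intensity / tl1.normalized_intensity
            if tl1 and last and tl1.normalized_intensity > 0
            else None
        )
    return {"stats": stats, "ratios": ratios}


def estimate_lateral_resolution(
    bead_image: np.ndarray,
    pixel_size_um: float,
) -> float:
    """Lateral FWHM (µm) from a 2D image of a single sub-resolution particle.

    Fits an isotropic 2D Gaussian with offset by least squares and returns
    FWHM = 2 √(2 ln 2) σ ≈ 2.3548 σ in physical units.
    """
    img = np.asarray(bead_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("bead image must be 2D")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    ny, nx = img.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    offset0 = float(np.median(img))
    amp0 = float(img.max() - offset0)
    if amp0 <= 0:
        raise RuntimeError("no blob above the background level")
    cy0, cx0 = np.unravel_index(np.argmax(img), img.shape)

    def model(p):
        amp, cy, cx, sigma, off = p
        return off + amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))

    def resid(p):
        return (model(p) - img).ravel()

    p0 = [amp0, float(cy0), float(cx0), max(1.0, min(ny, nx) / 8.0), offset0]
    sol = optimize.least_squares(resid, p0)
    if not sol.success or sol.x[3] <= 0:
        raise RuntimeError(
            f"Gaussian fit diverged (status {sol.status}, "
            f"residual {np.sqrt(np.mean(sol.fun**2)):.3g})"
        )
    return float(abs(sol.x[3]) * FWHM_PER_SIGMA * pixel_size_um)
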