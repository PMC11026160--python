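"""Sparse-annotation 3D masks and physical-distance morphology.

The semi-automated segmentation workflow for whole-bladder light-sheet
stacks, as library functions: polygons annotated on a few planes become
full 3D masks by shape-based interpolation; masks are grown and shrunk by
distances expressed in micrometres on anisotropic grids; and layer masks
are produced by successive dilation and subtraction of the bladder-cavity
mask (BC1 → BC2 → ..., L_k = BC_{k+1} − BC_k, tumour layers TL_k = L_k minus
the healthy annotation, healthy layer HL = L1 minus the tumour annotation).

Morphological distances are Euclidean in physical space: a voxel joins a
dilation if its anisotropy-aware distance to the existing foreground is
≤ the requested distance (closed ball).  Erosion is defined by complement
duality, erode(M, d) = ¬dilate(¬M, d).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .core import GeometryError, LayerSet, Mask3D, PlanarROI, VoxelVolume

__all__ = [
    "rasterize_polygon",
    "interpolate_roi_stack",
    "dilate_physical",
    "erode_physical",
    "boolean_op",
    "build_layers",
    "internal_tissue_mask",
]


# ---------------------------------------------------------------------------
# polygon rasterization
# ---------------------------------------------------------------------------

def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper intersection test for open segments (shared endpoints allowed)."""

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(p3, p4, p1)
    d2 = cross(p3, p4, p2)
    d3 = cross(p1, p2, p3)
    d4 = cross(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _check_simple(polygon: np.ndarray) -> None:
    n = len(polygon)
    edges = [(polygon[i], polygon[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent around the wrap
            if _segments_intersect(*edges[i], *edges[j]):
                raise ValueError("polygon is self-intersecting")


def rasterize_polygon(polygon: np.ndarray | Sequence, plane_shape: tuple[int, int]) -> np.ndarray:
    """Fill a simple polygon on a pixel grid.

    A pixel belongs to the mask iff its centre (integer coordinates) is
    inside the polygon under the even-odd rule; vertex order (clockwise or
    counter-clockwise) is irrelevant.

    Parameters
    ----------
    polygon:
        (n, 2) array of (y, x) vertices in continuous pixel coordinates.
    plane_shape:
        (ny, nx) of the target plane.

    Returns
    -------
    2D boolean mask of shape ``plane_shape``.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(np.unique(poly, axis=0)) < 3:
        raise ValueError("polygon must have at least 3 distinct (y, x) vertices")
    _check_simple(poly)

    ny, nx = plane_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    py, px = poly[:, 0], poly[:, 1]
    qy, qx = np.roll(py, -1), np.roll(px, -1)

    inside = np.zeros((ny, nx), dtype=bool)
    # even-odd crossing count with half-open edge convention [min, max)
    for y1, x1, y2, x2 in zip(py, px, qy, qx):
        if y1 == y2:
            continue  # horizontal edges never cross the scan ray
        cond = (yy >= min(y1, y2)) & (yy < max(y1, y2))
        x_at = x1 + (yy - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (xx < x_at)
    return inside


# ---------------------------------------------------------------------------
# shape-based interpolation of sparse planar annotations
# ---------------------------------------------------------------------------

def _signed_distance(mask2d: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance: negative inside, positive outside."""
    if mask2d.any():
        outside = ndimage.distance_transform_edt(~mask2d)
        inside = ndimage.distance_transform_edt(mask2d)
        return outside - inside
    # empty shape: everything is far outside
    return np.full(mask2d.shape, np.inf)


def interpolate_roi_stack(
    rois: Iterable[PlanarROI],
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> Mask3D:
    """Turn sparse planar polygon annotations into a dense 3D mask.

    On annotated planes the rasterized polygon is reproduced exactly.
    Between two consecutive annotated planes the shape morphs by linear
    blending of the planes' signed Euclidean distance maps, thresholded at
    zero — the standard shape-based interpolation, which degrades gracefully
    when the shape's topology changes.  No extrapolation happens before the
    first or after the last annotated plane.
    """
    roi_list = sorted(rois, key=lambda r: r.plane_index)
    if not roi_list:
        raise ValueError("at least one ROI is required")
    planes = [r.plane_index for r in roi_list]
    if len(set(planes)) != len(planes):
        raise ValueError(f"duplicate plane indices in {planes}")
    nz, ny, nx = shape
    if planes[0] < 0 or planes[-1] >= nz:
        raise GeometryError(f"plane index out of bounds for {nz} planes: {planes}")

    out = np.zeros(shape, dtype=bool)
    rasters = {r.plane_index: rasterize_polygon(r.polygon, (ny, nx)) for r in roi_list}
    for p, m in rasters.items():
        out[p] = m

    for (p0, p1) in zip(planes[:-1], planes[1:]):
        if p1 - p0 < 2:
            continue
        sd0 = _signed_distance(rasters[p0])
        sd1 = _signed_distance(rasters[p1])
        for p in range(p0 + 1, p1):
            w = (p - p0) / (p1 - p0)
            blend = (1.0 - w) * sd0 + w * sd1
            out[p] = blend < 0
    return Mask3D(out, spacing)


# ---------------------------------------------------------------------------
# physical-distance morphology
# ---------------------------------------------------------------------------

def dilate_physical(mask: Mask3D, distance_um: float) -> Mask3D:
    """Grow a mask by a Euclidean distance in µm, anisotropy-aware.

    The result contains exactly the voxels whose physical distance to the
    input foreground is ≤ ``distance_um``; it is a superset of the input and
    monotone in the distance.
    """
    if distance_um < 0:
        raise ValueError("dilation distance must be non-negative")
    if distance_um == 0 or not mask.data.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask.data, sampling=mask.spacing)
    return Mask3D(dist <= distance_um, mask.spacing)


def erode_physical(mask: Mask3D, distance_um: float) -> Mask3D:
    """Shrink a mask by a physical distance: erode(M, d) = ¬dilate(¬M, d)."""
    if distance_um < 0:
        raise ValueError("erosion distance must be non-negative")
    if distance_um == 0:
        return mask.copy()
    comp = Mask3D(~mask.data, mask.spacing)
    return Mask3D(~dilate_physical(comp, distance_um).data, mask.spacing)


# ---------------------------------------------------------------------------
# plane-wise Boolean algebra
# ---------------------------------------------------------------------------

_BOOL_OPS = {
    "and": np.logical_and,
    "or": np.logical_or,
    "subtract": lambda a, b: np.logical_and(a, np.logical_not(b)),
    "xor": np.logical_xor,
}


def boolean_op(a: Mask3D, b: Mask3D, op: str) -> Mask3D:
    """Voxel-wise set operation between two masks of identical geometry.

    Planes are processed one at a time, so the transient working set stays
    O(one plane) however deep the stack is — a streaming contract that keeps
    the operation usable on stacks too large for memory.
    """
    if op not in _BOOL_OPS:
        raise ValueError(f"op must be one of {sorted(_BOOL_OPS)}, got {op!r}")
    if not a.same_geometry(b):
        raise GeometryError("masks must share shape and spacing")
    fn = _BOOL_OPS[op]
    out = np.empty(a.shape, dtype=bool)
    for z in range(a.shape[0]):
        out[z] = fn(a.data[z], b.data[z])
    return Mask3D(out, a.spacing)


# ---------------------------------------------------------------------------
# concentric layer construction
# ---------------------------------------------------------------------------

def build_layers(
    bc: Mask3D,
    urothelium: Mask3D,
    tumour: Mask3D,
    thickness_um: float = 33.0,
    n_layers: int = 3,
) -> LayerSet:
    """Build concentric tissue layers from the bladder-cavity mask.

    Starting from the cavity mask BC1, each shell is a ``thickness_um``
    physical dilation of the previous one; layer L_k = BC_{k+1} − BC_k.
    Tumour layers are TL_k = L_k − urothelium-annotation, and the healthy
    surface layer is HL = L1 − tumour-annotation.  Defaults: three layers of
    33 µm, the depths reported for tumour-surface quantification (0–33,
    34–67, 68–100 µm).

    Returns a :class:`LayerSet` whose ``layers`` dict holds L1..Ln,
    TL1..TLn and HL, and whose ``shells`` list holds BC1..BC(n+1).
    """
    if thickness_um <= 0:
        raise ValueError("layer thickness must be positive")
    if n_layers < 1:
        raise ValueError("need at least one layer")
    if not bc.data.any():
        raise ValueError("the cavity seed mask is empty")
    for m in (urothelium, tumour):
        if not bc.same_geometry(m):
            raise GeometryError("all masks must share the cavity mask's geometry")

    shells = [bc.copy()]
    layers: dict[str, Mask3D] = {}
    for k in range(1, n_layers + 1):
        shells.append(dilate_physical(shells[-1], thickness_um))
        lk = boolean_op(shells[-1], shells[-2], "subtract")
        layers[f"L{k}"] = lk
        layers[f"TL{k}"] = boolean_op(lk, urothelium, "subtract")
    layers["HL"] = boolean_op(layers["L1"], tumour, "subtract")
    return LayerSet(layers=layers, thickness_um=thickness_um, shells=shells)


# ---------------------------------------------------------------------------
# internal-tissue mask (lumen removal + outer-edge erosion)
# ---------------------------------------------------------------------------

def internal_tissue_mask(
    autofluorescence: VoxelVolume,
    erosion_um: float = 500.0,
    threshold: float | None = None,
) -> Mask3D:
    """Segment internal bladder tissue: threshold, drop the lumen, peel the rind.

    The autofluorescence channel is thresholded (Otsu by default) to find
    tissue.  The background component touching the volume border is the
    exterior; the largest fully enclosed background component is the lumen
    and is excluded.  Finally an ``erosion_um`` rind is removed from the
    exterior-facing boundary only — the lumen boundary is left untouched, so
    signal just beneath the cavity surface survives.

    If no enclosed cavity exists (a collapsed bladder), a warning is issued
    and the mask keeps the full enclosed volume.
    """
    data = np.asarray(autofluorescence.data)
    spacing = autofluorescence.spacing
    if threshold is None:
        from skimage.filters import threshold_otsu

        if np.ptp(data) == 0:
            warnings.warn("constant volume: empty tissue mask returned")
            return Mask3D(np.zeros(data.shape, bool), spacing)
        threshold = float(threshold_otsu(data))
    tissue = data > threshold
    if not tissue.any():
        warnings.warn("no voxel above threshold: empty tissue mask returned")
        return Mask3D(tissue, spacing)

    background = ~tissue
    labels, n = ndimage.label(background)
    border_labels = set(np.unique(labels[0])) | set(np.unique(labels[-1]))
    for face in (labels[:, 0], labels[:, -1], labels[:, :, 0], labels[:, :, -1]):
        border_labels |= set(np.unique(face))
    border_labels.discard(0)

    enclosed = [lab for lab in range(1, n + 1) if lab not in border_labels]
    filled = tissue.copy()
    lumen = np.zeros(data.shape, bool)
    if enclosed:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, enclosed)
        lumen_label = enclosed[int(np.argmax(sizes))]
        lumen = labels == lumen_label
        # cavities other than the lumen are treated as tissue holes and filled
        for lab in enclosed:
            if lab != lumen_label:
                filled |= labels == lab
    else:
        warnings.warn(
            "no enclosed cavity found: returning mask without lumen removal"
        )

    exterior = background & ~lumen
    for lab in enclosed:
        exterior &= labels != lab
    # peel from the outer edge only: distance is measured to the exterior
    outer = filled | lumen
    if erosion_um > 0:
        dist_to_exterior = ndimage.distance_transform_edt(outer, sampling=spacing)
        keep = dist_to_exterior > erosion_um
    else:
        keep = np.ones(data.shape, bool)
    return Mask3D(filled & keep & ~lumen, spacing)
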