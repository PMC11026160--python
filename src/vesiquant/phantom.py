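"""Synthetic bladder phantom and companion generators.

Everything the quantification stages consume can be produced here with known
ground truth: a two-channel cleared-bladder volume (autofluorescence +
scattered signal) with labelled anatomy and nanobot puncta, tracer-particle
trajectories for mean-square-displacement analysis, diffusion-weighted MRI
ratio pairs with a known tumour volume, and grouped study tables of tumour
volumes and radioactivities.

The bladder is modelled as concentric ellipsoidal shells around a lumen —
urothelium, lamina propria and detrusor from the cavity outward — with a
tumour as a spherical cap protruding from the wall into the lumen.  Nanobot
puncta are sampled with a surface density per region that decays
exponentially with depth below the luminal surface, ρ(d) = ρ₀ exp(−d/λ).
With the default tumour:healthy surface-density ratio of 4 and decay length
λ = 95 µm, the first-to-third 33 µm layer intensity ratio is
exp(−66/95) ≈ 0.50 — the regime the layer quantification is meant to
recover.

All generators are pure functions of their spec (including its seed): the
same spec yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    SECONDS_PER_DAY,
    GeometryError,
    ActivityMeasurement,
    Mask3D,
    SubjectRecord,
    Trajectory,
    VoxelVolume,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "TracerSimSpec",
    "REGION_LABELS",
    "generate_bladder_phantom",
    "simulate_tracers",
    "generate_dwi_pair",
    "generate_study_table",
]

#: integer codes of the anatomy labels in the truth volume
REGION_LABELS = {
    "exterior": 0,
    "lumen": 1,
    "urothelium": 2,
    "lamina": 3,
    "detrusor": 4,
    "tumour": 5,
}
_LABEL_NAMES = {v: k for k, v in REGION_LABELS.items()}

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # σ = FWHM / 2.3548


@dataclass
class PhantomSpec:
    """Parameters of the synthetic cleared-bladder volume.

    Sizes are physical µm on a (z, y, x) voxel grid.  The default grid of
    120 × 256 × 256 voxels at (2.5, 1, 1) µm pitch holds a miniaturized
    bladder: the anatomy is scaled down so a desk-size volume still exposes
    a lumen, a three-layer wall and a tumour cap deep enough to carry three
    33 µm analysis layers, while the optical parameters (voxel pitch, PSF
    widths, 16-bit quantization) keep their full-scale values.
    """

    grid_shape: tuple[int, int, int] = (120, 256, 256)
    spacing: tuple[float, float, float] = (2.5, 1.0, 1.0)
    lumen_radius_um: float = 75.0
    urothelium_thickness_um: float = 33.0
    lamina_thickness_um: float = 12.0
    detrusor_thickness_um: float = 6.0
    # tumour cap: protrudes from the wall into the lumen along +x; large
    # enough that tumour depth below the cavity surface reaches ~96 µm, so
    # all three 33 µm analysis layers have tumour support
    tumour_basal_radius_um: float = 65.0
    tumour_protrusion_um: float = 60.0
    # channel intensities (a.u., 16-bit scale)
    af_mean: dict = field(
        default_factory=lambda: {
            "exterior": 100.0,
            "lumen": 300.0,
            "urothelium": 12000.0,
            "lamina": 4000.0,
            "detrusor": 9000.0,
            "tumour": 10000.0,
        }
    )
    af_noise_sigma: float = 300.0
    scattered_baseline: float = 20.0
    punctum_intensity_mean: float = 30000.0
    punctum_intensity_cv: float = 0.2
    # puncta statistics
    surface_density_tumour: float = 0.010  # puncta µm⁻³ at depth 0
    surface_density_healthy: float = 0.0025
    depth_decay_length_um: float = 95.0
    # optics
    psf_fwhm_lateral_um: float = 2.4
    psf_fwhm_axial_um: float = 5.5
    speckle_sigma: float = 0.2  # lognormal σ of multiplicative speckle
    bit_depth: int = 16
    margin_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing) or any(n < 1 for n in self.grid_shape):
            raise GeometryError("grid shape and spacing must be positive")
        for t in (
            self.urothelium_thickness_um,
            self.lamina_thickness_um,
            self.detrusor_thickness_um,
        ):
            if t <= 0:
                raise ValueError("all wall thicknesses must be positive")
        if self.surface_density_tumour < 0 or self.surface_density_healthy < 0:
            raise ValueError("puncta densities must be non-negative")
        if self.depth_decay_length_um <= 0:
            raise ValueError("depth decay length must be positive")
        if not 0 < self.tumour_protrusion_um < self.lumen_radius_um:
            raise GeometryError("tumour protrusion must be positive and smaller than the lumen radius")
        half_extent = [n * s / 2.0 for n, s in zip(self.grid_shape, self.spacing)]
        if self.outer_radius_um + self.margin_um > min(half_extent):
            raise GeometryError(
                f"grid too small: bladder radius {self.outer_radius_um:.0f} µm "
                f"+ margin {self.margin_um:.0f} µm exceeds half-extent "
                f"{min(half_extent):.0f} µm"
            )

    @property
    def outer_radius_um(self) -> float:
        return (
            self.lumen_radius_um
            + self.urothelium_thickness_um
            + self.lamina_thickness_um
            + self.detrusor_thickness_um
        )

    @property
    def density_ratio(self) -> float:
        if self.surface_density_healthy == 0:
            return float("inf")
        return self.surface_density_tumour / self.surface_density_healthy


@dataclass
class PhantomTruth:
    """Ground truth accompanying one generated phantom."""

    region_labels: VoxelVolume  # integer codes per REGION_LABELS
    puncta: pd.DataFrame  # columns z_um, y_um, x_um, region, depth_um
    depth_map_um: np.ndarray  # distance of every voxel to the cavity surface
    spec: PhantomSpec

    def puncta_in_depth_range(self, region: str, d0: float, d1: float) -> int:
        """Count truth puncta of one region with depth in [d0, d1)."""
        p = self.puncta
        sel = (p["region"] == region) & (p["depth_um"] >= d0) & (p["depth_um"] < d1)
        return int(sel.sum())

    def expected_layer_density(self, region: str, layer: int, thickness_um: float = 33.0) -> float:
        """Analytic expected puncta density (µm⁻³) in concentric layer ``layer`` (1-based)."""
        rho0 = (
            self.spec.surface_density_tumour
            if region == "tumour"
            else self.spec.surface_density_healthy
        )
        lam = self.spec.depth_decay_length_um
        d0, d1 = (layer - 1) * thickness_um, layer * thickness_um
        return rho0 * lam * (np.exp(-d0 / lam) - np.exp(-d1 / lam)) / thickness_um


@dataclass
class TracerSimSpec:
    """Parameters for the 2D tracer-particle simulation."""

    n_particles: int = 100
    diffusion_coeff: float = 0.25  # µm² s⁻¹ (2-µm tracer scale)
    advection_speed: float = 0.0  # tangential vortex speed (µm s⁻¹) at the seeding radius
    convergence_rate: float = 0.0  # s⁻¹ radial drift toward the vortex centre (swarm accumulation)
    vortex_center: tuple[float, float] = (0.0, 0.0)
    start_radius_um: float = 50.0
    dt: float = 0.1  # s
    n_steps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 2:
            raise ValueError("need at least two steps")
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion coefficient must be non-negative")
        if self.n_particles < 1:
            raise ValueError("need at least one particle")


# ---------------------------------------------------------------------------
# bladder phantom
# ---------------------------------------------------------------------------

def _physical_coords(shape, spacing):
    """Coordinate grids (µm) centred on the volume centre."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _region_labels(spec: PhantomSpec) -> np.ndarray:
    zz, yy, xx = _physical_coords(spec.grid_shape, spec.spacing)
    r = np.sqrt(zz**2 + yy**2 + xx**2)

    labels = np.full(spec.grid_shape, REGION_LABELS["exterior"], dtype=np.uint8)
    r_l = spec.lumen_radius_um
    r_u = r_l + spec.urothelium_thickness_um
    r_lp = r_u + spec.lamina_thickness_um
    r_d = r_lp + spec.detrusor_thickness_um
    labels[r <= r_d] = REGION_LABELS["detrusor"]
    labels[r <= r_lp] = REGION_LABELS["lamina"]
    labels[r <= r_u] = REGION_LABELS["urothelium"]
    labels[r <= r_l] = REGION_LABELS["lumen"]

    # tumour: spherical cap protruding into the lumen along +x, carried
    # through the full wall thickness behind its base
    a, h = spec.tumour_basal_radius_um, spec.tumour_protrusion_um
    r_ball = (a**2 + h**2) / (2.0 * h)
    centre_x = r_l - h + r_ball  # ball centre on the +x axis
    d_ball = np.sqrt(zz**2 + yy**2 + (xx - centre_x) ** 2)
    tumour = (d_ball <= r_ball) & (r <= r_d)
    labels[tumour] = REGION_LABELS["tumour"]
    return labels


def _separable_sigma_vox(spec: PhantomSpec) -> tuple[float, float, float]:
    sz = spec.psf_fwhm_axial_um * _FWHM_TO_SIGMA / spec.spacing[0]
    sy = spec.psf_fwhm_lateral_um * _FWHM_TO_SIGMA / spec.spacing[1]
    sx = spec.psf_fwhm_lateral_um * _FWHM_TO_SIGMA / spec.spacing[2]
    return (sz, sy, sx)


def _quantize(img: np.ndarray, bit_depth: int) -> np.ndarray:
    top = 2**bit_depth - 1
    return np.clip(np.rint(img), 0, top).astype(np.uint16 if bit_depth > 8 else np.uint8)


def generate_bladder_phantom(
    spec: PhantomSpec,
) -> tuple[VoxelVolume, VoxelVolume, PhantomTruth]:
    """Generate the two-channel bladder volume with ground truth.

    Returns ``(autofluorescence, scattered, truth)``.  The autofluorescence
    channel carries per-region mean intensities with additive Gaussian
    noise; the scattered channel carries a flat baseline plus nanobot puncta
    with multiplicative lognormal speckle.  Both channels are blurred by the
    separable anisotropic Gaussian PSF and quantized to ``bit_depth``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _region_labels(spec)
    cavity = labels == REGION_LABELS["lumen"]

    # depth below the luminal (cavity) surface, physical µm
    if cavity.any():
        depth = ndimage.distance_transform_edt(~cavity, sampling=spec.spacing)
    else:
        depth = np.zeros(spec.grid_shape)

    # --- puncta sampling -------------------------------------------------
    voxel_vol = float(np.prod(spec.spacing))
    lam_map = np.zeros(spec.grid_shape)
    tissue_t = labels == REGION_LABELS["tumour"]
    tissue_h = np.isin(
        labels,
        [REGION_LABELS["urothelium"], REGION_LABELS["lamina"], REGION_LABELS["detrusor"]],
    )
    decay = np.exp(-depth / spec.depth_decay_length_um)
    lam_map[tissue_t] = spec.surface_density_tumour * decay[tissue_t] * voxel_vol
    lam_map[tissue_h] = spec.surface_density_healthy * decay[tissue_h] * voxel_vol
    counts = rng.poisson(lam_map)

    idx = np.argwhere(counts > 0)
    reps = counts[counts > 0]
    vox = np.repeat(idx, reps, axis=0)
    jitter = rng.uniform(-0.5, 0.5, size=vox.shape)
    pos_vox = vox + jitter  # continuous voxel coordinates
    spacing_arr = np.asarray(spec.spacing)
    pos_um = pos_vox * spacing_arr
    regions = [
        _LABEL_NAMES[int(labels[tuple(v)])] for v in vox
    ]
    depths = depth[tuple(vox.T)] if len(vox) else np.empty(0)
    puncta = pd.DataFrame(
        {
            "z_um": pos_um[:, 0] if len(vox) else np.empty(0),
            "y_um": pos_um[:, 1] if len(vox) else np.empty(0),
            "x_um": pos_um[:, 2] if len(vox) else np.empty(0),
            "region": pd.Series(regions, dtype=object),
            "depth_um": depths,
        }
    )

    # --- scattered channel ------------------------------------------------
    scattered = np.full(spec.grid_shape, spec.scattered_baseline, dtype=float)
    if len(vox):
        # lognormal brightness with mean = punctum_intensity_mean
        cv = spec.punctum_intensity_cv
        sig = np.sqrt(np.log1p(cv**2))
        mu = np.log(spec.punctum_intensity_mean) - 0.5 * sig**2
        bright = rng.lognormal(mu, sig, size=len(vox))
        rounded = np.rint(pos_vox).astype(int)
        for axis in range(3):
            np.clip(rounded[:, axis], 0, spec.grid_shape[axis] - 1, out=rounded[:, axis])
        np.add.at(scattered, tuple(rounded.T), bright)

    sigma_vox = _separable_sigma_vox(spec)
    if any(s > 0 for s in sigma_vox):
        scattered = ndimage.gaussian_filter(scattered, sigma=sigma_vox)
    if spec.speckle_sigma > 0:
        speckle = rng.lognormal(-0.5 * spec.speckle_sigma**2, spec.speckle_sigma, spec.grid_shape)
        scattered = scattered * speckle

    # --- autofluorescence channel ----------------------------------------
    af = np.zeros(spec.grid_shape, dtype=float)
    for name, code in REGION_LABELS.items():
        af[labels == code] = spec.af_mean.get(name, 0.0)
    if any(s > 0 for s in sigma_vox):
        af = ndimage.gaussian_filter(af, sigma=sigma_vox)
    if spec.af_noise_sigma > 0:
        af = af + rng.normal(0.0, spec.af_noise_sigma, spec.grid_shape)

    af_vol = VoxelVolume(_quantize(af, spec.bit_depth), spec.spacing)
    sc_vol = VoxelVolume(_quantize(scattered, spec.bit_depth), spec.spacing)
    truth = PhantomTruth(
        region_labels=VoxelVolume(labels, spec.spacing),
        puncta=puncta,
        depth_map_um=depth,
        spec=spec,
    )
    return af_vol, sc_vol, truth


def phantom_masks(truth: PhantomTruth) -> dict[str, Mask3D]:
    """Derive the annotation masks the layer analysis needs from truth labels.

    Returns the cavity seed mask ``bc`` (the lumen), the tumour mask ``t1``,
    the non-tumour annotation ``u1`` (everything that is neither tumour nor
    cavity, the subtrahend that confines tumour layers TL_k to the tumour —
    the phantom equivalent of annotating all healthy tissue) and the
    wall-only healthy mask ``healthy_wall`` (urothelium + lamina propria +
    detrusor) used as the healthy region for occupancy and depth statistics.
    """
    labels = truth.region_labels.data
    spacing = truth.region_labels.spacing
    bc = Mask3D(labels == REGION_LABELS["lumen"], spacing)
    t1 = Mask3D(labels == REGION_LABELS["tumour"], spacing)
    u1 = Mask3D(
        ~np.isin(labels, [REGION_LABELS["lumen"], REGION_LABELS["tumour"]]), spacing
    )
    healthy_wall = Mask3D(
        np.isin(
            labels,
            [
                REGION_LABELS["urothelium"],
                REGION_LABELS["lamina"],
                REGION_LABELS["detrusor"],
            ],
        ),
        spacing,
    )
    return {"bc": bc, "t1": t1, "u1": u1, "healthy_wall": healthy_wall}


# ---------------------------------------------------------------------------
# tracer trajectories
# ---------------------------------------------------------------------------

def simulate_tracers(spec: TracerSimSpec) -> list[Trajectory]:
    """Simulate 2D tracer-particle tracks: Brownian steps plus optional vortex.

    Brownian displacements have per-axis variance 2·D·dt.  The vortex, when
    on, rotates each particle about ``vortex_center`` by the exact angle
    ω·dt with ω = advection_speed / start_radius_um, so with D = 0 (and no
    convergence) the tracks are closed circles.  A positive
    ``convergence_rate`` contracts radii toward the vortex centre by
    exp(−rate·dt) per step — the accumulation of tracers in the swarm that
    keeps the spatial distribution heterogeneous instead of flattening out.
    """
    rng = np.random.default_rng(spec.seed)
    n, steps = spec.n_particles, spec.n_steps
    theta0 = rng.uniform(0, 2 * np.pi, n)
    rad0 = spec.start_radius_um * np.sqrt(rng.uniform(0, 1, n))
    pos = np.stack(
        [
            spec.vortex_center[0] + rad0 * np.cos(theta0),
            spec.vortex_center[1] + rad0 * np.sin(theta0),
        ],
        axis=1,
    )
    omega = spec.advection_speed / spec.start_radius_um if spec.advection_speed else 0.0
    step_sigma = np.sqrt(2.0 * spec.diffusion_coeff * spec.dt)
    c = np.asarray(spec.vortex_center)

    out = np.empty((steps, n, 2))
    out[0] = pos
    cos_w, sin_w = np.cos(omega * spec.dt), np.sin(omega * spec.dt)
    shrink = np.exp(-spec.convergence_rate * spec.dt)
    for t in range(1, steps):
        if omega or shrink != 1.0:
            rel = pos - c
            rel = np.stack(
                [rel[:, 0] * cos_w - rel[:, 1] * sin_w,
                 rel[:, 0] * sin_w + rel[:, 1] * cos_w],
                axis=1,
            )
            pos = c + shrink * rel
        if step_sigma > 0:
            pos = pos + rng.normal(0.0, step_sigma, size=(n, 2))
        out[t] = pos

    times = np.arange(steps) * spec.dt
    return [Trajectory(times.copy(), out[:, i, :]) for i in range(n)]


# ---------------------------------------------------------------------------
# diffusion-weighted MRI pair
# ---------------------------------------------------------------------------

def generate_dwi_pair(
    tumour_volume_mm3: float,
    grid_shape: tuple[int, int, int] = (20, 160, 160),
    spacing_um: tuple[float, float, float] = (500.0, 100.0, 100.0),
    contrast: float = 2.0,
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> tuple[VoxelVolume, VoxelVolume, Mask3D]:
    """Synthesize a b = 0 / b > 0 volume pair with a hyperintense tumour.

    The default grid mirrors a small-animal diffusion acquisition: 20 slices
    of 0.5 mm over a 16 × 16 mm field of view at 160 × 160 points (0.1 mm
    in-plane).  The tumour is the ``n`` grid voxels closest to the volume
    centre, with ``n`` chosen so the truth-mask volume matches the request
    to within one voxel volume; its b_dw/b0 ratio exceeds the background's
    by ``contrast``.  Both channels carry multiplicative Gaussian noise.

    Returns ``(b0, b_dw, truth_mask)``.
    """
    voxel_mm3 = float(np.prod(spacing_um)) * 1e-9
    n_vox = int(round(tumour_volume_mm3 / voxel_mm3))
    if n_vox < 1:
        raise GeometryError("requested tumour volume is below one voxel")
    if n_vox > np.prod(grid_shape):
        raise GeometryError("requested tumour volume does not fit the grid")

    zz, yy, xx = _physical_coords(grid_shape, spacing_um)
    dist = np.sqrt(zz**2 + yy**2 + xx**2)
    flat = dist.ravel()
    order = np.argpartition(flat, n_vox - 1)[:n_vox]
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order] = True
    mask = mask.reshape(grid_shape)

    rng = np.random.default_rng(seed)
    base = 1000.0
    ratio_map = np.where(mask, contrast, 1.0)
    b0 = base * np.ones(grid_shape)
    b_dw = base * ratio_map
    if noise_sigma > 0:
        b0 = b0 * (1.0 + rng.normal(0.0, noise_sigma, grid_shape))
        b_dw = b_dw * (1.0 + rng.normal(0.0, noise_sigma, grid_shape))
    return (
        VoxelVolume(b0, spacing_um),
        VoxelVolume(b_dw, spacing_um),
        Mask3D(mask, spacing_um),
    )


# ---------------------------------------------------------------------------
# grouped study tables
# ---------------------------------------------------------------------------

def generate_study_table(
    group_specs: Sequence[dict],
    half_life_days: float = 8.01,
    measure_delay_days: float = 0.0,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Generate per-subject pre/post tumour volumes and activities by group.

    Each group spec is a dict with keys ``group`` (label), ``n`` (subjects),
    ``mean_pre_mm3``, ``fold_change`` (post/pre at the group level) and
    ``dispersion`` (lognormal coefficient of variation; 0 gives exact
    group-level values).  Optional keys ``injected_mbq`` and
    ``voi_fraction`` populate the activity fields; the measured VOI
    activity is physically decayed by ``measure_delay_days`` so that decay
    correction downstream recovers the true fraction.
    """
    rng = np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    hl_s = half_life_days * SECONDS_PER_DAY
    t_meas = measure_delay_days * SECONDS_PER_DAY
    for g in group_specs:
        n = int(g["n"])
        if n < 1:
            raise ValueError(f"group {g.get('group')!r} needs n ≥ 1")
        mean_pre = float(g["mean_pre_mm3"])
        fold = float(g["fold_change"])
        cv = float(g.get("dispersion", 0.0))
        if cv > 0:
            sig = np.sqrt(np.log1p(cv**2))
            pre = rng.lognormal(np.log(mean_pre) - 0.5 * sig**2, sig, n)
            post = pre * fold * rng.lognormal(-0.5 * sig**2, sig, n)
        else:
            pre = np.full(n, mean_pre)
            post = pre * fold
        inj_mbq = g.get("injected_mbq")
        voi_frac = g.get("voi_fraction", 0.0)
        for i in range(n):
            injected = voi = None
            if inj_mbq is not None:
                injected = ActivityMeasurement(float(inj_mbq), 0.0, hl_s)
                measured = float(inj_mbq) * voi_frac * 2.0 ** (-t_meas / hl_s)
                voi = ActivityMeasurement(measured, t_meas, hl_s)
            records.append(
                SubjectRecord(
                    subject_id=f"{g['group']}-{i + 1:02d}",
                    group=str(g["group"]),
                    pre_volume_mm3=float(pre[i]),
                    post_volume_mm3=float(post[i]),
                    injected_activity=injected,
                    voi_activity=voi,
                    tumour_volume_cm3=float(pre[i]) * 1e-3,
                )
            )
    return records
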