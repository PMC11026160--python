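"""Collective-motion readouts from 2D time-lapse data.

Two complementary quantifications of nanobot swarm behaviour: (1) the pixel
intensity distribution inside a fixed circular region of interest, sampled
at regular intervals (default every 15 s, as recorded at 25 frames per
second) — a dispersing, convecting swarm shows up as a broadening intensity
spectrum; and (2) mean-square-displacement analysis of tracer-particle
tracks, with a power-law fit MSD(τ) = 4 D τ^α distinguishing diffusive
(α ≈ 1) from advected, ballistic-like (α → 2) transport.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import HistogramResult, MSDCurve, Trajectory

__all__ = [
    "FrameSeries",
    "ROISpec",
    "roi_histogram_series",
    "histogram_spread",
    "compute_msd",
    "render_particle_video",
    "gaussian_blob_video",
]


@dataclass
class FrameSeries:
    """A 2D time-lapse: frames (t, y, x), frame rate and pixel size."""

    frames: np.ndarray
    fps: float = 25.0
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (t, y, x) array")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def duration_s(self) -> float:
        return (self.frames.shape[0] - 1) / self.fps


@dataclass
class ROISpec:
    """A circular region of interest in pixel coordinates."""

    center: tuple[float, float]  # (y, x)
    radius: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        ny, nx = shape
        cy, cx = self.center
        if not (0 <= cy - self.radius and cy + self.radius <= ny - 1
                and 0 <= cx - self.radius and cx + self.radius <= nx - 1):
            raise ValueError("ROI circle extends outside the frame")
        yy, xx = np.mgrid[0:ny, 0:nx]
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= self.radius**2


def _bit_depth_of(frames: np.ndarray) -> int:
    if frames.dtype == np.uint8:
        return 8
    if frames.dtype == np.uint16:
        return 16
    # float or other integer data: span the observed range
    return int(np.ceil(np.log2(max(2.0, float(frames.max()) + 1))))


def roi_histogram_series(
    video: FrameSeries,
    roi: ROISpec,
    interval_s: float = 15.0,
    n_bins: int | None = None,
) -> list[tuple[float, HistogramResult]]:
    """Pixel-intensity histograms inside the ROI at regular time points.

    One histogram per multiple of ``interval_s`` from 0 to the video
    duration (inclusive), each taken from the frame nearest that time.
    Bins default to one per integer intensity level of the acquisition bit
    depth.  Returns ``[(time_s, HistogramResult), ...]``.
    """
    if interval_s < 1.0 / video.fps:
        raise ValueError("interval must be at least one frame period")
    mask = roi.mask(video.frames.shape[1:])
    depth = _bit_depth_of(video.frames)
    top = 2**depth - 1
    if n_bins is None:
        edges = np.arange(0, top + 2, dtype=float) - 0.5
    else:
        edges = np.linspace(-0.5, top + 0.5, n_bins + 1)

    out = []
    t = 0.0
    while t <= video.duration_s + 1e-9:
        idx = int(round(t * video.fps))
        idx = min(idx, video.frames.shape[0] - 1)
        vals = video.frames[idx][mask]
        counts, _ = np.histogram(np.clip(vals, 0, top), bins=edges)
        out.append((t, HistogramResult(edges, counts.astype(np.int64), "linear")))
        t += interval_s
    return out


def histogram_spread(h: HistogramResult) -> dict[str, float]:
    """Spread of an intensity histogram: population SD (headline) and IQR.

    A broadening spectrum over time — increasing spread — is the signature
    of swarm-driven redistribution as opposed to passive settling.
    """
    counts = np.asarray(h.counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty histogram has no spread")
    centers = 0.5 * (np.asarray(h.bin_edges[:-1]) + np.asarray(h.bin_edges[1:]))
    w = counts / total
    mean = float(np.sum(w * centers))
    std = float(np.sqrt(np.sum(w * (centers - mean) ** 2)))
    cdf = np.cumsum(w)

    def quantile(q: float) -> float:
        return float(centers[np.searchsorted(cdf, q, side="left")])

    return {"std": std, "iqr": quantile(0.75) - quantile(0.25), "mean": mean}


def render_particle_video(
    trajectories: list[Trajectory],
    shape: tuple[int, int],
    pixel_size_um: float,
    origin_um: tuple[float, float] = (0.0, 0.0),
    counts_to_intensity: float = 1000.0,
    bit_depth: int = 16,
) -> FrameSeries:
    """Rasterize particle tracks into a time-lapse of occupancy images.

    Each frame is a 2D histogram of particle positions (particles per
    pixel × ``counts_to_intensity``, clipped to the bit depth); the frame
    rate comes from the tracks' common sampling interval.  ``origin_um``
    is the physical position of the image centre.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    n_frames = min(len(tr.times) for tr in trajectories)
    dt = float(trajectories[0].times[1] - trajectories[0].times[0])
    ny, nx = shape
    top = 2**bit_depth - 1
    frames = np.zeros((n_frames, ny, nx), dtype=np.uint16 if bit_depth > 8 else np.uint8)
    ox, oy = origin_um
    for t in range(n_frames):
        img = np.zeros((ny, nx))
        for tr in trajectories:
            x, y = tr.positions[t]
            ix = int(round((x - ox) / pixel_size_um + (nx - 1) / 2))
            iy = int(round((y - oy) / pixel_size_um + (ny - 1) / 2))
            if 0 <= iy < ny and 0 <= ix < nx:
                img[iy, ix] += counts_to_intensity
        frames[t] = np.clip(img, 0, top)
    return FrameSeries(frames, fps=1.0 / dt, pixel_size_um=pixel_size_um)


def gaussian_blob_video(
    shape: tuple[int, int],
    sigma0_px: float,
    diffusion_px2_s: float,
    fps: float,
    n_frames: int,
    amplitude: float = 4000.0,
    background: float = 100.0,
    bit_depth: int = 16,
) -> FrameSeries:
    """Analytic time-lapse of a diffusing 2D Gaussian bolus.

    The blob's variance grows as σ²(t) = σ0² + 2 D t while its integrated
    mass is conserved, so the peak decays and the intensity distribution
    inside any fixed region collapses toward the background — the passive
    no-fuel dispersion pattern.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    top = 2**bit_depth - 1
    frames = np.zeros((n_frames, ny, nx), dtype=np.uint16 if bit_depth > 8 else np.uint8)
    for t in range(n_frames):
        var = sigma0_px**2 + 2.0 * diffusion_px2_s * t / fps
        peak = amplitude * sigma0_px**2 / var
        img = background + peak * np.exp(-r2 / (2.0 * var))
        frames[t] = np.clip(np.rint(img), 0, top)
    return FrameSeries(frames, fps=fps, pixel_size_um=1.0)


def compute_msd(
    trajectories: list[Trajectory],
    max_lag_fraction: float = 0.25,
) -> MSDCurve:
    """Time-and-ensemble averaged MSD with a log-log power-law fit.

    Every trajectory must be uniformly sampled (same interval within a
    track; tracks may differ).  For each lag τ = k·dt the squared
    displacements of all start times of all tracks are pooled.  The fit
    MSD = 4 D τ^α is a least-squares line in log-log space over the
    computed lag range; stationary input returns D = 0, α = 0.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")

    dts = []
    for tr in trajectories:
        steps = np.diff(tr.times)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("non-uniform sampling: resample the trajectory upstream")
        dts.append(steps[0])
    if not np.allclose(dts, dts[0], rtol=1e-6):
        raise ValueError("all trajectories must share the sampling interval")
    dt = float(dts[0])

    max_lag = max(
        1, int(np.floor(max_lag_fraction * max(len(tr.times) for tr in trajectories))) - 1
    )
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=np.int64)
    for tr in trajectories:
        pos = tr.positions
        n = len(pos)
        for k in range(1, min(max_lag, n - 1) + 1):
            disp = pos[k:] - pos[:-k]
            sums[k - 1] += np.sum(disp[:, 0] ** 2 + disp[:, 1] ** 2)
            counts[k - 1] += n - k
    valid = counts > 0
    lags = np.arange(1, max_lag + 1)[valid] * dt
    msd = sums[valid] / counts[valid]

    positive = msd > 0
    if positive.sum() >= 2:
        slope, intercept = np.polyfit(np.log(lags[positive]), np.log(msd[positive]), 1)
        alpha = float(slope)
        diffusion = float(np.exp(intercept) / 4.0)
    else:
        alpha = 0.0
        diffusion = 0.0
    return MSDCurve(lags=lags, msd=msd, diffusion_coeff=diffusion, alpha=alpha)
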