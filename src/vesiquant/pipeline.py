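"""End-to-end orchestration: phantom → masks → quantification → report.

A single seeded configuration drives every stage; the run writes its
outputs plus a manifest recording the configuration snapshot, software
version, per-file checksums and stage timings, so a rerun with the same
seeds is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import I131_HALF_LIFE_DAYS, Mask3D
from .invivo import dwi_ratio_image, mask_volume, ntv, percent_reduction_vs_control
from .io import write_mask, write_study_table, write_trajectories, write_volume
from .masks import build_layers, internal_tissue_mask
from .motion import compute_msd
from .phantom import (
    PhantomSpec,
    TracerSimSpec,
    generate_bladder_phantom,
    generate_dwi_pair,
    generate_study_table,
    phantom_masks,
)
from .sls import foreground_detect, layer_profile, masked_histogram, penetration_stats

log = logging.getLogger("vesiquant")

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]


def demo_config() -> "PipelineConfig":
    """The bundled demo configuration (desk-scale phantom, scaled erosion)."""
    return PipelineConfig.from_yaml(Path(__file__).parent / "data" / "demo_config.yaml")

#: group-level post/pre fold changes of the six-arm therapy study design
DEFAULT_FOLD_CHANGES = {
    "non-treated": 2.45,
    "nanobots-urea": 1.93,
    "131I-LD-water": 1.66,
    "131I-LD-urea": 0.96,
    "131I-HD-water": 0.54,
    "131I-HD-urea": 0.27,
}


@dataclass
class PipelineConfig:
    """Parameters of a full analysis run.

    Defaults follow the published acquisition/processing settings where one
    exists: 33 µm layers, three layers, 500 µm outer-edge erosion,
    annotations every 15 planes of 2.5 µm (37.5 µm) and 16-bit histograms.
    Values with no printed counterpart are marked assumed in the manifest.
    """

    seed: int = 0
    # phantom overrides (None → PhantomSpec defaults)
    phantom: dict = field(default_factory=dict)
    layer_thickness_um: float = 33.0
    n_layers: int = 3
    erosion_um: float = 500.0
    annotation_interval_planes: int = 15
    plane_step_um: float = 2.5
    histogram_bins: int = 4096
    half_life_days: float = I131_HALF_LIFE_DAYS
    # therapy-arm design: mapping group label → post/pre fold change
    fold_changes: dict = field(default_factory=lambda: dict(DEFAULT_FOLD_CHANGES))
    group_n: int = 9
    group_dispersion: float = 0.25
    mean_pre_mm3: float = 10.0
    # tracer/MSD stage
    tracer: dict = field(default_factory=dict)
    # DWI stage
    dwi_volume_mm3: float = 10.0
    dwi_contrast: float = 2.0
    dwi_noise_sigma: float = 0.05

    @property
    def annotation_spacing_um(self) -> float:
        """Physical distance between annotated planes (planes × z-step)."""
        return self.annotation_interval_planes * self.plane_step_um

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(manifest: dict, name: str, t0: float) -> None:
    manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
    log.info("stage %s done in %.2f s", name, manifest["timings_s"][name])


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a seeded phantom and write outputs plus manifest.

    Stages: phantom generation, layer construction from the truth
    annotations, layer intensity profile, internal-tissue mask and masked
    histograms, foreground/penetration statistics, tracer MSD, the DWI
    volumetry recovery and the therapy-table NTV summary.  Returns the
    manifest dict (also written as ``manifest.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "assumed_parameters": [
            "phantom anatomy scale and intensities",
            "tracer simulation parameters",
            "study-table dispersion and group size",
        ],
        "timings_s": {},
        "outputs": {},
        "results": {},
    }

    # --- phantom ----------------------------------------------------------
    t0 = time.perf_counter()
    spec = PhantomSpec(**{"seed": config.seed, **config.phantom})
    af, sls_vol, truth = generate_bladder_phantom(spec)
    write_volume(af, out / "autofluorescence.tif")
    write_volume(sls_vol, out / "scattered.tif")
    write_volume(truth.region_labels, out / "truth_labels.tif")
    truth.puncta.to_csv(out / "truth_puncta.csv", index=False)
    _stage(manifest, "phantom", t0)

    # --- layers and profile ----------------------------------------------
    t0 = time.perf_counter()
    masks = phantom_masks(truth)
    layers = build_layers(
        masks["bc"],
        urothelium=masks["u1"],
        tumour=masks["t1"],
        thickness_um=config.layer_thickness_um,
        n_layers=config.n_layers,
    )
    profile = layer_profile(sls_vol, layers)
    rows = []
    for role, st in profile["stats"].items():
        if st is None:
            rows.append({"layer": role, "present": False})
        else:
            rows.append(
                {
                    "layer": role,
                    "present": True,
                    "integrated_intensity": st.integrated_intensity,
                    "voxel_count": st.voxel_count,
                    "physical_volume_um3": st.physical_volume_um3,
                    "normalized_intensity": st.normalized_intensity,
                }
            )
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "layer_profile.csv", index=False)
    manifest["results"]["layer_ratios"] = profile["ratios"]
    conservation = sum(
        layers[f"L{k}"].count() for k in range(1, config.n_layers + 1)
    ) == (layers.shells[-1].count() - layers.shells[0].count())
    manifest["results"]["layer_conservation"] = bool(conservation)
    _stage(manifest, "layers", t0)

    # --- internal tissue mask + histograms ---------------------------------
    t0 = time.perf_counter()
    internal = internal_tissue_mask(af, erosion_um=config.erosion_um)
    write_mask(internal, out / "internal_mask.tif")
    for scale in ("linear", "log"):
        hist = masked_histogram(
            sls_vol, internal, n_bins=config.histogram_bins, scale=scale
        )
        pd.DataFrame(
            {"bin_left": hist.bin_edges[:-1], "bin_right": hist.bin_edges[1:], "count": hist.counts}
        ).to_csv(out / f"histogram_{scale}.csv", index=False)
    manifest["results"]["internal_mask_voxels"] = internal.count()
    _stage(manifest, "internal_mask", t0)

    # --- penetration ------------------------------------------------------
    t0 = time.perf_counter()
    tissue = Mask3D(
        masks["t1"].data | masks["healthy_wall"].data, masks["t1"].spacing
    )
    fg, thr = foreground_detect(sls_vol, tissue)
    pen_t = penetration_stats(fg, masks["bc"], masks["t1"])
    pen_h = penetration_stats(fg, masks["bc"], masks["healthy_wall"])
    manifest["results"]["penetration"] = {
        "threshold": thr,
        "tumour": {
            "median_depth_um": pen_t.median_depth_um,
            "occupancy": pen_t.occupancy,
            "n_foreground": pen_t.n_foreground_voxels,
        },
        "healthy": {
            "median_depth_um": pen_h.median_depth_um,
            "occupancy": pen_h.occupancy,
            "n_foreground": pen_h.n_foreground_voxels,
        },
    }
    _stage(manifest, "penetration", t0)

    # --- tracer MSD -------------------------------------------------------
    t0 = time.perf_counter()
    from .phantom import simulate_tracers

    tracer_spec = TracerSimSpec(**{"seed": config.seed + 1, **config.tracer})
    tracks = simulate_tracers(tracer_spec)
    write_trajectories(tracks, out / "trajectories.csv")
    msd = compute_msd(tracks)
    manifest["results"]["msd"] = {
        "diffusion_coeff_um2_s": msd.diffusion_coeff,
        "alpha": msd.alpha,
        "n_tracks": len(tracks),
    }
    _stage(manifest, "msd", t0)

    # --- DWI volumetry ----------------------------------------------------
    t0 = time.perf_counter()
    from .core import DWIPair
    from skimage.filters import threshold_otsu

    b0, bdw, truth_mask = generate_dwi_pair(
        config.dwi_volume_mm3,
        contrast=config.dwi_contrast,
        noise_sigma=config.dwi_noise_sigma,
        seed=config.seed + 2,
    )
    ratio = dwi_ratio_image(DWIPair(b0, bdw))
    thr_dwi = float(threshold_otsu(np.asarray(ratio.data)))
    recovered = Mask3D(np.asarray(ratio.data) > thr_dwi, ratio.spacing)
    manifest["results"]["dwi"] = {
        "truth_volume_mm3": mask_volume(truth_mask),
        "recovered_volume_mm3": mask_volume(recovered),
        "threshold": thr_dwi,
    }
    _stage(manifest, "dwi", t0)

    # --- therapy table / NTV ----------------------------------------------
    t0 = time.perf_counter()
    group_specs = [
        {
            "group": g,
            "n": config.group_n,
            "mean_pre_mm3": config.mean_pre_mm3,
            "fold_change": fc,
            "dispersion": config.group_dispersion,
        }
        for g, fc in config.fold_changes.items()
    ]
    records = generate_study_table(
        group_specs, half_life_days=config.half_life_days, seed=config.seed + 3
    )
    write_study_table(records, out / "study_table.csv")
    ntv_df = ntv(records)
    ntv_df.to_csv(out / "ntv.csv", index=False)
    group_means = ntv_df.groupby("group")["ntv"].mean().to_dict()
    manifest["results"]["ntv_group_means"] = group_means
    if "non-treated" in group_means and "131I-HD-urea" in group_means:
        manifest["results"]["percent_reduction_HD_urea_vs_control"] = (
            percent_reduction_vs_control(
                group_means["131I-HD-urea"], group_means["non-treated"]
            )
        )
    _stage(manifest, "therapy", t0)

    # --- manifest ---------------------------------------------------------
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
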