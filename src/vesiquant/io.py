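"""Reading and writing the pipeline's file formats.

Volumes and masks travel as multi-page TIFF (16-bit or 8-bit grayscale,
plane order Z) with the voxel pitch embedded in ImageJ-style metadata, so a
written stack re-opens with its physical geometry intact.  Plane-streamed
reading is available for stacks that should not be loaded whole.  ROI
annotations are JSON; trajectories and study tables are CSV with declared
column schemas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import tifffile

from .core import ActivityMeasurement, Mask3D, PlanarROI, SubjectRecord, Trajectory, VoxelVolume

__all__ = [
    "read_volume",
    "write_volume",
    "iter_planes",
    "read_mask",
    "write_mask",
    "read_rois",
    "write_rois",
    "read_trajectories",
    "write_trajectories",
    "read_study_table",
    "write_study_table",
]

_SUPPORTED_DTYPES = {np.dtype(np.uint8), np.dtype(np.uint16), np.dtype(np.float32)}


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write a volume as a multi-page ImageJ TIFF with spacing metadata."""
    data = np.asarray(volume.data)
    if data.dtype not in _SUPPORTED_DTYPES:
        if np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)
        else:
            raise ValueError(
                f"unsupported dtype {data.dtype}: write uint8/uint16/float32"
            )
    sz, sy, sx = volume.spacing
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )


def _spacing_from_tiff(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    meta = tf.imagej_metadata
    if not meta or "spacing" not in meta:
        return None
    sz = float(meta["spacing"])
    page = tf.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        sx = xres[1] / xres[0]
        sy = yres[1] / yres[0]
    except (KeyError, ZeroDivisionError):
        return None
    return (sz, sy, sx)


def read_volume(
    path: str | Path, spacing: tuple[float, float, float] | None = None
) -> VoxelVolume:
    """Read a multi-page grayscale TIFF into a :class:`VoxelVolume`.

    Spacing is taken from the embedded ImageJ metadata; if the file has
    none and no explicit ``spacing`` is passed, the call fails rather than
    assuming a default.
    """
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a grayscale Z stack, got shape {data.shape}")
        if data.dtype not in _SUPPORTED_DTYPES:
            raise ValueError(
                f"{path}: unsupported TIFF sample format/bit depth {data.dtype}"
            )
        file_spacing = _spacing_from_tiff(tf)
    if spacing is None:
        if file_spacing is None:
            raise ValueError(
                f"{path}: no spacing metadata in file and none supplied; "
                "pass spacing explicitly"
            )
        spacing = file_spacing
    return VoxelVolume(data, spacing)


def iter_planes(path: str | Path) -> Iterator[np.ndarray]:
    """Yield Z planes of a multi-page TIFF one at a time (streaming)."""
    with tifffile.TiffFile(str(path)) as tf:
        for page in tf.pages:
            yield page.asarray()


def write_mask(mask: Mask3D, path: str | Path) -> None:
    """Write a binary mask as an 8-bit {0, 255} multi-page TIFF."""
    vol = VoxelVolume((mask.data.astype(np.uint8) * 255), mask.spacing)
    write_volume(vol, path)


def read_mask(path: str | Path, spacing: tuple[float, float, float] | None = None) -> Mask3D:
    vol = read_volume(path, spacing)
    return Mask3D(vol.data > 0, vol.spacing)


# ---------------------------------------------------------------------------
# ROI annotations (JSON)
# ---------------------------------------------------------------------------

def write_rois(rois: list[PlanarROI], path: str | Path) -> None:
    payload = [
        {"plane": int(r.plane_index), "vertices": np.asarray(r.polygon).tolist()}
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_rois(path: str | Path) -> list[PlanarROI]:
    payload = json.loads(Path(path).read_text())
    return [PlanarROI(int(d["plane"]), np.asarray(d["vertices"], float)) for d in payload]


# ---------------------------------------------------------------------------
# trajectories (CSV: track_id, t, x_um, y_um)
# ---------------------------------------------------------------------------

def write_trajectories(trajectories: list[Trajectory], path: str | Path) -> None:
    frames = []
    for i, tr in enumerate(trajectories):
        frames.append(
            pd.DataFrame(
                {
                    "track_id": i,
                    "t": tr.times,
                    "x_um": tr.positions[:, 0],
                    "y_um": tr.positions[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path)
    out = []
    for _, g in df.groupby("track_id", sort=True):
        g = g.sort_values("t")
        out.append(Trajectory(g["t"].to_numpy(), g[["x_um", "y_um"]].to_numpy()))
    return out


# ---------------------------------------------------------------------------
# study tables (CSV with declared schema)
# ---------------------------------------------------------------------------

_STUDY_COLUMNS = [
    "subject",
    "group",
    "pre_mm3",
    "post_mm3",
    "injected_MBq",
    "injected_t_s",
    "voi_MBq",
    "voi_t_s",
    "half_life_s",
    "tumour_cm3",
]


def write_study_table(records: list[SubjectRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "subject": r.subject_id,
                "group": r.group,
                "pre_mm3": r.pre_volume_mm3,
                "post_mm3": r.post_volume_mm3,
                "injected_MBq": r.injected_activity.activity_mbq if r.injected_activity else None,
                "injected_t_s": r.injected_activity.time_s if r.injected_activity else None,
                "voi_MBq": r.voi_activity.activity_mbq if r.voi_activity else None,
                "voi_t_s": r.voi_activity.time_s if r.voi_activity else None,
                "half_life_s": r.voi_activity.half_life_s if r.voi_activity else None,
                "tumour_cm3": r.tumour_volume_cm3,
            }
        )
    pd.DataFrame(rows, columns=_STUDY_COLUMNS).to_csv(path, index=False)


def read_study_table(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        def _act(mbq_col: str, t_col: str) -> ActivityMeasurement | None:
            if pd.isna(row.get(mbq_col)) or pd.isna(row.get("half_life_s")):
                return None
            return ActivityMeasurement(
                float(row[mbq_col]), float(row[t_col]), float(row["half_life_s"])
            )

        records.append(
            SubjectRecord(
                subject_id=str(row["subject"]),
                group=str(row["group"]),
                pre_volume_mm3=None if pd.isna(row.get("pre_mm3")) else float(row["pre_mm3"]),
                post_volume_mm3=None if pd.isna(row.get("post_mm3")) else float(row["post_mm3"]),
                injected_activity=_act("injected_MBq", "injected_t_s"),
                voi_activity=_act("voi_MBq", "voi_t_s"),
                tumour_volume_cm3=None
                if pd.isna(row.get("tumour_cm3"))
                else float(row["tumour_cm3"]),
            )
        )
    return records
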