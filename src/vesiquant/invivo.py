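"""In vivo quantification arithmetic.

Decay-corrected radioactivity (%ID and %ID cm⁻³), radiochemical yield,
diffusion-weighted MRI ratio volumetry, normalized tumour volume (NTV)
therapy readouts and the standard group statistics that accompany them.

Decay correction uses the base-2 half-life form A₀ = A · 2^(t/T½), which is
exact at whole numbers of half-lives.  NTV divides each subject's
post-treatment volume by the mean pre-treatment volume of its group, making
group trajectories comparable despite different starting sizes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import (
    ActivityMeasurement,
    DWIPair,
    GeometryError,
    Mask3D,
    SubjectRecord,
    VoxelVolume,
)

__all__ = [
    "decay_correct",
    "percent_id",
    "percent_id_per_cm3",
    "radiochemical_yield",
    "dwi_ratio_image",
    "mask_volume",
    "ntv",
    "percent_reduction_vs_control",
    "group_compare",
]


def decay_correct(m: ActivityMeasurement) -> float:
    """Activity (MBq) back-corrected to the reference time: A₀ = A·2^(t/T½)."""
    return m.activity_mbq * 2.0 ** (m.time_s / m.half_life_s)


def percent_id(voi: ActivityMeasurement, injected: ActivityMeasurement) -> float:
    """Percentage of the injected dose found in a volume of interest.

    Both measurements are decay-corrected to the common reference time
    before taking the ratio, so the result does not depend on when either
    was read out.
    """
    inj0 = decay_correct(injected)
    if inj0 <= 0:
        raise ValueError("injected activity must be positive")
    return 100.0 * decay_correct(voi) / inj0


def percent_id_per_cm3(pid: float, tumour_volume_cm3: float) -> float:
    """%ID normalized per cm³ of (MRI-derived) tumour volume."""
    if tumour_volume_cm3 <= 0:
        raise ValueError("tumour volume must be positive")
    return pid / tumour_volume_cm3


def radiochemical_yield(retained_mbq: float, initial_mbq: float) -> float:
    """Percent of the initial activity retained on the particles after washing."""
    if initial_mbq <= 0:
        raise ValueError("initial activity must be positive")
    if retained_mbq > initial_mbq:
        warnings.warn("retained activity exceeds initial: yield above 100%")
    return 100.0 * retained_mbq / initial_mbq


def dwi_ratio_image(pair: DWIPair, gaussian_sigma: float = 0.7) -> VoxelVolume:
    """Diffusion-weighted over baseline ratio image, Gaussian-smoothed.

    Voxels where the baseline is ~zero are set to 0 (with a warning giving
    their count) so the output is always finite.  ``gaussian_sigma`` is in
    voxel units per axis (σx = σy = σz), the convention of the original
    postprocessing; pass 0 to skip smoothing.
    """
    b0 = np.asarray(pair.b0.data, dtype=float)
    bdw = np.asarray(pair.b_dw.data, dtype=float)
    eps = 1e-12
    bad = np.abs(b0) <= eps
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-baseline voxels set to 0 in ratio image")
    ratio = np.where(bad, 0.0, bdw / np.where(bad, 1.0, b0))
    if gaussian_sigma > 0:
        ratio = ndimage.gaussian_filter(ratio, sigma=gaussian_sigma)
    return VoxelVolume(ratio, pair.b0.spacing)


def mask_volume(mask: Mask3D) -> float:
    """Volume of a mask in mm³ (voxel count × physical voxel volume)."""
    n = mask.count()
    if n == 0:
        warnings.warn("empty mask: volume 0")
        return 0.0
    return n * mask.voxel_volume_um3 * 1e-9


def ntv(records: list[SubjectRecord]) -> pd.DataFrame:
    """Normalized tumour volume per subject, with group mean ± s.e.m.

    NTV_i = post_i / mean(pre-treatment volumes of subject i's group).
    Returns a tidy frame with one row per subject (columns ``subject``,
    ``group``, ``pre_mm3``, ``post_mm3``, ``ntv``) plus group-level
    ``group_mean_ntv`` and ``group_sem_ntv`` columns.
    """
    rows = [
        r for r in records if r.pre_volume_mm3 is not None and r.post_volume_mm3 is not None
    ]
    if not rows:
        raise ValueError("no records with both pre and post volumes")
    df = pd.DataFrame(
        {
            "subject": [r.subject_id for r in rows],
            "group": [r.group for r in rows],
            "pre_mm3": [r.pre_volume_mm3 for r in rows],
            "post_mm3": [r.post_volume_mm3 for r in rows],
        }
    )
    pre_means = df.groupby("group")["pre_mm3"].transform("mean")
    if (pre_means <= 0).any():
        raise ValueError("a group has non-positive mean pre-treatment volume")
    df["ntv"] = df["post_mm3"] / pre_means
    grp = df.groupby("group")["ntv"]
    df["group_mean_ntv"] = grp.transform("mean")
    df["group_sem_ntv"] = grp.transform(lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0)
    return df


def percent_reduction_vs_control(ntv_treated: float, ntv_control: float) -> float:
    """Percent tumour-volume reduction of a treated group versus control."""
    if ntv_control <= 0:
        raise ValueError("control NTV must be positive")
    return 100.0 * (1.0 - ntv_treated / ntv_control)


def group_compare(
    values_by_group: dict[str, np.ndarray],
    method: str = "t_test_two_tailed_unpaired",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Standard group comparisons: unpaired two-tailed t-test or ANOVA+Tukey.

    For the t-test exactly two groups are required; ``equal_var=False``
    switches to Welch's form.  ``anova_tukey`` runs a one-way ANOVA over
    all groups followed by Tukey's HSD for each pair.  Returns one row per
    comparison with statistic, degrees of freedom and p-value.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for k, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs n ≥ 2")

    if method == "t_test_two_tailed_unpaired":
        if len(groups) != 2:
            raise ValueError("the t-test compares exactly two groups")
        (ka, va), (kb, vb) = groups.items()
        res = stats.ttest_ind(va, vb, equal_var=equal_var)
        df_ = (
            len(va) + len(vb) - 2
            if equal_var
            else float(res.df)  # Welch–Satterthwaite
        )
        return pd.DataFrame(
            [
                {
                    "comparison": f"{ka} vs {kb}",
                    "test": "t (pooled)" if equal_var else "t (Welch)",
                    "statistic": float(res.statistic),
                    "df": df_,
                    "p_value": float(res.pvalue),
                }
            ]
        )

    if method == "anova_tukey":
        names = list(groups)
        f_res = stats.f_oneway(*groups.values())
        n_total = sum(len(v) for v in groups.values())
        rows = [
            {
                "comparison": "one-way ANOVA",
                "test": "F",
                "statistic": float(f_res.statistic),
                "df": f"({len(groups) - 1}, {n_total - len(groups)})",
                "p_value": float(f_res.pvalue),
            }
        ]
        tk = stats.tukey_hsd(*groups.values())
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append(
                    {
                        "comparison": f"{names[i]} vs {names[j]}",
                        "test": "Tukey HSD",
                        "statistic": float(tk.statistic[i, j]),
                        "df": "",
                        "p_value": float(tk.pvalue[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    raise ValueError(f"unknown method {method!r}")
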