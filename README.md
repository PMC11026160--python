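# vesiquant

Quantification pipeline for studies of urease-powered nanobots in bladder
tumours.  It implements, as a tested and reusable Python library, the image
and data analyses such a study needs:

- **3D mask construction** for whole-organ light-sheet stacks: sparse
  planar ROI annotations interpolated into 3D masks (shape-based, signed
  distance blending), physical-distance dilation/erosion on anisotropic
  voxel grids, plane-streamed Boolean mask algebra, and concentric 33 µm
  tissue layers built by successive dilation of the bladder-cavity mask
  (L_k = BC_{k+1} − BC_k, tumour layers TL_k = L_k − healthy annotation,
  healthy layer HL = L₁ − tumour annotation).
- **Scattered-signal quantification**: integrated intensity normalized by
  layer volume, 16-bit masked voxel histograms (linear/log axes),
  Otsu-based signal detection, median penetration depth and occupancy,
  and lateral-resolution estimation by 2D Gaussian fitting.
- **Swarm-motion metrics**: ROI pixel-intensity histogram series at 15 s
  intervals with spread (SD/IQR) readouts, and mean-square-displacement
  analysis of tracer tracks with a `MSD = 4 D τ^α` power-law fit.
- **In vivo arithmetic**: radioactive decay correction
  (`A₀ = A · 2^(t/T½)`), %ID and %ID cm⁻³, radiochemical yield, DW-MRI
  ratio images (b>0 / b=0, 3D Gaussian σ = 0.7) and tumour volumetry,
  normalized tumour volume (NTV = post / group mean pre) with percent
  reduction versus control, and standard group statistics (unpaired
  two-tailed t-test, one-way ANOVA + Tukey).
- **A seeded synthetic phantom** supplying every input with ground truth:
  a two-channel cleared-bladder volume (layered wall, tumour cap, PSF-blurred
  speckle-noised nanobot puncta whose density decays as exp(−depth/λ)),
  tracer trajectories, DWI pairs and grouped therapy tables.

Everything runs on synthetic data; no external datasets are required.

## Worked example

```python
from vesiquant import build_layers, layer_profile
from vesiquant.phantom import PhantomSpec, generate_bladder_phantom, phantom_masks

# default conditions: 4:1 tumour:healthy surface density, λ = 95 µm decay
spec = PhantomSpec(seed=1)
af, scattered, truth = generate_bladder_phantom(spec)

m = phantom_masks(truth)
layers = build_layers(m["bc"], urothelium=m["u1"], tumour=m["t1"])  # 3 × 33 µm
profile = layer_profile(scattered, layers)
print(profile["ratios"])
```

prints

```
{'TL1_over_HL': 3.6313314594165127, 'TL3_over_TL1': 0.5382709635523759}
```

i.e. the volume-normalized scattered intensity at the tumour surface layer
is ≈ 3.6× that of the healthy urothelium (configured truth: 4× surface
density, biased slightly toward 1 by the intensity baseline), and the
intensity in the third 33 µm layer is ≈ 0.54× the first — the ≈ 50 % drop
expected from exp(−66 µm / 95 µm) ≈ 0.50.

Therapy-efficacy arithmetic works straight from group tables:

```python
from vesiquant import ntv, percent_reduction_vs_control
from vesiquant.phantom import generate_study_table

folds = {"non-treated": 2.45, "high-dose-urea": 0.27}
records = generate_study_table(
    [{"group": g, "n": 9, "mean_pre_mm3": 10, "fold_change": f, "dispersion": 0.0}
     for g, f in folds.items()])
means = ntv(records).groupby("group")["ntv"].mean()
print(percent_reduction_vs_control(means["high-dose-urea"], means["non-treated"]))
# 88.9795918367347  -> a ~90 % tumour-volume reduction vs non-treated
```

The full pipeline (phantom → masks → layers → histograms → penetration →
MSD → DWI → NTV, with a checksummed run manifest) is one call or one
command:

```sh
vesiquant run --seed 1 --out results/demo
```

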