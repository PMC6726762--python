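# quantafm

Automated quantification of DNA filaments and mono-nucleosomes in atomic
force microscopy (AFM) images.

AFM topographs of surface-deposited nucleosome samples show DNA as thin
bright filaments and nucleosome cores as bright disks riding on them.
From flattened 8-bit topographs, `quantafm` extracts per object:

- the **contour length** of free DNA molecules (nm),
- the apparent **nucleosome radius** *r* (nm) — roughly twice the
  crystallographic 5.5 nm because of AFM tip broadening,
- the **opening angle** *θ* ∈ [0°, 180°] between the two DNA arms at the
  core entry/exit site,
- the two **protruding-arm contour lengths** (nm), and from them
- the **DNA wrapping length** *l*<sub>w</sub> (bp) and the
  **positioning ratio** sa-ratio<sub>c</sub> ∈ [0, 0.5].

It is intended for biophysicists comparing nucleosome conformation across
conditions (e.g. linker histone H1 binding, histone mutations), where
hundreds of objects per class must be measured reproducibly.

## Method

The per-image pipeline follows a classical segmentation/tracing design:

1. **Denoising** — non-local means, then mean/median filtering and an
   anisotropic frequency-domain low-pass that suppresses horizontal
   scan-line stripes.
2. **Segmentation** — two-pass Otsu thresholding: an initial binarization,
   *background equalization* (bright contaminations larger than any DNA
   object are reset to the mean background intensity), a second Otsu pass,
   and an object-area filter.
3. **Tracing** — each object is thinned to a unit-width skeleton; the
   backbone is the maximum-weight simple path between skeleton endpoints
   (axial steps weigh 1, diagonal √2).  Contour length uses the Kulpa
   estimator

   *L* = (0.948 · *n*<sub>axial</sub> + 1.340 · *n*<sub>diagonal</sub>) · nm/px,

   plus a correction for the length the thinning erodes at each free end.
4. **Detection** — nucleosome candidates via a circular Hough transform
   (radii 8.5–14.0625 nm), matched uniquely to filaments by Euclidean
   vicinity; filaments with two or more candidates are excluded as
   ambiguous.  The skeleton is cut at the detected circle, yielding two
   protruding arms and the opening angle.
5. **Quantification** — each arm is corrected for tip broadening by adding
   (*r* − 5.5 nm); the wrapping length is

   *l*<sub>w</sub> = (⟨free DNA⟩ − short<sub>c</sub> − long<sub>c</sub>) / (nm/bp),

   with nm/bp calibrated from the free-DNA mean contour (0.34 nm/bp for
   B-DNA); positioning is sa-ratio<sub>c</sub> = short<sub>c</sub> /
   (short<sub>c</sub> + long<sub>c</sub>).  Class comparison uses
   Shapiro–Wilk gating into t-test/ANOVA + Tukey or Mann–Whitney /
   Kruskal–Wallis + Dunn (Bonferroni).

A fully seeded synthetic-scene generator (worm-like-chain filaments,
tip-broadened Gaussian cores, stripe/blob/Gaussian noise) provides ground
truth for every stage; see `docs/methods.md`.

## Worked example

```python
from quantafm import PipelineConfig, generate_scene, run_pipeline
from quantafm.synthetic import NoiseParams

scene = generate_scene(n_filaments=5, n_nucleosomes=3,
                       theta_deg=[45.0, 90.0, 135.0],
                       noise=NoiseParams(background_sigma=6), seed=1)
res = run_pipeline(scene.image, PipelineConfig())
for r in res.records:
    if r.object_kind == "free_dna":
        print(f"free DNA   length {r.total_length_nm:6.1f} nm")
    else:
        print(f"nucleosome r {r.radius_nm:4.1f} nm  theta {r.theta_deg:5.1f} deg"
              f"  arms {r.short_arm_nm:4.1f}/{r.long_arm_nm:4.1f} nm"
              f"  l_w {r.lw_bp:5.1f} bp  sa {r.sa_ratio_c:.3f}")
```

prints (seed 1):

```
nucleosome r  9.8 nm  theta  80.3 deg  arms 50.9/59.1 nm  l_w 116.9 bp  sa 0.465
free DNA   length  157.1 nm
nucleosome r  9.8 nm  theta  43.2 deg  arms 52.2/56.4 nm  l_w 121.0 bp  sa 0.482
free DNA   length  160.9 nm
nucleosome r  9.8 nm  theta 142.7 deg  arms 51.5/60.8 nm  l_w 109.9 bp  sa 0.462
free DNA   length  155.7 nm
free DNA   length  158.6 nm
free DNA   length  156.0 nm
```

The three rendered nucleosomes (true θ = 90°, 45°, 135°; true arms
50/58 nm) and the five 157.8 nm filaments are all recovered; the detected
radii ≈ 9.8 nm sit in the tip-broadened band around 2 × 5.5 nm, and the
near-central sa-ratios reflect the nearly symmetric arm design.

From a shell, the same pipeline runs as:

```sh
quantafm synth --n-scenes 3 --seed 1 --out scenes/
quantafm run --images scenes/ --out results/records.csv
quantafm summarize --records results/records.csv
```

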