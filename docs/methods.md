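# Methods

This note documents the models, parameter choices and numerical decisions
behind `quantafm`, and what the synthetic-scene tests do and do not
demonstrate about real AFM data.

## Input model

Images are flattened 8-bit grayscale height maps; higher intensity means
taller topography.  Pixel calibration is a configuration scalar
(default 2000 nm / 1024 px = 1.953125 nm/px, a 2 μm scan at 1024×1024)
rather than being read from TIFF tags, because vendor exports are
inconsistent about resolution metadata.  Deeper bit depths are rescaled
linearly so the maximum maps to 255; this assumes per-image min–max
z-scaling, the common export convention.  No plane or line flattening is
performed — inputs are assumed already flattened.

## Preprocessing

Two optional stages, each individually switchable:

- **Non-local means** (patch 5 px, search window 13 px).  The filter
  strength h defaults to 1.15 × the background noise scale, estimated as
  the normal-consistent median absolute deviation of the whole image —
  robust because DNA and particles cover a small area fraction.
- **Mean (3 px) → median (3 px) → low-pass.**  The low-pass is a
  frequency-domain Gaussian applied to *vertical* spatial frequency only
  (half-power at 0.35 × Nyquist by default): scan-line stripe artifacts
  are horizontal rows, i.e. energy at high vertical frequencies, while
  leaving horizontal detail untouched.

All stages preserve shape and the [0, 255] range.

## Segmentation

Otsu's threshold is computed on the 256-bin histogram with the foreground
defined as intensity strictly above the threshold; ties break toward the
lower level.  Contaminations are handled by *background equalization*:
connected components of the first-pass mask whose area exceeds the
maximum-object bound are reset to the mean background intensity, together
with any region above the background level (8-bit 90 by default) touching
them; the threshold is then recomputed.  Removing bright outliers can
only lower (never raise) the second-pass optimum on such scenes.

The object-area window derives from geometry when not set explicitly:
minimum = 25 % of a minimal free-DNA footprint (lower contour bound × 2 px
width), maximum = 4 × the footprint of a nucleosome-bearing fragment.
8-connectivity is used throughout so diagonal one-pixel filaments stay
connected.  Border-touching objects are retained but QC-flagged.

## Tracing

Objects are thinned with a homotopic unit-width skeletonization.  The
skeleton is an 8-adjacency pixel graph (axial weight 1, diagonal √2); the
backbone is the maximum-weight simple path between two degree-1 nodes.
The search condenses degree-2 chains into weighted edges between
endpoints/junctions and enumerates simple paths exhaustively in the
condensed multigraph.  Two safeguards keep worst cases bounded: skeletons
condensing to more than 40 special nodes, or searches exceeding 300 000
expansions, fall back to a double-sweep Dijkstra diameter (exact on
trees).  Such entangled skeletons only arise from noise clusters, which
the QC flags exclude from statistics anyway.

Contour length uses the Kulpa estimator, 0.948 per axial and 1.340 per
diagonal step — the standard coefficients minimizing digitization bias;
on digitized 300-px straight lines at 0°–90° the mean relative error is
under 2.5 %.  Thinning erodes each free end by about the local
half-width; the correction adds, per end, (EDT − 1) px, where EDT is the
distance from the endpoint to the nearest background pixel
(center-to-center).  For a 3-px-wide bar this recovers ~1 px per end and
exactly 0 for a one-pixel-wide path.  Backbones covering less than 80 %
of the total skeleton weight are flagged "branched" and excluded from
free-DNA statistics (nucleosome objects legitimately branch at the core).

## Nucleosome detection and geometry

Candidates come from a circular Hough transform over Canny edges
(σ = 2 px) with per-radius normalized accumulators, search radii
8.5–14.0625 nm.  The sensitivity s ∈ (0, 1) maps to an accumulator
threshold of 5 × (1 − s): at the default s = 0.93 a candidate needs about
35 % of a complete rim, and raising s only ever adds candidates.  Because
curved filament segments also vote for small circles, a candidate must
additionally be tall: the median intensity within half a radius of its
center must reach 150 (between the ~120 filament ridge and the ~220 core
peak).  Surviving candidates keep a minimum mutual spacing of one minimum
search radius.  An optional sweep runs s = 0.90/0.93/0.96 and keeps
candidates stable in at least two settings.

Matching to filaments uses the distance from the candidate center to the
nearest object pixel (≤ radius + 2 px).  Filaments attracting two or more
candidates are excluded wholesale — multi-nucleosome arrays are out of
scope and would corrupt arm statistics.

Arms are obtained by deleting skeleton pixels strictly inside the
candidate circle; the two largest remaining components incident to the
rim are ordered from their entry point outward along the geodesic to
their farthest pixel (robust to the spurious triangles 8-adjacency
creates).  Arm length = Kulpa length + end correction at the free end.

**Opening angle.**  Two estimators are provided.
`fit_opening_angle` fits a total-least-squares line to the first
`angle_fit_px` (default 5 ≈ 10 nm) pixels of each arm, oriented away from
the core; it carries a `theta_inverted` flag (both fitted directions in
the same half-plane along the entry-to-entry vector) that the
quantification stage resolves as 180° − θ.  The pipeline, however, uses
`opening_angle_vertex`: the angle subtended at the detected core center
by the mean positions of the two arm windows (up to 2 × `angle_fit_px`
pixels, skipping the first `angle_fit_px // 2`).  The reason is
systematic: inside the zone where the tip-broadened core merges with the
arm roots, the skeleton is a medial-axis artifact, and an entry-anchored
line fit is biased by +10–15° at small opening angles.  The vertex
construction — the same geometry as a manual angle-tool measurement
anchored on the core — is insensitive to this distortion; on rendered
scenes it recovers θ within ±10° for ~98 % of objects versus ~73 % for
the pure line fit.

## Quantification

- Arm correction: arm + (r − 5.5 nm), with r the detected (apparent)
  radius and 5.5 nm the known core radius; apparent radii run ≈ 2× the
  true radius due to tip convolution.  Radii below 5.5 nm give a negative
  correction and a QC flag.
- Wrapping length: l_w = (⟨free DNA⟩ − short_c − long_c) / (nm/bp),
  using the class-level mean free-DNA contour (not per-object totals) and
  the calibration nm/bp = ⟨free DNA⟩ / fragment bp.  Values are kept as
  floats; rounding to integer bp happens only in reports.  Negative l_w
  is flagged "over_extended", not dropped.
- Positioning: sa-ratio_c = short_c / (short_c + long_c) ∈ (0, 0.5];
  misordered arms are swapped and flagged.
- Validity: nucleosome records must have an arm-sum contour inside the
  configured window (default 65–155 nm for the 464 bp design) and none of
  the structural-abnormality flags; positioning analyses additionally
  require sa-ratio_c ≥ 0.3.  The two filter stages are applied
  separately so angle/wrapping statistics keep records that the
  positioning cut removes.

Summaries report mean ± sd (n − 1), median with a distribution-free 95 %
CI from binomial order statistics (the bootstrap alternative was rejected
for determinism), and probability-normalized histograms (θ in 15° bins
with the 180° value in the right-closed last bin; l_w 60–225 bp in 15-bp
bins; sa-ratio_c in 0.01 bins; arms in 10-nm bins).

Group comparison: Shapiro–Wilk per group at α = 0.05; all normal →
t-test (2 groups) or one-way ANOVA with Tukey HSD; otherwise
Mann–Whitney U or Kruskal–Wallis with Dunn's post test.  Dunn p-values
are Bonferroni-adjusted — Dunn's original proposal — with the usual
tie-corrected variance N(N+1)/12 − Σ(t³−t)/(12(N−1)).

## Synthetic scenes

The generator emulates the study conditions rather than arbitrary images:

- **Filaments**: 2-D worm-like chains, persistence 50 nm (dsDNA), equal
  2-nm steps with Gaussian turning angles of variance step/persistence,
  arc length exact by construction; self-intersecting draws are rejected.
  Default contour 157.8 nm (a 464 bp fragment at 0.34 nm/bp).
- **Nucleosomes**: Gaussian disks (peak ≈ 220) whose half-maximum radius
  equals 2 × 5.5 nm, directly encoding the tip-broadening artifact; the
  wrapped DNA inside the core is not rendered (unresolvable in real
  data).  Arms (defaults 50 and 58 nm) leave the apparent rim along exit
  directions separated by the requested θ, straight for the first 12 nm
  (the scale of the angle-fit window) and worm-like beyond.
- **Filament rendering**: Gaussian-profile ridges, FWHM 3 px, peak ≈ 120,
  over a background of 30.
- **Nuisance**: i.i.d. Gaussian background noise (σ = 6 by default),
  optional random per-row stripe offsets, optional bright blob
  contaminations (super-Gaussian, radius 15–40 px, peak 240).
- Layout keeps ≥ 20 px between object bounding disks; scenes regenerate
  bit-exactly from their seed.

What passing synthetic tests shows: the pipeline recovers geometry it was
pointed at — ≥ 90 % core detection with zero false pairings, contour
lengths within 5 %, opening angles within ±10° — under noise, stripes and
contaminations of realistic magnitude.  What it does not show: robustness
to real-world effects the generator omits — tip-shape asymmetry and
double-tip artifacts, height-dependent broadening, molecule overlap and
aggregation, surface adsorption anisotropy, and drift.  Real detection
rates will sit below the synthetic ones (the clean-scene rates here are
upper bounds, and the acceptance thresholds are set accordingly above the
rates reported for real data).

Default problem sizes in the test suite (scene counts, image sizes,
replicate counts) were chosen to exercise every code path at a few
minutes of total runtime; the end-to-end recovery suite uses twenty
1024² scenes of eight objects each.

## Known limitations

- Multi-nucleosome arrays are excluded by design (uniqueness rule).
- Overlapping or touching molecules are not disentangled; they fail QC.
- The opening angle of nearly closed (θ → 0) conformations is limited by
  the merge of the two arms at the core; below ~30° arms frequently fuse
  into a single skeleton branch and the object is flagged `single_arm`.
- Hough detection assumes disk-like cores; strongly elongated particles
  (e.g. aggregates) score poorly and are treated as filament material.
- z-scale (height) information is used only qualitatively (the intensity
  gate); no volume estimation is attempted.
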