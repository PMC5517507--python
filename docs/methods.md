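# Methods

## The measurement problem

En-face (C-scan) OCT reslices a 3D raster of the posterior pole into coronal
sections 2.6 µm apart (1,000 sections over a 2.6 mm tissue depth, 12 × 9 mm
laterally). Paging through the sections from anterior to posterior, the
Bruch's-membrane/choroid interface appears as a hyper-reflective island that
shrinks and finally disappears; the last section carrying the island is the
deepest point of the eyeball (DPE). The package automates that observer
procedure, measures the DPE's position relative to the optic disc and the
fovea, measures the disc's own configuration (ovality, torsion, tilt), and
runs the cohort statistics — all against synthetic phantoms whose ground
truth is known exactly.

## Conventions

All lateral geometry lives in a right-eye canonical frame: origin at the
fovea, +x temporal, +y superior, millimetres; left eyes are mirrored about
the vertical field axis on ingestion. Depth is positive-posterior in
micrometres from the most anterior rendered section (section 0). Signed
angles are *inferior-positive* from the temporal horizontal meridian: the
fovea sits at a small positive disc-fovea angle (2–6° inferior to the disc),
an inferior-hemisphere DPE has a positive disc-DPE angle, and inferotemporal
torsion is positive. This sign convention is fixed by requiring the
angle-addition identity (torsion = disc-DPE angle − disc-fovea angle) and
the group-level signs of published series to come out right; descriptions of
the rotational sense as clockwise/counterclockwise depend on display
orientation and are not normative.

## Phantom model

The globe wall is a smooth depth surface
`z(x, y) = −sag_R(x, y) + A·exp(−|p − c|² / 2σ²)`:

- `sag_R` — spherical cap of radius *R* tangent at the fovea. The default
  cohort draws *R* ≈ 60 ± 8 mm, much flatter than an anatomical globe,
  because the scanner software partially flattens the geometry and a full
  12-mm-radius cap would not fit the 2.6 mm axial span of the stack; the
  residual curvature is what the depth signal rides on.
- the Gaussian bump (amplitude *A* µm, width σ mm) is the staphyloma-like
  localized elongation that places the DPE away from the tangency point.
  Multi-bump composites are accepted by the renderer (any object with a
  `depth_um` method); the deepest point is always the defined truth.

The optic disc is a circle of radius *r* drawn *in* a locally tilted plane:
its en-face projection is an ellipse foreshortened by cos(tilt) along the
downhill direction, margin depths span `2r·sin(tilt)`, and the same plane
offset is imprinted into the rendered surface strictly inside the margin
(the peripapillary Bruch's membrane stays on the smooth wall, producing the
step a tilted nerve head shows against its surroundings). Ground truth per
eye — DPE position/depth (dense-grid argmax at 10 µm resolution over the
composite surface), torsion, ovality, horizontal/vertical tilt — comes from
closed forms, a route fully independent of the measurement code.

Rendering: for each pixel the hyper-reflective band occupies the
`band_sections` (default 8 ≈ 21 µm, an RPE/BM-complex thickness) sections
ending at the rasterized interface depth; dim retina lies anterior, darker
choroid posterior (relative reflectivities 0.25 / 0.90 / 0.45 of a 30,000
uint16 scale). Speckle is multiplicative Gaussian (default SD 0.15) — the
simplest model giving the granular en-face texture without claiming OCT
physics. Band thickness matters: a band thinner than the per-pixel depth
jump inside a tilted disc aliases into disconnected slivers at reduced
rasters; 8 sections keeps the imprint contiguous at half resolution.

What the phantom does *not* emulate: A-scan interference physics,
attenuation and shadowing, choroidal vasculature texture, eye-motion
artifacts, RPE-flattening of real scans (deliberately omitted — flattening
would erase the depth signal the method reads; how the clinical software
combines flattening with depth measurement is not documented), or a BM
opening (the disc interior renders as tilted band rather than a hole).
Passing tests therefore demonstrate the *procedure* is correct and robust to
speckle/fixation noise, not that it handles every real-scan pathology.

## Detection

1. **Threshold.** The band is the brightest tissue but occupies only
   `band/n_sections` of voxels, so Otsu-style class splits latch onto the
   retina/choroid modes. Instead two robust anchors set the cut: the volume
   median (background) and the median of the per-pixel maximum projection
   (band — every pixel column crosses the interface once); the threshold is
   their midpoint, computed after the same despeckle smoothing segmentation
   uses. If the maximum projection never rises above background the volume
   has no interface and detection errors out.
2. **Per-section mask.** Each section is Gaussian-smoothed (σ = 0.8 px); a
   pixel is band signal if the smoothed value clears the threshold *or* the
   raw value clears 1.25× the threshold (keeps structures thinner than the
   smoothing kernel). A 3×3 closing (erosion with the outside treated as
   foreground, so the field border is not shaved) fills speckle pinholes and
   regions below 0.05 mm² are removed — the clinical cue is an island, not
   stray bright pixels.
3. **Depth map.** Per pixel, the largest section index whose mask contains
   it; never-segmented pixels are missing (>50 % missing raises the
   `low_contrast` flag).
4. **DPE.** The deepest section of the 3×3-median-smoothed depth map; the
   center is the intensity-weighted centroid of the island in that section.
   Ties go posterior (sections) and to the largest area (islands, flagged
   `multiple_regions`); near-flat maps flag `low_relief`.

## Measurements

Distances are in-plane Euclidean (µm) at the DPE's coronal plane; depths are
exact section-count differences times the 2.6 µm pitch, signed positive when
the DPE lies posterior to the reference interface (temporal disc border for
the disc-DPE depth — sampled 0.75 px inside the clinical margin so the pixel
snap stays on the disc side — and the foveal interface for the fovea-DPE
depth). Ovality is LD/SD from a direct least-squares conic fit of the margin
points (Halir–Flusser, data normalized; written in-package because the
available library fitter is numerically unstable on exact ellipses).
Torsion is the long axis' deviation from the image vertical minus the
disc-fovea angle, wrapped to (−90°, 90°]; below ovality 1.02 the long-axis
orientation is numerically meaningless, so torsion reports 0 with
`torsion_defined = False`. Tilt angles are chord-vs-chord per the clinical
protocol: margin-point interface chord (ONH plane) against the depth map
sampled 0.3 mm outside the margin on each side (BM inner tips; samples
falling off the raster are clamped to the field edge, where the wall is
smooth), along the disc-fovea axis (horizontal, temporal-down positive) and
its perpendicular (vertical, inferior-down positive).

Classification: near-fovea within 3,000 µm of the fovea (inclusive), else
near-disc within 3,000 µm of the disc center, else superior/inferior by the
extended fovea-disc line (on-line ties go inferior). Near-fovea precedes
near-disc when both radii cover a point; with discs ≥ 4 mm from the fovea
the overlap is empty anyway.

## Cohort simulation

Group weights 40:125 (emmetropic:myopic out of 165), covariate
distributions (age, SE, axial length, RNFL, CCT, visual-field MD, sex,
laterality) and DPE-location category weights (22.5/7.5/22.5/47.5 % vs
31.2/5.6/43.2/20.0 %) follow the published series; axial length and
spherical equivalent are truncated to the group-definition thresholds
(AL > 24 mm & SE < −2 D vs AL < 24 mm & SE > 0.5 D; the published
emmetropic SE mean actually straddles its own threshold, so the truncated
simulated mean is higher), and draws beyond 30 mm axial length are
resampled. Bump amplitude is larger and AL-coupled in the myopic group
(≈250 ± 90 µm + 25 µm per mm of AL above 24) and smaller in the emmetropic
group (≈120 ± 50 µm) — chosen so measured disc-DPE depths land in the
published ranges. The disc plane tilts toward the bump (±10° azimuth
jitter); tilt magnitude is drawn per group and then capped so that the
ONH-plane dip plus the bump's own tail never out-deepens the bump peak —
this both keeps the planted bump the true DPE and reproduces the empirical
coupling between tilt and disc-DPE depth. Near-disc bumps keep ≥ 1.5 mm from
the disc center: a staphyloma apex on the nerve head itself would ride the
ONH step rather than the globe wall.

Left eyes (drawn at the published right:left rates) are stored mirrored;
truth manifests stay canonical. Re-scans rerun the renderer on the same
anatomy with fresh speckle and a lateral fixation offset (default SD
0.05 mm — small because the scanner's eye tracking re-centers on the fovea)
applied to the whole anatomy and the reported landmarks.

## Statistics

ICC is the consistency-type two-way mixed model (Shrout–Fleiss ICC(3,1) and
ICC(3,k)) computed from the ANOVA decomposition, with F-based 95 % CIs;
the error sum of squares is taken from the residual matrix (not by
subtraction) so perfect agreement yields exactly 1. The absolute-agreement
variant was the open alternative; consistency was chosen because the two
series share one caliper protocol, and the independent-oracle tests pin the
choice against pingouin's ICC(C,1)/ICC(C,k). Group comparisons use the
independent t-test for two groups and both one-way ANOVA and Kruskal–Wallis
for the four DPE-location groups; χ² is Pearson's without continuity
correction (the SPSS default the source tables reflect). Regressions screen
every candidate univariately and fit the multivariate OLS on survivors at
P < 0.2 (the stated rule; a table footnote in the source says P < 0.05 — the
text rule is implemented), reporting β with 95 % CIs and flagging collinear
survivor sets by design-matrix condition number instead of dropping terms.

## Problem sizes and numerical choices

The default scanner geometry (512 × 384 × 1,000, 23.4 µm pixels) is used
wherever a tolerance is stated in native pixels or sections (noiseless
recovery, segmentation Dice); simulation-heavy studies run at half or
quarter lateral resolution with proportionally reduced section counts, which
leaves all angle- and ratio-valued checks comfortably inside their
tolerances. Unit tests use a 128 × 96 raster. Other fixed choices: rendering
places the shallowest surface point 150 µm into the slab; rasterized
interface depths round to the nearest section; the dense-grid truth argmax
uses a 10 µm step; torsion definedness needs ovality ≥ 1.02; the minimum
island area is 0.05 mm²; pipeline outputs are byte-deterministic for a fixed
config seed (every stage draws from seeds spawned off it).

## Known limitations

- The sharp imprint step at the disc margin is a simplification; real tilted
  nerve heads blend into the peripapillary wall, so measured tilt against
  truly dragged BM tips would read lower than our chord measurement.
- At coarse rasters (≥ 90 µm pixels) the tilted-disc band aliases; disc-edge
  depth lookups there rely on the nearest-valid-pixel fallback.
- The detector's working range ends around speckle SD ≈ 0.4 at coarse
  rasters (spurious deep islands); the default level is 0.15.
- Cohort covariates are drawn independently within groups except for the
  amplitude–AL and tilt–depth couplings; correlation-structure analyses on
  simulated cohorts reflect only those two links.
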